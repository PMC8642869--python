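"""Posterior preterm-preeclampsia risk for one woman.

Builds a maternal profile, attaches first-trimester biomarker MoMs, and
shows how the competing-risks posterior updates the history-only prior.
"""

from pescreen import MaternalProfile, MoMSet, default_parameters, posterior_preterm_risk

params = default_parameters()

# A 36-year-old parous woman with preeclampsia in a previous pregnancy
profile = MaternalProfile(
    age=36.0,
    weight=78.0,
    height=156.0,
    parity_class="parous_previous_pe",
)

# History alone: the prior mass of the delivery-with-PE age below 37 weeks
prior_only = posterior_preterm_risk(profile, MoMSet({}), params)
print(f"history alone:      risk {prior_only.preterm_pe_probability:.4f} "
      f"({prior_only.one_in_n})")

# Add reassuring biomarkers (normal MAP/UtAPI, PlGF a little high)
good = MoMSet.from_moms({"MAP": 1.00, "UtAPI": 0.95, "PAPPA": 1.10, "PlGF": 1.20})
r = posterior_preterm_risk(profile, good, params)
print(f"reassuring markers: risk {r.preterm_pe_probability:.4f} ({r.one_in_n})")

# Add worrying biomarkers (raised MAP/UtAPI, low PAPP-A and PlGF)
bad = MoMSet.from_moms({"MAP": 1.10, "UtAPI": 1.60, "PAPPA": 0.45, "PlGF": 0.40})
r = posterior_preterm_risk(profile, bad, params)
print(f"worrying markers:   risk {r.preterm_pe_probability:.4f} ({r.one_in_n})")

print("\nA risk at or above 1:100 classifies the pregnancy as high risk for "
      "preterm PE; markers can move the same history prior in either direction.")
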