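"""Classifying one participant under all four EWGSOP2 reference standards.

Sarcopenia is confirmed when muscle strength (handgrip or five-times
sit-to-stand) AND muscle quantity (appendicular mass or muscle index) are
both low for the participant's sex.  The same person can be sarcopenic under
one criterion combination and healthy under another — the overlap between
combinations is known to be modest.
"""

from sarcscreen import ParticipantRecord, SarcopeniaCriterion, sarcopenia_reference, frailty_phenotype

record = ParticipantRecord(
    participant_id="P042",
    sex="female",
    age_years=74,
    height_m=1.54,
    weight_kg=61.0,
    handgrip_kg=15.2,   # below the 16 kg cutoff for women
    fivests_s=14.2,     # not above the 15 s cutoff
    asm_kg=12.8,        # below the 15 kg cutoff for women
    smi_kg_m2=12.8 / 1.54**2,  # 5.40, below the 5.5 kg/m^2 cutoff
    frailty_criteria=dict(
        slowness=True, exhaustion=True, weight_loss=False,
        weakness=True, low_activity=False,
    ),
)

for criterion in SarcopeniaCriterion:
    label = sarcopenia_reference(record, criterion)
    print(f"{criterion.label:10s} -> {'sarcopenic' if label else 'healthy'}")

frail, count = frailty_phenotype(record)
print(f"\nFried phenotype: {count}/5 criteria -> {'frail' if frail else 'not frail'}")
print("\nLow grip + low ASM/SMI flags her under both handgrip-based standards;")
print("her 5STS time is under 15 s, so the 5STS-based standards call her healthy.")
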