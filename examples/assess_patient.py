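"""Assess a few patient records with the initial expert rule base.

Each record is (ARTUL, RTT, MAMS): active resistance torque in N*m,
rehabilitation training time, and mean muscle-strength amplitude.  The
model prints the aggregated belief over health grades I-IV (I = best
recovery), the expected utility on the 1-4 scale, and the discrete grade.
"""

from brb_rehab import assess, initial_expert_rulebase

brb = initial_expert_rulebase()

patients = [
    (4.0, 5.0, 5.0),    # all attributes at their lowest referential value
    (6.0, 7.5, 9.0),    # between referential values: several rules fire
    (12.0, 15.0, 11.0), # all attributes at their highest referential value
]

for x in patients:
    r = assess(x, brb)
    beliefs = ", ".join(
        f"{label}: {b:.3f}" for label, b in zip(brb.grade_labels, r.belief)
    )
    print(f"ARTUL={x[0]:5.1f} RTT={x[1]:5.1f} MAMS={x[2]:5.1f}  ->  "
          f"[{beliefs}]  utility={r.utility:.3f}  grade={brb.grade_labels[r.grade - 1]}")

print("\nThe utility is the belief-weighted mean of the grade utilities {1,2,3,4};")
print("the discrete grade is the one whose utility is nearest.")
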