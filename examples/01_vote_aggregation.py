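"""Aggregate two experts' labels of one mixed independent component.

One expert sees many activity types in the component, the other only a
clear brain pattern.  Majority voting keeps every mentioned class above
the 0.33 threshold; probabilistic voting splits the first expert's single
vote four ways and keeps only Brain.
"""

from eegic import Annotation, build_label_matrix, majority_vote, \
    probabilistic_vote

table = [
    Annotation("ic1", "splitter", {"Eyes", "Muscle", "Heart", "Brain"}),
    Annotation("ic1", "purist", {"Brain"}),
]
matrix = build_label_matrix(table, classes=["Brain", "Eyes", "Muscle",
                                            "Heart"])

for name, strategy in (("majority", majority_vote),
                       ("probabilistic", probabilistic_vote)):
    agg = strategy(matrix, threshold=0.33)
    probs = agg.probabilities.loc["ic1"]
    kept = list(agg.targets.columns[agg.targets.loc["ic1"]])
    print(f"{name:>13} vote: "
          + ", ".join(f"{cls}={p:.3f}" for cls, p in probs.items())
          + f"  ->  classes kept: {kept}")

print("\nThe probabilistic vote dilutes the splitter's four-way annotation"
      "\n(0.25 each), so only Brain (0.625) clears the 0.33 threshold.")
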