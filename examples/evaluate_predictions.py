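"""Score a ranked edge list against a gold standard: edge classification
with indirect-effect errors and the dual precision-recall curve.

Uses a tiny hand-built example: the true network is the chain a -- b -- c,
and the predictions include one indirect error (a -- c, whose endpoints
share the common neighbor b) and one unrelated error (b -- d).
"""

from dekernet import GoldStandard, classify_edges, pr_curves

gold = GoldStandard(
    true_edges=frozenset({("a", "b"), ("b", "c")}),
    feature_names=("a", "b", "c", "d"),
)
ranked = [("a", "b", 0.9), ("a", "c", 0.5), ("b", "d", 0.1)]

cls = classify_edges({(a, b) for a, b, _ in ranked}, gold)
print(f"TP={cls.n_tp}  indirect FP={len(cls.indirect_false_positives)}  "
      f"other FP={len(cls.other_false_positives)}  FN={len(cls.false_negatives)}")

print("kept  recall  precision(incl)  precision(excl)")
for kept, recall, p_incl, p_excl in pr_curves(ranked, gold).points:
    print(f"{kept:4d}  {recall:6.2f}  {p_incl:15.2f}  {p_excl:15.2f}")

# Each curve point removes the lowest-ranked edge. Excluding indirect errors
# from the precision denominator never changes recall and can only raise
# precision — the gap between the two columns is the indirect-error share.
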