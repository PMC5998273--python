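"""Survey-tool accuracy from a reading-vs-titration contingency table.

Uses the cell counts of a three-analyst external validation study (1,704
card readings of 568 cards) to compute how often the card separates
adequately iodized salt (>= 15 ppm I) from inadequately iodized salt, and
a hand-made example of the ROC machinery.
"""

from saltcard import stats

# titration rows: <10, 10-15, >=15 ppm; card columns: <15, >=15 ppm
counts = [[290, 22], [150, 24], [96, 1122]]
table = stats.ContingencyTable.from_counts(
    counts, ("<10", "10-15", ">=15"), ("<15", ">=15")
)
correct = {"<10": {"<15"}, "10-15": {"<15"}, ">=15": {">=15"}}

print(table.to_frame(), "\n")
print(f"total readings              : {table.total}")
under = stats.contingency_accuracy(table, correct, rows=("<10", "10-15"))
print(f"under-iodized correct       : {100 * under:.1f}%  (n=486)")
adequate = stats.contingency_accuracy(table, correct, rows=(">=15",))
print(f"adequately iodized correct  : {100 * adequate:.1f}%  (n=1218)")
border = stats.contingency_accuracy(table, correct, rows=("10-15",))
print(f"borderline 10-15 ppm correct: {100 * border:.0f}%  (n=174)")

# ROC on a small synthetic score set: one discordant pair out of 16
scores = [1, 2, 3, 5, 4, 6, 7, 8]
labels = [False] * 4 + [True] * 4
roc = stats.roc_curve(scores, labels)
print(f"\nROC example: AUC = {roc.auc:.4f} (15/16 = {15 / 16:.4f})")
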