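"""Quality-control classification and fortification process actions.

Kenya's regulations require 30-50 ppm I at the time of production; at the
iodization line a technician raises the spray rate below 32 ppm and lowers
it above 46 ppm. This script shows the band/action classifiers, the
QC contingency accuracy of a validation study, the count-weighted
action-match aggregate of a fortification-plant usability study, and the
sample-prep dilution arithmetic.
"""

from saltcard import quantify, stats

print("ppm    QC band   action")
for ppm in (25.0, 30.0, 31.5, 40.0, 46.5, 50.0, 55.0):
    print(f"{ppm:5.1f}  {stats.classify_qc(ppm):<8}  {stats.process_action(ppm)}")

# QC accuracy table of the same 1,704 readings (rows = titration category)
counts = [[996, 24, 0], [292, 209, 15], [13, 62, 93]]
table = stats.ContingencyTable.from_counts(
    counts, ("<30", "30-50", ">50"), ("<30", "30-50", ">50")
)
diag = {r: {r} for r in table.row_labels}
print(f"\nQC categorization correct : "
      f"{100 * stats.contingency_accuracy(table, diag):.1f}% of {table.total}")
print(f"under-30 called sellable  : {100 * counts[0][1] / table.total:.1f}% of all readings"
      f"  ({100 * counts[0][1] / sum(counts[0]):.1f}% of the under-30 readings)")

# fortification-line study: 14 grab samples in three action categories
rate = stats.action_match_rate([0.33, 0.83, 0.86], [2, 5, 7])
print(f"card-driven actions match titration-driven: {100 * rate:.0f}%")

# sample prep: 3.25 g salt + 15.00 g water, brine density ~1.123 g/mL
factor = quantify.dilution_factor(3.25, 15.00, 1.123)
print(f"dilution factor solution mg/L -> solid ppm: {factor:.2f}")
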