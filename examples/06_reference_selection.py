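"""Class A-F reference-motif selection on the full synthetic study.

Every candidate motif is scored by AUROC (top peaks vs dinucleotide
shuffles) on both peak sets; the ordered decision rules then pick one
reference motif per protein with a confidence class.
"""

from motifbench import SimConfig, generate_study
from motifbench.pipeline import CompareParams, compare_study

study = generate_study(SimConfig(seed=7))
report = compare_study(study, CompareParams(seed=7, similarity_n=20_000))

print("protein  chosen motif         class  best test AUROC")
for r in report.reference.results:
    print(
        f"{r.protein:8s} {r.chosen[0]:20s} {r.selection_class:5s} "
        f"{r.best_test_auroc:.3f}"
    )
print()
print(f"class counts: {report.class_counts()}")
print(f"median test AUROC per class: {report.median_auroc_per_class()}")
print(
    "Class A means one motif predicted held-out peaks with AUROC at least "
    "0.1 above every competitor — here the planted true motif."
)
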