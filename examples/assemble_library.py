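"""From deconvolved assignments to an ordered library with statistics.

Maps placed insertions to ORFs, keeps up to three mutants per gene (most
upstream first), flags the consolidated representative, and reports
stratified coverage plus the redundancy-accuracy expectation.
"""

import tnarray as tn
from tnarray.assembly import AccuracyModel, redundancy_counts, total_mutants

design = tn.build_design(5, 5, 8, 12)
ref = tn.generate_reference(n_genes=150, seed=2)
placement = tn.simulate_picking(ref, design, 2400, duplicate_rate=0.2, seed=4)
matrix = tn.simulate_pool_counts(placement, design, tn.NoiseModel(seed=11))
assignments = tn.assignments_frame(tn.deconvolve(matrix, design), matrix)

manifest = tn.build_collection(assignments, ref.genes, max_redundancy=3)
counts = redundancy_counts(manifest)
print("genes by redundancy:", counts, "-> mutant entries:", total_mutants(counts))

report = tn.coverage_report(manifest["gene_id"], ref.genes)
print(report[["orfs_hit", "orfs_missing", "total", "pct_hit"]])

shares = {k: v / sum(counts.values()) for k, v in counts.items()}
model = AccuracyModel(40 / 53)  # per-mutant accuracy from re-sequencing 53 mutants
print(
    "expected fraction of genes correctly represented:",
    f"{tn.expected_accuracy(model, shares):.2f}",
)
# Coverage is highest for non-essential genes; the consolidated flag marks
# the most-upstream insertion per gene, the best bet for a full knockout.
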