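"""How many mutants must be picked to saturate the genome?

Builds a small synthetic annotation, compares the Monte Carlo coverage
estimator against the closed-form expectation, and inverts the curve for
the pick count reaching 99% expected ORF coverage.
"""

import tnarray as tn

ref = tn.generate_reference(n_genes=50, seed=17)
genes, G = ref.genes, ref.genome_length
print(f"synthetic genome: {G:,} bp, {len(genes)} genes")

for n in (10, 100, 1000):
    est = tn.simulate_coverage(genes, G, n, reps=1000, seed=23)
    analytic = tn.expected_coverage_analytic(genes, G, n)
    print(
        f"n={n:5d}  MC coverage {est.mean_coverage:.4f} +- {est.stderr:.4f}"
        f"  analytic {analytic:.4f}"
    )

n99 = tn.mutants_for_target(genes, G, target=0.99)
print(f"picks for >=99% expected ORF coverage: {n99}")
# The MC mean tracks the closed form within a few standard errors; the
# inverted count is the smallest n whose expected coverage clears the target.
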