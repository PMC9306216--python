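"""Planted-truth bookkeeping: score the classifier against the generator.

Simulates genomes with known per-vitamin capabilities at two annotation
dropout levels and scores the producer calls against the planted truth.
At zero dropout recovery is exact; with dropout d, a producer survives a
single-variant pathway with probability prod over roles of (1 - d^k),
where k is the role's KO count — printed here next to the observed recall.
"""

from vitacap import make_kb, predict_capability, simulate_genomes

kb = make_kb(seed=1, n_vitamins=1, roles_per_variant=3,
             variants_per_vitamin=1, kos_per_role=2)

for dropout in (0.0, 0.1, 0.3):
    planted = recovered = 0
    for seed in range(10):
        genomes, truth = simulate_genomes(
            kb, 200, {"THI": 0.5}, dropout=dropout, seed=seed
        )
        for g in genomes:
            if truth.capability[g.genome_id]["THI"]:
                planted += 1
                recovered += predict_capability(g, kb).verdicts["THI"].producer
    analytic = (1 - dropout**2) ** 3
    print(f"dropout {dropout:.1f}: recall {recovered / planted:.3f} "
          f"(analytic survival {analytic:.3f}, n={planted})")

print("\nObserved recall tracks the analytic KO-retention probability: "
      "annotation dropout, not the rule engine, is what loses producers.")
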