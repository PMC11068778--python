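"""Build, validate and score a residual-disease gene signature.

Simulates three labeled expression datasets (e.g. three cell-line models)
sharing 25 planted up-regulated genes in the "RD" class, defines the
signature as the intersection of significantly up-regulated genes, checks
it with a label-permutation set test, and scores single cells.
"""

from dtpkit import (
    SimExpressionTruth,
    build_intersection_signature,
    gen_labeled_expression,
    per_gene_tstat,
    permutation_set_test,
    score_cells,
)

genes = [f"gene_{i:04d}" for i in range(500)]
planted = genes[:25]

tables = {}
datasets = {}
for seed, name in enumerate(["model_A", "model_B", "model_C"]):
    truth = SimExpressionTruth(
        n_cells_per_class={"RD": 60, "nonRD": 60},
        genes=genes,
        signature_genes=planted,
        target_class="RD",
        effect_size=1.5,
        seed=seed,
    )
    datasets[name] = gen_labeled_expression(truth)
    tables[name] = per_gene_tstat(datasets[name], target="RD")

signature = build_intersection_signature(tables, alpha=0.05)
print(f"signature: {len(signature)} genes up-regulated in all three models")
print(f"planted genes recovered: {len(set(signature.genes) & set(planted))}/25")

res = permutation_set_test(datasets["model_A"], signature, target="RD", B=999, seed=1)
print(f"set statistic (mean t) = {res.t_obs:.2f}, permutation p = {res.p:.4g}")

scores = score_cells(datasets["model_A"], signature)
labels = datasets["model_A"].obs["label"]
print(
    f"mean per-cell score: RD = {scores[(labels == 'RD').to_numpy()].mean():.3f}, "
    f"nonRD = {scores[(labels == 'nonRD').to_numpy()].mean():.3f}"
)
# RD cells score visibly higher on the intersection signature; the
# permutation p (~1/(B+1)) says the set-level enrichment is not a label
# artifact.
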