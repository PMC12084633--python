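#!/usr/bin/env python
"""Uniqueness index: rank cell-specific splicing and check planted recovery.

Also computes the expression uniqueness index on the matched count matrix
and verifies that the planted unique genes top their cells' rankings.
"""

import pandas as pd

import neurosplice as ns
from _common import RESULTS, SCRATCH

results = pd.read_csv(SCRATCH / "pairwise_results.tsv", sep="\t")
truth = pd.read_csv(SCRATCH / "sim" / "truth_events.tsv", sep="\t")

table = ns.uniqueness_table(results)
ranked = table.assign(score=table["index"].abs()).sort_values("score", ascending=False)
ranked.head(20).drop(columns="score").to_csv(
    RESULTS / "uniqueness_top20.tsv", sep="\t", index=False, float_format="%.3f")

planted = truth.dropna(subset=["planted_cell"])
top = set(map(tuple, ranked.head(2 * len(planted))[["event_id", "cell_type"]].to_numpy()))
recovered = sum((r.event_id, r.planted_cell) in top for r in planted.itertuples())
print(f"planted-event recovery: {recovered}/{len(planted)} in the top "
      f"{2 * len(planted)} |index| ranks")
print(ranked.head(8)[["event_id", "cell_type", "event_type", "index", "n_significant"]]
      .to_string(index=False))

# expression side
expr = pd.read_csv(SCRATCH / "sim" / "expression.tsv", sep="\t", index_col=0)
gene_truth = pd.read_csv(SCRATCH / "sim" / "truth_genes.tsv", sep="\t")
expr_results = ns.run_all_pairs_expression(expr)
expr_table = ns.expression_uniqueness_table(expr_results)
expr_ranked = expr_table.assign(score=expr_table["index"].abs()).sort_values(
    "score", ascending=False)
expr_ranked.head(10).drop(columns="score").to_csv(
    RESULTS / "expression_uniqueness_top10.tsv", sep="\t", index=False, float_format="%.2f")
hits = 0
for r in gene_truth.itertuples():
    sub = expr_ranked[expr_ranked["cell_type"] == r.planted_cell]
    hits += bool(len(sub) and sub.iloc[0]["gene_id"] == r.gene_id)
print(f"planted-gene recovery: {hits}/{len(gene_truth)} top-ranked in their cell")
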