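#!/usr/bin/env python
"""Global summaries: type-count correlations, outlier cells, PCA.

Writes the cross-type adjusted-R^2 summary, per-type outlier flags, the
introns-per-gene histogram and the PCA variance profile to results.
"""

import json

import pandas as pd

import neurosplice as ns
from _common import RESULTS, SCRATCH

events = ns.read_event_table(SCRATCH / "sim" / "events.tsv")
results = pd.read_csv(SCRATCH / "pairwise_results.tsv", sep="\t")
psi = ns.read_psi_matrix(SCRATCH / "psi_matrix.tsv")

tcm = ns.count_significant_events(results, min_events=1)
tcm.cell_totals.to_csv(RESULTS / "cell_type_totals.tsv", sep="\t")

corr = ns.cross_type_correlation_summary(tcm)
corr.to_csv(RESULTS / "cross_type_correlation.tsv", sep="\t", index=False,
            float_format="%.4f")

outliers = {t: ns.detect_outlier_cells(tcm, t) for t in ns.EVENT_TYPES}
pd.DataFrame(
    [{"event_type": t, "outlier_cells": ",".join(cells) or "-"}
     for t, cells in outliers.items()]
).to_csv(RESULTS / "outlier_cells.tsv", sep="\t", index=False)
print("outlier cells per splice type:", json.dumps(outliers))

per_gene, hist = ns.introns_per_gene_histogram(results)
pd.Series(hist, name="n_genes").rename_axis("n_retained_introns").to_frame().to_csv(
    RESULTS / "introns_per_gene.tsv", sep="\t")
print("introns-per-gene histogram:", hist)

usage = ns.build_usage_matrix(psi)
meta = ns.events_to_frame(events)
coords, var = ns.pca_psi(usage, meta, "combined")
share = (var / var.sum())[:5]
pd.DataFrame({"component": [f"PC{i+1}" for i in range(5)],
              "variance_share": share.round(4)}).to_csv(
    RESULTS / "pca_variance.tsv", sep="\t", index=False)
print("PCA variance share (first 5 PCs):", [round(float(s), 3) for s in share])
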