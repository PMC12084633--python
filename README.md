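# neurosplice

Cell-type-resolved alternative splicing analysis: quantify percent spliced
in (PSI) from junction-spanning reads, call differential splicing across
every pair of cell types, and aggregate the significant differences into a
per-(event, cell) **uniqueness index** that pinpoints isoforms specific to
a single cell type.

The package is aimed at transcriptomics of sorted cell populations with
biological replicates — the motivating design is a nervous-system-wide
panel of 46 neuron types with 3–4 replicates each — where deep, uniform
coverage makes junction-level splicing quantification possible even for
lowly expressed genes.

## What it computes

For each splicing event (cassette exon, alternative 5'/3' splice site,
intron retention, mutually exclusive exons, or composite):

1. **PSI per replicate**: `psi = inclusion / (inclusion + exclusion)` from
   junction read counts, missing below 5 supporting reads.
2. **Pairwise differential splicing** for all N·(N−1) ordered cell-type
   comparisons: ΔPSI = mean PSI difference, Welch test on
   arcsine-sqrt-transformed PSIs (exact permutation for tiny designs), BH
   q-values per (pair, type) family; significant iff `p < 0.05`,
   `q < 0.05` and `|ΔPSI| > 10%`.
3. **Uniqueness index** for event *e* in cell *c*:

       U(e, c) = Σ_o oriented ΔPSI(c, o)   over significant comparisons o

   with splice-site deltas oriented so that the upstream choice in
   transcript coordinates is positive (A3S on +, A5S on − reverse sign).
   Bounded by ±(N−1): 45 in a 46-cell panel means 100% inclusion in *c*
   and 0% everywhere else; 0 means no systematic difference.
4. **Consequences**: retained introns classified frameshift / stop /
   neither by reading-frame arithmetic and stop-codon scanning; splice-site
   spacings and frame preservation.
5. **Global summaries**: per-type significant-event counts, cross-type
   adjusted-R² correlations, robust (median/MAD) outlier-cell detection,
   introns-per-gene histograms, PCA of standardized PSI matrices.
6. The same aggregation applied to DESeq-style log2 fold changes gives an
   **expression uniqueness index**, with a pan-neuronal variant restricted
   to genes expressed in ≥ 123 of 126 cell types.

A fully seeded synthetic-data generator (`neurosplice.simulate`) produces
junction counts and expression matrices with planted cell-unique events, a
planted splice-type-biased outlier cell, and ground-truth labels, so the
whole pipeline is benchmarked end to end.

## Worked example

```python
import neurosplice as ns

cfg = ns.SimulationConfig(seed=1)            # 46 cells x 4 reps, 300 events
ds  = ns.generate_splicing_dataset(cfg)
psi = ns.compute_psi_table(ds.counts, ds.events)
res = ns.run_all_pairs(psi, ds.events)       # 2070 ordered comparisons
tab = ns.uniqueness_table(res)
print(tab.assign(score=tab["index"].abs())
         .sort_values("score", ascending=False)
         .head(5)[["event_id", "cell_type", "index", "n_significant"]])
```

prints

```
  event_id cell_type      index  n_significant
0  EV00274       N42  26.217817             45
1  EV00278       N06  25.925303             45
2  EV00025       N25  23.706793             45
3  EV00217       N34  23.542056             45
4  EV00166       N23  22.456373             44
```

— exactly the five planted cell-unique events for this seed, each
significantly different from (nearly) all 45 other cell types with a
summed ΔPSI of 22–26. An index of 26.2 for EV00274 in N42 reads as "the
inclusion level in N42 differs from the other cells by an average ΔPSI of
~0.58 across 45 significant comparisons."

The same pipeline is packaged as numbered drivers under `analysis/`
(simulate → quantify → pairwise → uniqueness → consequences → summaries),
which write small summary tables to `results/tables/` and their bulky
intermediates to `scratch/`. A `neurosplice` CLI exposes each stage
(`neurosplice run --out DIR --seed 1`).

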