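#!/usr/bin/env python
"""Quantify PSI from junction counts and classify event usage.

Reads scratch/analysis/sim, writes the replicate-level PSI matrix to
scratch and the alternative / near-constitutive breakdown to results.
"""

import pandas as pd

import neurosplice as ns
from _common import RESULTS, SCRATCH

events = ns.read_event_table(SCRATCH / "sim" / "events.tsv")
counts = ns.read_junction_counts(SCRATCH / "sim" / "junction_counts.tsv")

psi = ns.compute_psi_table(counts, events, junction_threshold=5)
ns.write_psi_matrix(psi, SCRATCH / "psi_matrix.tsv")

usage = ns.build_usage_matrix(psi)
status = ns.classify_usage(usage)
breakdown = status.value_counts().rename_axis("status").to_frame("n_events")
breakdown.to_csv(RESULTS / "event_status.tsv", sep="\t")

n_missing = int(psi["psi"].isna().sum())
print(f"quantified {int(psi['psi'].notna().sum())} PSI entries "
      f"({n_missing} below the 5-read junction threshold)")
print(breakdown)
ns.write_vista_export(usage, SCRATCH / "vista_export.tsv")
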