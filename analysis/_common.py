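"""Shared paths and the study-design configuration for the analysis scripts.

Bulky intermediates (junction counts, PSI matrices, full pairwise tables)
live under ``scratch/analysis`` and are regenerated by re-running the
scripts in order; only small summary tables are kept under ``results``.
"""

from pathlib import Path

import neurosplice as ns

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results" / "tables"

SEED = 20250920

#: the study design: 46 cell types x 4 replicates, 300 events at depth 100,
#: 5 planted cell-unique events and one upstream-biased outlier cell
CONFIG = ns.SimulationConfig(seed=SEED)

for d in (SCRATCH, RESULTS):
    d.mkdir(parents=True, exist_ok=True)
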