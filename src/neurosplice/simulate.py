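"""Synthetic multi-cell-type junction-count and expression datasets.

The generator emulates the statistical structure of deep sorted-population
RNA-seq across a nervous system: many cell types (default 46), a few
biological replicates each (default 4), and junction-spanning read counts
per splicing event.  The model is deliberately minimal:

* each event draws a baseline inclusion level ``psi_e ~ Beta(alpha, beta)``
  shared by every cell type;
* per replicate, sequencing depth for the event is ``Poisson(mean_depth)``
  and inclusion reads are ``Binomial(depth, psi)`` (optionally
  Beta-Binomial with overdispersion ``rho`` to mimic extra
  between-replicate variability);
* *planted cell-unique events* move one cell's PSI by ``planted_delta``
  toward the farther bound (clamped to [0, 1]) -- these are the ground
  truth for recovery benchmarks of the uniqueness index;
* an optional *outlier cell* shifts every alternative-3'-splice-site event:
  a configured fraction (default 83%) toward the upstream choice in
  transcript orientation and the remainder toward the downstream choice,
  planting a splice-type-specific outlier;
* event types are drawn from a fixed mix dominated by intron retention,
  with both strands represented.

Matched gene-expression counts are Negative Binomial with lognormal gene
means, +/-20% size factors, and planted unique genes whose mean is scaled
by ``2**delta`` in a single cell type.

Everything is a pure function of the integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import Thresholds
from .errors import ConfigError
from .events import (
    SplicingEvent,
    write_event_table,
    write_junction_counts,
)

# Type mix of differential splicing: intron retention dominates (~52%),
# followed by alternative 5' (27%) and 3' (11%) splice sites; the remaining
# mass is split among cassette, MXE and composite events, normalized to 1.
_RAW_MIX = {
    "IR": 0.52,
    "A5S": 0.27,
    "A3S": 0.11,
    "cassette": 0.07,
    "MXE": 0.015,
    "composite": 0.035,
}
_MIX_TOTAL = sum(_RAW_MIX.values())
DEFAULT_TYPE_MIX: dict[str, float] = {k: v / _MIX_TOTAL for k, v in _RAW_MIX.items()}

_CHROMS = ("chrI", "chrII", "chrIII", "chrIV", "chrV")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic dataset; the defaults define the study design."""

    n_cells: int = 46
    replicates_per_cell: int | tuple[int, ...] = 4
    n_events: int = 300
    type_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    mean_depth: float = 100.0
    baseline_psi_alpha: float = 2.0
    baseline_psi_beta: float = 2.0
    n_planted_unique: int = 5
    planted_delta: float = 0.6
    outlier_cell: str | None = "auto"  # "auto" = last cell label, None = no outlier
    upstream_bias: float = 0.83
    outlier_shift: float = 0.3
    beta_binomial: bool = False
    overdispersion_rho: float = 0.02
    n_genes: int = 200
    n_planted_genes: int = 3
    expression_log2_delta: float = 3.0
    nb_dispersion: float = 0.1
    size_factor_range: float = 0.2
    mean_expression: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_events < 1:
            raise ConfigError("n_cells and n_events must be positive")
        if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("type_mix fractions must sum to 1")
        if unknown := set(self.type_mix) - set(_RAW_MIX):
            raise ConfigError(f"unknown event types in type_mix: {sorted(unknown)}")
        if not (0.0 < self.planted_delta <= 1.0):
            raise ConfigError("planted_delta must lie in (0, 1]")
        if not (0.0 < self.outlier_shift <= 1.0):
            raise ConfigError("outlier_shift must lie in (0, 1]")
        if not (0.0 <= self.upstream_bias <= 1.0):
            raise ConfigError("upstream_bias must lie in [0, 1]")
        if self.n_planted_unique > self.n_events:
            raise ConfigError("cannot plant more unique events than events")
        reps = self.replicates_per_cell
        if isinstance(reps, int):
            if reps < 1:
                raise ConfigError("replicates_per_cell must be >= 1")
        else:
            if len(reps) != self.n_cells or any(r < 1 for r in reps):
                raise ConfigError("per-cell replicate list must match n_cells, all >= 1")

    @property
    def cells(self) -> list[str]:
        return [f"N{i + 1:02d}" for i in range(self.n_cells)]

    @property
    def replicate_counts(self) -> np.ndarray:
        reps = self.replicates_per_cell
        if isinstance(reps, int):
            return np.full(self.n_cells, reps, dtype=int)
        return np.asarray(reps, dtype=int)

    def resolved_outlier(self) -> str | None:
        if self.outlier_cell is None:
            return None
        if self.outlier_cell == "auto":
            return self.cells[-1]
        if self.outlier_cell not in self.cells:
            raise ConfigError(f"outlier cell {self.outlier_cell!r} not among cell labels")
        return self.outlier_cell


@dataclass
class SyntheticDataset:
    events: list[SplicingEvent]
    counts: pd.DataFrame  # long junction-count table
    expression: pd.DataFrame  # genes x "cell.rep" columns
    truth_events: pd.DataFrame
    truth_genes: pd.DataFrame
    size_factors: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_event_table(self.events, outdir / "events.tsv")
        write_junction_counts(self.counts, outdir / "junction_counts.tsv")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        self.truth_events.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
        self.truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.size_factors.to_csv(outdir / "size_factors.tsv", sep="\t", index=False)


def _make_event(i: int, etype: str, gene: str, rng: np.random.Generator) -> SplicingEvent:
    chrom = _CHROMS[i % len(_CHROMS)]
    strand = "+" if rng.random() < 0.5 else "-"
    s = 1000 + 2000 * i
    # short alternative splice-site spacing, mixing frame-preserving and not
    dist = int(rng.choice([3, 6, 9, 12, 1, 2, 4, 5, 7, 8, 10, 15]))
    eid = f"EV{i + 1:05d}"
    if etype == "cassette":
        raw = [(s, s + 200), (s + 300, s + 500), (s, s + 500)]
        inc_raw = {0, 1}
    elif etype == "IR":
        raw = [(s, s + 50), (s + 150, s + 200), (s, s + 200)]
        inc_raw = {0, 1}
    elif etype == "A3S":
        raw = [(s, s + 100), (s, s + 100 + dist)]
        inc_raw = {0}
    elif etype == "A5S":
        raw = [(s, s + 200), (s + dist, s + 200)]
        inc_raw = {0}
    elif etype == "MXE":
        raw = [(s, s + 100), (s, s + 250)]
        inc_raw = {0}
    else:  # composite: cassette nested with an alternative 3' acceptor on the skip
        raw = [(s, s + 200), (s + 300, s + 500), (s, s + 500), (s, s + 500 + dist)]
        inc_raw = {0, 1}
    order = sorted(range(len(raw)), key=lambda k: raw[k])
    junctions = tuple(raw[k] for k in order)
    inclusion = tuple(sorted(order.index(k) for k in inc_raw))
    return SplicingEvent(eid, gene, chrom, strand, etype, junctions, inclusion)


def generate_splicing_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a full synthetic junction-count dataset with planted truth."""
    rng = np.random.default_rng(config.seed)
    cells = config.cells
    reps = config.replicate_counts
    R = int(reps.max())
    E, C = config.n_events, config.n_cells
    outlier = config.resolved_outlier()

    types = list(config.type_mix)
    type_of = rng.choice(types, size=E, p=[config.type_mix[t] for t in types])
    n_genes_pool = max(1, int(E * 0.85))
    gene_of = [f"G{g + 1:05d}" for g in rng.integers(0, n_genes_pool, size=E)]
    events = [_make_event(i, type_of[i], gene_of[i], rng) for i in range(E)]
    strands = np.array([e.strand for e in events])

    base_psi = rng.beta(config.baseline_psi_alpha, config.baseline_psi_beta, size=E)
    psi = np.tile(base_psi[:, None], (1, C))  # (E, C)

    # planted cell-unique events: shift toward the farther bound
    planted_cells = np.full(E, "", dtype=object)
    planted_dir = np.zeros(E, dtype=int)
    eligible_cells = [c for c in cells if c != outlier]
    if config.n_planted_unique > 0:
        if not eligible_cells:
            raise ConfigError("no eligible cells to plant unique events in")
        idx = rng.choice(E, size=config.n_planted_unique, replace=False)
        for e in idx:
            cell = eligible_cells[int(rng.integers(len(eligible_cells)))]
            ci = cells.index(cell)
            direction = 1 if base_psi[e] <= 0.5 else -1
            psi[e, ci] = float(np.clip(base_psi[e] + direction * config.planted_delta, 0.0, 1.0))
            planted_cells[e] = cell
            planted_dir[e] = direction

    # outlier cell: shift every A3S event, mostly toward upstream selection.
    # "Upstream" is transcript orientation; the PSI here tracks the
    # genomically-first acceptor, whose oriented sign flips on the + strand,
    # so an upstream-biased shift lowers PSI on + and raises it on -.
    outlier_dir = np.full(E, "", dtype=object)
    if outlier is not None:
        oi = cells.index(outlier)
        a3s = np.flatnonzero(type_of == "A3S")
        up = rng.random(a3s.size) < config.upstream_bias
        for k, e in enumerate(a3s):
            upstream = bool(up[k])
            sign_up = -1 if strands[e] == "+" else 1
            direction = sign_up if upstream else -sign_up
            psi[e, oi] = float(np.clip(psi[e, oi] + direction * config.outlier_shift, 0.0, 1.0))
            outlier_dir[e] = "up" if upstream else "down"

    # read counts: Poisson depth, (Beta-)Binomial inclusion
    depth = rng.poisson(config.mean_depth, size=(E, C, R))
    p_rep = np.broadcast_to(psi[:, :, None], (E, C, R)).copy()
    if config.beta_binomial:
        rho = config.overdispersion_rho
        a = np.clip(p_rep, 1e-9, 1 - 1e-9) * (1 - rho) / rho
        b = (1 - np.clip(p_rep, 1e-9, 1 - 1e-9)) * (1 - rho) / rho
        p_rep = rng.beta(a, b)
    inc = rng.binomial(depth, p_rep)
    exc = depth - inc

    # composite exclusion reads split between the two skip acceptors so that
    # their mean reproduces the exclusion evidence exactly
    comp_w = rng.beta(2.0, 2.0, size=E)

    frames = []
    rep_mask = np.zeros((C, R), dtype=bool)
    for ci in range(C):
        rep_mask[ci, : reps[ci]] = True
    cell_idx, rep_idx = np.nonzero(rep_mask)
    n_cr = cell_idx.size
    cell_labels = np.array(cells)[cell_idx]
    for e_i, ev in enumerate(events):
        inc_e = inc[e_i, cell_idx, rep_idx]
        exc_e = exc[e_i, cell_idx, rep_idx]
        nj = len(ev.junctions)
        counts_by_junction = np.empty((nj, n_cr), dtype=int)
        exc_slots = ev.exclusion_junction_index
        if ev.event_type == "composite":
            skip1 = rng.binomial(2 * exc_e, comp_w[e_i])
            skip2 = 2 * exc_e - skip1
            for j in ev.inclusion_junction_index:
                counts_by_junction[j] = inc_e
            counts_by_junction[exc_slots[0]] = skip1
            counts_by_junction[exc_slots[1]] = skip2
        else:
            for j in range(nj):
                counts_by_junction[j] = inc_e if j in ev.inclusion_junction_index else exc_e
        frames.append(
            pd.DataFrame(
                {
                    "event_id": ev.event_id,
                    "cell_type": np.tile(cell_labels, nj),
                    "replicate": np.tile(rep_idx + 1, nj),
                    "junction_index": np.repeat(np.arange(nj), n_cr),
                    "count": counts_by_junction.reshape(-1),
                }
            )
        )
    counts = pd.concat(frames, ignore_index=True)

    truth_events = pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "gene_id": gene_of,
            "event_type": type_of,
            "strand": strands,
            "baseline_psi": base_psi,
            "planted_cell": [c if c else pd.NA for c in planted_cells],
            "planted_direction": planted_dir,
            "outlier_direction": [d if d else pd.NA for d in outlier_dir],
        }
    )

    expression, truth_genes, size_factors = generate_expression_dataset(config)
    return SyntheticDataset(
        events=events,
        counts=counts,
        expression=expression,
        truth_events=truth_events,
        truth_genes=truth_genes,
        size_factors=size_factors,
        config=config,
    )


def generate_expression_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-Binomial gene counts with planted cell-unique genes.

    Returns ``(matrix, truth, size_factors)`` where ``matrix`` is genes x
    ``cell.rep`` columns.  Uses a seed stream independent of the splicing
    draw so both halves are reproducible in isolation.
    """
    rng = np.random.default_rng([config.seed, 17])
    cells = config.cells
    reps = config.replicate_counts
    genes = [f"G{g + 1:05d}" for g in range(config.n_genes)]
    G = config.n_genes

    mu = rng.lognormal(mean=math.log(config.mean_expression), sigma=1.2, size=G)
    planted = rng.choice(G, size=config.n_planted_genes, replace=False)
    planted_cell_idx = rng.choice(config.n_cells, size=config.n_planted_genes, replace=False)

    mu_mat = np.tile(mu[:, None], (1, config.n_cells))
    for g, ci in zip(planted, planted_cell_idx):
        mu_mat[g, ci] *= 2.0 ** config.expression_log2_delta

    r = config.size_factor_range
    cols, col_cells, col_sfs = [], [], []
    blocks = []
    phi = config.nb_dispersion
    nb_n = 1.0 / phi
    for ci, cell in enumerate(cells):
        for rep in range(1, reps[ci] + 1):
            sf = rng.uniform(1 - r, 1 + r)
            mean = mu_mat[:, ci] * sf
            nb_p = nb_n / (nb_n + mean)
            blocks.append(rng.negative_binomial(nb_n, nb_p))
            cols.append(f"{cell}.{rep}")
            col_cells.append(cell)
            col_sfs.append(sf)
    matrix = pd.DataFrame(np.column_stack(blocks), index=pd.Index(genes, name="gene_id"), columns=cols)

    truth = pd.DataFrame(
        {
            "gene_id": [genes[g] for g in planted],
            "planted_cell": [cells[ci] for ci in planted_cell_idx],
            "log2_delta": config.expression_log2_delta,
        }
    )
    size_factors = pd.DataFrame({"column": cols, "cell_type": col_cells, "size_factor": col_sfs})
    return matrix, truth, size_factors


def null_config(base: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A copy of ``base`` with every planted signal switched off."""
    base = base or SimulationConfig()
    return replace(
        base,
        n_planted_unique=0,
        outlier_cell=None,
        n_planted_genes=0,
        **overrides,
    )
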