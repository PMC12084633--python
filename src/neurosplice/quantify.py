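"""Percent-spliced-in (PSI) quantification from junction-spanning reads.

PSI for an event in one replicate is::

    psi = inclusion_reads / (inclusion_reads + exclusion_reads)

where ``inclusion_reads`` is the mean read count over the event's inclusion
junctions (e.g. the two flanking junctions of a cassette exon, or the two
exon--intron boundaries of a retained intron) and ``exclusion_reads`` the
mean over the remaining junctions (the skipping junction, the spliced
junction, or the alternative splice-site junction).  An entry is missing
whenever the summed evidence ``inclusion + exclusion`` falls below the
junction-read threshold (default 5 reads per biological replicate); missing
values propagate and are never imputed.

A :class:`UsageMatrix` averages replicate PSIs per cell type; an event is
"alternative" if any cell's mean PSI lies in the 10--90% band (boundaries
inclusive) and "near-constitutive" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CountTableError, InsufficientDataError
from .events import SplicingEvent

PSI_COLUMNS = ["event_id", "cell_type", "replicate", "psi", "coverage"]

#: PSI band (inclusive) within which an event counts as alternatively spliced
ALTERNATIVE_BAND = (0.10, 0.90)
_BAND_EPS = 1e-12


@dataclass
class UsageMatrix:
    """Mean PSI per (event, cell type) with replicate support.

    ``mean``: wide frame, events x cell types, NaN where no usable replicate.
    ``n_replicates``: same shape, number of non-missing replicates averaged.
    """

    mean: pd.DataFrame
    n_replicates: pd.DataFrame


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts["count"].isna().any():
        raise CountTableError("junction counts contain missing values")
    arr = counts["count"].to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise CountTableError("junction counts must be integers")
    if (arr < 0).any():
        raise CountTableError("junction counts must be non-negative")


def compute_psi_table(
    counts: pd.DataFrame,
    events: Sequence[SplicingEvent],
    junction_threshold: int = 5,
) -> pd.DataFrame:
    """Quantify PSI for every event across all (cell, replicate) pairs.

    Parameters
    ----------
    counts:
        Long table with columns ``event_id, cell_type, replicate,
        junction_index, count``.
    events:
        Event definitions; only events present in ``counts`` are quantified.
    junction_threshold:
        Minimum combined inclusion+exclusion evidence per replicate.

    Returns
    -------
    Long frame with columns ``event_id, cell_type, replicate, psi, coverage``;
    ``psi`` is NaN where coverage is below threshold (the row is kept so the
    replicate structure stays visible downstream).
    """
    _validate_counts(counts)
    ev_index = {e.event_id: e for e in events}
    unknown = set(counts["event_id"]) - set(ev_index)
    if unknown:
        raise CountTableError(f"counts reference undefined events: {sorted(unknown)[:5]}")

    # per (event, junction) weights: 1/n_inc for inclusion junctions, 1/n_exc otherwise
    weight_rows = []
    for e in ev_index.values():
        inc = set(e.inclusion_junction_index)
        n_inc, n_exc = len(inc), len(e.junctions) - len(inc)
        for j in range(len(e.junctions)):
            weight_rows.append(
                (e.event_id, j, 1.0 / n_inc if j in inc else 0.0, 0.0 if j in inc else 1.0 / n_exc)
            )
    weights = pd.DataFrame(weight_rows, columns=["event_id", "junction_index", "w_inc", "w_exc"])

    merged = counts.merge(weights, on=["event_id", "junction_index"], how="left", validate="m:1")
    if merged["w_inc"].isna().any():
        bad = merged.loc[merged["w_inc"].isna(), ["event_id", "junction_index"]].iloc[0]
        raise CountTableError(
            f"count row references undefined junction {bad.junction_index} of {bad.event_id}"
        )

    grp = merged.groupby(["event_id", "cell_type", "replicate"], sort=True)
    n_seen = grp["junction_index"].nunique()
    expected = n_seen.index.get_level_values("event_id").map(
        lambda eid: len(ev_index[eid].junctions)
    )
    if (n_seen.to_numpy() != np.asarray(expected)).any():
        raise CountTableError("some (cell, replicate) pairs lack counts for all junctions")
    if (grp.size().to_numpy() != n_seen.to_numpy()).any():
        raise CountTableError("duplicate (event, cell, replicate, junction) count rows")

    merged["inc_part"] = merged["count"] * merged["w_inc"]
    merged["exc_part"] = merged["count"] * merged["w_exc"]
    agg = grp[["inc_part", "exc_part"]].sum().reset_index()
    coverage = agg["inc_part"] + agg["exc_part"]
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(coverage > 0, agg["inc_part"] / coverage, np.nan)
    psi = np.where(coverage >= junction_threshold, psi, np.nan)
    out = agg[["event_id", "cell_type", "replicate"]].copy()
    out["psi"] = psi
    out["coverage"] = coverage
    return out


def compute_psi(
    counts: pd.DataFrame,
    event: SplicingEvent,
    junction_threshold: int = 5,
) -> pd.DataFrame:
    """PSI entries for a single event (see :func:`compute_psi_table`)."""
    sub = counts.loc[counts["event_id"] == event.event_id]
    if sub.empty:
        raise InsufficientDataError(f"no counts for event {event.event_id}")
    return compute_psi_table(sub, [event], junction_threshold)


def build_usage_matrix(psi: pd.DataFrame) -> UsageMatrix:
    """Average replicate PSIs per cell type (missing replicates skipped)."""
    dup = psi.duplicated(subset=["event_id", "cell_type", "replicate"])
    if dup.any():
        raise CountTableError("duplicate (event, cell, replicate) PSI entries")
    mean = psi.pivot_table(
        index="event_id", columns="cell_type", values="psi", aggfunc="mean"
    )
    n = (
        psi.dropna(subset=["psi"])
        .groupby(["event_id", "cell_type"])["psi"]
        .size()
        .unstack(fill_value=0)
        .reindex(index=mean.index, columns=mean.columns, fill_value=0)
        .astype(int)
    )
    return UsageMatrix(mean=mean, n_replicates=n)


def classify_event_status(cell_means: pd.Series | Iterable[float]) -> str:
    """Label one event ``alternative`` or ``near_constitutive``.

    Alternative iff any cell-type mean PSI falls in the inclusive 10--90%
    band; raises if every cell is missing.
    """
    vals = pd.Series(cell_means, dtype=float).dropna()
    if vals.empty:
        raise InsufficientDataError("event has no cell with a usable mean PSI")
    lo, hi = ALTERNATIVE_BAND
    in_band = (vals >= lo - _BAND_EPS) & (vals <= hi + _BAND_EPS)
    return "alternative" if bool(in_band.any()) else "near_constitutive"


def classify_usage(usage: UsageMatrix) -> pd.Series:
    """Vectorized :func:`classify_event_status` over a usage matrix."""
    m = usage.mean
    lo, hi = ALTERNATIVE_BAND
    any_present = m.notna().any(axis=1)
    if not any_present.all():
        raise InsufficientDataError("usage matrix contains all-missing event rows")
    in_band = ((m >= lo - _BAND_EPS) & (m <= hi + _BAND_EPS)).any(axis=1)
    return in_band.map({True: "alternative", False: "near_constitutive"}).rename("status")


# ---------------------------------------------------------------------------
# PSI matrix I/O: wide TSV, events as rows, cell.replicate columns
# ---------------------------------------------------------------------------


def write_psi_matrix(psi: pd.DataFrame, path: str | Path) -> None:
    wide = psi.pivot(index="event_id", columns=["cell_type", "replicate"], values="psi")
    wide.columns = [f"{c}.{r}" for c, r in wide.columns]
    wide.to_csv(path, sep="\t", float_format="%.6f", na_rep="NA")


def read_psi_matrix(path: str | Path) -> pd.DataFrame:
    wide = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    long = wide.stack(future_stack=True).rename("psi").reset_index()
    long.columns = ["event_id", "col", "psi"]
    cells_reps = long["col"].str.rsplit(".", n=1, expand=True)
    long["cell_type"] = cells_reps[0]
    long["replicate"] = cells_reps[1]
    return long[["event_id", "cell_type", "replicate", "psi"]]
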