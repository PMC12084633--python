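"""The uniqueness index: aggregating pairwise differences per cell.

For a splicing event and a focal cell type, the uniqueness index is the sum
of the *oriented* delta-PSI values over all of that cell's significant
pairwise comparisons against the other cell types.  With N cell types the
index is bounded by +/-(N - 1): an event 100% included in one cell and 0%
in the other 45 of a 46-cell dataset scores exactly 45, the mirrored
pattern scores -45, and 0 means no systematic difference.

Orientation makes "more upstream choice in transcript orientation" the
positive direction for splice-site and mutually-exclusive-exon events:
raw deltas are expressed for the genomically-first alternative, so the
sign is reversed for alternative 3' splice sites on the + strand and
alternative 5' splice sites on the - strand.  Cassette and intron
retention deltas are kept as-is (positive = more inclusion/retention);
composite events are oriented through their primary (cassette-like)
sub-choice, i.e. identity.

The same aggregation applied to significant log2 fold changes yields the
expression uniqueness index, and restricting to broadly expressed genes
(>= 123 of 126 cell types) gives the pan-neuronal ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_THRESHOLDS, Thresholds
from .errors import AnalysisError, UnknownEventTypeError
from .events import EVENT_TYPES, SplicingEvent
from .quantify import UsageMatrix


@dataclass(frozen=True)
class UniquenessRecord:
    event_id: str
    cell_type: str
    index: float
    n_significant: int

    @property
    def direction(self) -> int:
        return int(np.sign(self.index))


def orientation_sign(event_type: str, strand: str) -> int:
    """+1 or -1 mapping a genomically-first delta onto the upstream-positive axis."""
    if event_type not in EVENT_TYPES:
        raise UnknownEventTypeError(f"unknown event type {event_type!r}")
    if strand not in ("+", "-"):
        raise AnalysisError(f"strand must be '+' or '-', got {strand!r}")
    if event_type == "A3S" and strand == "+":
        return -1
    if event_type == "A5S" and strand == "-":
        return -1
    return 1


def orient_delta_psi(event: SplicingEvent | tuple[str, str], raw_delta: float) -> float:
    """Orient one raw delta-PSI; accepts an event or a (type, strand) pair."""
    if isinstance(event, tuple):
        etype, strand = event
    else:
        etype, strand = event.event_type, event.strand
    return orientation_sign(etype, strand) * raw_delta


def _oriented(results: pd.DataFrame) -> pd.Series:
    sign = np.where(
        ((results["event_type"] == "A3S") & (results["strand"] == "+"))
        | ((results["event_type"] == "A5S") & (results["strand"] == "-")),
        -1.0,
        1.0,
    )
    return results["delta_psi"] * sign


def uniqueness_index(
    results: pd.DataFrame, cell: str, event_id: str
) -> UniquenessRecord:
    """Index for one (event, cell) pair from an ordered pairwise table."""
    if cell not in set(results["cell_a"]):
        raise AnalysisError(f"unknown cell type {cell!r}")
    sub = results[(results["cell_a"] == cell) & (results["event_id"] == event_id)]
    sig = sub[sub["significant"]]
    total = float(_oriented(sig).sum()) if not sig.empty else 0.0
    return UniquenessRecord(event_id=event_id, cell_type=cell, index=total, n_significant=len(sig))


def uniqueness_table(
    results: pd.DataFrame,
    scope: str = "cell_centric",
    ascending: bool = False,
) -> pd.DataFrame:
    """All (event, cell) uniqueness records, ranked by index.

    ``scope="cell_centric"`` returns one row per (event, cell) sorted by
    index; ``scope="gene_centric"`` groups by gene and reports the cell
    with the extreme |index| per gene.
    """
    if scope not in ("cell_centric", "gene_centric"):
        raise AnalysisError(f"unknown scope {scope!r}")
    df = results.copy()
    df["oriented"] = _oriented(df)
    df["contrib"] = np.where(df["significant"], df["oriented"], 0.0)
    grouped = (
        df.groupby(["event_id", "cell_a"], sort=True)
        .agg(
            gene_id=("gene_id", "first"),
            event_type=("event_type", "first"),
            index=("contrib", "sum"),
            n_significant=("significant", "sum"),
        )
        .reset_index()
        .rename(columns={"cell_a": "cell_type"})
    )
    grouped["n_significant"] = grouped["n_significant"].astype(int)
    if scope == "gene_centric":
        grouped["abs_index"] = grouped["index"].abs()
        top = grouped.sort_values("abs_index", ascending=False, kind="mergesort")
        grouped = top.groupby("gene_id", sort=False).head(1).drop(columns="abs_index")
    grouped = grouped.sort_values("index", ascending=ascending, kind="mergesort").reset_index(drop=True)
    grouped["rank"] = np.arange(1, len(grouped) + 1)
    return grouped


def pan_neuronal_uniqueness(
    records: pd.DataFrame,
    breadth: pd.Series | dict,
    threshold: int = 123,
    total: int = 126,
) -> pd.DataFrame:
    """Rank broadly expressed genes by their extreme |uniqueness index|.

    ``breadth`` maps gene_id -> number of cell types expressing the gene
    (out of ``total``); genes below ``threshold`` or without breadth are
    excluded.
    """
    breadth = pd.Series(breadth)
    if (breadth > total).any():
        raise AnalysisError("breadth exceeds the stated total number of cell types")
    df = records.copy()
    df["breadth"] = df["gene_id"].map(breadth)
    df = df[df["breadth"].notna() & (df["breadth"] >= threshold)]
    df["score"] = df["index"].abs()
    per_gene = (
        df.sort_values("score", ascending=False, kind="mergesort")
        .groupby("gene_id", sort=False)
        .head(1)
        .loc[:, ["gene_id", "cell_type", "event_id", "index", "score", "breadth"]]
        .reset_index(drop=True)
    )
    per_gene["rank"] = np.arange(1, len(per_gene) + 1)
    return per_gene


def expression_uniqueness_index(
    expr_results: pd.DataFrame, cell: str, gene: str
) -> float:
    """Sum of significant log2 fold changes of ``cell`` vs every other cell."""
    sub = expr_results[
        (expr_results["cell_a"] == cell)
        & (expr_results["gene_id"] == gene)
        & expr_results["significant"]
    ]
    return float(sub["log2_fc"].sum())


def expression_uniqueness_table(
    expr_results: pd.DataFrame, ascending: bool = False
) -> pd.DataFrame:
    df = expr_results.copy()
    df["contrib"] = np.where(df["significant"], df["log2_fc"], 0.0)
    grouped = (
        df.groupby(["gene_id", "cell_a"], sort=True)
        .agg(index=("contrib", "sum"), n_significant=("significant", "sum"))
        .reset_index()
        .rename(columns={"cell_a": "cell_type"})
    )
    grouped["n_significant"] = grouped["n_significant"].astype(int)
    grouped = grouped.sort_values("index", ascending=ascending, kind="mergesort").reset_index(drop=True)
    grouped["rank"] = np.arange(1, len(grouped) + 1)
    return grouped


def write_vista_export(usage: UsageMatrix, path) -> None:
    """Spatial-heatmap export: one (cell_type, event_id, mean_psi) row per value."""
    long = usage.mean.stack(future_stack=True).rename("mean_psi").reset_index()
    long.columns = ["event_id", "cell_type", "mean_psi"]
    long = long[["cell_type", "event_id", "mean_psi"]].dropna(subset=["mean_psi"])
    long.to_csv(path, sep="\t", index=False, float_format="%.6f")
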