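"""Dataset-level summaries of the all-pairs differential results.

Covers the per-type significant-event count matrices, cross-splice-type
correlations (adjusted R-squared of one type's per-pair counts regressed
on another's), robust outlier-cell detection, the differentially-retained
introns-per-gene histogram, and PCA of standardized PSI usage matrices.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .config import DEFAULT_THRESHOLDS, Thresholds
from .errors import AnalysisError
from .events import EVENT_TYPES
from .quantify import UsageMatrix


@dataclass
class TypeCountMatrix:
    """Significant-event counts per unordered cell pair and event type.

    ``pair_counts``: long frame (cell_a, cell_b, event_type, n_significant)
    over the full pair x type grid (zeros included; cell_a < cell_b).
    ``cell_totals``: cells x event types, each cell's total over its pairs.
    """

    pair_counts: pd.DataFrame
    cell_totals: pd.DataFrame


def count_significant_events(
    results: pd.DataFrame,
    min_events: int = 1,
    cells: list[str] | None = None,
) -> TypeCountMatrix:
    """Tabulate significant events per (pair, type).

    With ``min_events > 1`` (the global-summary setting of 5), (pair, type)
    cells below the floor are zeroed out; per-pair heatmaps keep the floor
    of 1 since an event can be detected at most once per comparison.
    """
    if cells is None:
        cells = sorted(set(results["cell_a"]) | set(results["cell_b"]))
    sig = results[results["significant"]].copy()
    # de-duplicate the ordered table onto unordered pairs
    keep = sig["cell_a"] < sig["cell_b"]
    if not keep.any() and len(sig):
        keep = pd.Series(True, index=sig.index)  # table was already unordered
    sig = sig[keep]
    counts = (
        sig.groupby(["cell_a", "cell_b", "event_type"], observed=True)
        .size()
        .rename("n_significant")
    )
    pairs = list(itertools.combinations(cells, 2))
    grid = pd.MultiIndex.from_tuples(
        [(a, b, t) for (a, b) in pairs for t in EVENT_TYPES],
        names=["cell_a", "cell_b", "event_type"],
    )
    full = counts.reindex(grid, fill_value=0).reset_index()
    if min_events > 1:
        full.loc[full["n_significant"] < min_events, "n_significant"] = 0
    wide_a = full.pivot_table(
        index="cell_a", columns="event_type", values="n_significant", aggfunc="sum"
    )
    wide_b = full.pivot_table(
        index="cell_b", columns="event_type", values="n_significant", aggfunc="sum"
    )
    totals = (
        wide_a.reindex(index=cells, fill_value=0)
        .fillna(0)
        .add(wide_b.reindex(index=cells, fill_value=0).fillna(0), fill_value=0)
        .reindex(columns=list(EVENT_TYPES), fill_value=0)
        .astype(int)
    )
    totals.index.name = "cell_type"
    return TypeCountMatrix(pair_counts=full, cell_totals=totals)


def pair_count_matrix(tcm: TypeCountMatrix, event_type: str) -> pd.DataFrame:
    """Square heatmap-ready matrix for one event type (symmetric)."""
    sub = tcm.pair_counts[tcm.pair_counts["event_type"] == event_type]
    cells = sorted(set(sub["cell_a"]) | set(sub["cell_b"]))
    mat = pd.DataFrame(0, index=cells, columns=cells, dtype=int)
    for a, b, n in sub[["cell_a", "cell_b", "n_significant"]].itertuples(index=False):
        mat.loc[a, b] = n
        mat.loc[b, a] = n
    return mat


def cross_type_correlation(
    tcm: TypeCountMatrix, type_x: str, type_y: str
) -> tuple[float, int]:
    """Adjusted R-squared of per-pair counts of ``type_y`` on ``type_x``."""
    wide = tcm.pair_counts.pivot_table(
        index=["cell_a", "cell_b"], columns="event_type", values="n_significant"
    )
    x = wide[type_x].to_numpy(dtype=float)
    y = wide[type_y].to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise AnalysisError("need at least 3 cell pairs for a correlation")
    if np.allclose(x.var(), 0.0):
        raise AnalysisError(f"zero variance in {type_x} counts")
    if np.allclose(y.var(), 0.0):
        raise AnalysisError(f"zero variance in {type_y} counts")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.rsquared_adj), n


def cross_type_correlation_summary(tcm: TypeCountMatrix) -> pd.DataFrame:
    rows = []
    for tx, ty in itertools.permutations(EVENT_TYPES, 2):
        try:
            r2, n = cross_type_correlation(tcm, tx, ty)
        except AnalysisError:
            continue
        rows.append({"type_x": tx, "type_y": ty, "r2_adj": r2, "n_pairs": n})
    return pd.DataFrame(rows, columns=["type_x", "type_y", "r2_adj", "n_pairs"])


def detect_outlier_cells(
    tcm: TypeCountMatrix,
    event_type: str,
    k: float = 3.5,
    min_scale: float = 2.0,
) -> list[str]:
    """Cells whose per-type totals sit far above the robust center.

    Robust z = (total - median) / (1.4826 * MAD); when the MAD collapses to
    zero the IQR-based scale (IQR / 1.349) substitutes, and the scale never
    drops below ``min_scale`` counts so near-empty count families cannot
    flag Poisson-level noise.
    """
    totals = tcm.cell_totals[event_type]
    if len(totals) < 5:
        raise AnalysisError("need at least 5 cells for outlier detection")
    x = totals.to_numpy(dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0:
        q1, q3 = np.percentile(x, [25, 75])
        scale = (q3 - q1) / 1.349
    scale = max(scale, min_scale)
    z = (x - med) / scale
    return list(totals.index[z > k])


def introns_per_gene_histogram(
    results: pd.DataFrame,
) -> tuple[pd.Series, dict[int, int]]:
    """Distinct differentially-retained introns per gene, plus histogram."""
    sig_ir = results[(results["significant"]) & (results["event_type"] == "IR")]
    per_gene = sig_ir.groupby("gene_id")["event_id"].nunique()
    histogram = per_gene.value_counts().sort_index().to_dict()
    return per_gene, {int(k): int(v) for k, v in histogram.items()}


def standardize_usage(mean: pd.DataFrame) -> pd.DataFrame:
    """Complete-case, per-event standardization across cell types."""
    complete = mean.dropna(axis=0, how="any")
    sd = complete.std(axis=1, ddof=1)
    nonzero = sd > 0
    dropped = int((~nonzero).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} zero-variance events before PCA")
    complete = complete.loc[nonzero]
    return complete.sub(complete.mean(axis=1), axis=0).div(sd[nonzero], axis=0)


def pca_psi(
    usage: UsageMatrix,
    events: pd.DataFrame,
    event_type: str = "combined",
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of cell types over standardized per-event PSI profiles.

    ``event_type`` selects one category, or ``"combined"`` for all types
    except composite (excluded from the combined view because its event
    count would dominate the variance).  Events with any missing cell are
    dropped (complete case, no imputation).

    Returns cell coordinates (cells x components) and the variance of each
    component (squared singular value / (n_cells - 1)).
    """
    types = events.set_index("event_id")["event_type"]
    if event_type == "combined":
        keep = types[types != "composite"].index
    else:
        if event_type not in EVENT_TYPES:
            raise AnalysisError(f"unknown event type {event_type!r}")
        keep = types[types == event_type].index
    mean = usage.mean.loc[usage.mean.index.intersection(keep)]
    std = standardize_usage(mean)
    if std.empty:
        raise AnalysisError("no complete-case events available for PCA")
    X = std.to_numpy().T  # cells x events
    n_cells = X.shape[0]
    if n_cells < 3:
        raise AnalysisError("need at least 3 cell types for PCA")
    k = n_components or min(n_cells - 1, X.shape[1])
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=std.columns, columns=cols), pca.explained_variance_
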