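"""All-pairs differential splicing and differential expression.

Differential splicing between two cell types is tested per event on the
replicate PSI values with a two-sided Welch test on arcsine-square-root
transformed PSIs; when fewer than 8 usable replicates are available in
total (or either group has fewer than 2) the exact two-sample permutation
test on the transformed group-mean difference is used instead, so tiny
designs get exact rather than asymptotic p-values.  The effect size is the
untransformed difference of replicate-mean PSIs,
``delta_psi = mean(psi_a) - mean(psi_b)``.

q-values are Benjamini-Hochberg adjusted *within each (cell pair, event
type) family*, mirroring a per-comparison, per-type differential-splicing
run.  An event in a pair is significant when ``p < 0.05``, ``q < 0.05``
and ``|delta_psi| > 0.10`` (all thresholds configurable).

A comparison is attempted only when each cell retains at least
``n_nominal - 1`` usable replicates, where ``n_nominal`` is the cell's
replicate count; otherwise the result row is simply absent.

Differential expression is a stand-in for a full negative-binomial model:
log2 fold changes of size-factor-normalized means (pseudocount 0.5) with a
Welch test on log-normalized counts.  Externally computed result tables
with the same columns can be substituted anywhere downstream.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_THRESHOLDS, Thresholds
from .errors import AnalysisError
from .events import SplicingEvent, events_to_frame

#: minimum total usable replicates for the Welch path; below this the
#: exact permutation test runs instead
WELCH_MIN_TOTAL = 8

RESULT_COLUMNS = [
    "cell_a",
    "cell_b",
    "event_id",
    "gene_id",
    "event_type",
    "strand",
    "delta_psi",
    "p_value",
    "q_value",
    "n_rep_a",
    "n_rep_b",
    "significant",
]


def _asin_sqrt(x: np.ndarray) -> np.ndarray:
    return np.arcsin(np.sqrt(np.clip(x, 0.0, 1.0)))


def _welch_p(ma, va, na, mb, vb, nb):
    """Vectorized two-sided Welch p; exact 0/1 when both variances vanish."""
    na = na.astype(float)
    nb = nb.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_se = se2 == 0
    p = np.where(zero_se & (ma == mb), 1.0, p)
    p = np.where(zero_se & (ma != mb), 0.0, p)
    return p


def _perm_p(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Exact permutation p for rows of (xa | xb); statistic |mean_a - mean_b|."""
    na, nb = xa.shape[1], xb.shape[1]
    tot = na + nb
    x = np.concatenate([xa, xb], axis=1)
    combs = np.array(list(itertools.combinations(range(tot), na)))
    sums_a = x[:, combs].sum(axis=2)
    mean_a = sums_a / na
    mean_b = (x.sum(axis=1, keepdims=True) - sums_a) / nb
    stat = np.abs(mean_a - mean_b)
    obs = np.abs(xa.mean(axis=1) - xb.mean(axis=1))
    return (stat >= obs[:, None] - 1e-12).mean(axis=1)


def test_differential_splicing(
    psi_a: Sequence[float],
    psi_b: Sequence[float],
    coverage_a: Sequence[float] | None = None,
    coverage_b: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Test one event between two cell types.

    Returns ``(delta_psi, p_value)``; both NaN when either group has no
    usable replicate.  Coverage arguments are accepted for interface
    symmetry -- coverage filtering happens during PSI quantification.
    """
    a = np.asarray(psi_a, dtype=float)
    b = np.asarray(psi_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return (float("nan"), float("nan"))
    delta = float(a.mean() - b.mean())
    ta, tb = _asin_sqrt(a), _asin_sqrt(b)
    if a.size + b.size >= WELCH_MIN_TOTAL and a.size >= 2 and b.size >= 2:
        p = _welch_p(
            ta.mean(), ta.var(ddof=1), np.array(a.size),
            tb.mean(), tb.var(ddof=1), np.array(b.size),
        )
        return delta, float(p)
    p = _perm_p(ta[None, :], tb[None, :])[0]
    return delta, float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (empty in, empty out)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return bh_adjust_grouped(p, np.zeros(p.size, dtype=int))


def bh_adjust_grouped(p: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Vectorized BH within each group label, preserving input order."""
    df = pd.DataFrame({"p": p, "g": groups})
    df["m"] = df.groupby("g")["p"].transform("size")
    df = df.sort_values(["g", "p"], kind="mergesort")
    rank = df.groupby("g").cumcount() + 1
    df["q"] = np.minimum(df["p"] * df["m"] / rank, 1.0)
    # step-up: running minimum from the largest p within each group
    df = df.iloc[::-1]
    df["q"] = df.groupby("g", sort=False)["q"].cummin()
    return df["q"].sort_index().to_numpy()


def _psi_cube(psi: pd.DataFrame):
    """Pivot a long PSI frame into an (events x cells x reps) cube."""
    wide = psi.pivot(index="event_id", columns=["cell_type", "replicate"], values="psi")
    cells = sorted({c for c, _ in wide.columns})
    rep_cols = {c: [col for col in wide.columns if col[0] == c] for c in cells}
    nominal = np.array([len(rep_cols[c]) for c in cells])
    E, C, R = wide.shape[0], len(cells), int(nominal.max())
    cube = np.full((E, C, R), np.nan)
    for ci, c in enumerate(cells):
        cube[:, ci, : nominal[ci]] = wide[rep_cols[c]].to_numpy(dtype=float)
    return wide.index.to_numpy(), cells, nominal, cube


def run_all_pairs(
    psi: pd.DataFrame,
    events: Sequence[SplicingEvent] | pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    include_mirror: bool = True,
) -> pd.DataFrame:
    """Differential splicing for every pair of cell types.

    Returns one row per (ordered pair, event) that passes the replicate
    precondition.  With ``include_mirror=False`` only the ``cell_a < cell_b``
    half is returned (delta antisymmetry makes the other half redundant).
    """
    meta = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    event_ids, cells, nominal, cube = _psi_cube(psi)
    if len(cells) < 2:
        raise AnalysisError("need at least two cell types for pairwise comparisons")
    E, C = cube.shape[0], cube.shape[1]

    meta_idx = meta.set_index("event_id").reindex(event_ids)
    if meta_idx["event_type"].isna().any():
        raise AnalysisError("PSI matrix contains events missing from the event table")

    T = _asin_sqrt(cube)
    usable = ~np.isnan(cube)
    n = usable.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        m_raw = np.nanmean(cube, axis=2)
        m_t = np.nansum(np.where(usable, T, 0.0), axis=2) / np.maximum(n, 1)
        dev = np.where(usable, T - m_t[:, :, None], 0.0)
        v_t = (dev**2).sum(axis=2) / np.maximum(n - 1, 1)
    v_t = np.where(n >= 2, v_t, np.nan)

    recs_a, recs_b, recs_e = [], [], []
    recs_delta, recs_p, recs_na, recs_nb = [], [], [], []
    for i, j in itertools.combinations(range(C), 2):
        na, nb = n[:, i], n[:, j]
        valid = (na >= nominal[i] - 1) & (nb >= nominal[j] - 1) & (na > 0) & (nb > 0)
        if not valid.any():
            continue
        welch = valid & (na >= 2) & (nb >= 2) & (na + nb >= WELCH_MIN_TOTAL)
        perm = valid & ~welch
        p = np.full(E, np.nan)
        if welch.any():
            p_w = _welch_p(m_t[:, i], v_t[:, i], na, m_t[:, j], v_t[:, j], nb)
            p[welch] = p_w[welch]
        if perm.any():
            pairs_nn = {(int(ka), int(kb)) for ka, kb in zip(na[perm], nb[perm])}
            for ka, kb in pairs_nn:
                sel = perm & (na == ka) & (nb == kb)
                xa = np.sort(T[sel, i, :], axis=1)[:, :ka]
                xb = np.sort(T[sel, j, :], axis=1)[:, :kb]
                p[sel] = _perm_p(xa, xb)
        idx = np.flatnonzero(valid)
        recs_a.append(np.full(idx.size, i))
        recs_b.append(np.full(idx.size, j))
        recs_e.append(idx)
        recs_delta.append(m_raw[idx, i] - m_raw[idx, j])
        recs_p.append(p[idx])
        recs_na.append(na[idx])
        recs_nb.append(nb[idx])

    if not recs_a:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    ai = np.concatenate(recs_a)
    bi = np.concatenate(recs_b)
    ei = np.concatenate(recs_e)
    out = pd.DataFrame(
        {
            "cell_a": np.asarray(cells, dtype=object)[ai],
            "cell_b": np.asarray(cells, dtype=object)[bi],
            "event_id": event_ids[ei],
            "gene_id": meta_idx["gene_id"].to_numpy()[ei],
            "event_type": meta_idx["event_type"].to_numpy()[ei],
            "strand": meta_idx["strand"].to_numpy()[ei],
            "delta_psi": np.concatenate(recs_delta),
            "p_value": np.concatenate(recs_p),
            "n_rep_a": np.concatenate(recs_na),
            "n_rep_b": np.concatenate(recs_nb),
        }
    )
    type_codes = out["event_type"].astype("category").cat.codes.to_numpy()
    family = (ai * C + bi) * 8 + type_codes
    out["q_value"] = bh_adjust_grouped(out["p_value"].to_numpy(), family)
    out["significant"] = (
        (out["p_value"] < thresholds.p)
        & (out["q_value"] < thresholds.q)
        & (out["delta_psi"].abs() > thresholds.dpsi)
    )
    out = out[RESULT_COLUMNS]
    if include_mirror:
        mirror = out.copy()
        mirror[["cell_a", "cell_b"]] = out[["cell_b", "cell_a"]].to_numpy()
        mirror["delta_psi"] = -out["delta_psi"]
        mirror[["n_rep_a", "n_rep_b"]] = out[["n_rep_b", "n_rep_a"]].to_numpy()
        out = pd.concat([out, mirror], ignore_index=True)
        out = out.sort_values(["cell_a", "cell_b", "event_id"], kind="mergesort").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# differential expression (stand-in)
# ---------------------------------------------------------------------------

EXPR_RESULT_COLUMNS = ["cell_a", "cell_b", "gene_id", "log2_fc", "p_value", "significant"]


def estimate_size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with all-positive counts."""
    log = np.log(matrix.where(matrix > 0))
    ref = log.mean(axis=1)
    usable = ref.notna()
    if not usable.any():
        raise AnalysisError("no gene has positive counts in every sample")
    sf = np.exp((log.loc[usable].sub(ref[usable], axis=0)).median(axis=0))
    return sf


def test_differential_expression(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    size_factors_a: Sequence[float] | None = None,
    size_factors_b: Sequence[float] | None = None,
) -> tuple[float, float] | None:
    """log2 fold change and Welch p for one gene; ``None`` if all-zero."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("need at least two replicates per cell")
    sa = np.ones_like(a) if size_factors_a is None else np.asarray(size_factors_a, float)
    sb = np.ones_like(b) if size_factors_b is None else np.asarray(size_factors_b, float)
    na, nb_ = a / sa, b / sb
    if not (na.any() or nb_.any()):
        return None
    lfc = float(np.log2((na.mean() + 0.5) / (nb_.mean() + 0.5)))
    la, lb = np.log2(na + 0.5), np.log2(nb_ + 0.5)
    p = _welch_p(
        la.mean(), la.var(ddof=1), np.array(a.size),
        lb.mean(), lb.var(ddof=1), np.array(b.size),
    )
    return lfc, float(p)


def run_all_pairs_expression(
    matrix: pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    size_factors: pd.Series | None = None,
    include_mirror: bool = True,
) -> pd.DataFrame:
    """Differential expression for every pair of cell types.

    ``matrix`` is genes x samples with ``cell.replicate`` column names.
    Genes with zero counts in both cells of a pair are dropped from that
    comparison.
    """
    cells_of_col = pd.Index([c.rsplit(".", 1)[0] for c in matrix.columns])
    cells = sorted(cells_of_col.unique())
    if len(cells) < 2:
        raise AnalysisError("need at least two cell types")
    sf = estimate_size_factors(matrix) if size_factors is None else size_factors
    norm = matrix.div(sf, axis=1)
    log = np.log2(norm + 0.5)

    stats_m, stats_v, stats_n, means = {}, {}, {}, {}
    for c in cells:
        cols = matrix.columns[cells_of_col == c]
        if len(cols) < 2:
            raise AnalysisError(f"cell {c} has fewer than two replicates")
        sub = log[cols]
        stats_m[c] = sub.mean(axis=1).to_numpy()
        stats_v[c] = sub.var(axis=1, ddof=1).to_numpy()
        stats_n[c] = len(cols)
        means[c] = norm[cols].mean(axis=1).to_numpy()

    rows = []
    gene_ids = matrix.index.to_numpy()
    for a, b in itertools.combinations(cells, 2):
        keep = (means[a] > 0) | (means[b] > 0)
        lfc = np.log2((means[a] + 0.5) / (means[b] + 0.5))
        p = _welch_p(
            stats_m[a], stats_v[a], np.full(len(gene_ids), stats_n[a]),
            stats_m[b], stats_v[b], np.full(len(gene_ids), stats_n[b]),
        )
        rows.append(
            pd.DataFrame(
                {
                    "cell_a": a,
                    "cell_b": b,
                    "gene_id": gene_ids[keep],
                    "log2_fc": lfc[keep],
                    "p_value": p[keep],
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out["significant"] = (out["p_value"] < thresholds.expr_p) & (
        out["log2_fc"].abs() > thresholds.expr_lfc
    )
    out = out[EXPR_RESULT_COLUMNS]
    if include_mirror:
        mirror = out.copy()
        mirror[["cell_a", "cell_b"]] = out[["cell_b", "cell_a"]].to_numpy()
        mirror["log2_fc"] = -out["log2_fc"]
        out = pd.concat([out, mirror], ignore_index=True)
        out = out.sort_values(["cell_a", "cell_b", "gene_id"], kind="mergesort").reset_index(drop=True)
    return out
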