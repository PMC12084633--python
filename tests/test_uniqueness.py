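"""Uniqueness index: orientation rules, aggregation, rankings."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neurosplice as ns
from neurosplice.errors import AnalysisError

from conftest import make_extreme_psi


def _result_row(cell_a, cell_b, event_id="E1", gene_id="G1", event_type="cassette",
                strand="+", delta=0.0, p=1.0, q=1.0, significant=False):
    return dict(
        cell_a=cell_a, cell_b=cell_b, event_id=event_id, gene_id=gene_id,
        event_type=event_type, strand=strand, delta_psi=delta, p_value=p,
        q_value=q, n_rep_a=4, n_rep_b=4, significant=significant,
    )


def brute_force_index(results: pd.DataFrame, cell: str, event_id: str) -> float:
    """Independent re-filter and re-sum of the raw pairwise table."""
    total = 0.0
    for row in results.itertuples(index=False):
        if row.cell_a != cell or row.event_id != event_id:
            continue
        if not (row.p_value < 0.05 and row.q_value < 0.05 and abs(row.delta_psi) > 0.10):
            continue
        sign = 1.0
        if row.event_type == "A3S" and row.strand == "+":
            sign = -1.0
        if row.event_type == "A5S" and row.strand == "-":
            sign = -1.0
        total += sign * row.delta_psi
    return total


class TestOrientation:
    @pytest.mark.parametrize(
        "etype,strand,raw,expected",
        [
            ("cassette", "+", 0.20, 0.20),
            ("IR", "-", 0.20, 0.20),
            ("A3S", "+", 0.20, -0.20),   # genomically-first acceptor is downstream-coded
            ("A3S", "-", 0.20, 0.20),
            ("A5S", "-", 0.15, -0.15),
            ("A5S", "+", 0.15, 0.15),
            ("MXE", "+", 0.30, 0.30),
            ("composite", "-", 0.30, 0.30),
        ],
    )
    def test_orientation_rules(self, etype, strand, raw, expected):
        assert ns.orient_delta_psi((etype, strand), raw) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(
        etype=st.sampled_from(ns.EVENT_TYPES),
        strand=st.sampled_from(["+", "-"]),
        raw=st.floats(-1, 1),
    )
    def test_orientation_involution_and_strand_flip(self, etype, strand, raw):
        """Orienting twice with the same strand is the identity (the sign is
        an involution); a strand flip negates the composition exactly for the
        strand-sensitive splice-site types."""
        same_twice = ns.orient_delta_psi((etype, strand), ns.orient_delta_psi((etype, strand), raw))
        assert same_twice == pytest.approx(raw)
        flipped = "-" if strand == "+" else "+"
        crossed = ns.orient_delta_psi((etype, flipped), ns.orient_delta_psi((etype, strand), raw))
        if etype in ("A3S", "A5S"):
            assert crossed == pytest.approx(-raw)
        else:
            assert crossed == pytest.approx(raw)


class TestUniquenessIndex:
    def test_no_significant_comparisons_zero(self):
        res = pd.DataFrame([_result_row("A", "B"), _result_row("A", "C")])
        rec = ns.uniqueness_index(res, "A", "E1")
        assert rec.index == 0.0
        assert rec.n_significant == 0
        assert rec.direction == 0

    def test_unknown_cell_rejected(self):
        res = pd.DataFrame([_result_row("A", "B")])
        with pytest.raises(AnalysisError):
            ns.uniqueness_index(res, "Z", "E1")

    def test_four_cell_partial_significance(self):
        """Target psi 0.9 vs {0.2, 0.2, 0.5}; only the first two significant:
        index = 0.7 + 0.7 = 1.4."""
        rows = [
            _result_row("A", "B", delta=0.7, p=0.001, q=0.01, significant=True),
            _result_row("A", "C", delta=0.7, p=0.001, q=0.01, significant=True),
            _result_row("A", "D", delta=0.4, p=0.20, q=0.60, significant=False),
        ]
        res = pd.DataFrame(rows)
        rec = ns.uniqueness_index(res, "A", "E1")
        assert rec.index == pytest.approx(1.4)
        assert rec.n_significant == 2
        assert rec.index == pytest.approx(brute_force_index(res, "A", "E1"))

    def test_bound_by_n_significant(self, small_results):
        table = ns.uniqueness_table(small_results)
        assert (table["index"].abs() <= table["n_significant"] + 1e-9).all()

    def test_oracle_equivalence_random_small_instances(self):
        """Random tables with N <= 6 cells: groupby aggregation equals the
        row-by-row brute force exactly."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_cells = rng.integers(2, 7)
            cells = [f"C{i}" for i in range(n_cells)]
            n_events = rng.integers(1, 11)
            rows = []
            for e in range(n_events):
                etype = rng.choice(ns.EVENT_TYPES)
                strand = rng.choice(["+", "-"])
                for a, b in itertools.permutations(cells, 2):
                    if rng.random() < 0.2:
                        continue  # absent comparison contributes zero
                    rows.append(_result_row(
                        a, b, event_id=f"E{e}", event_type=etype, strand=strand,
                        delta=float(rng.uniform(-1, 1)), p=float(rng.uniform(0, 0.2)),
                        q=float(rng.uniform(0, 0.2)),
                    ))
            res = pd.DataFrame(rows)
            res["significant"] = (
                (res["p_value"] < 0.05) & (res["q_value"] < 0.05)
                & (res["delta_psi"].abs() > 0.10)
            )
            table = ns.uniqueness_table(res).set_index(["event_id", "cell_type"])
            for (e, c) in table.index[:20]:
                expected = brute_force_index(res, c, e)
                assert ns.uniqueness_index(res, c, e).index == pytest.approx(expected, abs=1e-12)
                assert table.loc[(e, c), "index"] == pytest.approx(expected, abs=1e-12)


class TestRankings:
    def test_unique_event_tops_descending_sort(self):
        rows = [
            _result_row("A", "B", delta=0.9, p=0.001, q=0.001, significant=True),
            _result_row("B", "A", delta=-0.9, p=0.001, q=0.001, significant=True),
            _result_row("A", "B", event_id="E2", delta=0.05),
            _result_row("B", "A", event_id="E2", delta=-0.05),
        ]
        table = ns.uniqueness_table(pd.DataFrame(rows))
        assert table.iloc[0][["event_id", "cell_type"]].tolist() == ["E1", "A"]

    def test_sign_flip_reverses_ranking(self):
        rows = [
            _result_row("A", "B", event_id=f"E{i}", delta=d, p=0.001, q=0.001,
                        significant=True)
            for i, d in enumerate([0.9, 0.5, -0.7])
        ]
        res = pd.DataFrame(rows)
        fwd = ns.uniqueness_table(res)["event_id"].tolist()
        flipped = res.assign(delta_psi=-res["delta_psi"])
        rev = ns.uniqueness_table(flipped)["event_id"].tolist()
        assert fwd == rev[::-1]

    def test_planted_events_top_ranked_small_scale(self, small_dataset, small_results):
        table = ns.uniqueness_table(small_results)
        table = table.assign(score=table["index"].abs()).sort_values("score", ascending=False)
        planted = small_dataset.truth_events.dropna(subset=["planted_cell"])
        top = set(map(tuple, table.head(2 * len(planted))[["event_id", "cell_type"]].to_numpy()))
        recovered = sum(
            (row.event_id, row.planted_cell) in top for row in planted.itertuples()
        )
        assert recovered == len(planted)

    def test_gene_centric_reports_extreme_cell(self):
        rows = [
            _result_row("A", "B", event_id="E1", gene_id="G1", delta=0.9,
                        p=0.001, q=0.001, significant=True),
            _result_row("B", "A", event_id="E1", gene_id="G1", delta=-0.9,
                        p=0.001, q=0.001, significant=True),
        ]
        table = ns.uniqueness_table(pd.DataFrame(rows), scope="gene_centric")
        assert len(table) == 1
        assert table.iloc[0]["cell_type"] == "A"


class TestPanNeuronal:
    def _records(self):
        return pd.DataFrame(
            {
                "event_id": ["E1", "E2", "E3"],
                "cell_type": ["A", "B", "C"],
                "gene_id": ["G1", "G1", "G2"],
                "event_type": ["cassette"] * 3,
                "index": [23.0, -5.0, 1.4],
                "n_significant": [30, 10, 2],
            }
        )

    def test_breadth_filter_and_max_abs_score(self):
        breadth = {"G1": 125, "G2": 122}
        table = ns.pan_neuronal_uniqueness(self._records(), breadth)
        assert table["gene_id"].tolist() == ["G1"]  # G2 below 123-cell breadth
        assert table.iloc[0]["score"] == pytest.approx(23.0)

    def test_ordering_by_score(self):
        breadth = {"G1": 126, "G2": 124}
        table = ns.pan_neuronal_uniqueness(self._records(), breadth)
        assert table["gene_id"].tolist() == ["G1", "G2"]

    def test_missing_breadth_excluded(self):
        table = ns.pan_neuronal_uniqueness(self._records(), {"G1": 126})
        assert set(table["gene_id"]) == {"G1"}


class TestExpressionUniqueness:
    def _expr(self, n_sig=2, lfc=3.0):
        rows = []
        for i in range(n_sig):
            rows.append(dict(cell_a="A", cell_b=f"B{i}", gene_id="G1",
                             log2_fc=lfc, p_value=0.001, significant=True))
        rows.append(dict(cell_a="A", cell_b="C", gene_id="G1",
                         log2_fc=1.0, p_value=0.5, significant=False))
        return pd.DataFrame(rows)

    def test_no_significant_zero(self):
        expr = self._expr(n_sig=0)
        assert ns.expression_uniqueness_index(expr, "A", "G1") == 0.0

    def test_sum_of_significant_lfc(self):
        expr = self._expr(n_sig=45, lfc=3.0)
        assert ns.expression_uniqueness_index(expr, "A", "G1") == pytest.approx(135.0)

    def test_planted_gene_attains_top_rank(self):
        """Pipeline recovery: the planted unique gene ranks first in its cell."""
        hits = 0
        for seed in range(5):
            cfg = ns.SimulationConfig(n_cells=8, n_events=10, n_genes=100,
                                      n_planted_genes=1, seed=100 + seed)
            matrix, truth, _ = ns.generate_expression_dataset(cfg)
            res = ns.run_all_pairs_expression(matrix)
            table = ns.expression_uniqueness_table(res)
            table = table.assign(score=table["index"].abs()).sort_values(
                "score", ascending=False)
            g, cell = truth.iloc[0][["gene_id", "planted_cell"]]
            top = table.iloc[0]
            hits += (top["gene_id"] == g and top["cell_type"] == cell)
        assert hits >= 4


def test_extreme_input_attains_bound():
    """psi 1.0 in one of 6 cells, 0.0 elsewhere: index = N-1 exactly."""
    psi, events = make_extreme_psi(6, 4, 1.0, 0.0)
    res = ns.run_all_pairs(psi, events)
    rec = ns.uniqueness_index(res, "N01", "EV1")
    assert rec.index == 5.0
    assert rec.n_significant == 5


def test_vista_export_columns(tmp_path, small_dataset):
    psi = ns.compute_psi_table(small_dataset.counts, small_dataset.events)
    usage = ns.build_usage_matrix(psi)
    path = tmp_path / "vista.tsv"
    ns.write_vista_export(usage, path)
    back = pd.read_csv(path, sep="\t")
    assert list(back.columns) == ["cell_type", "event_id", "mean_psi"]
    assert back["mean_psi"].between(0, 1).all()
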