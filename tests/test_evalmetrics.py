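"""Metrics: weighted tables, Kappa/IQS, dosage, masking loop, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedimpute.core import MISSING, GenotypeProbabilities, Variant
from pedimpute.evalmetrics import (
    ContingencyTable,
    MaskingPlan,
    build_weighted_table,
    dosage,
    dosage_correlation,
    iqs,
    kappa,
    run_masking_experiment,
    summarize_by_maf,
)


def reference_kappa(cells: np.ndarray) -> float:
    """Independently coded Kappa, written directly from the definition:
    observed agreement minus chance agreement over one minus chance."""
    cells = np.asarray(cells, dtype=float)
    n = cells.sum()
    po = sum(cells[i, i] for i in range(3)) / n
    pe = sum(cells.sum(axis=1)[i] * cells.sum(axis=0)[i] for i in range(3)) / n**2
    return (po - pe) / (1 - pe)


def onehot(calls) -> np.ndarray:
    p = np.zeros((len(calls), 3))
    p[np.arange(len(calls)), calls] = 1.0
    return p


class TestWeightedTable:
    def test_two_hard_calls_on_diagonal(self):
        t = build_weighted_table([0, 1], onehot([0, 1]))
        assert np.array_equal(t.cells, [[1, 0, 0], [0, 1, 0], [0, 0, 0]])
        assert t.total == 2

    def test_single_soft_posterior_fills_true_row(self):
        t = build_weighted_table([1], np.array([[0.2, 0.5, 0.3]]))
        assert np.allclose(t.cells[1], [0.2, 0.5, 0.3])
        assert np.allclose(t.cells[[0, 2]], 0)

    def test_matches_naive_double_loop_accumulation(self):
        rng = np.random.default_rng(8)
        g = rng.integers(0, 3, size=50)
        p = rng.dirichlet((1, 1, 1), size=50)
        t = build_weighted_table(g, p)
        cells = np.zeros((3, 3))
        for i in range(50):
            for j in range(3):
                cells[g[i], j] += p[i, j]
        assert np.allclose(t.cells, cells, atol=1e-12)
        assert np.allclose(t.row_marginals, cells.sum(axis=1), atol=1e-9)
        assert np.allclose(t.col_marginals, cells.sum(axis=0), atol=1e-9)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            build_weighted_table([], np.zeros((0, 3)))

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            ContingencyTable(np.array([[1, 0, 0], [0, -1, 0], [0, 0, 1]]))


class TestKappa:
    def test_perfect_diagonal_is_one(self):
        t = ContingencyTable(np.diag([3.0, 5.0, 2.0]))
        assert kappa(t) == pytest.approx(1.0)

    def test_uniform_table_is_zero(self):
        t = ContingencyTable(np.full((3, 3), 2.0))
        assert kappa(t) == pytest.approx(0.0)

    def test_degenerate_expected_agreement_is_undefined(self):
        t = ContingencyTable(np.array([[4.0, 0, 0], [0, 0, 0], [0, 0, 0]]))
        assert kappa(t) is None

    @given(st.lists(st.integers(0, 20), min_size=9, max_size=9))
    @settings(max_examples=300, deadline=None)
    def test_matches_independent_formula_on_random_tables(self, flat):
        cells = np.array(flat, dtype=float).reshape(3, 3)
        if cells.sum() == 0:
            return
        t = ContingencyTable(cells)
        got = kappa(t)
        n = cells.sum()
        pe = float(cells.sum(1) @ cells.sum(0)) / n**2
        if abs(1 - pe) < 1e-12:
            assert got is None
        else:
            assert got == pytest.approx(reference_kappa(cells), abs=1e-12)


class TestIqs:
    def test_degenerate_posteriors_matching_truth_give_one(self):
        g = [0, 1, 2, 1, 0]
        assert iqs(g, onehot(g)) == pytest.approx(1.0)

    def test_frequency_posteriors_give_chance_level_zero(self):
        # every posterior = empirical genotype-frequency vector -> IQS 0
        g = np.array([1, 1, 1, 0, 2, 1])
        freq = np.bincount(g, minlength=3) / len(g)
        p = np.tile(freq, (len(g), 1))
        assert iqs(g, p) == pytest.approx(0.0, abs=1e-12)

    @given(
        st.lists(st.integers(0, 2), min_size=4, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_equals_kappa_on_degenerate_posteriors(self, g, seed):
        rng = np.random.default_rng(seed)
        imp = rng.integers(0, 3, size=len(g))
        got = iqs(np.array(g), onehot(imp))
        cells = np.zeros((3, 3))
        for a, b in zip(g, imp):
            cells[a, b] += 1
        n = cells.sum()
        pe = float(cells.sum(1) @ cells.sum(0)) / n**2
        truth_poly = 0 < np.mean(g) / 2 < 1
        imp_poly = 0 < np.mean(imp) / 2 < 1
        if not truth_poly or not imp_poly or abs(1 - pe) < 1e-12:
            assert got is None
        else:
            assert got == pytest.approx(reference_kappa(cells), abs=1e-12)

    def test_monte_carlo_hard_calls_converge_to_iqs(self):
        rng = np.random.default_rng(42)
        g = rng.integers(0, 3, size=100)
        p = rng.dirichlet((2, 2, 2), size=100)
        expected = iqs(g, p)
        draws = []
        for _ in range(10_000):
            hard = np.array([rng.choice(3, p=pi) for pi in p])
            cells = np.zeros((3, 3))
            for a, b in zip(g, hard):
                cells[a, b] += 1
            draws.append(cells)
        mean_cells = np.mean(draws, axis=0)
        assert reference_kappa(mean_cells) == pytest.approx(expected, abs=0.01)

    def test_monomorphic_truth_is_undefined(self):
        # the polymorphism rule is about allele frequency: an all-het
        # truth has MAF 0.5 and stays defined, an all-ref truth does not
        assert iqs([1, 1, 1], onehot([0, 1, 2])) is not None
        assert iqs([0, 0, 0], onehot([0, 1, 2])) is None

    def test_iqs_can_be_negative_but_never_above_one(self):
        # systematic disagreement drives IQS below 0 (legal, as in
        # observed minima around -0.05)
        g = [0, 0, 2, 2, 1, 1]
        imp = [2, 2, 0, 0, 0, 2]
        val = iqs(g, onehot(imp))
        assert val is not None and -1.0 <= val < 0.0
        rng = np.random.default_rng(0)
        for _ in range(200):
            gg = rng.integers(0, 3, size=12)
            pp = rng.dirichlet((1, 1, 1), size=12)
            v = iqs(gg, pp)
            if v is not None:
                assert v <= 1.0 + 1e-12


class TestDosage:
    @pytest.mark.parametrize("p,want", [
        ((1, 0, 0), 0.0), ((0, 0, 1), 2.0), ((0.2, 0.5, 0.3), 1.1),
    ])
    def test_expected_alt_count(self, p, want):
        assert dosage(p) == pytest.approx(want)

    def test_unnormalised_rejected(self):
        with pytest.raises(ValueError):
            dosage((0.5, 0.5, 0.5))

    def test_identical_dosages_correlate_perfectly(self):
        g = [0, 1, 2, 1]
        assert dosage_correlation(g, onehot(g)) == pytest.approx(1.0)

    def test_monomorphic_truth_undefined(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet((1, 1, 1), size=5)
        assert dosage_correlation([1, 1, 1, 1, 1], p) is None

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=30)
        p = rng.dirichlet((1, 1, 1), size=30)
        got = dosage_correlation(g, p)
        d = p @ [0, 1, 2]
        x, y = g - g.mean(), d - d.mean()
        want = (x @ y) / np.sqrt((x @ x) * (y @ y))
        assert got == pytest.approx(want, abs=1e-12)


class TestMaskingPlan:
    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            MaskingPlan(("a", "a"), seed=1)

    def test_random_selection_is_prefix_of_permutation(self):
        plan5 = MaskingPlan.random(list("abcdefgh"), 5, seed=3)
        plan3 = MaskingPlan.random(list("abcdefgh"), 3, seed=3)
        assert plan5.ids[:3] == plan3.ids

    def test_oversized_plan_rejected_with_counts(self):
        with pytest.raises(ValueError, match="only 2"):
            MaskingPlan.random(["a", "b"], 5, seed=0)


def toy_masking_setup(n_variants=6):
    variants = [Variant(f"v{j}", 10 * (j + 1)) for j in range(n_variants)]
    rng = np.random.default_rng(2)
    truth = {iid: rng.integers(0, 3, size=n_variants) for iid in ("a", "b", "c")}
    maf = rng.uniform(0.001, 0.4, size=n_variants)
    return variants, truth, maf


class TestMaskingExperiment:
    def test_oracle_method_scores_one_everywhere_polymorphic(self):
        variants, truth, maf = toy_masking_setup()
        methods = {
            "oracle": lambda iid: GenotypeProbabilities(
                [iid], variants, onehot(truth[iid])[None]
            )
        }
        plan = MaskingPlan(("a", "b", "c"), seed=0)
        records, frame = run_masking_experiment(truth, variants, maf, methods, plan)
        assert len(records) == len(variants)
        for r in records:
            if r.valid_iqs:
                assert r.iqs == pytest.approx(1.0)
            if r.valid_corr:
                assert r.correlation == pytest.approx(1.0)
        assert any(r.valid_iqs for r in records)

    def test_empty_plan_warns_and_returns_nothing(self):
        variants, truth, maf = toy_masking_setup()
        with pytest.warns(UserWarning, match="empty masking plan"):
            records, frame = run_masking_experiment(
                truth, variants, maf, {}, MaskingPlan((), seed=0)
            )
        assert records == [] and frame.empty


class TestSummaries:
    def records_frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["method", "vid", "true_maf", "iqs", "correlation",
                     "valid_iqs", "valid_corr", "n_individuals"],
        )

    def test_single_bin_occupancy(self):
        frame = self.records_frame(
            [("m", "v1", 0.2, 0.5, 0.6, True, True, 10)]
        )
        out = summarize_by_maf(frame)
        iqs_rows = out[out.metric == "iqs"]
        occupied = iqs_rows[iqs_rows.bin_low == 0.05]
        empty = iqs_rows[iqs_rows.bin_low < 0.05]
        assert int(occupied.n_snp_p.iloc[0]) == 1
        assert (empty.n_snp_p == 0).all()
        assert empty["mean"].isna().all()

    def test_hand_computed_means_and_variances(self):
        rows = [
            ("m", "v1", 0.005, 0.2, 0.3, True, True, 5),
            ("m", "v2", 0.008, 0.4, 0.5, True, True, 5),
            ("m", "v3", 0.02, 0.6, 0.7, True, True, 5),
            ("m", "v4", 0.03, 0.8, 0.9, True, True, 5),
            ("m", "v5", 0.2, 1.0, 1.0, True, True, 5),
            ("m", "v6", 0.3, 0.0, np.nan, True, False, 5),
        ]
        out = summarize_by_maf(self.records_frame(rows))
        iq = out[(out.metric == "iqs") & (out.bin_low == 0.0)]
        assert iq["mean"].iloc[0] == pytest.approx(np.mean([0.2, 0.4]))
        assert iq["var"].iloc[0] == pytest.approx(np.var([0.2, 0.4], ddof=1))
        corr_common = out[(out.metric == "correlation") & (out.bin_low == 0.05)]
        assert int(corr_common.n_snp_p.iloc[0]) == 1  # invalid one excluded

    def test_maf_exactly_at_bin_edge_goes_left(self):
        frame = self.records_frame(
            [("m", "v1", 0.05, 0.5, 0.5, True, True, 3)]
        )
        out = summarize_by_maf(frame)
        iq = out[out.metric == "iqs"]
        assert int(iq[iq.bin_low == 0.01].n_snp_p.iloc[0]) == 1
        assert int(iq[iq.bin_low == 0.05].n_snp_p.iloc[0]) == 0

    def test_overlapping_bins_rejected(self):
        frame = self.records_frame([])
        with pytest.raises(ValueError, match="overlap"):
            summarize_by_maf(frame, bins=[(0, 0.1), (0.05, 0.2)])

    def test_out_of_range_variants_counted_as_excluded(self):
        frame = self.records_frame(
            [("m", "v1", 0.45, 0.5, 0.5, True, True, 3)]
        )
        out = summarize_by_maf(frame)
        assert out.attrs["excluded"] == 1
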