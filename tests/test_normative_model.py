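import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cctool.data_model import StructuralTable
from cctool.columns import STRUCTURAL_COLUMNS
from cctool.normative_model import (
    STUDY_BIN_EDGES,
    assign_bins,
    compute_bin_norms,
    compute_w_scores,
    fit_loess,
    loess_predict,
    make_age_bins,
    optimize_span,
)


def _struct_table(values: np.ndarray, ids=None) -> StructuralTable:
    """Wrap an n x 33 array as a StructuralTable (shifted into legal ranges)."""
    n = len(values)
    ids = ids or [f"S{i}" for i in range(n)]
    df = pd.DataFrame({"subject_id": ids})
    for j, col in enumerate(STRUCTURAL_COLUMNS):
        v = values[:, j] if values.ndim == 2 else values
        if col.startswith("volume") or col.startswith("md"):
            df[col] = 500.0 + v
        else:
            df[col] = 0.5 + 0.01 * v
    return StructuralTable(df)


class TestLoess:
    @pytest.mark.parametrize("degree", [1, 2])
    @pytest.mark.parametrize("span", [0.3, 0.6, 1.0])
    def test_reproduces_linear_data_exactly(self, degree, span):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 10, 25))
        y = 2.0 + 0.5 * x
        x_new = np.linspace(0, 10, 13)
        np.testing.assert_allclose(
            loess_predict(x, y, span, degree, x_new), 2.0 + 0.5 * x_new, atol=1e-8
        )

    def test_three_point_tricube_hand_oracle(self):
        # neighbours at d = (1, 0, 1), d_max = 1 -> tricube weights (0, 1, 0);
        # the minimum-norm weighted linear fit passes through the centre point
        pred = loess_predict(np.array([-1.0, 0, 1]), np.array([1.0, 0, 1]), 1.0, 1,
                             np.array([0.0]))
        assert pred[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_y_gives_constant_predictions(self):
        x = np.linspace(0, 5, 12)
        np.testing.assert_allclose(
            loess_predict(x, np.full(12, 3.3), 0.5, 2, x), 3.3, atol=1e-10
        )

    def test_too_few_neighbours_error_names_span(self):
        x = np.linspace(0, 1, 20)
        with pytest.raises(ValueError, match="0.05"):
            loess_predict(x, x, 0.05, 2, x)

    def test_matches_statsmodels_lowess_for_degree_one(self):
        """Independent cross-check: statsmodels' lowess (local linear, tricube)
        agrees with our degree-1 fit when the neighbourhood sizes coincide."""
        sm = pytest.importorskip("statsmodels.api")
        x = np.linspace(0, 6, 50)
        rng = np.random.default_rng(7)
        y = np.sin(x) + rng.normal(0, 0.1, 50)
        ours = loess_predict(x, y, 0.4, 1, x)
        theirs = sm.nonparametric.lowess(y, x, frac=0.4, it=0, return_sorted=False)
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestOptimizeSpan:
    def test_brent_on_convex_test_function(self):
        span = optimize_span(np.linspace(0, 1, 30), np.zeros(30), degree=1,
                             objective=lambda s: (s - 0.4) ** 2)
        assert span == pytest.approx(0.4, abs=1e-4)

    def test_matches_grid_oracle_on_noisy_quadratic(self):
        rng = np.random.default_rng(42)
        x = np.sort(rng.uniform(0, 10, 60))
        y = 0.5 * (x - 5) ** 2 + rng.normal(0, 1, 60)
        grid = np.arange(0.05, 1.0001, 0.005)
        sse = lambda s: fit_loess(x, y, s, 2).sse
        grid_vals = [sse(s) for s in grid]
        best = int(np.argmin(grid_vals))
        span = optimize_span(x, y, degree=2, objective="sse")
        assert sse(span) <= grid_vals[best] + 1e-6 or abs(span - grid[best]) <= 0.005

    def test_infeasible_lower_bound_raised(self, caplog):
        # n = 10, degree 2: span 0.05 gives 1 neighbour; bound must rise
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 10, 10))
        y = x**2 + rng.normal(0, 1, 10)
        with caplog.at_level("WARNING"):
            span = optimize_span(x, y, degree=2, objective="sse")
        assert span >= 3 / 10 - 1e-9
        assert any("feasible" in r.message for r in caplog.records)

    def test_loocv_objective_prefers_large_span_for_global_quadratic(self):
        rng = np.random.default_rng(9)
        x = np.sort(rng.uniform(0, 10, 30))
        y = (x - 5) ** 2 + rng.normal(0, 0.5, 30)
        assert optimize_span(x, y, degree=2, objective="loocv") > 0.5


class TestAgeBins:
    def test_study_bins_are_the_four_published_intervals(self):
        edges = make_age_bins("study")
        np.testing.assert_allclose(edges, STUDY_BIN_EDGES)
        # half-open convention reproduces the listed intervals
        assert assign_bins(np.array([72.0, 96.5, 96.6, 122.0, 122.1, 148.0, 148.1, 173.0]),
                           edges).tolist() == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_equal_bins_have_equal_width(self):
        edges = make_age_bins("equal", 0, 100, 4)
        np.testing.assert_allclose(np.diff(edges), 25.0)

    def test_single_equal_bin(self):
        np.testing.assert_allclose(make_age_bins("equal", 60, 200, 1), [60, 200])

    def test_out_of_range_age_snaps_to_nearest_bin(self, caplog):
        with caplog.at_level("WARNING"):
            idx = assign_bins(np.array([60.0, 180.0]), make_age_bins("study"))
        assert idx.tolist() == [0, 3]
        assert any("outside" in r.message for r in caplog.records)


class TestBinNorms:
    def test_two_point_bin_mean_and_sd(self):
        table = _struct_table(np.random.default_rng(8).normal(size=(4, 33)))
        df = table.df.copy()
        df.loc[:, "volume_anterior"] = [1.0, 3.0, 5.0, 9.0]
        table = StructuralTable(df)
        ages = np.array([80.0, 90.0, 130.0, 140.0])
        norms = compute_bin_norms(table, ages, np.array([72.0, 122.0, 173.0]))
        assert norms.mu.loc[0, "volume_anterior"] == pytest.approx(2.0)
        assert norms.sigma.loc[0, "volume_anterior"] == pytest.approx(np.sqrt(2))
        assert norms.n.tolist() == [2, 2]

    def test_empty_bin_errors(self):
        table = _struct_table(np.random.default_rng(0).normal(size=(6, 33)))
        ages = np.full(6, 80.0)
        with pytest.raises(ValueError, match="bin"):
            compute_bin_norms(table, ages, make_age_bins("study"))

    def test_zero_sd_errors(self):
        table = _struct_table(np.zeros((4, 33)))
        with pytest.raises(ValueError, match="zero normative SD"):
            compute_bin_norms(table, np.array([80.0, 90, 130, 140]),
                              np.array([72.0, 122.0, 173.0]))

    def test_small_bin_warns(self, caplog):
        table = _struct_table(np.random.default_rng(1).normal(size=(4, 33)))
        with caplog.at_level("WARNING"):
            compute_bin_norms(table, np.array([80.0, 90, 130, 140]),
                              np.array([72.0, 122.0, 173.0]))
        assert any("only" in r.message for r in caplog.records)

    def test_default_cohort_fills_study_bins(self):
        """39 FT subjects uniform over 72-173 months leave no bin below 2
        in at least 95% of 100 seeded draws."""
        edges = make_age_bins("study")
        ok = 0
        for seed in range(100):
            ages = np.random.default_rng(seed).uniform(72, 173, 39)
            counts = np.bincount(assign_bins(ages, edges), minlength=4)
            ok += counts.min() >= 2
        assert ok >= 95


class TestWScores:
    def test_formula_identities(self):
        rng = np.random.default_rng(3)
        ft = _struct_table(rng.normal(size=(10, 33)))
        ages = np.linspace(75, 170, 10)
        norms = compute_bin_norms(ft, ages, np.array([72.0, 173.0]))
        # a subject sitting exactly at the bin mean scores 0; mean + sd scores 1
        probe = ft.df.iloc[[0]].copy()
        for col in STRUCTURAL_COLUMNS:
            probe[col] = norms.mu.loc[0, col]
        w0 = compute_w_scores(StructuralTable(probe), np.array([100.0]), norms)
        np.testing.assert_allclose(w0.w.to_numpy(), 0.0, atol=1e-12)
        for col in STRUCTURAL_COLUMNS:
            probe[col] = norms.mu.loc[0, col] + norms.sigma.loc[0, col]
        w1 = compute_w_scores(StructuralTable(probe), np.array([100.0]), norms)
        np.testing.assert_allclose(w1.w.to_numpy(), 1.0, atol=1e-12)

    def test_ft_scored_against_own_norms_is_standardized(self, default_cohort):
        from cctool.preprocess import build_matrices

        clinical, structural = default_cohort
        ft = build_matrices(clinical, structural, group="FT")
        table = StructuralTable(
            pd.DataFrame(ft.Y, columns=ft.y_names).assign(subject_id=ft.row_ids)
        )
        norms = compute_bin_norms(table, ft.X[:, 0], make_age_bins("study"))
        w = compute_w_scores(table, ft.X[:, 0], norms)
        for b in range(4):
            block = w.w[w.bin_index.to_numpy() == b]
            np.testing.assert_allclose(block.mean(axis=0), 0, atol=1e-8)
            np.testing.assert_allclose(block.std(axis=0, ddof=1), 1, atol=1e-8)

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(0.5, 2), shift=st.floats(-2, 2))
    def test_affine_invariance(self, scale, shift):
        """Jointly rescaling a measure in the FT and VPT tables leaves its
        W-scores unchanged (the affine transform cancels)."""
        rng = np.random.default_rng(12)
        ft_vals = rng.normal(size=(12, 33))
        vpt_vals = rng.normal(size=(5, 33))
        ages_ft = np.linspace(75, 170, 12)
        ages_vpt = np.linspace(80, 160, 5)
        edges = np.array([72.0, 122.0, 173.0])

        def wtab(f, v):
            norms = compute_bin_norms(_struct_table(f), ages_ft, edges)
            return compute_w_scores(_struct_table(v, ids=[f"V{i}" for i in range(5)]),
                                    ages_vpt, norms)

        base = wtab(ft_vals, vpt_vals)
        scaled = wtab(scale * ft_vals + shift, scale * vpt_vals + shift)
        np.testing.assert_allclose(scaled.w.to_numpy(), base.w.to_numpy(), atol=1e-6)

    def test_loess_basis_runs_and_centres_ft_trajectory(self):
        rng = np.random.default_rng(5)
        ft = _struct_table(rng.normal(size=(20, 33)))
        ages = np.linspace(75, 170, 20)
        from cctool.normative_model import fit_normative_model

        norms = fit_normative_model(ft, ages, np.array([72.0, 122.0, 173.0]),
                                    objective="loocv")
        w = compute_w_scores(ft, ages, norms, basis="loess")
        assert np.isfinite(w.w.to_numpy()).all()
        assert abs(w.w.to_numpy().mean()) < 1.0
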