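"""Differential-expression stage: background correction, normalization,
replicate handling, moderation, tests and FDR adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hippostress import diffexpr
from hippostress.diffexpr import (
    FoldChangeMatrix,
    ModerationParams,
    TwoColorArray,
    TwoColorArraySet,
    aquantile_between_arrays,
    average_dye_swaps,
    benjamini_hochberg,
    collapse_probes_to_genes,
    compute_foldchanges,
    fit_moderation_params,
    loess_within_array,
    moderate_variances,
    normexp_background_correct,
    paired_de_test,
    timecourse_contrast,
)
from conftest import bh_bruteforce


def _matrix(values: dict, groups: dict, gene_map=None) -> FoldChangeMatrix:
    vals = pd.DataFrame(values)
    meta = pd.DataFrame(
        [{"group": g, "replicate": r, "swapped": s} for (g, r, s) in
         (groups[c] for c in vals.columns)],
        index=list(vals.columns))
    return FoldChangeMatrix(vals, meta, gene_map)


# ---------------------------------------------------------------------------
# normexp


class TestNormexp:
    def _arrays(self, rng, n=2000, mu=50.0, sigma=5.0, alpha=200.0):
        bg = rng.normal(mu, sigma, n)
        sig = rng.exponential(alpha, n)
        fg = np.maximum(bg + sig, 0)
        probes = pd.Index([f"p{i}" for i in range(n)])
        zero = np.zeros(n)
        return TwoColorArraySet([TwoColorArray("a1", probes, fg, zero, fg, zero,
                                               "red", "g", "1")])

    def test_output_strictly_positive_and_monotone(self):
        rng = np.random.default_rng(0)
        arrays = self._arrays(rng)
        corrected = normexp_background_correct(arrays)
        out = corrected.arrays[0].red_fg
        assert np.all(out > 0)
        x = arrays.arrays[0].red_fg
        order = np.argsort(x)
        assert np.all(np.diff(out[order]) >= -1e-9)

    def test_high_intensity_asymptote_matches_formula(self):
        # far above background the posterior mean approaches x - mu - sigma^2/alpha
        from hippostress.diffexpr import normexp_posterior_mean
        mu, sigma, alpha = 50.0, 5.0, 200.0
        x = np.array([mu + 20 * sigma])
        expected = x - mu - sigma**2 / alpha
        got = normexp_posterior_mean(x, mu, sigma, alpha)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_fit_recovers_parameters(self):
        from hippostress.diffexpr import _normexp_fit
        rng = np.random.default_rng(1)
        x = rng.normal(100.0, 10.0, 20000) + rng.exponential(300.0, 20000)
        mu, sigma, alpha = _normexp_fit(x)
        assert mu == pytest.approx(100.0, rel=0.1)
        assert alpha == pytest.approx(300.0, rel=0.1)

    def test_degenerate_input_falls_back_with_warning(self):
        probes = pd.Index(["p1", "p2", "p3"])
        const = np.full(3, 10.0)
        arrays = TwoColorArraySet([TwoColorArray("a1", probes, const, np.zeros(3),
                                                 const, np.zeros(3), "red")])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            out = normexp_background_correct(arrays)
        assert np.all(out.arrays[0].red_fg > 0)


# ---------------------------------------------------------------------------
# loess / aquantile / logFC


class TestNormalization:
    def test_constant_m_removed(self):
        rng = np.random.default_rng(2)
        A = rng.uniform(6, 14, 300)
        M = np.full(300, 1.7)
        out = loess_within_array(M, A)
        assert np.all(np.abs(out) < 1e-6)

    def test_quadratic_trend_decorrelated(self):
        rng = np.random.default_rng(3)
        A = rng.uniform(6, 14, 2000)
        M = 0.05 * (A - 10) ** 2 + rng.normal(0, 0.1, 2000)
        out = loess_within_array(M, A)
        assert abs(np.corrcoef(out, A)[0, 1]) < 0.05

    def test_too_few_points_identity_with_warning(self):
        M = np.arange(5.0)
        with pytest.warns(RuntimeWarning, match="fewer than 10"):
            out = loess_within_array(M, M)
        np.testing.assert_array_equal(out, M)

    def test_aquantile_equalizes_sorted_a(self):
        rng = np.random.default_rng(4)
        A = pd.DataFrame(rng.normal(10, [1, 2, 3], (500, 3)))
        out = aquantile_between_arrays(A)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 3):
            np.testing.assert_allclose(np.sort(out.iloc[:, j].to_numpy()), ref,
                                       atol=1e-12)

    def test_aquantile_identical_distributions_unchanged(self):
        rng = np.random.default_rng(5)
        col = np.sort(rng.normal(10, 1, 200))
        A = pd.DataFrame({"a": col, "b": rng.permutation(col)})
        out = aquantile_between_arrays(A)
        np.testing.assert_allclose(out["a"], A["a"], atol=1e-9)
        np.testing.assert_allclose(out["b"], A["b"], atol=1e-9)

    def test_foldchange_values_and_dye_orientation(self):
        probes = pd.Index([f"p{i}" for i in range(12)])
        stress = np.full(12, 400.0)
        control = np.full(12, 100.0)
        original = TwoColorArray("a1", probes, stress, np.zeros(12), control,
                                 np.zeros(12), "red", "acute", "1")
        swapped = TwoColorArray("a2", probes, stress, np.zeros(12), control,
                                np.zeros(12), "green", "acute", "1")
        fc = compute_foldchanges(TwoColorArraySet([original, swapped]), loess=False)
        np.testing.assert_allclose(fc.values["acute.1.a"], 2.0, atol=1e-9)
        # swapped array: stress on green, so the log-ratio flips sign
        np.testing.assert_allclose(fc.values["acute.1.b"], -2.0, atol=1e-9)
        assert fc.meta.loc["acute.1.b", "swapped"]


# ---------------------------------------------------------------------------
# replicate handling


class TestReplicates:
    def test_swap_pair_averaged(self):
        m = _matrix({"g.1.a": [0.8], "g.1.b": [1.2]},
                    {"g.1.a": ("g", "1", False), "g.1.b": ("g", "1", True)})
        out = average_dye_swaps(m)
        assert out.values.loc[0, "g.1"] == pytest.approx(1.0)

    def test_missing_member_uses_finite_value(self):
        m = _matrix({"g.1.a": [np.nan], "g.1.b": [0.6]},
                    {"g.1.a": ("g", "1", False), "g.1.b": ("g", "1", True)})
        assert average_dye_swaps(m).values.loc[0, "g.1"] == pytest.approx(0.6)

    def test_unpaired_column_passes_with_warning(self):
        m = _matrix({"g.1.a": [0.5]}, {"g.1.a": ("g", "1", False)})
        with pytest.warns(RuntimeWarning, match="no dye-swap partner"):
            out = average_dye_swaps(m)
        assert out.values.loc[0, "g.1"] == pytest.approx(0.5)

    def test_three_columns_per_replicate_rejected(self):
        m = _matrix({"x": [1.0], "y": [1.0], "z": [1.0]},
                    {c: ("g", "1", False) for c in ("x", "y", "z")})
        with pytest.raises(ValueError, match="max 2"):
            average_dye_swaps(m)

    @pytest.mark.parametrize("probe_values, expected", [
        ([0.7], 0.7),                  # single probe: identity
        ([0.2, 0.9, 1.0], 0.9),        # odd count: middle value
        ([0.2, 0.4, 0.9, 1.1], 0.65),  # even count: mean of the two middle
    ])
    def test_median_probe_collapse(self, probe_values, expected):
        probes = [f"p{i}" for i in range(len(probe_values))]
        m = _matrix({"g.1": probe_values}, {"g.1": ("g", "1", False)},
                    gene_map=pd.Series("GENE", index=range(len(probe_values))))
        m.values.index = probes
        m.gene_map = pd.Series("GENE", index=probes)
        out = collapse_probes_to_genes(m)
        assert out.values.loc["GENE", "g.1"] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# moderation


class TestModeration:
    def test_stated_shrinkage_formula(self):
        params = ModerationParams(d0=2.0, s0_sq=2.0)
        out = moderate_variances(np.array([1.0, 4.0]), 2.0, params)
        np.testing.assert_allclose(out, [1.5, 3.0])

    def test_no_shrinkage_limit(self):
        s2 = np.array([0.5, 2.0, 7.0])
        out = moderate_variances(s2, 3.0, ModerationParams(d0=0.0, s0_sq=1.0))
        np.testing.assert_array_equal(out, s2)

    def test_full_shrinkage_limit(self):
        out = moderate_variances(np.array([0.5, 2.0]), 3.0,
                                 ModerationParams(d0=np.inf, s0_sq=1.3))
        np.testing.assert_allclose(out, 1.3)

    def test_fit_recovers_planted_hyperparameters(self):
        # s^2 ~ s0^2 * F(d, d0) exactly matches the hierarchical model
        rng = np.random.default_rng(6)
        d, d0, s0_sq = 4.0, 8.0, 2.5
        s2 = s0_sq * rng.f(d, d0, size=200_000)
        params = fit_moderation_params(s2, d)
        assert params.d0 == pytest.approx(d0, rel=0.1)
        assert params.s0_sq == pytest.approx(s0_sq, rel=0.05)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="cannot fit prior"):
            fit_moderation_params(np.zeros(10), 2.0)


# ---------------------------------------------------------------------------
# paired test / time course


class TestPairedDE:
    def _simple(self, reps, group="acute"):
        cols = {f"{group}.{i + 1}": [v] for i, v in enumerate(reps)}
        groups = {c: (group, c.split(".")[1], False) for c in cols}
        return _matrix(cols, groups)

    def test_zero_replicates_not_significant(self):
        res = paired_de_test(self._simple([0.0, 0.0, 0.0]), "acute", moderation=False)
        assert res["logfc"].iloc[0] == 0.0
        assert not res["significant"].iloc[0]
        assert res["p"].iloc[0] == 1.0  # zero-variance zero-mean convention

    def test_closed_form_t_and_p(self):
        # mean 1.0, sd 0.2, n 3 -> t = 8.6603, two-sided p (df 2) = 0.013072
        res = paired_de_test(self._simple([0.8, 1.0, 1.2]), "acute", moderation=False)
        assert res["t"].iloc[0] == pytest.approx(8.6603, abs=1e-3)
        assert res["p"].iloc[0] == pytest.approx(0.01307, abs=2e-4)

    def test_thresholds_are_strict(self):
        # |logFC| exactly 0.5 is not differential no matter how small p is
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(rng.normal(0, 0.01, (50, 3)),
                            columns=["g.1", "g.2", "g.3"])
        vals.iloc[0] = [0.5, 0.5, 0.5]
        meta = pd.DataFrame({"group": "g", "replicate": ["1", "2", "3"],
                             "swapped": False}, index=vals.columns)
        res = paired_de_test(FoldChangeMatrix(vals, meta), "g", moderation=False)
        assert res["logfc"].iloc[0] == pytest.approx(0.5)
        assert res["adj_p"].iloc[0] < 0.05
        assert not res["significant"].iloc[0]

    def test_single_replicate_errors(self):
        m = self._simple([1.0])
        with pytest.raises(ValueError, match="insufficient degrees of freedom"):
            paired_de_test(m, "acute")

    def test_moderated_reduces_to_plain_t_when_d0_zero(self):
        rng = np.random.default_rng(8)
        vals = pd.DataFrame(rng.normal(0, 1, (200, 4)),
                            columns=[f"g.{i}" for i in range(1, 5)])
        meta = pd.DataFrame({"group": "g", "replicate": [str(i) for i in range(1, 5)],
                             "swapped": False}, index=vals.columns)
        m = FoldChangeMatrix(vals, meta)
        plain = paired_de_test(m, "g", moderation=False)
        mean, var, n = np.asarray(vals.mean(1)), np.asarray(vals.var(1, ddof=1)), 4
        params = ModerationParams(d0=0.0, s0_sq=1.0)
        s2 = moderate_variances(var, n - 1, params)
        t_expected = mean / np.sqrt(s2 / n)
        np.testing.assert_allclose(plain["t"], t_expected, rtol=1e-10)

    def test_unbiased_logfc_on_planted_profiles(self):
        # over 100 seeded datasets the per-gene estimate has mean error < 0.02
        from hippostress.simulate import SimulationConfig, simulate_foldchange_dataset
        errs = []
        for seed in range(100):
            cfg = SimulationConfig(n_genes=60, gene_cluster_sizes={1: 10, 2: 10, 3: 10},
                                   marker_gene_count=0, noise_sd=0.1, seed=seed)
            matrix, truth = simulate_foldchange_dataset(cfg)
            averaged = average_dye_swaps(matrix)
            for group in averaged.groups:
                res = paired_de_test(averaged, group, moderation=False)
                for cid in (1, 2, 3):
                    genes = truth.gene_cluster.index[truth.gene_cluster == cid]
                    true_val = truth.profiles.loc[cid, group]
                    errs.append(res.loc[genes, "logfc"].mean() - true_val)
        assert abs(np.mean(errs)) < 0.02


class TestTimecourse:
    def _two_groups(self, a_vals, b_vals):
        cols, groups = {}, {}
        for i, v in enumerate(a_vals):
            cols[f"t1.{i + 1}"] = v
            groups[f"t1.{i + 1}"] = ("t1", str(i + 1), False)
        for i, v in enumerate(b_vals):
            cols[f"t3.{i + 1}"] = v
            groups[f"t3.{i + 1}"] = ("t3", str(i + 1), False)
        return _matrix(cols, groups)

    def test_identical_periods_not_significant(self):
        m = self._two_groups([[0.4], [0.5], [0.6]], [[0.4], [0.5], [0.6]])
        res = timecourse_contrast(m, "t1", "t3", moderation=False)
        assert res["delta_logfc"].iloc[0] == pytest.approx(0.0)
        assert not res["significant"].iloc[0]

    def test_sign_convention_earlier_minus_later(self):
        # change greater in period 1 -> positive estimate
        m = self._two_groups([[1.0], [1.0], [1.0]], [[0.0], [0.0], [0.0]])
        res = timecourse_contrast(m, "t1", "t3", moderation=False)
        assert res["delta_logfc"].iloc[0] == pytest.approx(1.0)

    def test_null_rejection_rate_nominal(self):
        rng = np.random.default_rng(9)
        n_genes = 2000
        vals = pd.DataFrame(rng.normal(0, 1, (n_genes, 6)),
                            columns=[f"t{g}.{r}" for g in (1, 3) for r in (1, 2, 3)])
        meta = pd.DataFrame([(f"t{g}", str(r), False) for g in (1, 3) for r in (1, 2, 3)],
                            index=vals.columns, columns=["group", "replicate", "swapped"])
        res = timecourse_contrast(FoldChangeMatrix(vals, meta), "t1", "t3",
                                  moderation=False)
        frac = (res["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_genes))

    def test_unknown_group_rejected(self):
        m = self._two_groups([[1.0], [1.0]], [[0.0], [0.0]])
        with pytest.raises(KeyError):
            timecourse_contrast(m, "t1", "nope")


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


class TestBenjaminiHochberg:
    def test_singleton_identity(self):
        np.testing.assert_allclose(benjamini_hochberg(np.array([0.03])), [0.03])

    def test_worked_example(self):
        out = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_equal_pvalues_unchanged(self):
        out = benjamini_hochberg(np.full(7, 0.2))
        np.testing.assert_allclose(out, 0.2)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg(np.array([0.5, 1.2]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    def test_matches_bruteforce_and_preserves_order(self, pvals):
        p = np.array(pvals)
        adj = benjamini_hochberg(p)
        np.testing.assert_allclose(adj, bh_bruteforce(p), atol=1e-12)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(10)
        p = rng.uniform(size=200)
        ours = benjamini_hochberg(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)
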