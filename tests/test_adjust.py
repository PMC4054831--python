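import warnings

import numpy as np
import pandas as pd
import pytest

from salivamix import (
    BetaMatrix,
    ReferencePanel,
    adjust_for_composition,
    classify_marker_correlation,
    detect_outlier_samples,
    estimate_proportion,
    fit_marker_models,
    screen_discriminative,
    select_marker,
    simulate_cohort,
    simulate_mixture_series,
    simulate_reference_panel,
)


def toy_panel():
    return ReferencePanel(
        pd.DataFrame(
            {"buccal": [0.82, 0.70, 0.30, 0.50], "blood": [0.05, 0.20, 0.20, 0.48]},
            index=["m1", "m2", "m3", "m4"],
        )
    )


class TestScreenDiscriminative:
    def test_ranked_by_absolute_difference(self):
        top = screen_discriminative(toy_panel(), "buccal", "blood", k=2)
        assert list(top.index) == ["m1", "m2"]  # |Δ| = 0.77, 0.50

    def test_identical_profiles_tie_with_warning(self):
        panel = ReferencePanel(
            pd.DataFrame({"buccal": [0.5, 0.5, 0.5], "blood": [0.5, 0.5, 0.5]},
                         index=["a", "b", "c"])
        )
        with pytest.warns(UserWarning, match="tie"):
            top = screen_discriminative(panel, "buccal", "blood", k=2)
        assert list(top.index) == ["a", "b"]

    def test_k_exceeding_panel_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            screen_discriminative(toy_panel(), "buccal", "blood", k=5)


class TestEstimateProportion:
    @pytest.mark.parametrize(
        "obs,expected", [(0.82, 1.0), (0.05, 0.0), (0.435, 0.5)]
    )
    def test_inverts_mixture_at_marker(self, obs, expected):
        beta = pd.DataFrame({"s1": [obs]}, index=["m1"])
        p = estimate_proportion(
            BetaMatrix(beta=beta), "m1", toy_panel(), "buccal", "blood"
        )
        assert p["s1"] == pytest.approx(expected)

    def test_uninformative_marker_rejected(self):
        beta = pd.DataFrame({"s1": [0.5]}, index=["m4"])  # separation 0.02
        with pytest.raises(ValueError, match="uninformative"):
            estimate_proportion(BetaMatrix(beta=beta), "m4", toy_panel(), "buccal", "blood")

    def test_recovers_series_fractions(self, small_panel):
        panel, truth = small_panel
        fracs = np.linspace(0, 1, 11)
        matrix, _ = simulate_mixture_series(panel, fracs, noise_sd=0.0, seed=3)
        p = estimate_proportion(matrix, truth.marker_cpg, panel, "buccal", "blood")
        np.testing.assert_allclose(p.to_numpy(), fracs, atol=1e-10)


class TestFitMarkerModels:
    def test_duplicate_of_marker_fits_perfectly(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.1, 0.9, 10)
        beta = pd.DataFrame(
            {f"s{i}": [x[i], x[i], 0.4] for i in range(10)},
            index=["marker", "dup", "const"],
        )
        fit = fit_marker_models(BetaMatrix(beta=beta), "marker")
        assert fit.table.loc["dup", "slope:marker"] == pytest.approx(1.0)
        assert fit.table.loc["dup", "intercept"] == pytest.approx(0.0, abs=1e-10)
        assert fit.table.loc["dup", "r2"] == pytest.approx(1.0)
        assert fit.table.loc["const", "slope:marker"] == pytest.approx(0.0)
        assert fit.table.loc["const", "r2"] == 0.0
        assert fit.table.loc["const", "pvalue"] == 1.0
        assert not fit.table.loc["const", "affected"]

    def test_mixture_slope_equals_reference_ratio(self, small_panel):
        panel, truth = small_panel
        matrix, _, _ = simulate_cohort(
            panel, 6, noise_sd=0.0, seed=4,
            proportions=(np.linspace(0.15, 0.85, 6), np.linspace(0.2, 0.8, 6)),
        )
        marker = truth.marker_cpg
        fit = fit_marker_models(matrix, marker)
        delta = panel.means["buccal"] - panel.means["blood"]
        marker_delta = delta.loc[marker]
        expected = (delta / marker_delta).drop(marker)
        got = fit.table["slope:" + marker]
        np.testing.assert_allclose(got, expected.loc[got.index], atol=1e-8)

    def test_zero_variance_marker_errors(self):
        beta = pd.DataFrame(
            {"s1": [0.5, 0.1], "s2": [0.5, 0.2], "s3": [0.5, 0.3]},
            index=["flat", "cg"],
        )
        with pytest.raises(ValueError, match="zero variance"):
            fit_marker_models(BetaMatrix(beta=beta), "flat")

    def test_collinear_second_marker_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.2, 0.8, 8)
        beta = pd.DataFrame(
            np.vstack([x, x, rng.uniform(0, 1, 8)]),
            index=["m_a", "m_b", "cg"],
            columns=[f"s{i}" for i in range(8)],
        )
        with pytest.warns(UserWarning, match="collinear"):
            fit = fit_marker_models(BetaMatrix(beta=beta), ["m_a", "m_b"])
        assert (fit.table["slope:m_b"] == 0).all()


class TestSelectMarker:
    def test_single_candidate_returned(self, cohort):
        _, ptruth, matrix, _, _ = cohort
        chosen, scores = select_marker(matrix, [ptruth.marker_cpg])
        assert chosen == ptruth.marker_cpg

    def test_clean_mixture_proxy_beats_noisy_candidate(self, small_panel):
        panel, truth = small_panel
        matrix, _, _ = simulate_cohort(panel, 8, noise_sd=0.01, seed=5)
        rng = np.random.default_rng(6)
        noisy = matrix.beta.copy()
        bad = truth.discriminative_cpgs[1]
        noisy.loc[bad] = rng.uniform(0, 1, matrix.n_samples)  # destroys linearity
        noisy_matrix = BetaMatrix(beta=noisy)
        chosen, scores = select_marker(noisy_matrix, [truth.marker_cpg, bad])
        assert chosen == truth.marker_cpg
        assert scores[truth.marker_cpg] > scores[bad]

    def test_identical_candidates_tie_to_first_with_warning(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.2, 0.8, 6)
        beta = pd.DataFrame(
            np.vstack([x, x, x * 0.5 + 0.2, rng.uniform(0, 1, 6)]),
            index=["c1", "c2", "cg1", "cg2"],
            columns=[f"s{i}" for i in range(6)],
        )
        with pytest.warns(UserWarning, match="tie"):
            chosen, _ = select_marker(BetaMatrix(beta=beta), ["c1", "c2"])
        assert chosen == "c1"


class TestClassifyMarkerCorrelation:
    def test_duplicates_and_constants(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.1, 0.9, 8)
        rows = {"marker": x, "d1": x, "d2": 1 - x}
        for i in range(3):
            rows[f"flat{i}"] = np.full(8, 0.5)
        beta = pd.DataFrame(rows, index=[f"s{i}" for i in range(8)]).T
        r, counts = classify_marker_correlation(BetaMatrix(beta=beta), "marker")
        assert counts == {"strong": 2, "moderate": 0, "weak": 0, "undefined": 3}
        assert "marker" not in r.index  # self-excluded

    def test_mixture_cpgs_strong_independent_cpgs_weak(self, small_panel):
        panel, truth = small_panel
        matrix, _, _ = simulate_cohort(panel, 10, noise_sd=0.005, seed=7)
        rng = np.random.default_rng(8)
        beta = matrix.beta.copy()
        independent = [f"ind{i}" for i in range(10)]
        for cid in independent:
            beta.loc[cid] = rng.uniform(0.2, 0.8, matrix.n_samples)
        r, counts = classify_marker_correlation(
            BetaMatrix(beta=beta), truth.marker_cpg
        )
        strong_disc = r.loc[
            [c for c in truth.discriminative_cpgs if c != truth.marker_cpg]
        ].abs()
        assert (strong_disc > 0.8).all()
        assert (r.loc[independent].abs() < 0.8).all()


class TestDetectOutliers:
    def test_identical_marker_values_flag_nothing(self):
        beta = pd.DataFrame(
            {f"s{i}": [0.4, 0.1 * i] for i in range(6)}, index=["m", "cg"]
        )
        assert detect_outlier_samples(BetaMatrix(beta=beta), "m") == []

    def test_extreme_composition_pair_excluded(self, small_panel, cohort):
        panel, truth = small_panel
        n = 6
        p_heavy = [0.30, 0.32, 0.34, 0.36, 0.38, 0.99]
        p_light = [0.31, 0.33, 0.35, 0.37, 0.39, 0.97]
        matrix, design, _ = simulate_cohort(
            panel, n, noise_sd=0.005, seed=9, proportions=(p_heavy, p_light)
        )
        flagged = detect_outlier_samples(
            matrix, truth.marker_cpg, design=design
        )
        assert set(flagged) == {"pair6_H", "pair6_L"}

    def test_disabled_rule_returns_empty(self, cohort):
        _, ptruth, matrix, _, _ = cohort
        assert detect_outlier_samples(matrix, ptruth.marker_cpg, enabled=False) == []


class TestAdjustForComposition:
    @pytest.fixture
    def noisy_fit(self, small_panel):
        panel, truth = small_panel
        matrix, design, _ = simulate_cohort(
            panel, 10, noise_sd=0.02, seed=21,
            proportion_sampler={"pair_corr": 0.3, "heavy_offset": 0.1},
        )
        fit = fit_marker_models(matrix, truth.marker_cpg)
        return matrix, fit, truth

    def test_unaffected_cpgs_bit_identical(self, noisy_fit):
        matrix, fit, _ = noisy_fit
        adjusted = adjust_for_composition(matrix, fit)
        unaffected = adjusted.adjusted_mask.index[~adjusted.adjusted_mask]
        before = matrix.beta.loc[unaffected].to_numpy()
        after = adjusted.matrix.beta.loc[unaffected].to_numpy()
        assert (before == after).all()  # bytes-equal, not approx

    def test_noise_free_mixture_adjusts_to_constant(self, small_panel):
        panel, truth = small_panel
        matrix, _, _ = simulate_cohort(
            panel, 8, noise_sd=0.0, seed=22,
            proportions=(np.linspace(0.2, 0.8, 8), np.linspace(0.25, 0.75, 8)),
        )
        fit = fit_marker_models(matrix, truth.marker_cpg)
        adjusted = adjust_for_composition(matrix, fit)
        affected = fit.affected_cpgs
        spread = adjusted.matrix.beta.loc[affected].std(axis=1)
        assert spread.max() < 1e-8

    def test_residual_orthogonality_to_marker(self, noisy_fit):
        matrix, fit, truth = noisy_fit
        adjusted = adjust_for_composition(matrix, fit)
        marker_vals = adjusted.matrix.beta.loc[truth.marker_cpg]
        affected = [c for c in fit.affected_cpgs]
        r = adjusted.matrix.beta.loc[affected].T.corrwith(marker_vals).abs()
        assert r.max() < 0.05

    def test_idempotent_refit_gives_null_slopes(self, noisy_fit):
        matrix, fit, truth = noisy_fit
        adjusted = adjust_for_composition(matrix, fit)
        refit = fit_marker_models(adjusted.matrix, truth.marker_cpg)
        slopes = refit.table.loc[list(fit.affected_cpgs), "slope:" + truth.marker_cpg]
        assert slopes.abs().max() < 1e-6

    def test_injected_effect_survives_adjustment(self, small_panel):
        panel, truth = small_panel
        delta = (panel.means["buccal"] - panel.means["blood"]).abs()
        neutral = delta[delta < 0.01].index[0]  # composition-independent CpG
        matrix, design, _ = simulate_cohort(
            panel, 12, noise_sd=0.01, seed=23,
            proportion_sampler={"pair_corr": 0.3, "heavy_offset": 0.15},
            effect_spec=[(neutral, 0.08)],
        )
        fit = fit_marker_models(matrix, truth.marker_cpg)
        adjusted = adjust_for_composition(matrix, fit)
        diff_before = (
            matrix.beta.loc[neutral, design.heavy].to_numpy()
            - matrix.beta.loc[neutral, design.light].to_numpy()
        ).mean()
        diff_after = (
            adjusted.matrix.beta.loc[neutral, design.heavy].to_numpy()
            - adjusted.matrix.beta.loc[neutral, design.light].to_numpy()
        ).mean()
        assert abs(diff_after - diff_before) < 0.005

    def test_marker_itself_never_adjusted(self, noisy_fit):
        matrix, fit, truth = noisy_fit
        adjusted = adjust_for_composition(matrix, fit)
        np.testing.assert_array_equal(
            adjusted.matrix.beta.loc[truth.marker_cpg],
            matrix.beta.loc[truth.marker_cpg],
        )
        assert not adjusted.adjusted_mask.loc[truth.marker_cpg]

    def test_invalid_anchor_rejected(self, noisy_fit):
        matrix, fit, truth = noisy_fit
        with pytest.raises(ValueError, match="anchor"):
            adjust_for_composition(matrix, fit, anchors={truth.marker_cpg: 1.5})
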