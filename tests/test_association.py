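import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from salivamix import (
    AssociationTable,
    BetaMatrix,
    call_mvps,
    fisher_exact_rxc,
    mean_difference,
    paired_ewas,
    paired_t_test,
    power_paired_t,
    relative_discordance,
    volcano_export,
    wilcoxon_signed_rank_paired,
)
from .conftest import brute_force_wilcoxon


class TestWilcoxonExact:
    def test_floor_for_same_sign_untied_differences(self):
        light = np.linspace(0.1, 0.4, 16)
        heavy = light + np.linspace(0.01, 0.16, 16)  # untied, all positive
        p = wilcoxon_signed_rank_paired(heavy, light, mode="exact")
        assert p == pytest.approx(2 / 2**16)

    def test_symmetric_differences_give_p_one(self):
        heavy = np.array([0.5, 0.5, 0.5, 0.5])
        light = np.array([0.4, 0.6, 0.3, 0.7])  # diffs +.1,-.1,+.2,-.2
        assert wilcoxon_signed_rank_paired(heavy, light, mode="exact") == 1.0

    def test_matches_scipy_on_untied_data(self):
        rng = np.random.default_rng(5)
        for n in (6, 10, 14, 20):
            d = rng.normal(0.2, 1.0, n)
            p_ours = wilcoxon_signed_rank_paired(d, np.zeros(n), mode="exact")
            p_scipy = stats.wilcoxon(d, mode="exact").pvalue
            assert p_ours == pytest.approx(p_scipy, abs=1e-12)

    def test_all_sign_patterns_match_brute_force_n5(self):
        d0 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        for signs in itertools.product([-1, 1], repeat=5):
            d = d0 * np.array(signs)
            p = wilcoxon_signed_rank_paired(d, np.zeros(5), mode="exact")
            assert p == pytest.approx(brute_force_wilcoxon(d), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        diffs=st.lists(
            st.integers(-5, 5), min_size=2, max_size=12
        ).filter(lambda d: any(x != 0 for x in d))
    )
    def test_exact_matches_brute_force_with_ties_and_zeros(self, diffs):
        d = np.array(diffs, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = wilcoxon_signed_rank_paired(d, np.zeros(len(d)), mode="exact")
        assert p == pytest.approx(brute_force_wilcoxon(d), abs=1e-12)

    def test_all_zero_differences_warn_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            p = wilcoxon_signed_rank_paired([0.5, 0.5], [0.5, 0.5])
        assert p == 1.0

    def test_approx_agrees_with_exact_at_moderate_n(self):
        rng = np.random.default_rng(11)
        d = rng.normal(0.1, 1.0, 24)
        p_exact = wilcoxon_signed_rank_paired(d, np.zeros(24), mode="exact")
        p_approx = wilcoxon_signed_rank_paired(d, np.zeros(24), mode="approx")
        assert p_approx == pytest.approx(p_exact, abs=0.02)

    def test_pratt_zero_handling_hand_case(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, 3.0])
        p_wilcox = wilcoxon_signed_rank_paired(d, np.zeros(5), zero_method="wilcox")
        assert p_wilcox == pytest.approx(2 / 2**3)
        # pratt: zeros take midrank 1.5 but drop from the statistic; the
        # nonzero ranks become {3,4,5} and observed W+ = 12 is the most
        # extreme of the 2^3 sign assignments -> same doubled tail 2/8
        p_pratt = wilcoxon_signed_rank_paired(d, np.zeros(5), zero_method="pratt")
        assert p_pratt == pytest.approx(2 / 2**3)
        with pytest.raises(ValueError, match="zero_method"):
            wilcoxon_signed_rank_paired(d, np.zeros(5), zero_method="bogus")


class TestPairedEwas:
    def test_vectorized_path_matches_per_row_calls(self, small_panel, design4):
        rng = np.random.default_rng(13)
        samples = design4.sample_ids
        beta = pd.DataFrame(
            rng.uniform(0.1, 0.9, (30, len(samples))),
            index=[f"cg{i}" for i in range(30)],
            columns=samples,
        )
        # plant ties and zero differences in some rows
        beta.iloc[0] = 0.5
        beta.iloc[1, :4] = beta.iloc[1, 4:].to_numpy()
        matrix = BetaMatrix(beta=beta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = paired_ewas(matrix, design4, mode="exact")
            for cpg in matrix.cpg_ids:
                expected = wilcoxon_signed_rank_paired(
                    beta.loc[cpg, design4.heavy],
                    beta.loc[cpg, design4.light],
                    mode="exact",
                )
                assert table.table.loc[cpg, "pvalue"] == pytest.approx(expected)

    def test_missing_values_excluded_complete_case(self, design4):
        beta = pd.DataFrame(
            np.full((2, 8), 0.5), index=["cg1", "cg2"],
            columns=design4.sample_ids,
        )
        beta.loc["cg1", "a_H"] = np.nan
        beta.loc["cg2"] = np.linspace(0.1, 0.8, 8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = paired_ewas(BetaMatrix(beta=beta), design4)
        assert np.isnan(table.table.loc["cg1", "pvalue"])
        assert not np.isnan(table.table.loc["cg2", "pvalue"])


class TestMeanDifferenceAndMvps:
    def test_mean_difference_arithmetic(self):
        assert mean_difference([0.6, 0.6], [0.5, 0.5]) == pytest.approx(0.1)
        assert mean_difference([0.3], [0.3]) == 0.0
        assert mean_difference(
            [0.27, 0.25, 0.29], [0.20, 0.20, 0.20]
        ) == pytest.approx(0.07)

    def _table(self, pvals, diffs, label):
        frame = pd.DataFrame(
            {
                "pvalue": pvals,
                "mean_diff": diffs,
                "significant": np.array(pvals) < 0.01,
            },
            index=[f"cg{i}" for i in range(len(pvals))],
        )
        return AssociationTable(frame, 0.01, 0.05, n_pairs=8, label=label)

    def test_intersection_rule_on_toy_tables(self):
        t1 = self._table(
            [0.001, 0.001, 0.5, 0.001, 0.001, 0.001],
            [0.10, 0.02, 0.10, 0.06, -0.08, 0.05],
            "a",
        )
        t2 = self._table(
            [0.002, 0.005, 0.001, 0.5, 0.003, 0.009],
            [0.08, 0.03, 0.09, 0.07, -0.07, 0.04],
            "b",
        )
        mvps, counts = call_mvps([t1, t2], 0.01, 0.05)
        # cg0: P ok in both, |d| ok in both -> MVP; cg4 likewise (negative d)
        # cg1 fails d, cg2 fails P in t1, cg3 fails P in t2, cg5 d not > 0.05
        assert list(mvps) == ["cg0", "cg4"]
        assert counts["p_intersection"] == 4
        assert counts["mvps"] == 2

    def test_permissive_thresholds_flag_everything(self):
        t = self._table([0.5, 0.9], [0.0, 0.01], "a")
        mvps, _ = call_mvps([t], p_threshold=1.0, d_threshold=0.0)
        assert len(mvps) == 1  # mean_diff 0.0 is not > 0.0
        mvps2, _ = call_mvps([t], p_threshold=1.0, d_threshold=-0.1)
        assert len(mvps2) == 2

    def test_no_significant_cpgs_empty_set(self):
        t = self._table([0.5, 0.9], [0.5, 0.5], "a")
        mvps, counts = call_mvps([t], 0.01, 0.05)
        assert len(mvps) == 0

    def test_mismatched_cpg_sets_error(self):
        t1 = self._table([0.5], [0.1], "a")
        t2 = self._table([0.5, 0.9], [0.1, 0.1], "b")
        with pytest.raises(ValueError, match="different CpG sets"):
            call_mvps([t1, t2])


class TestFisherExact:
    def test_cord_insertion_table(self):
        # frozen oracle: R fisher.test gives 0.008052
        assert fisher_exact_rxc([[12, 4], [4, 9], [0, 3]]) == pytest.approx(
            0.008052, abs=5e-4
        )

    def test_balanced_2x2_is_one(self):
        assert fisher_exact_rxc([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_reduces_to_2x2_closed_form(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            table = rng.integers(0, 12, size=(2, 2))
            if table.sum() == 0:
                continue
            ours = fisher_exact_rxc(table)
            scipy_p = stats.fisher_exact(table)[1]
            assert ours == pytest.approx(scipy_p, abs=1e-10)

    def test_enumerated_probabilities_sum_to_one(self):
        # with an impossible-to-beat cutoff every table is included
        table = [[3, 2, 1], [1, 4, 2], [2, 0, 5]]
        total = fisher_exact_rxc(table, tol=1e9)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1, -1], [2, 3]])


class TestPairedT:
    def test_hand_computed_statistic(self):
        d = np.array([2.0, -1.0, 3.0, 0.0, 1.0])
        t, p = paired_t_test(d, np.zeros(5))
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(expected_t)
        assert p == pytest.approx(2 * stats.t.sf(abs(expected_t), 4))

    def test_zero_variance_differences_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t_test([1.0, 2.0, 3.0, 4.0], [0.0, 1.0, 2.0, 3.0])

    def test_identical_vectors_error(self):
        with pytest.raises(ValueError):
            paired_t_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        for alpha in (0.01, 0.05):
            assert power_paired_t(16, 0.0, 0.025, alpha) == pytest.approx(alpha, abs=1e-9)

    def test_monotonicity(self):
        base = power_paired_t(16, 0.02, 0.025, 0.01)
        assert power_paired_t(24, 0.02, 0.025, 0.01) > base
        assert power_paired_t(16, 0.03, 0.025, 0.01) > base
        assert power_paired_t(16, 0.02, 0.035, 0.01) < base
        assert power_paired_t(16, 0.02, 0.025, 0.001) < base

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            power_paired_t(1, 0.05, 0.025, 0.01)
        with pytest.raises(ValueError):
            power_paired_t(16, 0.05, 0.0, 0.01)


class TestDiscordance:
    def test_study_arithmetic(self):
        assert relative_discordance(2619, 1921) == pytest.approx(0.267, abs=5e-4)
        assert relative_discordance(1000, 500) == 0.5
        assert relative_discordance(800, 800) == 0.0

    def test_order_enforced(self):
        with pytest.raises(ValueError):
            relative_discordance(1921, 2619)


class TestVolcanoExport:
    def test_round_trip_and_row_count(self, tmp_path):
        frame = pd.DataFrame(
            {
                "pvalue": [0.001, 0.5],
                "mean_diff": [0.07, -0.01],
                "significant": [True, False],
            },
            index=["cg1", "cg2"],
        )
        table = AssociationTable(frame, 0.01, 0.05, n_pairs=8)
        path = tmp_path / "volcano.tsv"
        volcano_export(table, path)
        out = pd.read_csv(path, sep="\t", index_col="cpg_id")
        assert len(out) == 2
        assert out.loc["cg1", "neg_log10_p"] == pytest.approx(3.0)
        assert bool(out.loc["cg1", "mvp"]) is True

    def test_empty_table_header_only(self, tmp_path):
        frame = pd.DataFrame(columns=["pvalue", "mean_diff", "significant"])
        table = AssociationTable(frame, 0.01, 0.05, n_pairs=8)
        path = tmp_path / "volcano.tsv"
        volcano_export(table, path)
        assert len(pd.read_csv(path, sep="\t")) == 0
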