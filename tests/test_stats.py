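"""Downstream statistics: normalization, fold change, Mann-Whitney,
Spearman, echo index derivation and strategy comparison."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from refstab import (
    ExpressionMatrix,
    derive_echo_indices,
    fold_change,
    mann_whitney,
    normalize_goi,
    percent_difference_matrix,
    spearman,
)
from refstab.stats import StatsError, compare_strategies


def enumeration_mw_p(x, y):
    """Oracle: exact two-sided Mann-Whitney p by complete enumeration of all
    C(n1+n2, n1) group assignments of the pooled sample (tie-free data)."""
    pooled = np.concatenate([x, y])
    n = len(pooled)
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mid = n1 * (len(y)) / 2
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        count += abs(u - mid) >= abs(u_obs - mid) - 1e-9
        total += 1
    return count / total


def enumeration_spearman_p(x, y):
    """Oracle: exact two-sided permutation p for Spearman rho (midranks)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho_obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in permutations(ry):
        rho = abs(np.corrcoef(rx, np.array(perm))[0, 1])
        count += rho >= rho_obs - 1e-12
        total += 1
    return count / total


class TestNormalize:
    def test_unit_nf_is_identity(self, small_matrix):
        nf = pd.Series(1.0, index=small_matrix.columns)
        pd.testing.assert_frame_equal(normalize_goi(small_matrix, nf), small_matrix)

    def test_doubling_data_and_nf_cancels(self, small_matrix):
        nf = pd.Series(np.linspace(0.5, 2, 6), index=small_matrix.columns)
        a = normalize_goi(small_matrix, nf)
        b = normalize_goi(small_matrix * 2, nf * 2)
        pd.testing.assert_frame_equal(a, b)

    def test_sample_mismatch_raises(self, small_matrix):
        nf = pd.Series(1.0, index=[f"other{j}" for j in range(6)])
        with pytest.raises(StatsError, match="missing"):
            normalize_goi(small_matrix, nf)


class TestFoldChange:
    def test_constant_groups(self):
        groups = pd.Series(["normal"] * 3 + ["hyperchol"] * 3, index=range(6))
        fc = fold_change(np.array([1, 1, 1, 6, 6, 6.0]), groups)
        assert fc["fold_change"] == pytest.approx(6.0)

    def test_means_two_and_four(self):
        groups = pd.Series(["normal"] * 3 + ["hyperchol"] * 3, index=range(6))
        fc = fold_change(np.array([1, 2, 3, 2, 4, 6.0]), groups)
        assert fc["fold_change"] == pytest.approx(2.0)
        assert fc["mean_normal"] == pytest.approx(2.0)
        assert fc["mean_hyperchol"] == pytest.approx(4.0)
        assert fc["sem_normal"] == pytest.approx(1.0 / np.sqrt(3))

    def test_empty_group_rejected(self):
        groups = pd.Series(["normal"] * 3, index=range(3))
        with pytest.raises(StatsError):
            fold_change(np.ones(3), groups)


class TestMannWhitney:
    def test_fully_separated_samples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0
        assert p == pytest.approx(0.10, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        with pytest.warns(UserWarning):
            _, p = mann_whitney([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_u_statistics_sum_to_n1_n2(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=5), rng.normal(size=7)
        u_xy, _ = mann_whitney(x, y)
        u_yx, _ = mann_whitney(y, x)
        assert u_xy + u_yx == pytest.approx(35)

    @pytest.mark.parametrize("n1, n2", [(3, 4), (4, 4), (5, 6)])
    def test_exact_p_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(10):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            _, p = mann_whitney(x, y, mode="exact")
            assert p == pytest.approx(enumeration_mw_p(x, y), abs=1e-9)

    def test_exact_mode_rejects_ties(self):
        with pytest.raises(StatsError, match="tie"):
            mann_whitney([1, 2, 2], [2, 3, 4], mode="exact")

    def test_approx_mode_handles_ties(self):
        _, p = mann_whitney([1, 2, 2, 3], [2, 3, 4, 4], mode="approx")
        assert 0 < p <= 1


class TestSpearman:
    def test_monotone_links(self):
        x = np.array([1.0, 2.5, 3.0, 7.0, 9.0])
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        rho, _ = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8, abs=1e-12)

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_exact_p_matches_permutation_oracle(self, n):
        rng = np.random.default_rng(n)
        for trial in range(4):
            x = rng.normal(size=n)
            # include ties in half the trials
            y = np.round(rng.normal(size=n), 0 if trial % 2 else 2)
            if np.ptp(y) == 0:
                continue
            _, p = spearman(x, y)
            assert p == pytest.approx(enumeration_spearman_p(x, y), abs=1e-9)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="variance"):
            rho, p = spearman([1, 2, 3, 4], [5, 5, 5, 5])
        assert np.isnan(rho) and np.isnan(p)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = x + rng.normal(0, 2, size=30)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestEchoIndices:
    def test_a_minus_ar_duration(self):
        m = pd.DataFrame({"a_duration": [33.4], "ar_duration_left": [40.5]})
        out = derive_echo_indices(m)
        assert out.loc[0, "a_ar_left"] == pytest.approx(-7.1, abs=1e-12)

    def test_deceleration_rate_from_e_and_dt(self):
        # 117.7 cm/s over 24.0 ms -> 49.0 m/s^2
        m = pd.DataFrame({"e_velocity": [117.7], "deceleration_time": [24.0]})
        out = derive_echo_indices(m)
        assert out.loc[0, "deceleration_rate"] == pytest.approx(49.04, abs=5e-3)

    def test_measured_deceleration_rate_takes_precedence(self):
        m = pd.DataFrame(
            {
                "e_velocity": [117.7],
                "deceleration_time": [24.0],
                "deceleration_rate": [51.2],
            }
        )
        assert derive_echo_indices(m).loc[0, "deceleration_rate"] == 51.2

    def test_e_over_em(self):
        m = pd.DataFrame({"e_velocity": [72.9], "em_lateral": [5.74]})
        assert derive_echo_indices(m).loc[0, "e_em_lateral"] == pytest.approx(
            12.7, abs=0.01
        )

    def test_missing_operand_yields_nan_not_zero(self):
        m = pd.DataFrame({"e_velocity": [72.9]})
        out = derive_echo_indices(m)
        assert np.isnan(out.loc[0, "e_a_ratio"])
        assert np.isnan(out.loc[0, "a_ar_right"])

    def test_zero_denominator_flagged(self):
        m = pd.DataFrame({"e_velocity": [72.9], "a_velocity": [0.0]})
        assert np.isnan(derive_echo_indices(m).loc[0, "e_a_ratio"])


class TestCompareStrategies:
    def _noise_free_matrix(self):
        from conftest import noise_free_config, quantify_chain

        cfg = noise_free_config().with_overrides(loading_sd_log2=0.4)
        matrix, _ = quantify_chain(cfg, seed=2)
        return cfg, matrix

    def test_noise_free_data_gives_identical_fc_across_strategies(self):
        cfg, matrix = self._noise_free_matrix()
        refs = cfg.reference_genes
        table = compare_strategies(
            matrix,
            ["Bnp"],
            {"top3": refs[:3], "pair": refs[3:5], "single": [refs[6]]},
        )
        assert table["fold_change"].to_numpy() == pytest.approx(
            [6.0, 6.0, 6.0], rel=1e-9
        )

    def test_absent_reference_gene_named_in_error(self):
        _, matrix = self._noise_free_matrix()
        with pytest.raises(StatsError, match="Nope"):
            compare_strategies(matrix, ["Bnp"], {"bad": ["Nope"]})

    def test_percent_difference_of_printed_folds(self):
        table = pd.DataFrame(
            {
                "gene": ["Bnp", "Bnp"],
                "strategy": ["over", "under"],
                "fold_change": [6.84, 4.2],
            }
        )
        pct = percent_difference_matrix(table, "Bnp")
        assert pct.loc["over", "under"] == pytest.approx(62.857, abs=1e-2)
        assert pct.loc["over", "over"] == 0.0

    def test_holm_adjustment_is_monotone_and_bounded(self):
        _, matrix = self._noise_free_matrix()
        refs = ["Gapdh", "Hprt1", "Sdha"]
        table = compare_strategies(
            matrix, ["Bnp", "Anp", "Nox-2"], {"top3": refs}, holm=True
        )
        assert (table["p_holm"] >= table["p"] - 1e-15).all()
        assert (table["p_holm"] <= 1.0).all()
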