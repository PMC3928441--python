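"""geNorm: pairwise variation, the M statistic, stepwise ranking,
normalization factors and the V_n/n+1 gene-count rule."""

import dataclasses
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from refstab import (
    genorm,
    normalization_factor,
    optimal_gene_count,
    pairwise_variation,
    rank_genes_stepwise,
    simulate_experiment,
    stability_m,
)
from refstab.genorm import GenormError

from conftest import noise_free_config


def brute_force_m(data: pd.DataFrame) -> pd.Series:
    """Independent double-loop oracle using statistics.stdev."""
    genes = list(data.index)
    out = {}
    for j in genes:
        vs = []
        for k in genes:
            if k == j:
                continue
            ratios = [
                float(np.log2(data.loc[j, s] / data.loc[k, s])) for s in data.columns
            ]
            vs.append(statistics.stdev(ratios))
        out[j] = sum(vs) / len(vs)
    return pd.Series(out)


def brute_force_ranking(data: pd.DataFrame) -> list[str]:
    """Independent stepwise-exclusion oracle (same removal rule)."""
    remaining = list(data.index)
    removed = []
    while len(remaining) > 2:
        m = brute_force_m(data.loc[remaining])
        worst_val = max(m[g] for g in remaining)
        worst = next(g for g in remaining if m[g] == worst_val)  # first-listed tie-break
        removed.append(worst)
        remaining.remove(worst)
    return remaining + removed[::-1]


class TestPairwiseVariation:
    def test_proportional_genes_have_zero_variation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pairwise_variation(a, 2.5 * a) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_sd(self):
        # log2 ratios (0, 1, 2, 3) -> SD with n-1 = 3 is 1.2910
        v = pairwise_variation([1, 2, 4, 8], [1, 1, 1, 1])
        assert v == pytest.approx(1.29099, abs=1e-4)

    def test_sample_specific_scaling_cancels(self):
        rng = np.random.default_rng(0)
        a, b = rng.lognormal(size=(2, 6))
        load = rng.lognormal(size=6)
        assert pairwise_variation(a * load, b * load) == pytest.approx(
            pairwise_variation(a, b), abs=1e-12
        )

    def test_too_short_rejected(self):
        with pytest.raises(GenormError):
            pairwise_variation([1.0], [2.0])


class TestStabilityM:
    MATRIX = pd.DataFrame(
        [[1, 2, 4, 8], [2, 4, 8, 16], [1, 1, 1, 1]],
        index=["g1", "g2", "g3"],
        dtype=float,
    )

    def test_hand_computed_m_values(self):
        m = stability_m(self.MATRIX)
        assert m.to_numpy() == pytest.approx([0.64550, 0.64550, 1.29099], abs=1e-4)

    def test_matches_brute_force_oracle(self, small_matrix):
        np.testing.assert_allclose(
            stability_m(small_matrix), brute_force_m(small_matrix), atol=1e-12
        )

    def test_per_gene_rescaling_leaves_all_m_unchanged(self, small_matrix):
        scaled = small_matrix.copy()
        scaled.iloc[0] *= 37.5
        np.testing.assert_allclose(
            stability_m(scaled), stability_m(small_matrix), atol=1e-12
        )

    def test_all_proportional_gives_all_zero(self):
        base = np.array([1.0, 3.0, 0.5, 2.0])
        data = pd.DataFrame([base, 2 * base, 5 * base], index=list("abc"))
        assert stability_m(data).to_numpy() == pytest.approx([0, 0, 0], abs=1e-15)

    def test_single_gene_rejected(self):
        with pytest.raises(GenormError):
            stability_m(self.MATRIX.iloc[:1])

    @given(
        arrays(
            float,
            (5, 8),
            elements=st.floats(min_value=-2, max_value=2, allow_nan=False),
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_adding_noise_gene_never_decreases_max_m(self, log_expr):
        data = pd.DataFrame(2.0**log_expr, index=[f"g{i}" for i in range(5)])
        rng = np.random.default_rng(0)
        noisy = pd.concat(
            [data, pd.DataFrame(2.0 ** rng.normal(0, 3, (1, 8)), index=["noise"])]
        )
        assert stability_m(noisy).max() >= stability_m(data).max() - 1e-12


class TestStepwiseRanking:
    def test_injected_group_shift_removed_first(self):
        cfg = noise_free_config()
        genes = tuple(
            dataclasses.replace(g, extra_group_shift_log2=2.0 if g.name == "Actb" else 0.0)
            for g in cfg.genes
        )
        cfg = cfg.with_overrides(genes=genes, loading_sd_log2=0.3)
        ct, truth = simulate_experiment(cfg, seed=0)
        # exact quantities (noise-free): use ground truth directly
        data = truth.true_quantity.loc[cfg.reference_genes]
        ranking, exclusion, _, _ = rank_genes_stepwise(data)
        assert exclusion[0] == "Actb"
        assert ranking[-1] == "Actb"

    def test_final_two_genes_share_their_m_value(self, small_matrix):
        ranking, _, trajectory, final_m = rank_genes_stepwise(small_matrix)
        best_two = ranking[:2]
        assert final_m[best_two[0]] == pytest.approx(final_m[best_two[1]], abs=1e-15)
        # with 2 genes, M reduces to their mutual pairwise variation
        v12 = pairwise_variation(
            small_matrix.loc[best_two[0]], small_matrix.loc[best_two[1]]
        )
        assert final_m[best_two[0]] == pytest.approx(v12, abs=1e-12)

    def test_removal_order_matches_independent_oracle(self):
        rng = np.random.default_rng(11)
        data = pd.DataFrame(
            2.0 ** rng.normal(0, 1, (5, 10)), index=[f"g{i}" for i in range(5)]
        )
        ranking, _, _, _ = rank_genes_stepwise(data)
        assert ranking == brute_force_ranking(data)


class TestNormalizationFactor:
    def test_geometric_mean_of_two(self):
        data = pd.DataFrame({"s": [2.0, 8.0]}, index=["a", "b"])
        assert normalization_factor(data, ["a", "b"])["s"] == pytest.approx(4.0)

    def test_geometric_mean_of_three(self):
        data = pd.DataFrame({"s": [1.0, 8.0, 64.0]}, index=["a", "b", "c"])
        assert normalization_factor(data, ["a", "b", "c"])["s"] == pytest.approx(8.0)

    def test_duplicated_gene_weights_the_geometric_mean(self):
        data = pd.DataFrame({"s": [2.0, 8.0]}, index=["a", "b"])
        nf = normalization_factor(data, ["a", "a", "b"])["s"]
        assert nf == pytest.approx((2.0 * 2.0 * 8.0) ** (1 / 3))

    def test_empty_subset_rejected(self):
        with pytest.raises(GenormError):
            normalization_factor(pd.DataFrame({"s": [1.0]}, index=["a"]), [])


class TestOptimalGeneCount:
    def test_proportional_genes_give_zero_v_and_n_two(self):
        base = np.array([1.0, 3.0, 0.5, 2.0, 1.5])
        data = pd.DataFrame(
            [base, 2 * base, 5 * base, 0.1 * base], index=list("abcd")
        )
        v, n = optimal_gene_count(data, list("abcd"))
        assert v.to_numpy() == pytest.approx([0.0, 0.0], abs=1e-12)
        assert n == 2

    def test_smallest_n_below_cutoff_is_recommended(self, small_matrix):
        ranking, _, _, _ = rank_genes_stepwise(small_matrix)
        v, n = optimal_gene_count(small_matrix, ranking, cutoff=0.15)
        below = [k for k in v.index if v[k] < 0.15]
        assert n == (min(below) if below else len(ranking))

    def test_no_v_below_cutoff_recommends_all_with_warning(self, small_matrix):
        ranking, _, _, _ = rank_genes_stepwise(small_matrix)
        with pytest.warns(UserWarning, match="cutoff"):
            _, n = optimal_gene_count(small_matrix, ranking, cutoff=1e-9)
        assert n == len(ranking)


class TestGenormEndToEnd:
    def test_invariance_to_global_scalings(self, small_matrix):
        result = genorm(small_matrix)
        rng = np.random.default_rng(1)
        scaled = small_matrix * rng.lognormal(size=6)           # per-sample
        scaled = scaled.mul(rng.lognormal(size=4), axis=0)      # per-gene
        other = genorm(scaled)
        np.testing.assert_allclose(result.m_values, other.m_values, atol=1e-12)
        np.testing.assert_allclose(result.v_series, other.v_series, atol=1e-12)
        assert result.ranking == other.ranking

    def test_default_noise_keeps_reference_m_in_high_stability_band(self):
        from conftest import quantify_chain
        from refstab import SimulationConfig

        cfg = SimulationConfig(seed=0)
        matrix, _ = quantify_chain(cfg, seed=0)
        result = genorm(matrix.restrict(cfg.reference_genes))
        assert bool(result.highly_stable.all())
        assert result.m_values.max() < 0.5
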