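import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from refstab import (
    CtMatrix,
    QuantityMatrix,
    bestkeeper,
    ct_to_quantity,
    delta_ct,
    genorm,
    normfinder,
)

import oracles


def _ct(values, groups=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    g = dict(zip(samples, groups)) if groups else None
    return CtMatrix(pd.DataFrame(values, index=genes, columns=samples), g)


def _qm(values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return QuantityMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(values.shape[0])],
            columns=[f"s{i}" for i in range(values.shape[1])],
        )
    )


class TestCtToQuantity:
    def test_powers_of_two(self):
        q = ct_to_quantity(_ct([[20, 21, 22], [25, 25, 25]]))
        np.testing.assert_allclose(q.values.loc["g0"], [1, 0.5, 0.25])
        np.testing.assert_allclose(q.values.loc["g1"], [1, 1, 1])

    def test_elementwise_oracle_with_nonstandard_efficiency(self, rng):
        ct = rng.uniform(18, 30, size=(4, 5))
        q = ct_to_quantity(_ct(ct), efficiency=1.9)
        expected = 1.9 ** (ct.min(axis=1, keepdims=True) - ct)
        np.testing.assert_allclose(q.values.to_numpy(), expected, atol=1e-12)
        assert np.allclose(q.values.max(axis=1), 1.0)

    def test_masked_gene_dropped_with_warning(self):
        vals = np.array([[20.0, 21, 22], [np.nan, 25, 26], [24, 25, 23]])
        with pytest.warns(UserWarning, match="dropped 1 gene"):
            q = ct_to_quantity(_ct(vals))
        assert list(q.values.index) == ["g0", "g2"]


class TestGenorm:
    def test_proportional_rows_have_zero_m_and_v(self):
        base = np.array([1.0, 0.5, 0.25, 0.125, 1.0, 0.8])
        q = _qm(np.vstack([base, 2 * base, 0.5 * base]) / 2)
        res = genorm(q)
        np.testing.assert_allclose(res.m_values, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.pairwise_variation, 0.0, atol=1e-12)

    def test_noisy_gene_excluded_first(self, rng):
        base = rng.uniform(0.1, 1.0, size=6)
        rows = np.vstack([base, 2 * base, 0.5 * base, base * 2.0 ** rng.normal(0, 1, 6)])
        res = genorm(_qm(rows))
        assert res.exclusion_order[0] == "g3"
        assert res.ranks["g3"] == 4.0
        assert sorted(res.ranks[["g0", "g1", "g2"]]) == [1.5, 1.5, 3.0]

    def test_m_values_match_double_loop_oracle(self, rng):
        q = 2.0 ** rng.normal(0, 1.5, size=(7, 9))
        res = genorm(_qm(q))
        np.testing.assert_allclose(res.m_values, oracles.genorm_m(q), atol=1e-10)

    def test_pairwise_variation_matches_nf_oracle(self, rng):
        q = 2.0 ** rng.normal(0, 1.0, size=(6, 8))
        res = genorm(_qm(q))
        index_of = {f"g{i}": i for i in range(6)}
        expected = oracles.genorm_v(q, res.stability_order, index_of)
        np.testing.assert_allclose(res.pairwise_variation, expected, atol=1e-10)

    def test_fewer_than_three_genes_rejected(self):
        with pytest.raises(ValueError, match="at least 3 genes"):
            genorm(_qm([[1, 0.5], [0.5, 1]]))

    def test_scaling_one_gene_row_leaves_m_unchanged(self, rng):
        q = 2.0 ** rng.normal(0, 1, size=(5, 7))
        m1 = genorm(_qm(q)).m_values
        q2 = q.copy()
        q2[2] *= 37.5  # per-gene calibration must not matter
        m2 = genorm(_qm(q2)).m_values
        np.testing.assert_allclose(m1, m2, atol=1e-10)


class TestNormfinder:
    def test_sample_centered_constant_gene_is_most_stable(self, rng):
        # g0 equals the panel mean in every sample, so its sample-centered
        # values are identically zero; it must attain the minimum stability
        others = rng.uniform(18, 30, size=(4, 10))
        g0 = others.mean(axis=0)  # then g0 also equals the 5-row column mean
        res = normfinder(_ct(np.vstack([g0, others])))
        assert res.rho["g0"] == res.rho.min()
        assert res.rho["g0"] == pytest.approx(0.0, abs=1e-9)

    def test_grouped_equal_means_gives_zero_d_and_rho(self, rng):
        # g0 constant across groups; g1/g2 shift in opposite directions so
        # the panel's average group effect cancels; residual noise ~0
        groups = ["x"] * 4 + ["y"] * 4
        ct = np.vstack(
            [
                np.full(8, 20.0),
                [18, 18, 18, 18, 24, 24, 24, 24],  # +6 cycles in group y
                [28, 28, 28, 28, 22, 22, 22, 22],  # −6 cycles in group y
            ]
        )
        ct = ct + rng.normal(0, 0.01, ct.shape)
        res = normfinder(_ct(ct, groups))
        assert res.mode == "grouped"
        assert abs(res.d.loc["g0"]).max() < 0.05
        assert res.rho["g0"] < 0.05
        assert res.rho["g0"] < res.rho["g1"]

    def test_grouped_variance_rank_recovery(self):
        # two equal-mean groups, genes with known increasing noise SD:
        # the stability values should come back in the true σ order
        true_sd = np.sqrt(np.linspace(0.01, 0.5, 8))
        corrs = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            mu = rng.uniform(18, 26, size=8)
            blocks = [
                mu[:, None] + rng.normal(0, true_sd[:, None], (8, 10))
                for _ in range(2)
            ]
            ct = np.hstack(blocks)
            res = normfinder(_ct(ct, ["a"] * 10 + ["b"] * 10))
            corrs.append(sps.spearmanr(res.rho.to_numpy(), true_sd).statistic)
        assert np.mean(corrs) >= 0.8

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2 samples"):
            normfinder(_ct(np.ones((3, 3)) * 20, ["a", "a", "b"]))


class TestBestkeeper:
    def test_identical_rows_correlate_perfectly_with_index(self):
        row = np.array([20.0, 22, 21, 24, 23])
        res = bestkeeper(_ct(np.vstack([row, row, row])))
        np.testing.assert_allclose(res.index, row)
        np.testing.assert_allclose(res.stats["r_index"], 1.0)

    def test_constant_gene_ranks_first_with_undefined_r(self):
        ct = np.vstack([np.full(5, 20.0), [18, 22, 19, 25, 21], [25, 28, 26, 30, 27]])
        res = bestkeeper(_ct(ct))
        assert res.stats.loc[0, "sd_ct"] == 0.0
        assert np.isnan(res.stats.loc[0, "r_index"])
        assert res.ranks["g0"] == 1.0

    def test_statistics_match_direct_formula_oracle(self, rng):
        ct = rng.uniform(15, 32, size=(5, 10))
        res = bestkeeper(_ct(ct))
        rows, index = oracles.bestkeeper_stats(ct)
        np.testing.assert_allclose(res.index, index, atol=1e-10)
        for i, row in enumerate(rows):
            got = res.stats.iloc[i]
            assert got["mean_ct"] == pytest.approx(row["mean"], abs=1e-10)
            assert got["geo_mean_ct"] == pytest.approx(row["geo_mean"], abs=1e-10)
            assert got["sd_ct"] == pytest.approx(row["sd"], abs=1e-10)
            assert got["cv_pct"] == pytest.approx(row["cv_pct"], abs=1e-10)
            assert got["r_index"] == pytest.approx(row["r"], abs=1e-10)

    def test_r_invariant_to_positive_affine_transform(self, rng):
        ct = rng.uniform(18, 30, size=(4, 8))
        base = bestkeeper(_ct(ct))
        # replace one gene by an affine image of itself with positive slope
        # and recompute its correlation against the *same* index
        r0 = base.stats.loc[0, "r_index"]
        transformed = 1.7 * ct[0] + 3.0
        r1 = sps.pearsonr(transformed, base.index.to_numpy()).statistic
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_sd_above_one_flagged_inconsistent(self, random_ct):
        res = bestkeeper(random_ct)
        np.testing.assert_array_equal(
            res.stats["inconsistent"], res.stats["sd_ct"] > 1.0
        )


class TestDeltaCt:
    def test_constant_offset_pair_has_zero_sd(self):
        ct = np.vstack([[20, 22, 24, 21], [23, 25, 27, 24], [20, 26, 22, 28]])
        res = delta_ct(_ct(ct))
        assert res.pairwise_sd.loc["g0", "g1"] == pytest.approx(0.0, abs=1e-12)

    def test_two_genes_share_the_single_pair_score(self, rng):
        ct = rng.uniform(18, 30, size=(2, 6))
        res = delta_ct(_ct(ct))
        assert res.scores["g0"] == pytest.approx(res.scores["g1"], abs=1e-14)

    def test_scores_match_double_loop_oracle(self, rng):
        ct = rng.uniform(15, 32, size=(6, 8))
        res = delta_ct(_ct(ct))
        np.testing.assert_allclose(res.scores, oracles.delta_ct_scores(ct), atol=1e-12)
        np.testing.assert_allclose(
            res.pairwise_sd, res.pairwise_sd.T, atol=0
        )
        assert np.all(np.diag(res.pairwise_sd) == 0)

    def test_missing_wells_use_pairwise_complete_case(self):
        ct = np.array(
            [[20.0, 21, 22, 23], [22, 23, 24, 25], [25, np.nan, 27, 28]]
        )
        with pytest.warns(UserWarning, match="pairwise complete-case"):
            res = delta_ct(_ct(ct))
        # g0–g1 uses all 4 samples; pairs with g2 use the 3 shared ones
        d = ct[0, [0, 2, 3]] - ct[2, [0, 2, 3]]
        assert res.pairwise_sd.loc["g0", "g2"] == pytest.approx(d.std(ddof=1))


class TestInvariances:
    def test_per_sample_ct_shift_leaves_genorm_and_deltact_unchanged(self, random_ct, rng):
        shift = rng.uniform(-3, 3, size=random_ct.values.shape[1])
        shifted = CtMatrix(random_ct.values + shift)
        m0 = genorm(ct_to_quantity(random_ct)).m_values
        m1 = genorm(ct_to_quantity(shifted)).m_values
        np.testing.assert_allclose(m0, m1, atol=1e-10)
        s0 = delta_ct(random_ct).scores
        s1 = delta_ct(shifted).scores
        np.testing.assert_allclose(s0, s1, atol=1e-10)

    def test_gene_input_order_does_not_change_any_ranking(self, random_ct, rng):
        perm = rng.permutation(len(random_ct.gene_ids))
        shuffled = CtMatrix(random_ct.values.iloc[perm])
        for fn in (
            lambda c: genorm(ct_to_quantity(c)).ranks,
            lambda c: normfinder(c).ranks,
            lambda c: bestkeeper(c).ranks,
            lambda c: delta_ct(c).ranks,
        ):
            a, b = fn(random_ct).sort_index(), fn(shuffled).sort_index()
            np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)
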