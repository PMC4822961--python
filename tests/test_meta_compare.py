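import numpy as np
import pandas as pd
import pytest
from scipy import stats

from abkfs.data_model import DataError, Dataset, GeneSetCollection, SampleMeta
from abkfs.meta_compare import (
    _rank_ratios,
    _rp_from_fc,
    ease_enrichment,
    effect_size_meta,
    fold_change,
    hedges_d,
    rank_product,
    welch_bonferroni,
)


def make_dataset(values_by_region, klasses_by_region, feature_ids=None):
    """Build a Dataset from per-region value blocks (features x samples)."""
    samples, columns = [], []
    for region, block in values_by_region.items():
        block = np.asarray(block, dtype=float)
        for j, k in enumerate(klasses_by_region[region]):
            samples.append(SampleMeta(f"{region}_s{j}", region, int(k)))
            columns.append(block[:, j])
    n = len(columns[0])
    feature_ids = feature_ids or [f"g{i}" for i in range(n)]
    matrix = pd.DataFrame(
        np.column_stack(columns), index=feature_ids,
        columns=[s.sample_id for s in samples],
    )
    return Dataset(matrix=matrix, samples=samples)


class TestFoldChange:
    def test_equal_means_give_zero(self):
        ds = make_dataset({"R": [[1, 1, 1, 1]]}, {"R": [0, 0, 1, 1]})
        assert fold_change(ds)["g0"] == 0.0

    def test_unit_shift_gives_plus_one(self):
        ds = make_dataset({"R": [[2, 2, 3, 3]]}, {"R": [0, 0, 1, 1]})
        assert fold_change(ds)["g0"] == pytest.approx(1.0)

    def test_planted_shift_recovered_at_n50(self):
        # 100 planted features at delta=2 with unit noise, 50 samples/class:
        # each per-feature estimate has sd 0.2, the ensemble mean sd 0.02
        rng = np.random.default_rng(14)
        n = 50
        control = rng.normal(5, 1, size=(100, n))
        affected = rng.normal(7, 1, size=(100, n))
        ds = make_dataset(
            {"R": np.hstack([control, affected])}, {"R": [0] * n + [1] * n}
        )
        fc = fold_change(ds)
        assert fc.mean() == pytest.approx(2.0, abs=0.1)
        assert np.all(np.abs(fc - 2.0) < 1.0)

    def test_region_without_controls_errors(self):
        ds = make_dataset(
            {"R1": [[1, 2]], "R2": [[3, 4]]}, {"R1": [0, 1], "R2": [1, 1]}
        )
        with pytest.raises(DataError):
            fold_change(ds, per_region=True)


class TestRankProduct:
    def _ranked_dataset(self, fcs_by_region, n_controls=2):
        """Controls at 0, affected at the configured per-feature fold change."""
        blocks, klasses = {}, {}
        for region, fcs in fcs_by_region.items():
            fcs = np.asarray(fcs, dtype=float)
            n = len(fcs)
            block = np.zeros((n, 2 * n_controls))
            block[:, n_controls:] = fcs[:, None]
            blocks[region] = block
            klasses[region] = [0] * n_controls + [1] * n_controls
        return make_dataset(blocks, klasses)

    def test_rank_one_in_both_regions_gives_point_one(self):
        # feature 0 has the largest FC among 10 features in both of K=2 regions
        fcs = np.array([10.0] + list(np.linspace(1, 5, 9)))
        ds = self._ranked_dataset({"R1": fcs, "R2": fcs})
        res = rank_product(ds, direction="up", B_perm=1, seed=0)
        assert res.table.loc["g0", "rp"] == pytest.approx(0.1)
        assert res.K == 2

    def test_ranks_one_and_four_give_point_two(self):
        fcs1 = np.array([10.0] + list(np.linspace(1, 5, 9)))  # g0 rank 1
        fcs2 = fcs1.copy()
        fcs2[0] = 3.9  # in R2, g0 falls to rank 4 (below 5.0, 4.5, 4.0)
        ds = self._ranked_dataset({"R1": fcs1, "R2": fcs2})
        res = rank_product(ds, direction="up", B_perm=1, seed=0)
        rr = res.rank_ratios.loc["g0"]
        assert rr["R1"] == pytest.approx(0.1)
        assert rr["R2"] == pytest.approx(0.4)
        assert res.table.loc["g0", "rp"] == pytest.approx(np.sqrt(0.1 * 0.4))

    def test_rank_product_invariant_to_monotone_fc_transform(self):
        rng = np.random.default_rng(6)
        fc = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("ABC"))
        for transform in (lambda x: 2 * x + 1, np.tanh):
            np.testing.assert_allclose(
                _rp_from_fc(fc, "up"), _rp_from_fc(transform(fc), "up")
            )

    def test_direction_flips_rank_order(self):
        rng = np.random.default_rng(7)
        fc = pd.DataFrame(rng.normal(size=(11, 2)), columns=list("AB"))
        up = _rank_ratios(fc, "up")
        down = _rank_ratios(fc, "down")
        # per column, up-rank + down-rank = n + 1 for distinct values
        np.testing.assert_allclose((up + down).to_numpy(), (11 + 1) / 11)

    def test_b_perm_zero_rejected(self):
        ds = self._ranked_dataset({"R1": [1.0, 2.0]})
        with pytest.raises(ValueError):
            rank_product(ds, B_perm=0)


class TestEffectSize:
    def test_hedges_worked_values(self):
        d, var = hedges_d(np.array([1.0]), np.array([0.0]), np.array([1.0]), 10, 10)
        assert d[0] == pytest.approx(0.9577, abs=1e-4)
        assert var[0] == pytest.approx(0.2229, abs=1e-4)

    def test_identical_class_means_give_zero_effect(self):
        rng = np.random.default_rng(30)
        base = rng.normal(0, 1, size=(5, 6))
        block = np.hstack([base, base])  # class means identical by construction
        ds = make_dataset({"R1": block, "R2": block},
                          {r: [0] * 6 + [1] * 6 for r in ("R1", "R2")})
        res = effect_size_meta(ds, B_perm=2, seed=0)
        np.testing.assert_allclose(res.d.to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(res.table["z"].to_numpy(), 0.0, atol=1e-12)

    def test_fixed_effect_matches_closed_form_two_regions(self):
        rng = np.random.default_rng(31)
        ds = make_dataset(
            {"R1": rng.normal(0, 1, (4, 8)), "R2": rng.normal(0, 1, (4, 10))},
            {"R1": [0] * 4 + [1] * 4, "R2": [0] * 5 + [1] * 5},
        )
        res = effect_size_meta(ds, model="fixed", B_perm=1, seed=0)
        d = res.d.to_numpy()
        var = res.var.to_numpy()
        w = 1 / var
        mu = (w * d).sum(axis=1) / w.sum(axis=1)
        np.testing.assert_allclose(res.table["mu"].to_numpy(), mu)
        np.testing.assert_allclose(
            res.table["z"].to_numpy(), mu * np.sqrt(w.sum(axis=1))
        )

    def test_identity_permutation_gives_fdr_one(self, monkeypatch):
        class IdentityRng:
            def permutation(self, x):
                return np.asarray(x)

        rng = np.random.default_rng(32)
        ds = make_dataset(
            {"R1": rng.normal(0, 1, (6, 8))}, {"R1": [0] * 4 + [1] * 4}
        )
        import abkfs.meta_compare as mc

        monkeypatch.setattr(mc.np.random, "default_rng", lambda seed=None: IdentityRng())
        res = effect_size_meta(ds, B_perm=1, seed=0)
        np.testing.assert_allclose(res.fdr_curve, 1.0)

    def test_random_model_never_tightens_standard_errors(self):
        # adding a non-negative between-region variance can only inflate se
        rng = np.random.default_rng(33)
        block1 = rng.normal(0, 1, (10, 12))
        block2 = rng.normal(0, 1, (10, 12))
        block1[:5, 6:] += 2.0
        block2[:5, 6:] += 0.5  # heterogeneous effects
        ds = make_dataset({"R1": block1, "R2": block2},
                          {r: [0] * 6 + [1] * 6 for r in ("R1", "R2")})
        fixed = effect_size_meta(ds, model="fixed", B_perm=1, seed=0)
        random = effect_size_meta(ds, model="random", B_perm=1, seed=0)
        assert (
            random.table["se"].to_numpy() >= fixed.table["se"].to_numpy() - 1e-12
        ).all()

    def test_degenerate_sd_feature_excluded(self):
        block = np.vstack([np.ones((1, 8)), np.random.default_rng(1).normal(size=(2, 8))])
        ds = make_dataset({"R1": block}, {"R1": [0] * 4 + [1] * 4})
        res = effect_size_meta(ds, B_perm=1, seed=0)
        assert res.excluded == ["g0"]
        assert list(res.table.index) == ["g1", "g2"]


class TestWelchBonferroni:
    def test_bonferroni_scales_and_caps(self):
        rng = np.random.default_rng(40)
        block = rng.normal(0, 1, size=(10, 12))
        block[0, 6:] += 5.0
        ds = make_dataset({"R": block}, {"R": [0] * 6 + [1] * 6})
        res = welch_bonferroni(ds)
        t, p = stats.ttest_ind(
            block[:, 6:], block[:, :6], axis=1, equal_var=False
        )
        np.testing.assert_allclose(res.table["p"].to_numpy(), p)
        np.testing.assert_allclose(
            res.table["bf"].to_numpy(), np.minimum(1.0, p * 10)
        )

    def test_identical_groups_give_t_zero_p_one(self):
        block = np.tile(np.array([[1.0, 2.0, 3.0]]).T, (1, 4))
        ds = make_dataset({"R": block}, {"R": [0, 0, 1, 1]})
        res = welch_bonferroni(ds)
        np.testing.assert_allclose(res.table["t"], 0.0)
        np.testing.assert_allclose(res.table["p"], 1.0)

    def test_bf_ordering_matches_p_ordering(self):
        rng = np.random.default_rng(41)
        block = rng.normal(0, 1, size=(30, 10))
        ds = make_dataset({"R": block}, {"R": [0] * 5 + [1] * 5})
        res = welch_bonferroni(ds)
        p_order = res.table["p"].rank(method="first")
        bf_order = res.table["bf"].rank(method="first")
        # ties introduced by capping at 1 keep 'first' order stable
        uncapped = res.table["bf"] < 1.0
        assert (p_order[uncapped] == bf_order[uncapped]).all()

    def test_small_class_errors(self):
        ds = make_dataset({"R": [[1.0, 2.0, 3.0]]}, {"R": [0, 1, 1]})
        with pytest.raises(DataError):
            welch_bonferroni(ds)

    def test_region_centering_removes_region_offsets(self):
        rng = np.random.default_rng(42)
        base = rng.normal(0, 1, size=(5, 8))
        ds = make_dataset(
            {"R1": base, "R2": base + 10.0},  # pure region offset
            {r: [0] * 4 + [1] * 4 for r in ("R1", "R2")},
        )
        centred = welch_bonferroni(ds, center_by_region=True)
        single = welch_bonferroni(
            make_dataset({"R1": np.hstack([base - base.mean(axis=1, keepdims=True)] * 2),
                          },
                         {"R1": ([0] * 4 + [1] * 4) * 2}),
        )
        np.testing.assert_allclose(
            centred.table["t"].to_numpy(), single.table["t"].to_numpy(), atol=1e-9
        )


class TestEaseEnrichment:
    def test_single_hit_gives_ease_one(self):
        sets = GeneSetCollection({"S": frozenset({"g1", "g2"})})
        res = ease_enrichment({"g1", "x1"}, {f"g{i}" for i in range(3)} | {"x1", "x2"}, sets)
        assert res.table.loc["S", "list_hits"] == 1
        assert res.table.loc["S", "ease"] == pytest.approx(1.0)

    def test_worked_example_20_5_5_5(self):
        background = {f"g{i}" for i in range(20)}
        members = frozenset({f"g{i}" for i in range(5)})
        sets = GeneSetCollection({"S": members})
        res = ease_enrichment(set(members), background, sets)
        assert res.table.loc["S", "p_fisher"] == pytest.approx(1 / 15504, rel=1e-9)
        assert res.table.loc["S", "ease"] == pytest.approx(76 / 15504, rel=1e-9)

    def test_fisher_matches_scipy_and_ease_dominates(self):
        rng = np.random.default_rng(50)
        background = [f"g{i}" for i in range(40)]
        for _ in range(100):
            set_size = int(rng.integers(2, 20))
            list_size = int(rng.integers(2, 20))
            members = frozenset(rng.choice(background, set_size, replace=False))
            lst = set(rng.choice(background, list_size, replace=False))
            res = ease_enrichment(lst, background, GeneSetCollection({"S": members}))
            a = int(res.table.loc["S", "list_hits"])
            table = np.array(
                [
                    [a, list_size - a],
                    [set_size - a, 40 - list_size - (set_size - a)],
                ]
            )
            _, p_ref = stats.fisher_exact(table, alternative="greater")
            assert res.table.loc["S", "p_fisher"] == pytest.approx(p_ref, rel=1e-9)
            assert res.table.loc["S", "ease"] >= res.table.loc["S", "p_fisher"] - 1e-12

    def test_empty_list_errors(self):
        sets = GeneSetCollection({"S": frozenset({"g1"})})
        with pytest.raises(DataError):
            ease_enrichment(set(), {"g1"}, sets)
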