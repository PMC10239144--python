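import numpy as np
import pytest

from katzncp.datasets import AssociationMatrix, DiseaseDagForest, SyntheticConfig, generate_synthetic
from katzncp.similarity import (
    SimilarityMatrix,
    gaussian_profile_kernel,
    integrate_disease,
    integrate_mirna,
    mirna_functional_similarity,
    semantic_mask,
    semantic_similarity,
    wang_contributions,
    xuan_contributions,
)

from .conftest import random_forest
from . import oracles


class TestWangContributions:
    def test_singleton_dag(self):
        forest = DiseaseDagForest()
        forest.add_disease("X")
        c = wang_contributions(forest, "X")
        assert c.contributions == {"X": 1.0}
        assert c.dv == 1.0

    def test_single_hop_halves(self, chain_pair_forest):
        c = wang_contributions(chain_pair_forest, "X")
        assert c.contributions == {"X": 1.0, "t1": 0.5}
        assert c.dv == 1.5

    def test_diamond(self, diamond_forest):
        c = wang_contributions(diamond_forest, "X")
        assert c.contributions == {"X": 1.0, "b": 0.5, "c": 0.5, "a": 0.25}
        assert c.dv == pytest.approx(2.25)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        forest = random_forest(rng, n_diseases=4, max_nodes=5)
        for d in forest.diseases:
            dp = wang_contributions(forest, d).contributions
            brute = oracles.brute_wang_contributions(forest.dags[d], d)
            assert dp == pytest.approx(brute, abs=1e-15)

    def test_adding_shared_ancestor_never_decreases_similarity(self):
        # monotonicity of the hop-discounted scheme in shared structure
        base = DiseaseDagForest()
        base.add_disease("X", [("t1", "X")])
        base.add_disease("Y", [("t2", "Y")])
        before = semantic_similarity(
            {d: wang_contributions(base, d) for d in ["X", "Y"]}, ["X", "Y"]
        ).values[0, 1]
        grown = DiseaseDagForest()
        grown.add_disease("X", [("t1", "X"), ("s", "t1")])
        grown.add_disease("Y", [("t2", "Y"), ("s", "t2")])
        after = semantic_similarity(
            {d: wang_contributions(grown, d) for d in ["X", "Y"]}, ["X", "Y"]
        ).values[0, 1]
        assert after >= before


class TestXuanContributions:
    def test_single_disease_forest_degenerates_to_zero(self):
        forest = DiseaseDagForest()
        forest.add_disease("X", [("t1", "X")])
        c = xuan_contributions(forest, "X")
        assert all(v == 0.0 for v in c.contributions.values())
        assert c.dv == 0.0

    def test_rare_and_universal_terms(self):
        forest = DiseaseDagForest()
        for j in range(4):
            edges = [("common", f"d{j}")]
            if j == 0:
                edges.append(("rare", "common"))
            forest.add_disease(f"d{j}", edges)
        c = xuan_contributions(forest, "d0")
        assert c.contributions["rare"] == pytest.approx(-np.log(0.25))  # ~1.3863
        assert c.contributions["common"] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_count_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        forest = random_forest(rng, n_diseases=5, max_nodes=4)
        for d in forest.diseases:
            got = xuan_contributions(forest, d).contributions
            brute = oracles.brute_xuan_contributions(forest.dags, d)
            assert got == pytest.approx(brute, abs=1e-15)


class TestSemanticSimilarity:
    def test_self_similarity_is_one(self):
        # the shared-term sum over a disease's own DAG doubles its semantic
        # value, so the diagonal is exactly 1
        forest = DiseaseDagForest()
        forest.add_disease("X", [("t1", "X"), ("t2", "t1")])
        forest.add_disease("Y", [("t1", "Y"), ("t2", "t1")])
        dd = semantic_similarity({d: wang_contributions(forest, d) for d in "XY"}, ["X", "Y"])
        assert dd.values[0, 0] == 1.0 and dd.values[1, 1] == 1.0
        # near-identical DAGs differing only in the disease node stay below 1
        assert 0.0 < dd.values[0, 1] < 1.0

    def test_disjoint_dags_give_zero(self):
        forest = DiseaseDagForest()
        forest.add_disease("X", [("t1", "X")])
        forest.add_disease("Y", [("t2", "Y")])
        dd = semantic_similarity({d: wang_contributions(forest, d) for d in "XY"}, ["X", "Y"])
        assert dd.values[0, 1] == 0.0

    def test_shared_single_ancestor(self, chain_pair_forest):
        dd = semantic_similarity(
            {d: wang_contributions(chain_pair_forest, d) for d in "XY"}, ["X", "Y"]
        )
        # shared term t1 contributes 0.5 from each side over DV 1.5 + 1.5
        assert dd.values[0, 1] == pytest.approx(1 / 3)

    def test_zero_semantic_value_pair_warns(self):
        # X is an ancestor of every disease, so under the information-content
        # scheme its whole DAG ({X}) is universal and DV(X) = 0; its
        # self-comparison divides by zero and must yield 0 with a warning
        forest = DiseaseDagForest()
        forest.add_disease("X")
        forest.add_disease("Y", [("X", "Y")])
        forest.add_disease("Z", [("X", "Z")])
        contribs = {d: xuan_contributions(forest, d) for d in "XYZ"}
        assert contribs["X"].dv == 0.0
        with pytest.warns(UserWarning, match="zero total semantic value"):
            dd = semantic_similarity(contribs, ["X", "Y", "Z"], kind="DD2")
        assert dd.values[0, 0] == 0.0
        # Y and Z share only the universal (zero-information) term X
        assert dd.values[1, 2] == 0.0
        assert dd.values[1, 1] == 1.0

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_small_forests(self, seed):
        """Dynamic program equals exhaustive path/intersection enumeration."""
        rng = np.random.default_rng(200 + seed)
        forest = random_forest(rng, n_diseases=int(rng.integers(2, 7)), max_nodes=5)
        names = forest.diseases
        dp = semantic_similarity({d: wang_contributions(forest, d) for d in names}, names)
        brute = oracles.brute_semantic_matrix(
            {d: oracles.brute_wang_contributions(forest.dags[d], d) for d in names},
            names,
        )
        np.testing.assert_allclose(dp.values, brute, atol=1e-12)


class TestFunctionalSimilarity:
    @staticmethod
    def _dd(values, names):
        return SimilarityMatrix(np.asarray(values, float), names, "DD1")

    def test_equal_disease_sets_give_one(self):
        md = AssociationMatrix(np.array([[1, 1], [1, 1]], bool), ["m1", "m2"], ["a", "b"])
        dd = self._dd([[1.0, 0.2], [0.2, 1.0]], ["a", "b"])
        mm = mirna_functional_similarity(dd, md)
        assert mm.values[0, 1] == pytest.approx(1.0)

    def test_unrelated_disease_sets_give_zero(self):
        md = AssociationMatrix(np.array([[1, 0], [0, 1]], bool), ["m1", "m2"], ["a", "b"])
        dd = self._dd([[1.0, 0.0], [0.0, 1.0]], ["a", "b"])
        mm = mirna_functional_similarity(dd, md)
        assert mm.values[0, 1] == 0.0

    def test_best_match_average_value(self):
        # D(m1) = {X}, D(m2) = {X, Y}, dd(X, Y) = 1/3 -> (1 + 1 + 1/3) / 3
        md = AssociationMatrix(np.array([[1, 0], [1, 1]], bool), ["m1", "m2"], ["X", "Y"])
        dd = self._dd([[1.0, 1 / 3], [1 / 3, 1.0]], ["X", "Y"])
        mm = mirna_functional_similarity(dd, md)
        assert mm.values[0, 1] == pytest.approx(7 / 9)

    def test_mirna_without_association_is_undefined_not_zero(self):
        md = AssociationMatrix(np.array([[1, 1], [0, 0]], bool), ["m1", "m2"], ["a", "b"])
        dd = self._dd(np.eye(2), ["a", "b"])
        mm = mirna_functional_similarity(dd, md)
        assert np.isnan(mm.values[0, 1])
        assert not mm.defined[0, 1]
        assert mm.defined[0, 0]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_loop_oracle_and_is_symmetric(self, seed):
        rng = np.random.default_rng(300 + seed)
        md_values = rng.random((6, 5)) < 0.4
        md = AssociationMatrix(md_values | _ensure_any(md_values),
                               [f"m{i}" for i in range(6)], [f"d{j}" for j in range(5)])
        raw = rng.random((5, 5))
        dd_values = (raw + raw.T) / 2
        np.fill_diagonal(dd_values, 1.0)
        dd = self._dd(dd_values, md.disease_names)
        mm = mirna_functional_similarity(dd, md)
        brute = oracles.brute_functional_similarity(dd_values, md.values)
        np.testing.assert_allclose(mm.values, brute, atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(mm.values, mm.values.T, atol=0, equal_nan=True)
        finite = np.isfinite(mm.values)
        assert (mm.values[finite] >= 0).all() and (mm.values[finite] <= 1 + 1e-12).all()


def _ensure_any(values):
    out = np.zeros_like(values)
    if not values.any():
        out[0, 0] = True
    return out


class TestGaussianKernel:
    def test_identity_profiles(self):
        # 2x2 identity: gamma = 1, off-diagonal exp(-2)
        md = AssociationMatrix(np.eye(2, dtype=bool), ["m1", "m2"], ["a", "b"])
        gd = gaussian_profile_kernel(md, "disease")
        assert gd.values[0, 0] == 1.0
        assert gd.values[0, 1] == pytest.approx(np.exp(-2.0))

    def test_identical_columns_give_one(self):
        md = AssociationMatrix(np.array([[1, 1], [0, 0], [1, 1]], bool),
                               ["m1", "m2", "m3"], ["a", "b"])
        gd = gaussian_profile_kernel(md, "disease")
        assert gd.values[0, 1] == pytest.approx(1.0)

    def test_all_zero_matrix_is_fatal(self):
        md = AssociationMatrix(np.zeros((2, 2), bool), ["m1", "m2"], ["a", "b"])
        with pytest.raises(ValueError, match="bandwidth undefined"):
            gaussian_profile_kernel(md, "disease")

    @pytest.mark.parametrize("seed", range(20))
    def test_bounds_symmetry_and_oracle(self, seed):
        rng = np.random.default_rng(400 + seed)
        values = rng.random((7, 5)) < 0.3
        values[0, 0] = True
        md = AssociationMatrix(values, [f"m{i}" for i in range(7)],
                               [f"d{j}" for j in range(5)])
        for axis, profiles in (("disease", values.T), ("mirna", values)):
            g = gaussian_profile_kernel(md, axis)
            np.testing.assert_allclose(
                g.values, oracles.brute_gaussian_kernel(profiles.astype(float)),
                atol=1e-12)
            assert (g.values > 0).all() and (g.values <= 1.0).all()
            np.testing.assert_allclose(g.values, g.values.T, atol=0)
            # kernel hits 1 exactly iff profiles identical
            same = (profiles[:, None, :] == profiles[None, :, :]).all(axis=2)
            np.testing.assert_array_equal(g.values == 1.0, same)


class TestIntegration:
    @staticmethod
    def _sim(values, kind):
        n = len(values)
        return SimilarityMatrix(np.asarray(values, float),
                                [f"e{i}" for i in range(n)], kind)

    def test_full_mask_is_plain_mean(self):
        dd1 = self._sim([[1.0, 0.4], [0.4, 1.0]], "DD1")
        dd2 = self._sim([[1.0, 0.2], [0.2, 1.0]], "DD2")
        gd = self._sim([[1.0, 0.9], [0.9, 1.0]], "GD")
        out = integrate_disease(dd1, dd2, gd, np.ones((2, 2), bool))
        assert out.values[0, 1] == pytest.approx(0.3)

    def test_empty_mask_is_kernel(self):
        dd1 = self._sim([[1.0, 0.4], [0.4, 1.0]], "DD1")
        dd2 = self._sim([[1.0, 0.2], [0.2, 1.0]], "DD2")
        gd = self._sim([[1.0, 0.9], [0.9, 1.0]], "GD")
        out = integrate_disease(dd1, dd2, gd, np.zeros((2, 2), bool))
        assert out.values[0, 1] == pytest.approx(0.9)
        assert out.values[0, 0] == 1.0  # diagonal pinned even off-mask

    def test_mixed_mask_blends_cell_by_cell(self):
        rng = np.random.default_rng(0)
        raw = [rng.random((3, 3)) for _ in range(3)]
        mats = []
        for r in raw:
            sym = (r + r.T) / 2
            np.fill_diagonal(sym, 1.0)
            mats.append(sym)
        dd1, dd2, gd = (self._sim(m, k) for m, k in zip(mats, ["DD1", "DD2", "GD"]))
        mask = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=bool)
        out = integrate_disease(dd1, dd2, gd, mask)
        for i in range(3):
            for j in range(3):
                if i == j:
                    assert out.values[i, j] == 1.0
                elif mask[i, j]:
                    assert out.values[i, j] == pytest.approx(
                        (mats[0][i, j] + mats[1][i, j]) / 2)
                else:
                    assert out.values[i, j] == pytest.approx(mats[2][i, j])

    def test_mirna_integration_uses_defined_mask(self):
        # m2 has no associations: its functional similarity is undefined and
        # the blend must fall back to the kernel row
        md = AssociationMatrix(np.array([[1, 1], [0, 0], [1, 0]], bool),
                               ["m1", "m2", "m3"], ["a", "b"])
        dd = SimilarityMatrix(np.eye(2), ["a", "b"], "DD1")
        mm1 = mirna_functional_similarity(dd, md, "MM1")
        mm2 = mirna_functional_similarity(dd, md, "MM2")
        gm = gaussian_profile_kernel(md, "mirna")
        im = integrate_mirna(mm1, mm2, gm)
        assert im.values[0, 1] == pytest.approx(gm.values[0, 1])
        assert im.values[0, 2] == pytest.approx((mm1.values[0, 2] + mm2.values[0, 2]) / 2)
        im.validate()

    def test_integrated_matrices_symmetric_unit_diagonal(self, small_synthetic):
        md, forest = small_synthetic
        from katzncp.evaluation import compute_similarities
        bundle = compute_similarities(md, forest)
        for sim in (bundle.integrated_disease, bundle.integrated_mirna):
            sim.validate()
            assert np.all(np.diag(sim.values) == 1.0)


def test_semantic_mask_requires_both_dags(chain_pair_forest):
    mask = semantic_mask(chain_pair_forest, ["X", "Y", "Z"])
    assert mask[0, 1] and not mask[0, 2] and not mask[2, 2]
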