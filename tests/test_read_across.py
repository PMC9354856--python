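import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from raidkit.data_model import FoldChangeMatrix, ToxicityLabels, ValidationError
from raidkit.read_across import (
    biosimilar_neighbors,
    class_ellipses,
    fit_pca,
    loading_length,
    pc_related_gene_set,
    plsda,
    project,
    qivive_rmse,
    quadrant_top_genes,
    venn_partition,
)


def _frame(arr, prefix_r="S", prefix_c="g"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix_r}{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix_c}{j}" for j in range(arr.shape[1])],
    )


class TestFitPca:
    def test_collinear_data_explained_by_first_component(self):
        t = np.linspace(-2, 2, 8)
        X = _frame(np.outer(t, [1.0, -2.0, 0.5]))
        pca = fit_pca(X)
        ratio = pca.explained_variance_ratio
        assert ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_scores_equal_centered_data_times_loadings(self):
        rng = np.random.default_rng(0)
        X = _frame(rng.normal(size=(10, 4)))
        pca = fit_pca(X)
        recomputed = (X - pca.center) @ pca.loadings
        assert np.allclose(recomputed.to_numpy(), pca.scores.to_numpy(), atol=1e-8)

    def test_explained_variance_matches_eigendecomposition(self):
        X = _frame([[1.0, 2.0, 0.5], [0.0, 1.0, 1.5], [2.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        pca = fit_pca(X)
        evals = np.linalg.eigvalsh(np.cov(X.to_numpy(), rowvar=False))[::-1]
        assert np.allclose(pca.explained_variance, evals[: pca.n_components], atol=1e-10)

    def test_loadings_orthonormal_and_variance_conserved(self):
        rng = np.random.default_rng(1)
        X = _frame(rng.normal(size=(12, 5)))
        pca = fit_pca(X)
        L = pca.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(pca.n_components), atol=1e-8)
        total_var = X.var(ddof=1).sum()
        assert pca.explained_variance.sum() == pytest.approx(total_var, abs=1e-8)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(2)
        X = _frame(rng.normal(size=(9, 4)))
        pca = fit_pca(X)
        for c in pca.loadings.columns:
            col = pca.loadings[c].to_numpy()
            assert col[np.abs(col).argmax()] > 0

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            fit_pca(_frame(np.ones((5, 3))))

    def test_too_few_substances_rejected(self):
        with pytest.raises(ValidationError, match="3 substances"):
            fit_pca(_frame([[1.0, 2.0], [3.0, 4.0]]))


class TestProject:
    def test_training_rows_project_to_training_scores(self):
        rng = np.random.default_rng(3)
        X = _frame(rng.normal(size=(8, 3)))
        pca = fit_pca(X)
        assert np.allclose(
            project(pca, X).to_numpy(), pca.scores.to_numpy(), atol=1e-8
        )

    def test_training_mean_projects_to_origin(self):
        rng = np.random.default_rng(4)
        X = _frame(rng.normal(size=(7, 3)))
        pca = fit_pca(X)
        mean_row = pd.DataFrame([X.mean(axis=0)], index=["mean"])
        assert np.allclose(project(pca, mean_row).to_numpy(), 0.0, atol=1e-10)

    def test_hand_built_two_feature_case(self):
        X = _frame([[1.0, 0.0], [-1.0, 0.0], [0.5, 0.0], [-0.5, 0.0]])
        pca = fit_pca(X)
        new = pd.DataFrame({"g0": [2.0], "g1": [0.0]}, index=["N"])
        # center is the origin; PC1 loading is (1, 0) by the sign convention
        assert project(pca, new).loc["N", "PC1"] == pytest.approx(2.0, abs=1e-12)

    def test_feature_mismatch_lists_missing(self):
        rng = np.random.default_rng(5)
        pca = fit_pca(_frame(rng.normal(size=(6, 3))))
        with pytest.raises(ValidationError, match="g2"):
            project(pca, _frame(rng.normal(size=(2, 2))))


class TestLoadingLength:
    @pytest.mark.parametrize(
        "l1,l2,expected", [(0.3, 0.4, 0.5), (0.0, 0.0, 0.0), (-0.6, 0.8, 1.0)]
    )
    def test_pythagorean(self, l1, l2, expected):
        assert loading_length(np.array([l1, l2])) == pytest.approx(expected)


class TestQuadrantTopGenes:
    def _pca_with_loadings(self, loadings):
        genes = [f"g{i}" for i in range(len(loadings))]
        L = pd.DataFrame(loadings, index=genes, columns=["PC1", "PC2"])
        from raidkit.data_model import PCAResult

        return PCAResult(
            scores=pd.DataFrame(np.zeros((3, 2)), columns=["PC1", "PC2"]),
            loadings=L,
            explained_variance=np.array([1.0, 0.5]),
            center=pd.Series(0.0, index=genes[:2]),
        )

    def test_signs_assign_quadrants(self):
        pca = self._pca_with_loadings([[0.5, -0.5], [0.5, 0.5], [-0.5, -0.5]])
        assert list(quadrant_top_genes(pca, 4).entries["gene"]) == ["g0"]
        assert list(quadrant_top_genes(pca, 1).entries["gene"]) == ["g1"]
        assert list(quadrant_top_genes(pca, 3).entries["gene"]) == ["g2"]
        assert quadrant_top_genes(pca, 2).entries.empty

    def test_fewer_genes_than_k_returns_all(self):
        pca = self._pca_with_loadings([[0.1, 0.1], [0.2, 0.3]])
        assert len(quadrant_top_genes(pca, 1, k=30).entries) == 2

    def test_ranking_equals_brute_force_sort(self):
        rng = np.random.default_rng(6)
        loadings = rng.normal(size=(40, 2))
        pca = self._pca_with_loadings(loadings)
        ranking = quadrant_top_genes(pca, 1, k=10).entries
        brute = sorted(
            (
                (np.hypot(l1, l2), f"g{i}")
                for i, (l1, l2) in enumerate(loadings)
                if l1 > 0 and l2 > 0
            ),
            key=lambda t: (-t[0], t[1]),
        )[:10]
        assert list(ranking["gene"]) == [g for _, g in brute]

    def test_zero_loading_belongs_to_no_quadrant(self):
        pca = self._pca_with_loadings([[0.0, 0.5], [0.5, 0.5]])
        for q in (1, 2, 3, 4):
            assert "g0" not in list(quadrant_top_genes(pca, q).entries["gene"])


class TestPcRelatedGeneSet:
    def _pca(self, n_genes, rng):
        genes = [f"g{i:02d}" for i in range(n_genes)]
        from raidkit.data_model import PCAResult

        L = pd.DataFrame(
            rng.normal(size=(n_genes, 2)), index=genes, columns=["PC1", "PC2"]
        )
        return PCAResult(
            scores=pd.DataFrame(np.zeros((3, 2)), columns=["PC1", "PC2"]),
            loadings=L,
            explained_variance=np.array([1.0, 0.5]),
            center=pd.Series(dtype=float),
        )

    def test_saturates_to_all_genes_when_k_large(self):
        pca = self._pca(10, np.random.default_rng(7))
        assert pc_related_gene_set(pca, k=30) == set(pca.loadings.index)

    def test_matches_brute_force_construction(self):
        pca = self._pca(200, np.random.default_rng(8))
        k = 30
        expected = set()
        for pc in ("PC1", "PC2"):
            order = pca.loadings[pc].sort_values()
            expected |= set(order.index[:k]) | set(order.index[-k:])
        assert pc_related_gene_set(pca, k=k) == expected


class TestVennPartition:
    def test_identical_sets_put_all_mass_in_full_intersection(self):
        s = {"A": {"x", "y"}, "B": {"x", "y"}, "C": {"x", "y"}}
        counts = venn_partition(s)
        assert counts[frozenset({"A", "B", "C"})] == 2
        assert sum(counts.values()) == 2

    def test_disjoint_sets_populate_singletons_only(self):
        counts = venn_partition({"A": {"x"}, "B": {"y", "z"}})
        assert counts[frozenset({"A"})] == 1
        assert counts[frozenset({"B"})] == 2
        assert counts[frozenset({"A", "B"})] == 0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        universe = [f"e{i}" for i in range(60)]
        sets = {
            name: {e for e in universe if rng.random() < p}
            for name, p in (("A", 0.5), ("B", 0.3), ("C", 0.4))
        }
        counts = venn_partition(sets)
        for r in range(1, 4):
            for combo in itertools.combinations(sets, r):
                members = [
                    e
                    for e in universe
                    if all(e in sets[n] for n in combo)
                    and all(e not in sets[n] for n in sets if n not in combo)
                ]
                assert counts[frozenset(combo)] == len(members)
        assert sum(counts.values()) == len(set().union(*sets.values()))


def _fc(arr, source):
    return FoldChangeMatrix(values=np.exp2(_frame(arr)), source=source)


class TestQiviveRmse:
    def test_perfect_prediction_gives_zero_raid_rmse(self):
        rng = np.random.default_rng(10)
        vivo = rng.normal(size=(6, 4))
        vitro = vivo + rng.normal(0, 1.0, (6, 4))
        cmp_ = qivive_rmse(
            _fc(vivo, "predicted"), _fc(vivo, "in_vivo"), _fc(vitro, "in_vitro")
        )
        assert np.allclose(cmp_.per_gene_rmse_raid.to_numpy(), 0.0, atol=1e-12)

    def test_identical_rmse_vectors_give_t0_p1(self):
        rng = np.random.default_rng(11)
        vivo = rng.normal(size=(5, 3))
        other = vivo + rng.normal(0, 0.5, (5, 3))
        cmp_ = qivive_rmse(
            _fc(other, "predicted"), _fc(vivo, "in_vivo"), _fc(other, "in_vitro")
        )
        assert cmp_.welch_t == 0.0 and cmp_.welch_p == 1.0

    def test_hand_computed_three_gene_toy(self):
        rng = np.random.default_rng(12)
        vivo = rng.normal(size=(4, 3))
        pred = vivo + rng.normal(0, 0.3, (4, 3))
        vitro = vivo + rng.normal(0, 1.0, (4, 3))
        cmp_ = qivive_rmse(
            _fc(pred, "predicted"), _fc(vivo, "in_vivo"), _fc(vitro, "in_vitro")
        )

        def znorm(m):
            return (m - m.mean()) / m.std()

        zp, zv, zt = znorm(pred), znorm(vivo), znorm(vitro)
        rmse_p = np.sqrt(((zp - zv) ** 2).mean(axis=0))
        rmse_t = np.sqrt(((zt - zv) ** 2).mean(axis=0))
        assert np.allclose(cmp_.per_gene_rmse_raid.to_numpy(), rmse_p, atol=1e-12)
        assert np.allclose(cmp_.per_gene_rmse_invitro.to_numpy(), rmse_t, atol=1e-12)
        # Welch's t from the hand-coded formula on the two 3-vectors
        va, vb = rmse_p.var(ddof=1) / 3, rmse_t.var(ddof=1) / 3
        t = (rmse_p.mean() - rmse_t.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        assert cmp_.welch_t == pytest.approx(t, rel=1e-10)
        assert cmp_.welch_p == pytest.approx(2 * stats.t.sf(abs(t), df), rel=1e-10)

    def test_invariant_to_gene_relabeling(self):
        rng = np.random.default_rng(13)
        vivo, pred, vitro = (rng.normal(size=(5, 4)) for _ in range(3))
        a = qivive_rmse(_fc(pred, "predicted"), _fc(vivo, "in_vivo"), _fc(vitro, "in_vitro"))
        perm = ["g2", "g0", "g3", "g1"]
        b = qivive_rmse(
            FoldChangeMatrix(values=np.exp2(_frame(pred)[perm]), source="predicted"),
            FoldChangeMatrix(values=np.exp2(_frame(vivo)[perm]), source="in_vivo"),
            FoldChangeMatrix(values=np.exp2(_frame(vitro)[perm]), source="in_vitro"),
        )
        assert sorted(a.per_gene_rmse_raid) == pytest.approx(sorted(b.per_gene_rmse_raid))
        assert a.welch_t == pytest.approx(b.welch_t, rel=1e-12)

    def test_important_scope_requires_bank(self):
        rng = np.random.default_rng(14)
        m = rng.normal(size=(4, 3))
        with pytest.raises(ValidationError, match="bank"):
            qivive_rmse(
                _fc(m, "predicted"), _fc(m, "in_vivo"), _fc(m, "in_vitro"),
                scope="invitro_important",
            )


class TestBiosimilarNeighbors:
    def _scores(self, pts, names=None):
        names = names or [f"S{i}" for i in range(len(pts))]
        return pd.DataFrame(pts, index=names, columns=["PC1", "PC2"])

    def test_duplicate_of_query_ranks_first_at_zero_distance(self):
        scores = self._scores([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]], ["q", "twin", "far"])
        out = biosimilar_neighbors(scores, "q", k=2)
        assert out.loc[0, "substance"] == "twin"
        assert out.loc[0, "distance"] == 0.0

    def test_k_larger_than_population_returns_all(self):
        scores = self._scores([[0.0, 0.0], [1.0, 0.0]])
        assert len(biosimilar_neighbors(scores, "S0", k=99)) == 1

    def test_ordering_equals_brute_force_pairwise_distances(self):
        rng = np.random.default_rng(15)
        pts = rng.normal(size=(5, 2))
        scores = self._scores(pts)
        out = biosimilar_neighbors(scores, "S2", k=4)
        brute = sorted(
            (float(np.hypot(*(pts[i] - pts[2]))), f"S{i}") for i in range(5) if i != 2
        )
        assert list(out["substance"]) == [s for _, s in brute]
        assert np.allclose(out["distance"], [d for d, _ in brute])

    def test_unknown_query_rejected(self):
        with pytest.raises(ValidationError, match="unknown query"):
            biosimilar_neighbors(self._scores([[0, 0], [1, 1]]), "nope")


class TestPlsda:
    def _separable(self, n=40, seed=16):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 6))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        X[:, 0] += 4.0 * y  # wide margin
        matrix = _frame(X)
        labels = ToxicityLabels(
            {s: ("toxic" if yi else "non_toxic") for s, yi in zip(matrix.index, y)}
        )
        return matrix, labels

    def test_separable_classes_classified_perfectly(self):
        matrix, labels = self._separable()
        out = plsda(matrix, labels, split_seed=0)
        assert out.holdout_accuracy == 1.0

    def test_permuted_labels_score_near_chance(self):
        matrix, labels = self._separable(n=60)
        rng = np.random.default_rng(17)
        permuted = list(labels.labels.values())
        rng.shuffle(permuted)
        shuffled = ToxicityLabels(dict(zip(labels.labels, permuted)))
        out = plsda(matrix, shuffled, split_seed=0)
        # 18 held-out substances: binomial 95% band around 0.5
        n_test = len(out.test_substances)
        band = 1.96 * np.sqrt(0.25 / n_test)
        assert abs(out.holdout_accuracy - 0.5) <= band + 1e-9

    def test_first_weight_vector_proportional_to_xty(self):
        matrix, labels = self._separable(n=30, seed=18)
        out = plsda(matrix, labels, split_seed=3)
        train = [s for s in matrix.index if s not in out.test_substances]
        X = matrix.loc[train].to_numpy()
        y = labels.binary(train).astype(float)
        xty = (X - X.mean(0)).T @ (y - y.mean())
        w1 = out.x_weights["PLS1"].to_numpy()
        cos = abs(xty @ w1) / (np.linalg.norm(xty) * np.linalg.norm(w1))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_single_class_rejected(self):
        matrix, _ = self._separable(n=10)
        labels = ToxicityLabels({s: "toxic" for s in matrix.index})
        with pytest.raises(ValidationError, match="both"):
            plsda(matrix, labels)


class TestClassEllipses:
    def test_centers_match_class_means(self):
        rng = np.random.default_rng(19)
        scores = pd.DataFrame(
            rng.normal(size=(20, 2)), columns=["PC1", "PC2"],
            index=[f"S{i}" for i in range(20)],
        )
        labels = ToxicityLabels(
            {s: ("toxic" if i < 8 else "non_toxic") for i, s in enumerate(scores.index)}
        )
        out = class_ellipses(scores, labels)
        toxic_pts = scores.iloc[:8]
        assert np.allclose(out["toxic"]["center"], toxic_pts.mean(axis=0), atol=1e-12)
        assert out["toxic"]["n"] == 8
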