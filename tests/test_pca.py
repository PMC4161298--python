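import numpy as np
import pandas as pd
import pytest

from dispca.exceptions import ConfigurationError, ValidationError
from dispca.pca import (
    ScoreMatrix,
    build_matrix,
    center_columns,
    correlate_loadings,
    encode_design,
    filter_region,
    prune_by_distance,
    residualize,
    run_pca,
    top_loading_genes,
)
from dispca.pca import test_confounders as confounder_regression
from dispca.scores import GeneScoreTable


def _table(ds, genes_p):
    df = pd.DataFrame(
        {"gene_id": list(genes_p), "n_snps": 1, "raw_stat": list(genes_p.values()),
         "empirical_p": list(genes_p.values())}
    )
    return GeneScoreTable(dataset_id=ds, table=df, null_size=100, seed=0)


def _matrix(Z, covariates=None):
    d, g = Z.shape
    return ScoreMatrix(
        Z=Z, dataset_ids=[f"D{i}" for i in range(d)],
        gene_ids=[f"G{j}" for j in range(g)], covariates=covariates,
    )


class TestBuildMatrix:
    def test_gene_intersection_sorted(self):
        t1 = _table("D1", {"A": 0.5, "B": 0.1, "C": 0.2})
        t2 = _table("D2", {"B": 0.3, "C": 0.4, "D": 0.9})
        m = build_matrix([t1, t2])
        assert m.gene_ids == ["B", "C"]
        assert m.dataset_ids == ["D1", "D2"]

    def test_entries_are_neglog10(self):
        t1 = _table("D1", {"A": 0.01})
        t2 = _table("D2", {"A": 0.1})
        m = build_matrix([t1, t2])
        assert m.Z[0, 0] == pytest.approx(2.0)
        assert m.Z[1, 0] == pytest.approx(1.0)

    def test_three_tables_match_hand_assembly(self, rng):
        genes = [f"g{i}" for i in range(5)]
        ps = [dict(zip(genes, rng.uniform(0.01, 1, size=5))) for _ in range(3)]
        m = build_matrix([_table(f"D{i}", p) for i, p in enumerate(ps)])
        hand = np.array([[-np.log10(p[g]) for g in sorted(genes)] for p in ps])
        np.testing.assert_allclose(m.Z, hand)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValidationError):
            build_matrix([_table("D1", {"A": 0.5}), _table("D2", {"B": 0.5})])

    def test_missing_covariates_rejected(self):
        cov = pd.DataFrame(
            {"dataset_id": ["D1"], "array": ["a"], "method": ["m"], "n": [100]}
        )
        with pytest.raises(ValidationError):
            build_matrix([_table("D1", {"A": 0.5}), _table("D2", {"A": 0.4})], cov)


class TestCentering:
    def test_mean_removal(self):
        B = center_columns(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(B[:, 0], [-1.0, 1.0])

    def test_constant_column_zeroed(self):
        B = center_columns(np.full((4, 2), 7.0))
        assert np.all(B == 0)

    def test_random_matrix_columns_centered(self, rng):
        B = center_columns(rng.normal(size=(5, 7)))
        assert np.max(np.abs(B.mean(axis=0))) < 1e-12


def _random_cov(d, rng):
    return pd.DataFrame(
        {
            "dataset_id": [f"D{i}" for i in range(d)],
            "array": rng.choice(["x", "y"], size=d),
            "method": rng.choice(["l", "t"], size=d),
            "n": rng.integers(500, 5000, size=d),
        }
    )


class TestConfounders:
    def test_gene_equal_to_covariate_most_significant(self, rng):
        d = 8
        cov = _random_cov(d, rng)
        design = encode_design(cov)
        Z = rng.normal(size=(d, 10))
        Z[:, 0] = design["log10_n"] * 3.0  # perfect fit to one covariate
        report = confounder_regression(_matrix(Z, cov), alpha=0.05)
        assert report.p_values["log10_n"].idxmin() == "G0"

    def test_closed_form_slope_single_covariate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 2.5, 4.0, 3.5, 5.5, 6.0])
        design = pd.DataFrame({"intercept": np.ones(6), "c": x})
        Z = y[:, None]
        m = ScoreMatrix(Z=Z, dataset_ids=[f"D{i}" for i in range(6)], gene_ids=["G"])
        report = confounder_regression(m, design=design)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert report.coefficients.loc["G", "c"] == pytest.approx(slope)

    def test_matches_statsmodels_per_gene(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        d, g = 9, 6
        cov = _random_cov(d, rng)
        Z = rng.normal(size=(d, g))
        matrix = _matrix(Z, cov)
        report = confounder_regression(matrix)
        X = encode_design(cov).to_numpy()
        for j in range(g):
            fit = sm.OLS(Z[:, j], X).fit()
            np.testing.assert_allclose(
                report.coefficients.iloc[j].to_numpy(), fit.params[1:], rtol=1e-8
            )
            np.testing.assert_allclose(
                report.p_values.iloc[j].to_numpy(), fit.pvalues[1:], rtol=1e-6
            )

    def test_rank_deficient_design_named(self, rng):
        d = 6
        design = pd.DataFrame(
            {"intercept": np.ones(d), "a": np.arange(d, dtype=float),
             "b": 2.0 * np.arange(d)}
        )
        m = ScoreMatrix(Z=rng.normal(size=(d, 3)),
                        dataset_ids=[f"D{i}" for i in range(d)],
                        gene_ids=["G0", "G1", "G2"])
        with pytest.raises(ConfigurationError, match="collinear"):
            confounder_regression(m, design=design)


class TestResidualize:
    def test_perfect_fit_gives_zero_column(self, rng):
        d = 7
        cov = _random_cov(d, rng)
        design = encode_design(cov)
        Z = rng.normal(size=(d, 4))
        Z[:, 2] = 5.0 * design["log10_n"] - 1.0
        R = residualize(_matrix(Z, cov))
        assert np.max(np.abs(R[:, 2])) < 1e-10

    def test_intercept_only_equals_centering(self, rng):
        d = 6
        Z = rng.normal(size=(d, 5))
        design = pd.DataFrame({"intercept": np.ones(d)})
        m = ScoreMatrix(Z=Z, dataset_ids=[f"D{i}" for i in range(d)],
                        gene_ids=[f"G{j}" for j in range(5)])
        np.testing.assert_allclose(residualize(m, design=design), center_columns(Z))

    def test_matches_hat_matrix_projection(self, rng):
        d = 9
        cov = _random_cov(d, rng)
        Z = rng.normal(size=(d, 8))
        X = encode_design(cov).to_numpy()
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        R = residualize(_matrix(Z, cov))
        np.testing.assert_allclose(R, (np.eye(d) - H) @ Z, atol=1e-10)
        # residual columns orthogonal to every design column
        assert np.max(np.abs(X.T @ R)) < 1e-8


class TestRunPca:
    def test_two_by_two_by_hand(self):
        res = run_pca(np.array([[-1.0, -1.0], [1.0, 1.0]]))
        np.testing.assert_allclose(np.sqrt(res.eigenvalues), [2.0, 0.0], atol=1e-12)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_eigenvalues_match_row_covariance(self, rng):
        for _ in range(10):
            M = rng.normal(size=(6, 20))
            res = run_pca(M)
            B = center_columns(M)
            eig = np.sort(np.linalg.eigvalsh(B @ B.T))[::-1]
            np.testing.assert_allclose(res.eigenvalues, eig[:6], atol=1e-8)

    def test_coords_are_centered_matrix_times_loadings(self, rng):
        M = rng.normal(size=(8, 50))
        res = run_pca(M)
        np.testing.assert_allclose(
            res.dataset_coords, center_columns(M) @ res.gene_loadings, atol=1e-8
        )

    def test_loadings_orthonormal_and_fractions_valid(self, rng):
        res = run_pca(rng.normal(size=(7, 30)))
        W = res.gene_loadings
        np.testing.assert_allclose(W.T @ W, np.eye(W.shape[1]), atol=1e-8)
        vf = res.variance_fraction
        assert np.all(vf >= 0) and np.all(np.diff(vf) <= 1e-12)
        assert vf.sum() == pytest.approx(1.0)

    def test_row_permutation_equivariance(self, rng):
        M = rng.normal(size=(6, 40))
        perm = rng.permutation(6)
        a = run_pca(M)
        b = run_pca(M[perm])
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-8)
        np.testing.assert_allclose(a.dataset_coords[perm], b.dataset_coords, atol=1e-6)

    def test_sign_convention_fixed(self, rng):
        res = run_pca(rng.normal(size=(5, 12)))
        for j in range(res.gene_loadings.shape[1]):
            col = res.gene_loadings[:, j]
            assert col[np.argmax(np.abs(col))] >= 0

    def test_residualization_zeroes_one_component_per_covariate(self, rng):
        # 3 independent covariates + centering -> exactly 4 null directions
        d, g = 10, 200
        Z = rng.normal(size=(d, g))
        design = pd.DataFrame(
            {"intercept": np.ones(d), "c1": rng.normal(size=d),
             "c2": rng.normal(size=d), "c3": rng.normal(size=d)}
        )
        m = ScoreMatrix(Z=Z, dataset_ids=[f"D{i}" for i in range(d)],
                        gene_ids=[f"G{j}" for j in range(g)])
        res = run_pca(residualize(m, design=design), source="residualized")
        n_zero = int(np.sum(res.eigenvalues < 1e-10 * res.eigenvalues[0]))
        assert n_zero == 4


class TestTopGenesAndPruning:
    def test_saturation_returns_all(self):
        p = _fake_pca(np.array([[0.1], [0.2], [0.3]]), ["A", "B", "C"])
        assert len(top_loading_genes(p, pcs=[0], k=10)) == 3

    def test_absolute_value_ranking(self):
        p = _fake_pca(np.array([[0.9], [-0.95], [0.1]]), ["A", "B", "C"])
        assert top_loading_genes(p, pcs=[0], k=2)["gene_id"].tolist() == ["B", "A"]

    def test_matches_independent_sort(self, rng):
        L = rng.normal(size=(40, 2))
        ids = [f"g{i:02d}" for i in range(40)]
        p = _fake_pca(L, ids)
        got = top_loading_genes(p, pcs=[0, 1], k=15)["gene_id"].tolist()
        score = np.abs(L).mean(axis=1)
        expected = [ids[i] for i in sorted(range(40), key=lambda i: (-score[i], ids[i]))][:15]
        assert got == expected

    def _positions(self, cms, chrom="1"):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(cms))],
             "chrom": chrom, "pos_cm": cms}
        )

    def test_prune_pairwise_rule(self):
        ranked = pd.DataFrame({"gene_id": ["g0", "g1", "g2"]})
        out = prune_by_distance(ranked, self._positions([1.00, 1.05, 1.20]), 0.1)
        assert out["gene_id"].tolist() == ["g0", "g2"]

    def test_prune_noop_when_far_apart(self):
        ranked = pd.DataFrame({"gene_id": ["g0", "g1", "g2"]})
        out = prune_by_distance(ranked, self._positions([1.0, 2.0, 3.0]), 0.1)
        assert out["gene_id"].tolist() == ["g0", "g1", "g2"]

    def test_prune_chain_greedy_left_to_right(self):
        ranked = pd.DataFrame({"gene_id": ["g0", "g1", "g2"]})
        out = prune_by_distance(ranked, self._positions([1.00, 1.08, 1.15]), 0.1)
        assert out["gene_id"].tolist() == ["g0", "g2"]

    def test_prune_missing_cm_rejected(self):
        ranked = pd.DataFrame({"gene_id": ["g0", "gX"]})
        with pytest.raises(ValidationError):
            prune_by_distance(ranked, self._positions([1.0]), 0.1)

    def test_hla_region_filter(self):
        genes = pd.DataFrame(
            {"gene_id": ["in", "out"], "chrom": ["6", "6"],
             "start_bp": [26_000_000, 40_000_000], "end_bp": [26_100_000, 40_100_000]}
        )
        assert filter_region(genes)["gene_id"].tolist() == ["out"]


class TestCorrelateLoadings:
    def test_self_correlation_is_one(self, rng):
        res = run_pca(rng.normal(size=(6, 30)))
        r, p = correlate_loadings(res, res, k=10)
        assert r == pytest.approx(1.0)

    def test_sign_flip_invariance(self, rng):
        res = run_pca(rng.normal(size=(6, 30)))
        import copy

        flipped = copy.deepcopy(res)
        flipped.gene_loadings = -flipped.gene_loadings
        r, _ = correlate_loadings(res, flipped, k=10)
        assert r == pytest.approx(1.0)

    def test_independent_results_t_p_matches_permutation(self, rng):
        a = run_pca(rng.normal(size=(8, 200)))
        b = run_pca(rng.normal(size=(8, 200)))
        b.gene_ids = a.gene_ids
        r, p = correlate_loadings(a, b, k=50)
        assert abs(r) < 0.5
        # permutation oracle on the same selected vectors
        shared = a.gene_ids
        ia = np.arange(len(shared))
        A = a.gene_loadings[ia][:, :2]
        B = b.gene_loadings[ia][:, :2]
        for j in range(2):
            if np.dot(A[:, j], B[:, j]) < 0:
                B[:, j] = -B[:, j]
        score = (np.abs(A).mean(axis=1) + np.abs(B).mean(axis=1)) / 2
        sel = np.argsort(-score)[:50]
        x, y = A[sel].ravel(), B[sel].ravel()
        obs = abs(np.corrcoef(x, y)[0, 1])
        perm = np.array(
            [abs(np.corrcoef(x, rng.permutation(y))[0, 1]) for _ in range(2000)]
        )
        p_perm = (1 + np.sum(perm >= obs)) / 2001
        assert abs(p - p_perm) < 0.1

    def test_too_few_shared_genes(self, rng):
        a = run_pca(rng.normal(size=(4, 10)))
        b = run_pca(rng.normal(size=(4, 10)), gene_ids=[f"x{i}" for i in range(10)])
        with pytest.raises(ValidationError):
            correlate_loadings(a, b, k=5)


def _fake_pca(loadings, gene_ids):
    """PcaResult stub carrying only loadings/ids (for ranking helpers)."""
    from dispca.pca import PcaResult

    L = np.asarray(loadings, dtype=float)
    k = L.shape[1]
    return PcaResult(
        dataset_ids=[], gene_ids=list(gene_ids), dataset_coords=np.zeros((0, k)),
        gene_loadings=L, eigenvalues=np.ones(k), variance_fraction=np.ones(k) / k,
        left_vectors=np.zeros((0, k)),
    )
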