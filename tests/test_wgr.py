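"""Gibbs sampler correctness: closed-form oracles, invariance, recovery."""

import numpy as np
import pytest

from hegp import (
    GibbsConfig,
    OrthogonalKey,
    PlainDataset,
    SimScenario,
    ebv,
    encrypt,
    fit,
    gblup_loglik,
    gblup_to_marker_effects,
    grm,
    normalize,
    sample_key,
    simulate_dataset,
)
from hegp.exceptions import InvalidArgumentError


class TestConfig:
    def test_burn_in_must_precede_end(self):
        with pytest.raises(InvalidArgumentError):
            GibbsConfig(n_iter=100, burn_in=100)

    def test_thin_positive(self):
        with pytest.raises(InvalidArgumentError):
            GibbsConfig(thin=0)

    def test_snp_blup_forces_pi_zero(self):
        cfg = GibbsConfig(model="snp_blup", pi_init=0.5, estimate_pi=True)
        assert cfg.pi_init == 0.0
        assert not cfg.estimate_pi

    def test_unknown_model(self):
        with pytest.raises(InvalidArgumentError):
            GibbsConfig(model="bayesZ")


class TestFit:
    def test_null_phenotype_gives_null_effects(self):
        rng = np.random.default_rng(1)
        M = rng.integers(0, 3, size=(60, 20)).astype(float)
        ds = PlainDataset(y=np.zeros(60), X=np.ones((60, 1)), M=M - M.mean(axis=0))
        cfg = GibbsConfig(
            n_iter=2000, burn_in=500, seed=2, model="snp_blup",
            fix_variances=(0.01, 1.0),
        )
        s = fit(ds, cfg)
        z = np.abs(s.alpha_mean) / s.alpha.std(axis=0, ddof=1)
        assert np.all(z < 3.0)

    def test_snp_blup_matches_ridge_closed_form(self):
        ds, _ = simulate_dataset(SimScenario(n=200, p=100, h2=0.5, qtl_prop=1.0, seed=6))
        s2a, s2e = 0.005, 0.5
        cfg = GibbsConfig(
            n_iter=30000, burn_in=5000, thin=5, seed=3, model="snp_blup",
            fix_variances=(s2a, s2e),
        )
        s = fit(ds, cfg)
        # oracle: direct dense solve of the joint normal equations
        M, X, y = ds.M, ds.X, ds.y
        lam = s2e / s2a
        q, p = X.shape[1], M.shape[1]
        A = np.block([[X.T @ X, X.T @ M], [M.T @ X, M.T @ M + lam * np.eye(p)]])
        sol = np.linalg.solve(A, np.concatenate([X.T @ y, M.T @ y]))
        oracle = sol[q:]
        # batch-means Monte-Carlo SE per coordinate
        nb = 50
        bs = s.alpha.shape[0] // nb
        bm = s.alpha[: nb * bs].reshape(nb, bs, -1).mean(axis=1)
        se = bm.std(axis=0, ddof=1) / np.sqrt(nb)
        z = np.abs(s.alpha_mean - oracle) / se
        # per-coordinate 3-SE agreement up to expected multiplicity over 100 coords
        assert (z <= 3.0).mean() >= 0.95
        assert z.max() < 5.0

    def test_chain_state_identical_plain_vs_cipher(self):
        ds, _ = simulate_dataset(SimScenario(n=100, p=50, h2=0.5, qtl_prop=0.2, seed=5))
        cipher = encrypt(ds, sample_key(100, seed=9))
        cfg = GibbsConfig(
            n_iter=100, burn_in=0, thin=1, seed=42, model="snp_blup",
            fix_variances=(0.01, 0.5),
        )
        a, b = fit(ds, cfg), fit(cipher, cfg)
        rel = np.abs(a.alpha - b.alpha) / (np.abs(a.alpha) + 1e-8)
        assert rel.max() <= 1e-6

    def test_h2_recovered_across_replicates(self):
        hits = 0
        for rep in range(10):
            ds, truth = simulate_dataset(
                SimScenario(n=1000, p=2000, h2=0.5, qtl_prop=0.1, seed=100 + rep)
            )
            cfg = GibbsConfig(n_iter=3000, burn_in=1000, thin=2, seed=rep)
            s = fit(ds, cfg)
            if abs(s.h2.mean() - 0.5) <= 0.1:
                hits += 1
        assert hits >= 8

    def test_pi_recovered_with_sparse_architecture(self):
        ds, _ = simulate_dataset(
            SimScenario(n=600, p=1000, h2=0.7, qtl_prop=0.01, seed=2)
        )
        cfg = GibbsConfig(n_iter=3000, burn_in=1000, thin=2, seed=1)
        s = fit(ds, cfg)
        assert s.pi.mean() > 0.9

    def test_permutation_key_leaves_summaries_unchanged(self):
        ds, _ = simulate_dataset(SimScenario(n=80, p=30, h2=0.5, qtl_prop=0.3, seed=8))
        perm = np.random.default_rng(3).permutation(80)
        key = OrthogonalKey(np.eye(80)[perm], (80,))
        cfg = GibbsConfig(
            n_iter=500, burn_in=100, seed=7, model="snp_blup", fix_variances=(0.01, 0.5)
        )
        a, b = fit(ds, cfg), fit(encrypt(ds, key), cfg)
        assert np.max(np.abs(a.alpha_mean - b.alpha_mean)) <= 1e-6

    def test_monomorphic_marker_excluded(self):
        rng = np.random.default_rng(4)
        M = rng.integers(0, 3, size=(50, 10)).astype(float)
        M = M - M.mean(axis=0)
        M[:, 3] = 0.0
        ds = PlainDataset(y=rng.standard_normal(50), X=np.ones((50, 1)), M=M)
        with pytest.warns(UserWarning, match="zero variance"):
            s = fit(ds, GibbsConfig(n_iter=200, burn_in=50, seed=1))
        assert s.excluded_markers == ["m3"]
        assert np.all(s.alpha[:, 3] == 0.0)

    def test_rank_deficient_x_rejected(self):
        rng = np.random.default_rng(4)
        X = np.ones((30, 2))  # duplicated intercept
        ds = PlainDataset(
            y=rng.standard_normal(30), X=X,
            M=rng.integers(0, 3, size=(30, 5)).astype(float),
        )
        with pytest.raises(InvalidArgumentError, match="rank"):
            fit(ds, GibbsConfig(n_iter=100, burn_in=10, seed=1))

    def test_no_markers_rejected(self):
        ds = PlainDataset(y=np.zeros(5), X=np.ones((5, 1)), M=np.zeros((5, 0)))
        with pytest.raises(InvalidArgumentError):
            fit(ds, GibbsConfig(n_iter=10, burn_in=1, seed=1))

    def test_posterior_sample_invariants(self):
        ds, _ = simulate_dataset(SimScenario(n=100, p=40, h2=0.3, qtl_prop=0.1, seed=3))
        s = fit(ds, GibbsConfig(n_iter=600, burn_in=100, thin=2, seed=9))
        assert set(np.unique(s.delta)).issubset({0, 1})
        assert np.all(s.alpha[s.delta == 0] == 0.0)
        assert np.all(s.sigma2_alpha > 0) and np.all(s.sigma2_e > 0)
        assert np.all((s.pi >= 0) & (s.pi <= 1))
        assert np.all((s.h2 >= 0) & (s.h2 <= 1))
        rhat = s.split_rhat()
        assert set(rhat) == {"sigma2_e", "sigma2_alpha", "h2"}


class TestEBV:
    def test_zero_effects_zero_ebv(self):
        assert np.all(ebv(np.ones((5, 3)), np.zeros(3)) == 0.0)

    def test_single_marker_doubling(self):
        out = ebv(np.array([[0.0], [1.0], [2.0]]), np.array([2.0]))
        assert np.allclose(out, [0.0, 2.0, 4.0])

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            ebv(np.ones((4, 3)), np.ones(2))


class TestGBLUPLoglik:
    def test_reduces_to_iid_gaussian(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(40)
        s2u, s2e = 0.7, 0.3
        ll = gblup_loglik(y, None, None, np.eye(40), s2u, s2e)
        v = s2u + s2e
        scalar = -0.5 * (40 * np.log(2 * np.pi * v) + (y @ y) / v)
        assert ll == pytest.approx(scalar, abs=1e-10)

    def test_invariant_under_rotation(self):
        n = 200
        rng = np.random.default_rng(1)
        M = rng.integers(0, 3, size=(n, 300)).astype(float)
        G = grm(normalize(M))
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta = np.array([0.3, -0.2])
        key = sample_key(n, seed=2)
        P = key.matrix
        ll_plain = gblup_loglik(y, X, beta, G, 0.5, 0.5)
        ll_cipher = gblup_loglik(P @ y, P @ X, beta, P @ G @ P.T, 0.5, 0.5)
        assert abs(ll_plain - ll_cipher) <= 1e-6

    def test_three_by_three_longhand(self):
        # hand-computable V: diagonal, so the quadratic form is a scalar sum
        y = np.array([1.0, -2.0, 0.5])
        V = np.diag([2.0, 1.0, 0.5])
        # V = G*s2u + I*s2e with G=diag(1.5,0.5,0), s2u=1, s2e=0.5
        G = np.diag([1.5, 0.5, 0.0])
        ll = gblup_loglik(y, None, None, G, 1.0, 0.5)
        quad = 1.0 / 2.0 + 4.0 / 1.0 + 0.25 / 0.5
        logdet = np.log(2.0) + np.log(1.0) + np.log(0.5)
        expect = -0.5 * (3 * np.log(2 * np.pi) + logdet + quad)
        assert ll == pytest.approx(expect, abs=1e-12)

    def test_not_positive_definite_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gblup_loglik(np.ones(3), None, None, -10.0 * np.eye(3), 1.0, 0.5)


class TestGBLUPToMarkerEffects:
    def test_zero_genetic_values(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((5, 3))
        assert np.allclose(gblup_to_marker_effects(np.zeros(5), M), 0.0)

    def test_recovers_consistent_effects(self):
        rng = np.random.default_rng(2)
        M = rng.standard_normal((10, 6))  # p < n: MM' singular, pinv path
        alpha = rng.standard_normal(6)
        u = M @ alpha  # consistent by construction
        with pytest.warns(UserWarning, match="rank deficient"):
            alpha_hat = gblup_to_marker_effects(u, M)
        assert np.linalg.norm(M @ alpha_hat - u) <= 1e-8

    def test_small_fixture_longhand_inversion(self):
        M = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        u = np.array([1.0, 2.0])
        # MM' = [[2,1],[1,2]]; longhand inverse = (1/3) [[2,-1],[-1,2]]
        w = (1.0 / 3.0) * np.array([[2.0, -1.0], [-1.0, 2.0]]) @ u
        expect = M.T @ w
        assert np.allclose(gblup_to_marker_effects(u, M), expect, atol=1e-12)

    def test_rank_deficient_warns(self):
        M = np.ones((4, 2))  # MM' has rank 1
        with pytest.warns(UserWarning, match="rank deficient"):
            out = gblup_to_marker_effects(np.ones(4), M)
        assert np.linalg.norm(M @ out - np.ones(4)) <= 1e-8
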