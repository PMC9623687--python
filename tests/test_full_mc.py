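"""Full Monte Carlo SNP-BLUP: sampling, MME assembly, PEV and reliability."""

import numpy as np
import pytest

import mcblup as mb
from mcblup.full_mc import column_normals


class TestSampleU:
    def test_determinism_and_column_substreams(self, small_ds):
        U1 = mb.sample_U(small_ds.Zc, small_ds.L, 0.5, 8, seed=5)
        U2 = mb.sample_U(small_ds.Zc, small_ds.L, 0.5, 8, seed=5)
        np.testing.assert_array_equal(U1.U, U2.U)
        # each column depends only on its own index, not on n_mc, up to the
        # global 1/sqrt(n_mc) column scaling
        U3 = mb.sample_U(small_ds.Zc, small_ds.L, 0.5, 3, seed=5)
        np.testing.assert_allclose(U1.U[:, :3] * np.sqrt(8), U3.U * np.sqrt(3))

    def test_blend_limits(self, small_ds):
        # w=1: no marker component -> U U' approaches A22; w=0 -> Zc Zc'
        n_mc = 4000
        U1 = mb.sample_U(small_ds.Zc, small_ds.L, 1.0, n_mc, seed=2)
        err1 = np.abs(U1.U @ U1.U.T - small_ds.A22.values).max()
        U0 = mb.sample_U(small_ds.Zc, small_ds.L, 0.0, n_mc, seed=2)
        err0 = np.abs(U0.U @ U0.U.T - small_ds.Zc.Zc @ small_ds.Zc.Zc.T).max()
        assert err1 < 0.2 and err0 < 0.2

    def test_w_out_of_range(self, small_ds):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            mb.sample_U(small_ds.Zc, small_ds.L, 1.2, 10, seed=0)

    def test_column_normals_stream_separation(self):
        a = column_normals(4, 3, seed=9, stream=0)
        b = column_normals(4, 3, seed=9, stream=1)
        assert not np.allclose(a, b)


class TestDeterministicU:
    def test_identity(self):
        Gw = mb.BlendedRelationship(("a", "b"), np.eye(2), 0.5)
        U = mb.deterministic_U_from_cholesky(Gw)
        np.testing.assert_array_equal(U.U, np.eye(2))

    def test_closed_form_2x2(self):
        Gw = mb.BlendedRelationship(("a", "b"), np.array([[1, 0.5], [0.5, 1]]), 0.5)
        U = mb.deterministic_U_from_cholesky(Gw)
        np.testing.assert_allclose(U.U, [[1, 0], [0.5, np.sqrt(0.75)]])

    def test_not_pd_error(self):
        Gw = mb.BlendedRelationship(("a", "b"), np.array([[1.0, 2.0], [2.0, 1.0]]), 0.5)
        with pytest.raises(np.linalg.LinAlgError):
            mb.deterministic_U_from_cholesky(Gw)

    def test_oracle_reproduces_gblup(self, small_ds):
        """Exact-covariance substitution makes the full-MC model GBLUP itself."""
        params = small_ds.params
        Gw = small_ds.blended()
        exact = mb.gblup_reliability(Gw, small_ds.phenotypes, params)
        U = mb.deterministic_U_from_cholesky(Gw)
        mme = mb.build_full_mc_mme(U, small_ds.phenotypes, params)
        block = mb.solve_pev_block(mme)
        sigma = mb.animal_variance(U=U, mode="mc")
        res = mb.full_mc_reliability(U, block, sigma, params)
        assert np.abs(res.r2 - exact.r2).max() <= 1e-8


class TestMMEAssembly:
    def test_zero_U(self):
        pheno = mb.PhenotypeData(("a", "b", "c"), np.zeros(3))
        U = mb.MCSampleMatrix(("a", "b", "c"), np.zeros((3, 2)), 2, 0, 0.5)
        mme = mb.build_full_mc_mme(U, pheno, mb.ModelParams.from_lambda(2.0, 0.5))
        expected = np.diag([3.0, 2.0, 2.0])
        np.testing.assert_allclose(mme.C, expected)

    def test_hand_assembly_two_records(self):
        # weights (2,1), U = [[1],[1]] -> C = [[3,3],[3,3+lam]]
        pheno = mb.PhenotypeData(("a", "b"), np.array([1.0, 0.0]), np.array([2.0, 1.0]))
        U = mb.MCSampleMatrix(("a", "b"), np.ones((2, 1)), 1, 0, 0.5)
        lam = 0.7
        mme = mb.build_full_mc_mme(U, pheno, mb.ModelParams.from_lambda(lam, 0.5))
        np.testing.assert_allclose(mme.C, [[3, 3], [3, 3 + lam]])

    def test_symmetry_random(self, small_ds):
        U = mb.sample_U(small_ds.Zc, small_ds.L, 0.5, 20, seed=1)
        mme = mb.build_full_mc_mme(U, small_ds.phenotypes, small_ds.params)
        np.testing.assert_allclose(mme.C, mme.C.T)

    @pytest.mark.parametrize("n_mc", [1, 7, 64])
    def test_order_is_one_plus_n_mc(self, small_ds, n_mc):
        """MME size depends only on the MC sample count, not on n or m."""
        U = mb.sample_U(small_ds.Zc, small_ds.L, 0.5, n_mc, seed=1)
        mme = mb.build_full_mc_mme(U, small_ds.phenotypes, small_ds.params)
        assert mme.order == 1 + n_mc


class TestPevBlock:
    def test_block_diagonal_case(self):
        lam = 2.5
        C = np.diag([4.0, lam, lam, lam])
        mme = mb.MMESystem(C, None, lam)
        blk = mb.solve_pev_block(mme)
        np.testing.assert_allclose(blk.C_uss, np.eye(3) / lam)

    def test_two_by_two_closed_form(self):
        lam = 0.9
        C = np.array([[1.0, 1.0], [1.0, 1.0 + lam]])
        blk = mb.solve_pev_block(mb.MMESystem(C, None, lam))
        np.testing.assert_allclose(blk.C_uss, [[1.0 / lam]])

    def test_symmetric_psd(self, small_ds):
        U = mb.sample_U(small_ds.Zc, small_ds.L, 0.5, 30, seed=4)
        mme = mb.build_full_mc_mme(U, small_ds.phenotypes, small_ds.params)
        blk = mb.solve_pev_block(mme)
        np.testing.assert_allclose(blk.C_uss, blk.C_uss.T, atol=1e-12)
        assert np.linalg.eigvalsh(blk.C_uss).min() > 0


class TestAnimalVariance:
    def test_mc_identity(self):
        U = mb.MCSampleMatrix(("a", "b"), np.eye(2), 2, None, 0.5)
        np.testing.assert_allclose(mb.animal_variance(U=U, mode="mc"), [1.0, 1.0])

    def test_exact_pure_rpg_non_inbred(self, small_ds):
        F = mb.InbreedingVector(small_ds.Zc.ids, np.zeros(len(small_ds.Zc.ids)))
        sigma = mb.animal_variance(Zc=small_ds.Zc, inbreeding=F, w=1.0, mode="exact")
        np.testing.assert_allclose(sigma, 1.0)

    def test_exact_equals_gw_diagonal(self, small_ds):
        """Default convention reproduces diag(Gw) exactly for every animal."""
        Fall = mb.inbreeding_coefficients(small_ds.pedigree)
        pos = {a: i for i, a in enumerate(Fall.ids)}
        F = mb.InbreedingVector(small_ds.Zc.ids,
                                Fall.F[[pos[a] for a in small_ds.Zc.ids]])
        for w in (0.2, 0.5, 0.8):
            sigma = mb.animal_variance(Zc=small_ds.Zc, inbreeding=F, w=w, mode="exact")
            np.testing.assert_allclose(sigma, np.diag(small_ds.blended(w).Gw),
                                       atol=1e-10)

    def test_paper_literal_convention(self, small_ds):
        F = mb.InbreedingVector(small_ds.Zc.ids,
                                np.full(len(small_ds.Zc.ids), 0.1))
        default = mb.animal_variance(Zc=small_ds.Zc, inbreeding=F, w=1.0, mode="exact")
        literal = mb.animal_variance(Zc=small_ds.Zc, inbreeding=F, w=1.0,
                                     mode="exact", convention="paper-literal")
        np.testing.assert_allclose(default - literal, 0.2)


class TestFullMcReliability:
    def test_strong_shrinkage_limit(self, small_ds):
        """lambda -> infinity: no genetic signal, all reliabilities -> 0."""
        params = mb.ModelParams.from_lambda(1e8, 0.5)
        U = mb.deterministic_U_from_cholesky(small_ds.blended())
        res = mb.full_mc_reliability_pipeline(U, small_ds.phenotypes, params,
                                              engine="direct")
        assert np.abs(res.r2).max() <= 1e-3

    def test_zero_sigma_error(self, small_ds):
        U = mb.sample_U(small_ds.Zc, small_ds.L, 0.5, 10, seed=0)
        with pytest.raises(ValueError, match="variance"):
            mb.animal_variance(U=mb.MCSampleMatrix(U.ids, np.zeros_like(U.U),
                                                   U.n_mc, 0, 0.5), mode="mc")

    @pytest.mark.parametrize("w", [0.2, 0.8])
    def test_reduced_engine_matches_direct(self, small_ds, w):
        """The n x n rank-reduced solver is algebraically identical to the
        direct order-(1+n_mc) route."""
        params = mb.ModelParams.from_heritability(0.3, w)
        U = mb.sample_U(small_ds.Zc, small_ds.L, w, 300, seed=9)
        direct = mb.full_mc_reliability_pipeline(U, small_ds.phenotypes, params,
                                                 engine="direct")
        reduced = mb.full_mc_reliability_pipeline(U, small_ds.phenotypes, params,
                                                  engine="reduced")
        np.testing.assert_allclose(reduced.pev, direct.pev, atol=1e-9)
        np.testing.assert_allclose(reduced.r2, direct.r2, atol=1e-9)

    def test_reduced_engine_heterogeneous_weights(self, small_ds):
        rng = np.random.default_rng(0)
        wts = rng.uniform(0.5, 5.0, size=len(small_ds.phenotypes.ids))
        pheno = mb.PhenotypeData(small_ds.phenotypes.ids, small_ds.phenotypes.y, wts)
        U = mb.sample_U(small_ds.Zc, small_ds.L, 0.5, 200, seed=9)
        direct = mb.full_mc_reliability_pipeline(U, pheno, small_ds.params,
                                                 engine="direct")
        reduced = mb.full_mc_reliability_pipeline(U, pheno, small_ds.params,
                                                  engine="reduced")
        np.testing.assert_allclose(reduced.pev, direct.pev, atol=1e-9)

    def test_seed_determinism_end_to_end(self, small_ds):
        runs = []
        for _ in range(2):
            U = mb.sample_U(small_ds.Zc, small_ds.L, 0.5, 40, seed=77)
            runs.append(mb.full_mc_reliability_pipeline(U, small_ds.phenotypes,
                                                        small_ds.params))
        np.testing.assert_array_equal(runs[0].r2, runs[1].r2)

    def test_mse_decreases_with_n_mc(self, small_ds):
        """More MC samples bring the approximation closer to exact GBLUP."""
        exact = mb.gblup_reliability(small_ds.blended(), small_ds.phenotypes,
                                     small_ds.params)
        mses = []
        for n_mc in (200, 2000, 20000):
            vals = []
            for seed in range(3):
                U = mb.sample_U(small_ds.Zc, small_ds.L, 0.5, n_mc, seed=seed)
                ap = mb.full_mc_reliability_pipeline(U, small_ds.phenotypes,
                                                     small_ds.params)
                vals.append(np.mean((ap.r2 - exact.r2) ** 2))
            mses.append(np.mean(vals))
        assert mses[0] > mses[1] > mses[2]


class TestInflationMechanism:
    def test_slope_above_one_with_information_spread(self, small_ds):
        """With heterogeneous record weights (a realistic reliability range),
        the MC approximation is inflated: the exact-on-approx slope exceeds 1
        at a small MC sample count and moves toward 1 as n_mc grows."""
        from scipy.stats import linregress

        rng = np.random.default_rng(5)
        n = len(small_ds.phenotypes.ids)
        wts = np.exp(rng.uniform(np.log(0.2), np.log(50.0), size=n))
        pheno = mb.PhenotypeData(small_ds.phenotypes.ids, small_ds.phenotypes.y, wts)
        exact = mb.gblup_reliability(small_ds.blended(), pheno, small_ds.params)
        slopes = []
        for n_mc in (2000, 20000):
            per_seed = []
            for seed in (101, 102, 103):
                U = mb.sample_U(small_ds.Zc, small_ds.L, 0.5, n_mc, seed=seed)
                ap = mb.full_mc_reliability_pipeline(U, pheno, small_ds.params)
                per_seed.append(linregress(ap.r2, exact.r2).slope)
            slopes.append(np.mean(per_seed))
        assert slopes[0] > 1.0
        assert abs(slopes[1] - 1.0) < abs(slopes[0] - 1.0)
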