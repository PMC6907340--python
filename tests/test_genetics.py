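"""Sampling and inheritance rules of the bivariate maternal/direct model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from apiselect import genetics as gen
from apiselect.genetics import VarianceComponents

ZERO_VC = VarianceComponents(0.0, 0.0, 0.0, 0.0)


class TestVarianceComponents:
    def test_study_variances_imply_the_stated_correlations(self):
        assert VarianceComponents(1, 2, -0.75, 1).r_md == pytest.approx(-0.5303, abs=1e-4)
        assert VarianceComponents(1, 2, -1.25, 1).r_md == pytest.approx(-0.8839, abs=1e-4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sigma_Amd=-1.5),  # |cov| > sqrt(1*2): not PSD
            dict(sigma2_E=-0.1),
            dict(sigma2_Am=-1.0),
        ],
    )
    def test_invalid_components_are_rejected(self, kwargs):
        base = dict(sigma2_Am=1.0, sigma2_Ad=2.0, sigma_Amd=-0.75, sigma2_E=1.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            VarianceComponents(**base)

    @given(
        am=st.floats(0.0, 4.0),
        ad=st.floats(0.0, 4.0),
        rho=st.floats(-1.0, 1.0),
    )
    def test_chol_factor_reproduces_sigma(self, am, ad, rho):
        cov = rho * np.sqrt(am * ad)
        vc = VarianceComponents(am, ad, cov, 1.0)
        b = vc.chol
        assert np.allclose(b @ b.T, vc.sigma_A, atol=1e-10)


class TestBaseSampling:
    def test_degenerate_variance_yields_zeros(self, rng):
        out = gen.sample_base_queens(3, ZERO_VC, rng)
        assert out.shape == (3, 2)
        assert np.all(out == 0)

    def test_moderate_covariance_gives_minus_053_correlation(self, rng):
        vc = VarianceComponents(1, 2, -0.75, 1)
        bv = gen.sample_base_queens(100_000, vc, rng)
        r = np.corrcoef(bv.T)[0, 1]
        se = (1 - vc.r_md**2) / np.sqrt(len(bv))
        assert abs(r - (-0.5303)) < 3 * se

    def test_strong_covariance_matches_sigma_elementwise(self, rng):
        vc = VarianceComponents(1, 2, -1.25, 1)
        bv = gen.sample_base_queens(100_000, vc, rng)
        emp = np.cov(bv.T)
        # SE of a covariance estimate: sqrt((s_ii s_jj + s_ij^2)/n)
        s = vc.sigma_A
        for i in range(2):
            for j in range(2):
                se = np.sqrt((s[i, i] * s[j, j] + s[i, j] ** 2) / len(bv))
                assert abs(emp[i, j] - s[i, j]) < 3 * se


class TestInheritance:
    def test_drone_equals_dam_when_variance_or_mendelian_term_vanishes(self, rng, vc):
        assert np.allclose(gen.make_drone_tbv(np.array([0.0, 0.0]), 0.0, ZERO_VC, rng), 0.0)
        # fully inbred dam: sqrt(1-F) = 0 kills the Mendelian term exactly
        d = gen.make_drone_tbv(np.array([1.5, -0.5]), 1.0, vc, rng)
        assert np.allclose(d, [1.5, -0.5])

    def test_drone_variance_is_twice_sigma(self, rng, vc):
        queens = gen.sample_base_queens(100_000, vc, rng)
        drones = gen.make_drone_tbv(queens, np.zeros(len(queens)), vc, rng)
        emp = np.cov(drones.T)
        s = 2 * vc.sigma_A
        for i in range(2):
            for j in range(2):
                se = np.sqrt((s[i, i] * s[j, j] + s[i, j] ** 2) / len(queens))
                assert abs(emp[i, j] - s[i, j]) < 3 * se

    def test_offspring_midparent_trivials(self, rng, vc):
        r = gen.make_queen_offspring_tbv(np.array([2.0, 0.0]), np.array([0.0, 2.0]), 0.0, ZERO_VC, rng)
        assert np.allclose(r, [1.0, 1.0])
        r = gen.make_queen_offspring_tbv(np.array([1.0, 1.0]), np.array([3.0, -1.0]), 1.0, vc, rng)
        assert np.allclose(r, [2.0, 0.0])

    def test_inbreeding_out_of_range_raises(self, rng, vc):
        with pytest.raises(ValueError):
            gen.make_drone_tbv(np.array([0.0, 0.0]), 1.2, vc, rng)
        with pytest.raises(ValueError):
            gen.make_queen_offspring_tbv(np.array([0.0, 0.0]), np.array([0.0, 0.0]), -0.1, vc, rng)

    def test_mendelian_variance_shrinks_linearly_with_inbreeding(self, rng, vc):
        """Var(offspring - midparent) = (1 - F) Sigma_A / 4, checked by regression."""
        n = 40_000
        fs = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        slopes = []
        for f in fs:
            q = gen.sample_base_queens(n, vc, rng)
            d = gen.sample_base_queens(n, vc, rng)
            off = gen.make_queen_offspring_tbv(q, d, np.full(n, f), vc, rng)
            dev = off - 0.5 * (q + d)
            slopes.append(np.var(dev.sum(axis=1)))
        tot_var = vc.sigma_A.sum() / 4  # Var of (m+d) Mendelian deviation at F=0
        fit = np.polyfit(fs, slopes, 1)
        assert fit[0] == pytest.approx(-tot_var, rel=0.1)
        assert fit[1] == pytest.approx(tot_var, rel=0.05)

    def test_stationarity_over_ten_generations(self, rng, vc):
        """Unselected random mating keeps cohort covariance at Sigma_A."""
        n = 30_000
        queens = gen.sample_base_queens(n, vc, rng)
        for _ in range(10):
            dam_idx = rng.permutation(n)
            dd_idx = rng.permutation(n)
            drones = gen.make_drone_tbv(queens[dd_idx], np.zeros(n), vc, rng)
            queens = gen.make_queen_offspring_tbv(queens[dam_idx], drones, np.zeros(n), vc, rng)
        emp = np.cov(queens.T)
        s = vc.sigma_A
        for i in range(2):
            for j in range(2):
                se = np.sqrt((s[i, i] * s[j, j] + s[i, j] ** 2) / n)
                # allow extra slack: generations are not fully independent samples
                assert abs(emp[i, j] - s[i, j]) < 5 * se


class TestWorkerGroupAndPhenotype:
    @pytest.mark.parametrize(
        "queen, drones, expected",
        [
            ([0, 0], [[0, 0]] * 12, [0, 0]),
            ([2, 2], [[0, 0]] * 12, [1, 1]),
            ([1, -1], [[2, 0]] * 6 + [[0, 2]] * 6, [1, 0]),
        ],
    )
    def test_worker_group_is_mean_of_queen_and_mates(self, queen, drones, expected):
        assert np.allclose(gen.worker_group_tbv(np.array(queen, float), np.array(drones, float)), expected)

    def test_empty_drone_list_is_rejected(self):
        with pytest.raises(ValueError):
            gen.worker_group_tbv(np.zeros(2), np.zeros((0, 2)))

    @pytest.mark.parametrize("bv, total", [([0, 0], 0.0), ([1.2, -0.4], 0.8), ([-1, 1], 0.0)])
    def test_total_breeding_value(self, bv, total):
        assert gen.total_breeding_value(np.array(bv, float)) == pytest.approx(total)

    def test_phenotype_is_direct_plus_maternal_plus_noise(self, rng, vc):
        noiseless = VarianceComponents(vc.sigma2_Am, vc.sigma2_Ad, vc.sigma_Amd, 0.0)
        y = gen.colony_phenotype(np.array([0.5, 1.0]), np.array([0.2, 0.9]), noiseless, rng)
        assert y == pytest.approx(1.2)

        n = 100_000
        w = gen.sample_base_queens(n, vc, rng)
        q = gen.sample_base_queens(n, vc, rng)
        y = gen.colony_phenotype(w, q, vc, rng)
        resid = y - (w[:, 1] + q[:, 0])
        assert abs(resid.mean()) < 3 * np.sqrt(1.0 / n)
        assert np.var(resid) == pytest.approx(1.0, abs=3 * np.sqrt(2.0 / n))

    def test_base_population_phenotypes_average_zero(self, rng, vc):
        n = 100_000
        q = gen.sample_base_queens(n, vc, rng)
        drones = gen.make_drone_tbv(gen.sample_base_queens(n, vc, rng), np.zeros(n), vc, rng)
        w = gen.worker_group_tbv(q, drones[:, None, :])
        y = gen.colony_phenotype(w, q, vc, rng)
        se = y.std() / np.sqrt(n)
        assert abs(y.mean()) < 3 * se


class TestFiniteLocus:
    def test_zero_variance_gives_zero_effects(self, rng):
        model = gen.init_locus_model(ZERO_VC, 400, rng)
        assert np.all(model.effects == 0)

    def test_base_covariance_matches_sigma(self, rng, vc):
        model = gen.init_locus_model(vc, 400, rng)
        assert np.allclose(model.base_covariance(), vc.sigma_A, rtol=1e-8)
        # and empirically over sampled base queens, within 5%
        n = 10_000
        mat = (rng.random((n, 400)) < 0.5).astype(np.uint8)
        pat = (rng.random((n, 400)) < 0.5).astype(np.uint8)
        tbv = gen.haplotypes_tbv(mat, pat, model)
        emp = np.cov(tbv.T)
        assert np.allclose(emp, vc.sigma_A, atol=0.05 * np.abs(vc.sigma_A).max() + 0.03)

    def test_single_locus_closed_form(self):
        effect = np.array([[0.7, -0.3]])
        model = gen.LocusModel(effects=effect, init_freq=np.array([0.3]))
        expected = 2 * 0.3 * 0.7 * np.outer(effect[0], effect[0])
        assert np.allclose(model.base_covariance(), expected)

    def test_gamete_sampling_frequencies_and_drone_rule(self, rng):
        g = gen.Genotype(
            maternal_haplotype=np.ones(50, dtype=np.uint8),
            paternal_haplotype=np.zeros(50, dtype=np.uint8),
        )
        n = 500
        freq = np.mean([gen.sample_gamete(g, rng) for _ in range(n)], axis=0)
        # 50 loci tested jointly: use a Bonferroni-wide 4.5 SE band
        assert np.all(np.abs(freq - 0.5) < 4.5 * 0.5 / np.sqrt(n))
        drone = gen.Genotype(maternal_haplotype=np.ones(50, dtype=np.uint8))
        with pytest.raises(ValueError):
            gen.sample_gamete(drone, rng)

    def test_homozygous_queen_and_her_drone_have_equal_tbv(self, rng, vc):
        model = gen.init_locus_model(vc, 100, rng)
        hap = (rng.random(100) < 0.5).astype(np.uint8)
        queen = gen.Genotype(maternal_haplotype=hap, paternal_haplotype=hap.copy())
        drone = gen.Genotype(maternal_haplotype=hap.copy())
        assert np.allclose(gen.genotype_tbv(queen, model), gen.genotype_tbv(drone, model))

    def test_locus_count_mismatch_raises(self, rng, vc):
        model = gen.init_locus_model(vc, 100, rng)
        bad = gen.Genotype(maternal_haplotype=np.zeros(99, dtype=np.uint8))
        with pytest.raises(ValueError):
            gen.genotype_tbv(bad, model)

    def test_one_generation_selection_response_matches_infinitesimal(self, rng, vc):
        """Mass selection response agrees between the two genetic models."""
        n, top = 6000, 1200

        def respond_inf():
            q = gen.sample_base_queens(n, vc, rng)
            y = q.sum(axis=1) + rng.standard_normal(n)
            sel = np.argsort(-y)[:top]
            d = gen.make_drone_tbv(gen.sample_base_queens(top, vc, rng), np.zeros(top), vc, rng)
            off = gen.make_queen_offspring_tbv(q[sel], d, np.zeros(top), vc, rng)
            return off.sum(axis=1).mean()

        def respond_fin():
            model = gen.init_locus_model(vc, 400, rng)
            mat = (rng.random((n, 400)) < 0.5).astype(np.uint8)
            pat = (rng.random((n, 400)) < 0.5).astype(np.uint8)
            q = gen.haplotypes_tbv(mat, pat, model)
            y = q.sum(axis=1) + rng.standard_normal(n)
            sel = np.argsort(-y)[:top]
            sire_hap = (rng.random((top, 400)) < 0.5).astype(np.uint8)
            off_mat = gen.sample_gametes(mat[sel], pat[sel], rng)
            off = gen.haplotypes_tbv(off_mat, sire_hap, model)
            return off.sum(axis=1).mean()

        r_inf = np.mean([respond_inf() for _ in range(3)])
        r_fin = np.mean([respond_fin() for _ in range(3)])
        # ~ i * h-ish * sigma / 2; both estimates carry Monte-Carlo noise
        assert r_inf > 0.2 and r_fin > 0.2
        assert r_inf == pytest.approx(r_fin, abs=0.12)
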