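"""QTL architecture: effects, omega coupling, TBV and phenotypes."""

import numpy as np
import pytest

from qtlbench.founder_genome import GenomeLayout, hide_even_snps
from qtlbench.traits import (QTLSet, TraitConfig, assign_and_tune_omega,
                             compute_tbv, genetic_correlations,
                             sample_qtl_positions,
                             sample_standardized_effects,
                             simulate_phenotypes, trait_effects)

CFG = TraitConfig()


@pytest.fixture(scope="module")
def tuned_arch():
    """Full-size architecture on LD-free synthetic dosages (HWE binomials)."""
    rng = np.random.default_rng(21)
    p = np.clip(rng.normal(0.5, 0.15, CFG.n_qtl), 0.05, 0.95)
    dosages = rng.binomial(2, p, size=(3000, CFG.n_qtl)).astype(float)
    p_hat = dosages.mean(axis=0) / 2
    alpha = sample_standardized_effects(p_hat, CFG, rng)
    omega, labels = assign_and_tune_omega(alpha, dosages, CFG, rng)
    alpha_t = trait_effects(alpha, omega, CFG)
    qtlset = QTLSet(positions=np.arange(CFG.n_qtl),
                    chromosome=np.ones(CFG.n_qtl, dtype=int),
                    pos_mb=np.linspace(1, 99, CFG.n_qtl),
                    alpha_sdu=alpha, omega=omega, omega_class=labels,
                    alpha_t=alpha_t, p=p_hat, config=CFG)
    return qtlset, dosages


class TestQtlPositions:
    def test_drawn_from_hidden_set(self, rng):
        rel = hide_even_snps(GenomeLayout())
        pos = sample_qtl_positions(rel.hidden_indices, 50, rng)
        assert pos.size == 50 and np.unique(pos).size == 50
        assert np.all(np.isin(pos, rel.hidden_indices))
        assert not np.any(np.isin(pos, rel.released_indices))

    def test_empty_and_insufficient(self, rng):
        assert sample_qtl_positions(np.arange(10), 0, rng).size == 0
        with pytest.raises(ValueError):
            sample_qtl_positions(np.arange(10), 11, rng)

    def test_uniform_across_chromosomes(self):
        rel = hide_even_snps(GenomeLayout())
        layout = GenomeLayout()
        rng = np.random.default_rng(8)
        counts = np.zeros(5)
        n_rep = 400
        for _ in range(n_rep):
            pos = sample_qtl_positions(rel.hidden_indices, 50, rng)
            counts += np.bincount(layout.chrom_of_snp[pos] - 1, minlength=5)
        per_chrom = counts / n_rep
        assert np.allclose(per_chrom, 10.0, atol=0.5)


class TestStandardizedEffects:
    def test_hwe_variance_is_one(self, rng):
        p = rng.uniform(0.1, 0.9, 50)
        a = sample_standardized_effects(p, CFG, rng)
        assert np.sum(2 * p * (1 - p) * a ** 2) == pytest.approx(1.0, abs=1e-12)

    def test_gamma_shape_and_signs(self):
        # the common rescaling removes the gamma scale parameter, but the
        # shape survives in scale-free moments: CV of gamma(k) is 1/sqrt(k)
        rng = np.random.default_rng(9)
        p = np.full(100_000, 0.5)
        a = sample_standardized_effects(p, CFG, rng)
        cv = np.abs(a).std() / np.abs(a).mean()
        assert cv == pytest.approx(1.0 / np.sqrt(CFG.gamma_shape), rel=0.02)
        assert abs((a > 0).mean() - 0.5) < 0.01

    def test_raw_gamma_mean(self):
        # mean of the unstandardized magnitudes = shape * scale = 2.268
        rng = np.random.default_rng(10)
        raw = rng.gamma(CFG.gamma_shape, CFG.gamma_scale, 100_000)
        a = sample_standardized_effects(np.full(100_000, 0.5), CFG,
                                        np.random.default_rng(10))
        # same substream: the standardized vector is proportional to the draws
        ratio = np.abs(a) / raw
        assert np.allclose(ratio, ratio[0])
        assert raw.mean() == pytest.approx(CFG.gamma_shape * CFG.gamma_scale,
                                           rel=0.02)


class TestTraitEffects:
    def test_omega_one_silences_ratio_trait(self, rng):
        a = rng.normal(size=20) * 0.1
        at = trait_effects(a, np.ones(20), CFG)
        assert np.all(at[:, 2] == 0.0)
        assert np.allclose(at[:, 1], at[:, 0] * CFG.mu_t2 / CFG.mu_t1)

    def test_omega_zero_t1_only(self):
        at = trait_effects(np.array([0.1]), np.array([0.0]), CFG)
        assert at[0, 1] == 0.0
        # a positive T1 effect dilutes fat content
        assert at[0, 2] == pytest.approx(12 / 210 - 0.06)
        assert at[0, 2] < 0

    def test_worked_example(self):
        # alpha_T1 = 10 kg, omega = 2
        at = trait_effects(np.array([0.1]), np.array([2.0]), CFG)
        assert at[0, 0] == pytest.approx(10.0)
        assert at[0, 1] == pytest.approx(1.2)
        assert at[0, 2] == pytest.approx(13.2 / 210 - 0.06)

    def test_nonpositive_trait_mean_rejected(self):
        with pytest.raises(ValueError):
            trait_effects(np.array([-2.1]), np.array([1.0]), CFG)

    def test_covariance_sign_rules(self, rng):
        """omega>1: T3 covaries + with T1 and T2; 0<omega<1: - with both;
        omega<0: - with T1, + with T2 (and T1-T2 coupling follows omega's
        sign)."""
        a = rng.normal(size=200)
        a = np.where(np.abs(a) < 0.05, 0.1, a) * 0.01
        for omega, s12, s13, s23 in [
            (2.0, +1, +1, +1), (0.5, +1, -1, -1), (-1.0, -1, -1, +1),
        ]:
            at = trait_effects(a, np.full(a.size, omega), CFG)
            assert np.all(np.sign(at[:, 0] * at[:, 1]) == s12)
            assert np.all(np.sign(at[:, 0] * at[:, 2]) == s13)
            assert np.all(np.sign(at[:, 1] * at[:, 2]) == s23)


class TestOmegaTuning:
    def test_class_counts_and_pleiotropy_census(self, tuned_arch):
        qtlset, _ = tuned_arch
        omega = qtlset.omega
        assert (omega == -1).sum() == 4
        assert (omega == 0).sum() == 4
        assert ((omega > 0) & (omega < 1)).sum() == 7
        assert (omega == 1).sum() == 31
        assert ((omega > 1) & (omega <= 4)).sum() == 4
        # every QTL hits T1; omega != 0 hits T2; omega != 1 hits T3
        assert (qtlset.alpha_t[:, 0] != 0).sum() == 50
        assert (qtlset.alpha_t[:, 1] != 0).sum() == 46
        assert (qtlset.alpha_t[:, 2] != 0).sum() == 19

    def test_realized_correlations_near_target(self, tuned_arch):
        qtlset, dosages = tuned_arch
        rg = genetic_correlations(dosages @ qtlset.alpha_t)
        assert np.all(np.abs(rg - np.array(CFG.target_rg)) <= CFG.rg_tol + 1e-9)

    def test_variance_shares_self_normalize(self, tuned_arch):
        qtlset, _ = tuned_arch
        for t in range(3):
            assert qtlset.var_contrib(t).sum() / qtlset.sigma2_g(t) == \
                pytest.approx(1.0)


class TestTBV:
    def test_linearity_and_centering(self):
        alpha_t = trait_effects(np.array([0.1]), np.array([2.0]), CFG)
        dosages = np.array([[0.0], [1.0], [2.0]])
        tbv = compute_tbv(dosages, alpha_t)
        # doubling the dosage doubles the (uncentered) effect
        assert np.allclose(tbv[2] - tbv[0], 2 * alpha_t[0])
        assert np.allclose(tbv.mean(axis=0), 0.0)

    def test_null_genome_is_centering_constant(self):
        alpha_t = trait_effects(np.array([0.1]), np.array([1.0]), CFG)
        tbv = compute_tbv(np.zeros((5, 1)), alpha_t)
        assert np.allclose(tbv, 0.0)


class TestPhenotypes:
    def test_heritability_one_gives_yd_equal_tbv(self, tuned_arch):
        qtlset, dosages = tuned_arch
        tbv = compute_tbv(dosages, qtlset.alpha_t)
        cfg1 = TraitConfig(h2=(1.0, 1.0, 1.0))
        phen = simulate_phenotypes(tbv, cfg1, np.random.default_rng(0))
        assert np.allclose(phen["yd"], tbv)

    def test_realized_heritabilities(self, tuned_arch):
        qtlset, dosages = tuned_arch
        tbv = compute_tbv(dosages, qtlset.alpha_t)
        phen = simulate_phenotypes(tbv, CFG, np.random.default_rng(1))
        h2 = tbv.var(axis=0) / phen["yd"].var(axis=0)
        assert np.all(np.abs(h2 - np.array(CFG.h2)) < 0.05)

    def test_residual_correlations_match_genetic(self, tuned_arch):
        qtlset, dosages = tuned_arch
        tbv = compute_tbv(dosages, qtlset.alpha_t)
        phen = simulate_phenotypes(tbv, CFG, np.random.default_rng(2))
        re_corr = np.corrcoef(phen["residual"], rowvar=False)
        g_corr = np.corrcoef(tbv, rowvar=False)
        assert abs(re_corr[0, 1] - g_corr[0, 1]) < 0.04
        assert abs(re_corr[0, 2] - g_corr[0, 2]) < 0.04
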