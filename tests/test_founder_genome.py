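"""Founder-genome construction: priors, LD sampling, conditional alleles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtlbench.founder_genome import (FREQ_CLAMP, GameteMatrix, GenomeLayout,
                                     LDProfile, build_founder_gametes,
                                     conditional_allele_prob, hide_even_snps,
                                     sample_prior_freqs, sample_signed_ld,
                                     target_r)


def two_locus_conditional(f_a: float, f_b: float, r: float, b_allele: int) -> float:
    """Oracle: P(allele 1 at locus A | observed allele at locus B).

    Enumerates the 2x2 haplotype table implied by the marginals and the r
    statistic, f(AB) = f_A f_B + r sqrt(f_A(1-f_A) f_B(1-f_B)), and
    conditions on the observed B allele.  Only valid when all four haplotype
    frequencies are non-negative.
    """
    d = r * np.sqrt(f_a * (1 - f_a) * f_b * (1 - f_b))
    f11 = f_a * f_b + d
    f12 = f_a * (1 - f_b) - d
    f21 = (1 - f_a) * f_b - d
    f22 = (1 - f_a) * (1 - f_b) + d
    assert min(f11, f12, f21, f22) >= 0
    if b_allele == 1:
        return f11 / (f11 + f21)
    return f12 / (f12 + f22)


class TestPriorFreqs:
    def test_distribution_moments(self):
        layout = GenomeLayout(n_chromosomes=1, snps_per_chrom=100_000)
        f = sample_prior_freqs(layout, np.random.default_rng(1))
        assert abs(f.mean() - 0.5) < 0.005
        assert abs(f.std() - 0.1) < 0.01
        assert f.min() >= FREQ_CLAMP[0] and f.max() <= FREQ_CLAMP[1]

    def test_degenerate_sd_gives_half(self):
        layout = GenomeLayout(n_chromosomes=1, snps_per_chrom=10)
        f = sample_prior_freqs(layout, np.random.default_rng(0), sd=0.0)
        assert np.all(f == 0.5)

    def test_out_of_range_draw_clamped(self):
        layout = GenomeLayout(n_chromosomes=1, snps_per_chrom=1000)
        f = sample_prior_freqs(layout, np.random.default_rng(2), mean=1.07, sd=0.0)
        assert np.all(f == FREQ_CLAMP[1])


class TestTargetR:
    @pytest.mark.parametrize("d, expected", [
        (1.0, 0.0), (2.5, 0.0), (0.5, 0.5), (0.025, 0.975),
    ])
    def test_linear_profile(self, d, expected):
        assert target_r(d, LDProfile()) == pytest.approx(expected)

    def test_short_distance_near_one(self):
        assert target_r(0.025, LDProfile()) > 0.9

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            target_r(-0.1, LDProfile())

    def test_profiles_monotone_and_bounded(self):
        d = np.linspace(0.0, 2.0, 200)
        for kind in ("linear", "exponential"):
            v = target_r(d, LDProfile(kind=kind))
            assert np.all(np.diff(v) <= 1e-12)
            assert v.min() >= 0 and v.max() <= 1
            assert np.all(v[d >= 1.0] == 0)


class TestSampleSignedLD:
    def test_sign_proportion(self):
        prof = LDProfile()
        r = sample_signed_ld(np.full(100_000, 0.5), prof, np.random.default_rng(3))
        assert abs((r > 0).mean() - 0.5) < 0.005

    def test_degenerate_exact(self):
        prof = LDProfile(sigma_r=0.0, sign_prob=1.0)
        r = sample_signed_ld(np.array([0.3]), prof, np.random.default_rng(0))
        assert r[0] == pytest.approx(0.3)

    def test_magnitude_clamped_to_one(self):
        prof = LDProfile(sigma_r=0.0, sign_prob=1.0)
        r = sample_signed_ld(np.array([1.5]), prof, np.random.default_rng(0))
        assert r[0] == 1.0


class TestConditionalAlleleProb:
    def test_zero_ld_returns_prior(self, rng):
        h = rng.integers(0, 2, size=(30, 5))
        p = conditional_allele_prob(0.37, h, np.full(5, 0.4), np.zeros(5))
        assert np.allclose(p, 0.37)

    def test_full_coupling_equal_freqs(self):
        # r = 1 at equal frequencies: only coupling haplotypes exist
        p = conditional_allele_prob(0.5, np.array([1]), np.array([0.5]),
                                    np.array([1.0]))
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("f_a", [0.2, 0.5, 0.8])
    @pytest.mark.parametrize("f_b", [0.3, 0.5, 0.6])
    @pytest.mark.parametrize("r", [-0.5, -0.2, 0.0, 0.3, 0.6])
    @pytest.mark.parametrize("b_allele", [0, 1])
    def test_matches_two_locus_oracle(self, f_a, f_b, r, b_allele):
        d = r * np.sqrt(f_a * (1 - f_a) * f_b * (1 - f_b))
        table = [f_a * f_b + d, f_a * (1 - f_b) - d,
                 (1 - f_a) * f_b - d, (1 - f_a) * (1 - f_b) + d]
        if min(table) < 0:
            pytest.skip("r incompatible with marginals")
        expected = two_locus_conditional(f_a, f_b, r, b_allele)
        got = conditional_allele_prob(f_a, np.array([b_allele]),
                                      np.array([f_b]), np.array([r]))
        # the implementation floors vanishing factors at 1e-6, so a table
        # with an exactly-zero haplotype class can differ at that order
        assert got == pytest.approx(expected, abs=1e-5)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(f1=st.floats(0.05, 0.95), f_l=st.floats(0.05, 0.95),
           r=st.floats(-1.0, 1.0), h=st.integers(0, 1))
    def test_normalized_and_complementary(self, f1, f_l, r, h):
        """P(allele1) is a probability; relabeling allele 1<->2 at the new
        SNP (which flips the prior and the sign of r) gives 1 - P."""
        p1 = conditional_allele_prob(f1, np.array([h]), np.array([f_l]),
                                     np.array([r]))
        p2 = conditional_allele_prob(1 - f1, np.array([h]), np.array([f_l]),
                                     np.array([-r]))
        assert 0.0 <= p1 <= 1.0
        assert p1 + p2 == pytest.approx(1.0, abs=1e-9)

    def test_empty_window_returns_prior(self):
        p = conditional_allele_prob(0.42, np.empty((4, 0), dtype=int),
                                    np.empty(0), np.empty(0))
        assert np.allclose(p, 0.42)


class TestBuildFounderGametes:
    @pytest.fixture(scope="class")
    def small_build(self):
        layout = GenomeLayout(n_chromosomes=1, chrom_length_mb=10.0,
                              snps_per_chrom=400)
        gm = build_founder_gametes(layout, LDProfile(),
                                   np.random.default_rng(5), n_gametes=200)
        return layout, gm

    def test_shapes_and_binary(self, small_build):
        layout, gm = small_build
        assert gm.alleles.shape == (200, 400)
        assert set(np.unique(gm.alleles)) <= {0, 1}
        assert np.allclose(gm.realized_freqs, gm.alleles.mean(axis=0))

    def test_mean_maf_realistic(self, small_build):
        _, gm = small_build
        maf = np.minimum(gm.realized_freqs, 1 - gm.realized_freqs)
        assert 0.2 <= maf.mean() <= 0.35

    def test_ld_decays_monotonically_to_floor(self, small_build):
        layout, gm = small_build
        a = gm.alleles.astype(float)
        pos = layout.pos_mb
        keep = a.std(axis=0) > 0
        c = np.corrcoef(a[:, keep], rowvar=False) ** 2
        d = np.abs(pos[keep][:, None] - pos[keep][None, :])
        iu = np.triu_indices_from(c, k=1)
        r2, dist = c[iu], d[iu]
        edges = [(0.0, 0.1), (0.1, 0.5), (0.5, 1.0), (1.0, np.inf)]
        means = [r2[(dist > lo) & (dist <= hi)].mean() for lo, hi in edges]
        assert np.all(np.diff(means) <= 0)
        # beyond the LD cutoff: indistinguishable from the independence floor
        assert means[-1] < 3.0 / gm.n_gametes

    def test_zero_profile_independent(self):
        layout = GenomeLayout(n_chromosomes=1, chrom_length_mb=10.0,
                              snps_per_chrom=400)
        gm = build_founder_gametes(layout, LDProfile(kind="zero"),
                                   np.random.default_rng(6), n_gametes=200)
        a = gm.alleles.astype(float)
        keep = a.std(axis=0) > 0
        c = np.corrcoef(a[:, keep], rowvar=False) ** 2
        iu = np.triu_indices_from(c, k=1)
        assert c[iu].mean() < 3.0 / gm.n_gametes


class TestHideEvenSnps:
    def test_default_layout_counts(self):
        rel = hide_even_snps(GenomeLayout())
        assert rel.n_released == 10_000
        assert rel.hidden_indices.size == 10_000
        within = rel.pos_mb[rel.chromosome == 1]
        assert np.allclose(np.diff(within), 0.05)

    def test_single_chromosome_halving(self):
        rel = hide_even_snps(GenomeLayout(n_chromosomes=1))
        assert rel.n_released == 2000

    def test_partition_disjoint_and_complete(self):
        layout = GenomeLayout(n_chromosomes=2, snps_per_chrom=10)
        rel = hide_even_snps(layout)
        assert np.intersect1d(rel.released_indices, rel.hidden_indices).size == 0
        assert np.union1d(rel.released_indices, rel.hidden_indices).size == layout.n_snps

    def test_odd_snp_count_rejected(self):
        with pytest.raises(ValueError):
            GenomeLayout(n_chromosomes=1, snps_per_chrom=401)
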