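"""Construction of founder gametes under a target linkage-disequilibrium profile.

The founder genome is built SNP by SNP along each chromosome.  At each new
SNP a prior allele frequency is drawn, a vector of signed LD coefficients
(the ``r`` statistic) linking the new SNP to its upstream neighbours is
sampled around a distance-dependent target, and every founder gamete then
receives an allele with the conditional probability implied by the
two-locus haplotype frequencies.  This produces a population whose LD decays
with physical distance the way dense livestock SNP panels do, without a
coalescent or mutation-drift model.

Half of the constructed SNPs (the even-numbered ones, 1-based) are withheld
from the released marker map; QTLs are later placed on the withheld loci so
that causal variants are never directly genotyped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "LDProfile",
    "GameteMatrix",
    "ReleasedMap",
    "sample_prior_freqs",
    "target_r",
    "sample_signed_ld",
    "conditional_allele_prob",
    "build_founder_gametes",
    "hide_even_snps",
]

#: bounds used to keep allele frequencies strictly inside (0, 1) so that the
#: binomial standard-deviation terms sqrt(f(1-f)) stay defined.
FREQ_CLAMP = (0.01, 0.99)

#: floor applied to each per-locus conditional factor; negative factors arise
#: when a sampled r is incompatible with the allele frequencies (the implied
#: haplotype frequency would be negative).
FACTOR_EPS = 1e-6


@dataclass(frozen=True)
class GenomeLayout:
    """Marker layout of the constructed genome.

    Defaults give 5 chromosomes of 100 Mb carrying 4,000 equally spaced SNPs
    each (0.025 Mb apart); after hiding every second SNP the released map has
    10,000 SNPs at 0.05 Mb.
    """

    n_chromosomes: int = 5
    chrom_length_mb: float = 100.0
    snps_per_chrom: int = 4000
    ld_window: int = 40

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.snps_per_chrom < 2:
            raise ValueError("layout needs >=1 chromosome with >=2 SNPs")
        if self.snps_per_chrom % 2 != 0:
            raise ValueError("snps_per_chrom must be even (half are hidden)")

    @property
    def spacing_mb(self) -> float:
        """Distance between adjacent constructed SNPs in Mb."""
        return self.chrom_length_mb / self.snps_per_chrom

    @property
    def n_snps(self) -> int:
        """Total constructed SNP count over all chromosomes."""
        return self.n_chromosomes * self.snps_per_chrom

    @property
    def chrom_of_snp(self) -> np.ndarray:
        """Chromosome number (1-based) of each constructed SNP."""
        return np.repeat(np.arange(1, self.n_chromosomes + 1), self.snps_per_chrom)

    @property
    def pos_mb(self) -> np.ndarray:
        """Within-chromosome position in Mb of each constructed SNP.

        SNP ``j`` (1-based within its chromosome) sits at ``j * spacing``, so
        the default layout runs from 0.025 Mb to 100.0 Mb.
        """
        one = (np.arange(1, self.snps_per_chrom + 1)) * self.spacing_mb
        return np.tile(one, self.n_chromosomes)


@dataclass(frozen=True)
class LDProfile:
    """Target LD decay and the sampling noise around it.

    ``expected_abs_r`` maps an inter-SNP distance (Mb) to the expected
    absolute value of the r statistic.  The default is linear from 1 at zero
    distance to 0 at ``cutoff_mb``; LD beyond the cutoff is treated as
    negligible.  Sampled values scatter around the target with standard
    deviation ``sigma_r`` and carry a random sign.
    """

    kind: str = "linear"
    cutoff_mb: float = 1.0
    sigma_r: float = 0.1
    sign_prob: float = 0.5
    custom: Callable[[np.ndarray], np.ndarray] | None = None

    def expected_abs_r(self, distance_mb: np.ndarray | float) -> np.ndarray:
        d = np.asarray(distance_mb, dtype=float)
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        if self.kind == "linear":
            out = np.clip(1.0 - d / self.cutoff_mb, 0.0, 1.0)
        elif self.kind == "exponential":
            # half-life chosen so the profile is ~0 at the cutoff
            out = np.where(d >= self.cutoff_mb, 0.0, np.exp(-6.0 * d / self.cutoff_mb))
        elif self.kind == "zero":
            out = np.zeros_like(d)
        elif self.kind == "custom":
            if self.custom is None:
                raise ValueError("custom profile requires a callable")
            out = np.clip(np.asarray(self.custom(d), dtype=float), 0.0, 1.0)
        else:
            raise ValueError(f"unknown LD profile kind {self.kind!r}")
        return out


@dataclass
class GameteMatrix:
    """Binary founder haplotypes: one row per gamete, one column per SNP.

    ``alleles`` holds 1 where a gamete carries allele 1 and 0 for allele 2;
    ``prior_freqs`` are the f(1)' values the construction drew, and
    ``realized_freqs`` the frequency of allele 1 actually attained among the
    gametes.
    """

    alleles: np.ndarray
    prior_freqs: np.ndarray
    realized_freqs: np.ndarray
    layout: GenomeLayout

    @property
    def n_gametes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]


@dataclass(frozen=True)
class ReleasedMap:
    """The marker map released to analysts, plus the withheld loci.

    Constructed SNPs are numbered 1.. within each chromosome; odd-numbered
    SNPs form the released map (double spacing) and even-numbered SNPs are
    hidden.  QTLs are drawn from the hidden set.
    """

    released_indices: np.ndarray  # column indices into the constructed genome
    hidden_indices: np.ndarray
    chromosome: np.ndarray  # per released SNP, 1-based
    pos_mb: np.ndarray  # per released SNP, within-chromosome
    snp_ids: np.ndarray  # per released SNP, e.g. "snp_1_0.025"

    @property
    def n_released(self) -> int:
        return self.released_indices.size


def sample_prior_freqs(layout: GenomeLayout, rng: np.random.Generator,
                       mean: float = 0.5, sd: float = 0.1) -> np.ndarray:
    """Draw prior allele-1 frequencies f(1)' ~ N(mean, sd) for every SNP.

    Draws outside (0, 1) are clamped to ``FREQ_CLAMP``.
    """
    f = rng.normal(mean, sd, size=layout.n_snps)
    return np.clip(f, *FREQ_CLAMP)


def target_r(distance_mb: np.ndarray | float, profile: LDProfile) -> np.ndarray:
    """Expected absolute r between two SNPs a given distance apart."""
    return profile.expected_abs_r(distance_mb)


def sample_signed_ld(r_targets: np.ndarray, profile: LDProfile,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample signed LD coefficients r' ~ +/- N(r_target, sigma_r).

    Magnitudes are clamped to [0, 1] (r is a correlation); signs are i.i.d.
    positive with probability ``sign_prob``.
    """
    r = np.asarray(r_targets, dtype=float)
    mag = np.clip(rng.normal(r, profile.sigma_r), 0.0, 1.0)
    sign = np.where(rng.random(r.shape) < profile.sign_prob, 1.0, -1.0)
    return sign * mag


def conditional_allele_prob(prior_freq: float,
                            window_alleles: np.ndarray,
                            window_freqs: np.ndarray,
                            r_prime: np.ndarray) -> np.ndarray:
    """Probability that a gamete carries allele 1 at the new SNP.

    Given the alleles a gamete already carries at up to ``ld_window`` upstream
    loci, the conditional probability of each allele ``x_k`` at the new SNP is
    proportional to::

        f(x_k)' * prod_l P(h(j-l) | x_k)

    where each factor is the two-locus conditional probability of the
    observed upstream allele given ``x_k``, derived from the haplotype
    frequency identity f(AB) = f(A) f(B) + r sqrt(f_A (1-f_A) f_B (1-f_B)):

        [f(x_k)' f(h(j-l)) + gamma r'_l sqrt(f(x_k)'(1-f(x_k)') f(h)(1-f(h)))]
        / f(x_k)'

    with gamma = +1 when x_k equals the observed upstream allele and -1
    otherwise.  Factors that would be negative (r' incompatible with the
    marginals) are floored at a small epsilon; if both alleles' products
    vanish the prior frequency is returned.

    Parameters
    ----------
    prior_freq : prior frequency of allele 1 at the new SNP.
    window_alleles : (..., w) array of 0/1 upstream alleles (1 = allele 1),
        nearest locus first or last — order only has to match ``window_freqs``.
    window_freqs : (w,) realized frequencies of allele 1 at the upstream loci.
    r_prime : (w,) signed LD of the new SNP with each upstream locus.

    Returns
    -------
    Probability of allele 1, with shape ``window_alleles.shape[:-1]``.
    """
    h = np.asarray(window_alleles)
    scalar_in = h.ndim == 1
    h = np.atleast_2d(h)
    f_l = np.asarray(window_freqs, dtype=float)
    r = np.asarray(r_prime, dtype=float)
    f1 = float(prior_freq)
    f2 = 1.0 - f1
    if h.shape[-1] == 0:
        p = np.full(h.shape[0], f1)
        return p[0] if scalar_in else p

    # frequency of the allele actually observed upstream, per gamete/locus
    f_obs = np.where(h == 1, f_l, 1.0 - f_l)
    # covariance term; sqrt(f_obs(1-f_obs)) is symmetric in the observed allele
    s = r * np.sqrt(f1 * f2 * f_obs * (1.0 - f_obs))
    gamma1 = np.where(h == 1, 1.0, -1.0)  # +1 when x_k = observed, for k = 1
    fac1 = np.maximum((f1 * f_obs + gamma1 * s) / f1, FACTOR_EPS)
    fac2 = np.maximum((f2 * f_obs - gamma1 * s) / f2, FACTOR_EPS)
    num1 = f1 * np.prod(fac1, axis=-1)
    num2 = f2 * np.prod(fac2, axis=-1)
    tot = num1 + num2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0.0, num1 / np.where(tot > 0.0, tot, 1.0), f1)
    if scalar_in:
        return float(p[0])
    return p


def build_founder_gametes(layout: GenomeLayout, profile: LDProfile,
                          rng: np.random.Generator,
                          n_gametes: int = 2040) -> GameteMatrix:
    """Construct all founder gametes chromosome by chromosome, SNP by SNP.

    All gametes are completed at SNP j before SNP j+1 starts, because the
    conditional probability uses the *realized* allele frequencies of the
    upstream columns.  One signed-LD vector r' is drawn per SNP and shared by
    every gamete: r' describes population-level LD, which a single haplotype
    does not perturb appreciably.
    """
    n_snps = layout.n_snps
    alleles = np.empty((n_gametes, n_snps), dtype=np.int8)
    prior = np.empty(n_snps)
    realized = np.empty(n_snps)
    spacing = layout.spacing_mb
    w_max = layout.ld_window

    col = 0
    for _chrom in range(layout.n_chromosomes):
        for j in range(layout.snps_per_chrom):
            f1 = float(np.clip(rng.normal(0.5, 0.1), *FREQ_CLAMP))
            prior[col] = f1
            w = min(j, w_max)
            if w == 0:
                draw = rng.random(n_gametes) < f1
                alleles[:, col] = draw
            else:
                cols = np.arange(col - w, col)
                dist = spacing * np.arange(w, 0, -1)
                r_targets = profile.expected_abs_r(dist)
                r_prime = sample_signed_ld(r_targets, profile, rng)
                f_up = np.clip(realized[cols], *FREQ_CLAMP)
                p1 = conditional_allele_prob(f1, alleles[:, cols], f_up, r_prime)
                alleles[:, col] = rng.random(n_gametes) < p1
            realized[col] = alleles[:, col].mean()
            col += 1
    return GameteMatrix(alleles=alleles, prior_freqs=prior,
                        realized_freqs=realized, layout=layout)


def hide_even_snps(layout: GenomeLayout) -> ReleasedMap:
    """Partition constructed SNPs into the released map and the hidden set.

    Within each chromosome the odd-numbered SNPs (1-based) are released and
    the even-numbered ones hidden, so the released map has half the SNPs at
    twice the spacing.
    """
    if layout.snps_per_chrom % 2 != 0:
        raise ValueError("snps_per_chrom must be even")
    within = np.tile(np.arange(layout.snps_per_chrom), layout.n_chromosomes)
    idx = np.arange(layout.n_snps)
    released = idx[within % 2 == 0]  # 0-based even == 1-based odd
    hidden = idx[within % 2 == 1]
    chrom = layout.chrom_of_snp[released]
    pos = layout.pos_mb[released]
    ids = np.array([f"snp_{c}_{p:.3f}" for c, p in zip(chrom, pos)])
    return ReleasedMap(released_indices=released, hidden_indices=hidden,
                       chromosome=chrom, pos_mb=pos, snp_ids=ids)
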