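# Methods

This note documents the models implemented in `qtlbench`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not emulate.

## Founder genome

The founder population is constructed directly in LD space rather than by
coalescent or forward mutation–drift simulation. Chromosomes are built
left to right; at each new SNP *j*:

1. a prior allele-1 frequency f(1)′ ~ N(0.5, 0.1) is drawn, clamped to
   [0.01, 0.99] so the Bernoulli sd terms √(f(1−f)) stay defined;
2. one signed LD vector r′ is drawn for the up-to-40 upstream SNPs,
   |r′_l| ~ N(r°(d_l), 0.1) clamped to [0, 1], sign positive with
   probability 0.5. The vector is shared by all gametes: r′ is a
   population-level quantity which a single haplotype does not perturb;
3. every gamete receives allele x_k with probability proportional to
   f(x_k)′ · Π_l P(h_l | x_k), each factor the two-locus conditional
   probability of the observed upstream allele implied by
   f(AB) = f(A)f(B) + r√(f_A(1−f_A) f_B(1−f_B)). Upstream frequencies are
   the *realized* frequencies of the already-completed columns (hence the
   strictly column-major construction). Factors are floored at 10⁻⁶ —
   sampled r′ can be incompatible with the marginals, which would give a
   negative haplotype frequency — and the two allele probabilities are
   renormalized; if both vanish the prior is used.

The target decay r°(d) is linear, 1 − d/1 Mb, zero beyond 1 Mb (the
window length × spacing). The form is configurable (`linear`,
`exponential`, `zero`, custom table); linear is the simplest curve
matching both endpoints and the cutoff.

Because the per-locus sign draws conflict with each other (SNP j−1 and
j−2 are themselves correlated, yet j receives independently signed
targets toward both), realized LD sits well below the targets: adjacent
constructed SNPs (0.025 Mb) realize mean r² ≈ 0.25, decaying to the
1/(2N) independence floor beyond 1 Mb, with mean MAF ≈ 0.25. This is the
intended behaviour — the profile shapes, rather than pins, the decay
curve, and the result resembles dense-chip LD in dairy sheep. Anyone
needing stronger short-range LD should supply a slower-decaying profile,
not expect r° to be realized verbatim.

## Pedigree and meiosis

Discrete generations G0..G4, each exactly 20 males + 1,000 females. Every
sire is mated to 50 dams drawn without replacement (each dam has a single
mate); each dam leaves one daughter except one dam per sire family,
chosen uniformly, who leaves a daughter and a son. Which dams bear sons
is not structurally constrained beyond this one-per-family rule, which
keeps the paternal half-sib structure balanced. Founder genotypes pair
the 2,040 constructed gametes at random. Meiosis is Haldane: per
chromosome, crossover count ~ Poisson(length in Morgans), positions
uniform, no interference, starting haplotype fair. The map scale is
1 cM/Mb (configurable), the livestock convention, making each chromosome
1 Morgan.

With 20 sires per generation the effective size is
Ne = 4·20·1000/1020 ≈ 78, so allele frequencies drift noticeably:
mean |Δf| from founders to G4 is ≈ 0.05 (≈ √(4·pq/(2Ne))·√(2/π)). The
drift test asserts this analytic bound rather than a tighter ad hoc one.

## Trait architecture

Substitution effects: |α| ~ Gamma(shape 0.42, scale 5.4), sign fair. The
vector is rescaled so Σ 2p_k q_k α²_k = 1 ("standardized units"), with p
taken from the phenotyped G1–G3 females; the gamma scale parameter is
thereby removed and only the shape (effect-size skew) matters. Trait
units follow from α_T1 = α_sdu·σ_T1 and the ω coupling equations; at
ω = 1 the ratio-trait effect is algebraically zero and is set to exact
zero so the pleiotropy census is sharp (with the reference class counts
{4, 4, 7, 31, 4}: 46 QTLs touch fat yield, 19 touch fat content). Note
the covariance signs implied by the equations: α_T3 ∝ α_T1(ω−1), so for
0 < ω < 1 the T3 contribution covaries *negatively* with both T1 and T2;
for ω > 1 positively with both; for ω < 0 negatively with T1 and
positively with T2.

ω tuning minimizes the squared deviation of the three realized genetic
correlations — computed from TBV of the phenotyped females, so LD and
drift are included — from (0.80, −0.45, 0.17). Only the 11 continuous ω
values move (bounded coordinate descent with a quasi-Newton polish);
the discrete classes stay at −1, 0, 1. Effect sizes are heavy-tailed
(typically ~5 QTLs carry most of the variance), so feasibility depends
on *which* QTL carries which class: when the continuous search stalls,
the tuner swaps class assignments between QTL pairs (best-improvement,
counts preserved) and, failing that, redraws the assignment. Convergence
tolerance is 0.03 per correlation; at full scale the tuner essentially
always converges, in reduced profiles (3 free ω values) it may warn and
keep the best solution.

TBV are dosage-weighted effect sums, centered within the phenotyped
sample (an affine shift; phenotypes are deviations). Residuals are
trivariate normal with variances σ²_g(1−h²)/h² computed from the
*realized* TBV variances — hitting the target heritabilities in the
delivered sample — and correlation matrix equal to the realized genetic
correlation matrix (eigenvalue-clipped to positive definite if a
degenerate reduced configuration requires it). The ratio trait's
residuals are generated, not derived as a noise ratio of T2/T1.

## Detectability screen and scoring

The screen fits, per trait, one OLS regression of the 3,000 females' YD
on all 50 QTL dosage columns jointly (intercept included; monomorphic or
collinear columns dropped and reported untestable), and flags
per-coefficient partial F tests at p < 0.05/10,000 = 5 × 10⁻⁶ — the
Bonferroni correction over the *released marker* count, i.e. the tests an
analyst would actually run. Joint fitting removes spurious signal from
linkage between QTLs. At full scale ~12–14 QTLs per trait are detectable,
carrying ≈ 0.9 of each trait's genetic variance.

Mapping scores: a true QTL is detected if any submitted position on the
same chromosome is within 1 Mb (inclusive — "within" is read as ≤, and
cross-chromosome distance is undefined); one submission may credit
several QTLs and several submissions one QTL (counted once); unmatched
submissions are false positives. Variance explained is
Σ_detected 2pqα²_T / Σ_all 2pqα²_T; per-QTL correlation contributions are
2pqα_i α_j/(σ_Gi σ_Gj), which sum to the architecture's total correlation
up to QTL–QTL LD (a ±0.05 gap is normal).

Prediction scores: r_DGV = Pearson(TBV, DGV) and b_DGV = slope of TBV on
DGV, with a two-sided t test of slope = 1 (the conventional check behind
"significantly biased" annotations; a residual-free perfect fit reports
p = 1 at slope 1).

## GBLUP reference

GRM: centered dosage cross-products over released markers scaled by
Σ2pq (VanRaden's first construction), centering frequencies from the
training set, monomorphic columns dropped; mean diagonal ≈ 1. DGV for
the 1,020 candidates solve
(G_tt + λI)a = y − ȳ, DGV = G_ct a, with λ = (1−h²)/h² fixed from the
simulated heritability — variance-component estimation is deliberately
out of scope, the predictor exists to exercise the evaluation path. The
SNP-ridge twin (penalty λ·Σ2pq on centered dosages) is mathematically
identical and serves as the correctness oracle; the two agree to machine
precision on random instances.

Because λ is the true variance ratio, the reference predictor is
calibrated: across full-scale seeds b_DGV ≈ 0.91–1.01 and
r_DGV ≈ 0.66–0.71 for milk yield. A GBLUP whose variance components are
estimated from the marker data (as workshop participants would have done)
shrinks harder and shows b_DGV well above 1; users comparing against such
results should treat the bias slope as diagnostic of the variance ratio
used, not of the GRM.

## Problem sizes, seeds, limitations

All randomness flows from one master seed through four fixed-index named
substreams (genome, pedigree, qtl, residuals), so e.g. redrawing
residuals never perturbs genotypes. Identical seeds give byte-identical
participant exports.

The default (full) profile is the study scale throughout: 2,040 founder
gametes × 20,000 constructed SNPs, 5,100 individuals, 3,000 phenotyped
females, 1,020 candidates; one full pipeline plus GBLUP takes ~1.5 min on
a single core. The mini profile (1 × 10 Mb chromosome, 400 SNPs, 100
founders, 3 generations, 10 QTLs with proportionally apportioned ω
classes) runs in well under a second and drives most of the test suite.

Known limitations: the founder model has no mutation, selection or
demographic history — long-range LD arises only from the construction
window and drift, so realized LD beyond 1 Mb is thinner than in selected
livestock populations; QTL effects are purely additive (no dominance,
epistasis, or QTL × environment); generations do not overlap and there
is no selection during pedigree expansion; genotypes are error-free and
fully phased internally. Passing tests therefore certify the machinery
and its internal consistency on this idealized population, not method
performance on real dairy data.
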