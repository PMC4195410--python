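"""Pleiotropic QTL architecture for three correlated dairy traits.

Fifty biallelic QTLs jointly generate milk yield (T1), fat yield (T2) and
fat content (T3 = T2/T1).  Allele substitution effects are gamma-distributed
with random sign and standardized so that, summed over QTLs under
Hardy-Weinberg, they account for one squared standard-deviation unit of T1.
A per-QTL parameter ``omega`` couples the T1 and T2 effects in mean units:

    alpha_T1 = alpha_sdu * sigma_T1
    alpha_T2 = omega * alpha_T1 * mu_T2 / mu_T1
    alpha_T3 = (mu_T2 + alpha_T2) / (mu_T1 + alpha_T1) - mu_T3

so omega = 1 moves T1 and T2 proportionally and leaves the ratio trait T3
untouched; omega = 0 gives a T1-only QTL that still shifts T3; omega > 1 or
omega < 0 makes T3 covary positively or negatively with T1 respectively.
The omega values of the continuous classes are tuned by coordinate search
until the genetic correlations realized in the phenotyped generations match
their targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

__all__ = [
    "TraitConfig",
    "QTLSet",
    "sample_qtl_positions",
    "sample_standardized_effects",
    "trait_effects",
    "assign_omega_classes",
    "assign_and_tune_omega",
    "compute_tbv",
    "simulate_phenotypes",
    "genetic_correlations",
]

TRAITS = ("T1", "T2", "T3")

#: omega classes: fixed values for the discrete classes, (lo, hi) search
#: intervals for the continuous ones.
OMEGA_NEG, OMEGA_ZERO, OMEGA_ONE = -1.0, 0.0, 1.0
MID_BOUNDS = (1e-3, 1.0 - 1e-3)   # open interval (0, 1)
HIGH_BOUNDS = (1.0 + 1e-3, 4.0)   # (1, 4]


@dataclass(frozen=True)
class TraitConfig:
    """Trait means, scales, heritabilities and QTL-architecture settings.

    Defaults mimic a Sarda-like dairy sheep population: milk yield mean
    200 kg (sd 100 kg), fat yield mean 12 kg, fat content 0.06, with
    heritabilities (0.35, 0.35, 0.50) and genetic correlations
    (T1T2, T1T3, T2T3) = (0.80, -0.45, 0.17).
    """

    mu_t1: float = 200.0
    mu_t2: float = 12.0
    sigma_t1: float = 100.0
    h2: tuple[float, float, float] = (0.35, 0.35, 0.50)
    target_rg: tuple[float, float, float] = (0.80, -0.45, 0.17)  # (12, 13, 23)
    gamma_shape: float = 0.42
    gamma_scale: float = 5.4
    n_qtl: int = 50
    #: QTLs per omega class: exactly -1, exactly 0, inside (0,1), exactly 1,
    #: inside (1,4]
    omega_class_counts: tuple[int, int, int, int, int] = (4, 4, 7, 31, 4)
    rg_tol: float = 0.03
    max_sweeps: int = 60
    n_restarts: int = 8
    max_swaps: int = 15

    def __post_init__(self) -> None:
        if sum(self.omega_class_counts) != self.n_qtl:
            raise ValueError("omega class counts must sum to n_qtl")
        if not all(0.0 < h <= 1.0 for h in self.h2):
            raise ValueError("heritabilities must lie in (0, 1]")

    @property
    def mu_t3(self) -> float:
        return self.mu_t2 / self.mu_t1


CLASS_NAMES = ("neg", "zero", "mid", "one", "high")

#: reference class counts at 50 QTLs: 4 at -1, 4 at 0, 7 in (0,1), 31 at 1,
#: 4 in (1,4]
REFERENCE_CLASS_COUNTS = (4, 4, 7, 31, 4)


def scaled_class_counts(n_qtl: int) -> tuple[int, int, int, int, int]:
    """Apportion the reference omega-class proportions to another QTL count.

    Largest-remainder apportionment of the 50-QTL class counts; ties go to
    the lower class index.
    """
    ref = np.asarray(REFERENCE_CLASS_COUNTS, dtype=float)
    quota = ref * n_qtl / ref.sum()
    counts = np.floor(quota).astype(int)
    frac = quota - counts
    order = np.lexsort((np.arange(frac.size), -frac))
    for i in order[: n_qtl - counts.sum()]:
        counts[i] += 1
    return tuple(int(c) for c in counts)


@dataclass
class QTLSet:
    """The realized QTL architecture.

    ``positions`` index columns of the constructed genome (all hidden SNPs);
    ``p`` is the frequency of allele 1 (the counted allele) in the phenotyped
    generations; ``alpha_t`` has one column per trait in trait units.
    """

    positions: np.ndarray
    chromosome: np.ndarray
    pos_mb: np.ndarray
    alpha_sdu: np.ndarray
    omega: np.ndarray
    omega_class: np.ndarray  # strings from CLASS_NAMES
    alpha_t: np.ndarray      # (n_qtl, 3)
    p: np.ndarray
    config: TraitConfig

    @property
    def n_qtl(self) -> int:
        return self.positions.size

    def var_contrib(self, trait: int) -> np.ndarray:
        """Per-QTL additive variance 2 p q alpha^2 for one trait (0-based)."""
        return 2.0 * self.p * (1.0 - self.p) * self.alpha_t[:, trait] ** 2

    def sigma2_g(self, trait: int) -> float:
        """Total QTL variance for a trait (sum of 2pq alpha^2 over QTLs)."""
        return float(self.var_contrib(trait).sum())

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame({
            "chromosome": self.chromosome, "pos_mb": self.pos_mb,
            "omega": self.omega, "omega_class": self.omega_class,
            "alpha_sdu": self.alpha_sdu,
            "alpha_t1": self.alpha_t[:, 0], "alpha_t2": self.alpha_t[:, 1],
            "alpha_t3": self.alpha_t[:, 2], "p": self.p,
        })
        for t in range(3):
            s2 = self.sigma2_g(t)
            df[f"var_share_{TRAITS[t].lower()}"] = (
                self.var_contrib(t) / s2 if s2 > 0 else np.nan)
        return df


def sample_qtl_positions(hidden_indices: np.ndarray, n_qtl: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw QTL positions uniformly without replacement from the hidden SNPs."""
    hidden = np.asarray(hidden_indices)
    if hidden.size < n_qtl:
        raise ValueError(f"only {hidden.size} hidden SNPs for {n_qtl} QTLs")
    return np.sort(rng.choice(hidden, size=n_qtl, replace=False))


def sample_standardized_effects(freqs: np.ndarray, cfg: TraitConfig,
                                rng: np.random.Generator) -> np.ndarray:
    """Gamma-distributed substitution effects, signed and standardized.

    Raw magnitudes are Gamma(shape, scale) with signs +/-1 equiprobable; the
    vector is rescaled so the Hardy-Weinberg variance sum(2 p q alpha^2)
    equals 1, i.e. the QTLs jointly explain one sd-unit of the reference
    trait.
    """
    p = np.asarray(freqs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("QTL allele frequencies must lie in [0, 1]")
    raw = rng.gamma(cfg.gamma_shape, cfg.gamma_scale, size=p.size)
    sign = np.where(rng.random(p.size) < 0.5, 1.0, -1.0)
    hw = 2.0 * p * (1.0 - p)
    total = np.sum(hw * raw ** 2)
    if total <= 0:
        raise ValueError("all QTLs monomorphic: cannot standardize effects")
    scale = 1.0 / np.sqrt(total)
    return sign * raw * scale


def trait_effects(alpha_sdu: np.ndarray, omega: np.ndarray,
                  cfg: TraitConfig) -> np.ndarray:
    """Map standardized effects and omega to per-trait effects (n, 3).

    The T3 effect is the shift the QTL induces in the ratio trait's mean;
    it is algebraically zero at omega = 1 and is set to exactly zero there
    so pleiotropy classes are sharp.
    """
    a = np.atleast_1d(np.asarray(alpha_sdu, dtype=float))
    w = np.atleast_1d(np.asarray(omega, dtype=float))
    a_t1 = a * cfg.sigma_t1
    denom = cfg.mu_t1 + a_t1
    if np.any(denom <= 0):
        raise ValueError("mu_T1 + alpha_T1 must stay positive")
    a_t2 = np.where(w == 0.0, 0.0, w * a_t1 * (cfg.mu_t2 / cfg.mu_t1))
    a_t3 = np.where(w == 1.0, 0.0,
                    (cfg.mu_t2 + a_t2) / denom - cfg.mu_t3)
    return np.column_stack([a_t1, a_t2, a_t3])


def assign_omega_classes(cfg: TraitConfig, rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Randomly assign omega classes to QTLs and draw initial omega values."""
    n_neg, n_zero, n_mid, n_one, n_high = cfg.omega_class_counts
    labels = np.array(
        ["neg"] * n_neg + ["zero"] * n_zero + ["mid"] * n_mid
        + ["one"] * n_one + ["high"] * n_high)
    rng.shuffle(labels)
    omega = np.empty(cfg.n_qtl)
    omega[labels == "neg"] = OMEGA_NEG
    omega[labels == "zero"] = OMEGA_ZERO
    omega[labels == "one"] = OMEGA_ONE
    omega[labels == "mid"] = rng.uniform(0.2, 0.8, size=(labels == "mid").sum())
    omega[labels == "high"] = rng.uniform(1.2, 3.0, size=(labels == "high").sum())
    return omega, labels


def genetic_correlations(tbv: np.ndarray) -> np.ndarray:
    """Pairwise correlations (T1T2, T1T3, T2T3) of a (n, 3) TBV matrix."""
    c = np.corrcoef(tbv, rowvar=False)
    return np.array([c[0, 1], c[0, 2], c[1, 2]])


def _tuning_objective(omega: np.ndarray, alpha_sdu: np.ndarray,
                      dosages: np.ndarray, cfg: TraitConfig) -> float:
    a_t = trait_effects(alpha_sdu, omega, cfg)
    tbv = dosages @ a_t
    rg = genetic_correlations(tbv)
    return float(np.sum((rg - np.asarray(cfg.target_rg)) ** 2))


def assign_and_tune_omega(alpha_sdu: np.ndarray, dosages: np.ndarray,
                          cfg: TraitConfig, rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Assign omega classes and tune the continuous values to the target rg.

    ``dosages`` is the (n_individuals, n_qtl) allele-1 count matrix of the
    phenotyped generations; the realized genetic correlations are computed
    from the TBV it implies.  Only omegas in the open classes (0,1) and
    (1,4] move; the discrete classes stay at -1, 0 and 1.  A coordinate
    search (bounded scalar minimization per free omega, swept repeatedly)
    minimizes the squared deviation of the three correlations from target.
    Because effect sizes are heavy-tailed, feasibility also hinges on which
    QTL carries which class (a class can only contribute as much covariance
    as the variance of the QTLs assigned to it), so when continuous tuning
    stalls the search additionally swaps class assignments between QTL pairs
    (class counts preserved, best-improvement swap, up to ``max_swaps``).
    If a draw cannot reach all targets the assignment is re-drawn up to
    ``n_restarts`` times and the best solution kept, with a warning when
    even that fails.
    """
    targets = np.asarray(cfg.target_rg)
    best: tuple[float, np.ndarray, np.ndarray] | None = None

    def _converged(omega: np.ndarray) -> bool:
        a_t = trait_effects(alpha_sdu, omega, cfg)
        rg = genetic_correlations(dosages @ a_t)
        return bool(np.all(np.abs(rg - targets) <= cfg.rg_tol))

    def _tune_continuous(omega: np.ndarray, labels: np.ndarray) -> float:
        """Coordinate sweeps plus a quasi-Newton polish; mutates omega."""
        free = np.flatnonzero((labels == "mid") | (labels == "high"))
        if free.size == 0:
            return _tuning_objective(omega, alpha_sdu, dosages, cfg)
        bounds = [MID_BOUNDS if labels[k] == "mid" else HIGH_BOUNDS
                  for k in free]
        sse = _tuning_objective(omega, alpha_sdu, dosages, cfg)
        prev = np.inf
        for _sweep in range(cfg.max_sweeps):
            for k in free:
                lo, hi = MID_BOUNDS if labels[k] == "mid" else HIGH_BOUNDS

                def f1d(x: float, k: int = k) -> float:
                    om = omega.copy()
                    om[k] = x
                    return _tuning_objective(om, alpha_sdu, dosages, cfg)

                res = minimize_scalar(f1d, bounds=(lo, hi), method="bounded",
                                      options={"xatol": 1e-4})
                if res.fun < sse:
                    omega[k] = float(res.x)
                    sse = float(res.fun)
            if _converged(omega) or prev - sse < 1e-10:
                break
            prev = sse

        def f_free(x: np.ndarray) -> float:
            om = omega.copy()
            om[free] = x
            return _tuning_objective(om, alpha_sdu, dosages, cfg)

        res = minimize(f_free, omega[free], bounds=bounds, method="L-BFGS-B")
        if res.fun < sse:
            omega[free] = res.x
            sse = float(res.fun)
        return sse

    n = cfg.n_qtl
    for _restart in range(max(1, cfg.n_restarts)):
        omega, labels = assign_omega_classes(cfg, rng)
        sse = _tune_continuous(omega, labels)
        for _swap_round in range(cfg.max_swaps):
            if _converged(omega):
                return omega, labels
            best_swap, best_sse = None, sse
            for i in range(n):
                for j in range(i + 1, n):
                    if labels[i] == labels[j]:
                        continue
                    om = omega.copy()
                    om[i], om[j] = om[j], om[i]
                    s = _tuning_objective(om, alpha_sdu, dosages, cfg)
                    if s < best_sse:
                        best_swap, best_sse = (i, j), s
            if best_swap is None:
                break
            i, j = best_swap
            omega[i], omega[j] = omega[j], omega[i]
            labels[i], labels[j] = labels[j], labels[i]
            sse = _tune_continuous(omega, labels)
        if _converged(omega):
            return omega, labels
        if best is None or sse < best[0]:
            best = (sse, omega.copy(), labels.copy())
    assert best is not None
    warnings.warn(
        "omega tuning did not reach the target genetic correlations within "
        f"tolerance {cfg.rg_tol}; best squared deviation {best[0]:.4g}",
        RuntimeWarning)
    return best[1], best[2]


def compute_tbv(dosages: np.ndarray, alpha_t: np.ndarray,
                center_rows: np.ndarray | None = None) -> np.ndarray:
    """True breeding values: dosage-weighted sum of QTL effects, per trait.

    TBV are expressed as deviations: the mean over ``center_rows`` (default
    all rows) is subtracted, an affine shift that leaves variances,
    correlations and rankings untouched.
    """
    tbv = np.asarray(dosages, dtype=float) @ alpha_t
    ref = tbv if center_rows is None else tbv[center_rows]
    return tbv - ref.mean(axis=0)


def _nearest_pd_corr(c: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore a unit diagonal."""
    vals, vecs = np.linalg.eigh(c)
    if vals.min() > 1e-10:
        return c
    vals = np.clip(vals, 1e-8, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def simulate_phenotypes(tbv: np.ndarray, cfg: TraitConfig,
                        rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Yield deviations = TBV + correlated normal residuals.

    Residual variances are set from the *realized* TBV variances so the
    delivered sample hits the target heritabilities:
    sigma2_e = var(TBV) (1 - h2) / h2.  The residual correlation matrix
    equals the realized genetic correlation matrix (repaired to the nearest
    positive-definite correlation if degenerate).
    """
    tbv = np.asarray(tbv, dtype=float)
    var_g = tbv.var(axis=0)
    h2 = np.asarray(cfg.h2)
    var_e = var_g * (1.0 - h2) / h2
    corr = np.corrcoef(tbv, rowvar=False)
    if np.any(np.linalg.eigvalsh(corr) < 1e-10):
        warnings.warn("residual correlation matrix repaired to positive "
                      "definite", RuntimeWarning)
        corr = _nearest_pd_corr(corr)
    sd_e = np.sqrt(var_e)
    cov = corr * np.outer(sd_e, sd_e)
    resid = rng.multivariate_normal(np.zeros(3), cov, size=tbv.shape[0],
                                    method="cholesky" if np.all(var_e > 0)
                                    else "svd")
    return {"tbv": tbv, "residual": resid, "yd": tbv + resid}
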