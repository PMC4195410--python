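"""True-model screen: which QTLs are detectable at all?

A multiple regression of each trait's yield deviations on all 50 true QTL
dosages, fitted on the phenotyped females, bounds what any mapping method
could find: a QTL whose effect is not significant even when every causal
genotype is in the model will not be detected from markers.  Fitting all
QTLs jointly excludes spurious signal from linkage between QTLs.  The
per-QTL test is a partial F test (1 numerator df) at a Bonferroni-corrected
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .traits import QTLSet, TRAITS

__all__ = [
    "bonferroni_threshold",
    "fit_full_qtl_regression",
    "flag_detectable",
    "DetectabilityReport",
]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test p-value threshold for an overall significance level."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def fit_full_qtl_regression(yd: np.ndarray, qtl_dosages: np.ndarray) -> pd.DataFrame:
    """OLS of one trait's phenotypes on all QTL dosages jointly.

    Monomorphic dosage columns, and columns that are collinear with earlier
    ones, are dropped before fitting (they carry no testable effect) and
    reported with p = 1.  Returns one row per QTL with the effect estimate,
    the 1-df partial F statistic (the squared t) and its p-value.
    """
    y = np.asarray(yd, dtype=float)
    x = np.asarray(qtl_dosages, dtype=float)
    n, k = x.shape
    if y.size != n:
        raise ValueError("phenotype/dosage row mismatch")
    if n <= k + 1:
        raise ValueError("need more observations than QTLs plus intercept")

    keep = x.std(axis=0) > 0
    if keep.sum() < keep.size:
        pass  # monomorphic: no segregating effect to test
    # collinearity among the remaining columns (with intercept): QR pivoting
    kept_idx = np.flatnonzero(keep)
    xc = np.column_stack([np.ones(n), x[:, kept_idx]])
    rank = np.linalg.matrix_rank(xc)
    if rank < xc.shape[1]:
        warnings.warn("collinear QTL dosage columns dropped", RuntimeWarning)
        _, r, piv = scipy.linalg.qr(xc, mode="economic", pivoting=True)
        tol = np.abs(r[0, 0]) * max(xc.shape) * np.finfo(float).eps
        good_cols = np.sort(piv[np.abs(np.diag(r)) > tol])
        good_cols = good_cols[good_cols > 0]  # keep intercept implicitly
        kept_idx = kept_idx[good_cols - 1]

    res = sm.OLS(y, sm.add_constant(x[:, kept_idx])).fit()
    beta = np.full(k, np.nan)
    fstat = np.full(k, np.nan)
    pval = np.ones(k)
    beta[kept_idx] = res.params[1:]
    fstat[kept_idx] = res.tvalues[1:] ** 2
    pval[kept_idx] = res.pvalues[1:]
    return pd.DataFrame({"qtl": np.arange(k), "beta": beta, "F": fstat,
                         "p": pval, "tested": np.isin(np.arange(k), kept_idx)})


@dataclass
class DetectabilityReport:
    """Per-trait regression tables plus detectability summaries."""

    threshold: float
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def n_detectable(self, trait: str) -> int:
        return int(self.tables[trait]["detectable"].sum())

    def var_explained(self, trait: str) -> float:
        t = self.tables[trait]
        return float(t.loc[t["detectable"], "var_share"].sum())

    @property
    def n_detectable_any(self) -> int:
        """QTLs detectable on at least one trait."""
        mask = np.zeros(len(next(iter(self.tables.values()))), dtype=bool)
        for t in self.tables.values():
            mask |= t["detectable"].to_numpy()
        return int(mask.sum())


def flag_detectable(yd_by_trait: np.ndarray, qtl_dosages: np.ndarray,
                    qtlset: QTLSet, threshold: float) -> DetectabilityReport:
    """Run the screen for every trait and attach variance shares.

    ``yd_by_trait`` is (n_females, 3); ``var_share`` is the proportion of the
    trait's total QTL variance carried by each QTL, 2pq alpha^2 / sigma2_G.
    """
    report = DetectabilityReport(threshold=threshold)
    for t, name in enumerate(TRAITS):
        tab = fit_full_qtl_regression(yd_by_trait[:, t], qtl_dosages)
        s2 = qtlset.sigma2_g(t)
        tab["var_share"] = qtlset.var_contrib(t) / s2 if s2 > 0 else np.nan
        tab["detectable"] = tab["p"] < threshold
        report.tables[name] = tab
    return report
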