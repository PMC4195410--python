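"""Scoring of QTL-mapping submissions and genomic predictions.

Mapping submissions are lists of proposed (chromosome, position) locations
per trait.  A true QTL counts as detected when at least one submitted
position lies within 1 Mb of it on the same chromosome (boundary
inclusive); every submitted position that matches no QTL is a false
positive.  Detected sets are also summarized by the share of true genetic
variance they carry, 2pq alpha^2 / sigma2_G per QTL, and by each QTL's
signed contribution to the genetic correlation between a pair of traits,
2pq alpha_i alpha_j / (sigma_Gi sigma_Gj).

Genomic predictions are scored per trait by the Pearson correlation between
true breeding values and submitted direct genomic values (accuracy) and by
the slope of the regression of TBV on DGV (bias; 1 = unbiased), with a
two-sided t test of slope = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .traits import QTLSet

__all__ = [
    "MappingScore",
    "PredictionScore",
    "match_positions",
    "variance_explained",
    "correlation_contribution",
    "score_prediction",
]


@dataclass
class MappingScore:
    """Outcome of matching one submission against the true QTLs."""

    detected: np.ndarray        # boolean per true QTL
    false_positives: int
    pairs: list[tuple[int, int]] = field(default_factory=list)  # (qtl, sub)

    @property
    def n_true_detected(self) -> int:
        return int(self.detected.sum())


@dataclass
class PredictionScore:
    """Accuracy and bias of one DGV submission for one trait."""

    r_dgv: float
    b_dgv: float
    slope_p: float
    n: int


def match_positions(sub_chrom: np.ndarray, sub_pos_mb: np.ndarray,
                    qtlset: QTLSet, window_mb: float = 1.0,
                    chrom_length_mb: float | None = None) -> MappingScore:
    """Match submitted positions to true QTLs within a distance window.

    A submission may credit several QTLs (if two true QTLs fall within the
    window) and several submissions may hit one QTL, which is still counted
    once.  Order and duplicates of the submission do not affect the true
    detections; each non-matching entry adds one false positive.
    """
    sc = np.atleast_1d(np.asarray(sub_chrom))
    sp = np.atleast_1d(np.asarray(sub_pos_mb, dtype=float))
    if sc.size != sp.size:
        raise ValueError("chromosome and position vectors differ in length")
    if np.any(sp < 0):
        raise ValueError("submitted positions must be non-negative")
    if chrom_length_mb is not None and np.any(sp > chrom_length_mb):
        raise ValueError("submitted position beyond chromosome end")
    detected = np.zeros(qtlset.n_qtl, dtype=bool)
    pairs: list[tuple[int, int]] = []
    n_fp = 0
    for s in range(sc.size):
        hit = (qtlset.chromosome == sc[s]) & \
              (np.abs(qtlset.pos_mb - sp[s]) <= window_mb)
        if hit.any():
            for q in np.flatnonzero(hit):
                pairs.append((int(q), s))
            detected |= hit
        else:
            n_fp += 1
    return MappingScore(detected=detected, false_positives=n_fp, pairs=pairs)


def variance_explained(detected: np.ndarray, qtlset: QTLSet, trait: int) -> float:
    """Share of the trait's total QTL variance carried by the detected QTLs.

    sum over detected QTLs of 2pq alpha^2, divided by the same sum over all
    QTLs — so detecting everything scores exactly 1.
    """
    mask = np.asarray(detected, dtype=bool)
    s2 = qtlset.sigma2_g(trait)
    if s2 == 0:
        return float("nan")
    return float(qtlset.var_contrib(trait)[mask].sum() / s2)


def correlation_contribution(qtlset: QTLSet, trait_i: int, trait_j: int) -> np.ndarray:
    """Signed per-QTL contribution to the genetic correlation of two traits.

    2 p q alpha_i alpha_j / (sigma_Gi sigma_Gj); the sum over all QTLs is
    the architecture's total correlation (ignoring LD between QTLs).
    """
    hw = 2.0 * qtlset.p * (1.0 - qtlset.p)
    s_i = np.sqrt(qtlset.sigma2_g(trait_i))
    s_j = np.sqrt(qtlset.sigma2_g(trait_j))
    return hw * qtlset.alpha_t[:, trait_i] * qtlset.alpha_t[:, trait_j] / (s_i * s_j)


def score_prediction(dgv: np.ndarray, tbv: np.ndarray) -> PredictionScore:
    """Accuracy and bias of direct genomic values against true breeding values.

    ``b_dgv`` is the slope of TBV regressed on DGV; its p-value tests
    H0: slope = 1 with a two-sided t test.  A perfect, residual-free fit has
    no evidence against unbiasedness when the slope is 1 (p = 1) and
    certain evidence when it is not (p = 0).
    """
    dgv = np.asarray(dgv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    n = dgv.size
    if n < 3:
        raise ValueError("need at least 3 candidates to score a prediction")
    if dgv.std() == 0 or tbv.std() == 0:
        raise ValueError("zero-variance DGV or TBV: score undefined")
    r = float(np.corrcoef(tbv, dgv)[0, 1])
    x = dgv - dgv.mean()
    b = float(np.dot(x, tbv) / np.dot(x, x))
    a = tbv.mean()
    resid = tbv - a - b * x
    sse = float(np.dot(resid, resid))
    if sse <= 1e-12 * float(np.dot(tbv - tbv.mean(), tbv - tbv.mean())):
        slope_p = 1.0 if abs(b - 1.0) < 1e-12 else 0.0
    else:
        se = np.sqrt(sse / (n - 2) / np.dot(x, x))
        t = (b - 1.0) / se
        slope_p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return PredictionScore(r_dgv=r, b_dgv=b, slope_p=slope_p, n=n)
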