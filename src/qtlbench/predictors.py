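"""Reference genomic-prediction methods: GBLUP and its SNP-ridge twin.

GBLUP predicts breeding values from a genomic relationship matrix (GRM)
built from marker dosages: centered cross-products scaled by sum(2 p q)
(VanRaden's first method).  With the variance ratio lambda = (1 - h2) / h2
fixed from the known heritability, the direct genomic values of the
unphenotyped candidates are

    dgv_c = G_ct (G_tt + lambda I)^(-1) (y - ybar)

Ridge regression on the same centered dosages with penalty
lambda_ridge = lambda * sum(2 p q) yields identical predictions (the
kernel/primal duality), which serves as this module's correctness oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GRM", "compute_grm", "gblup_predict", "snp_ridge_predict"]


@dataclass
class GRM:
    """Genomic relationship matrix with its centering frequencies."""

    matrix: np.ndarray
    freqs: np.ndarray        # allele-1 frequency per retained SNP
    scale: float             # sum of 2 p q over retained SNPs
    kept: np.ndarray         # indices of retained (polymorphic) SNP columns


def _center(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    return np.asarray(dosages, dtype=np.float64) - 2.0 * freqs


def compute_grm(dosages: np.ndarray, freqs: np.ndarray | None = None) -> GRM:
    """GRM from a (n_individuals, n_snps) dosage matrix.

    Monomorphic columns (at the centering frequencies) are dropped.  With
    ``freqs`` omitted, frequencies are taken from the matrix itself; pass
    training-set frequencies when the matrix stacks training and candidate
    individuals.
    """
    x = np.asarray(dosages, dtype=np.float64)
    if freqs is None:
        freqs = x.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    kept = np.flatnonzero((freqs > 0.0) & (freqs < 1.0))
    if kept.size == 0:
        raise ValueError("no polymorphic SNPs to build a GRM from")
    f = freqs[kept]
    z = _center(x[:, kept], f)
    scale = float(np.sum(2.0 * f * (1.0 - f)))
    return GRM(matrix=(z @ z.T) / scale, freqs=f, scale=scale, kept=kept)


def gblup_predict(y_train: np.ndarray, grm: GRM | np.ndarray,
                  train_idx: np.ndarray, cand_idx: np.ndarray,
                  h2: float) -> np.ndarray:
    """Direct genomic values of candidates from GBLUP with known h2.

    ``grm`` covers training and candidate individuals jointly;
    ``train_idx``/``cand_idx`` index its rows.  The overall mean is
    estimated by the training phenotype average.  As h2 -> 0 the
    predictions shrink to zero deviation from the mean.
    """
    g = grm.matrix if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    lam = (1.0 - h2) / h2
    gtt = g[np.ix_(train_idx, train_idx)]
    gct = g[np.ix_(cand_idx, train_idx)]
    lhs = gtt + lam * np.eye(train_idx.size)
    rhs = y - y.mean()
    try:
        alpha = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:  # pragma: no cover - jitter fallback
        import warnings
        warnings.warn("singular GBLUP system; jittering the diagonal",
                      RuntimeWarning)
        alpha = np.linalg.solve(lhs + 1e-8 * np.eye(train_idx.size), rhs)
    return gct @ alpha


def snp_ridge_predict(y_train: np.ndarray, dosages_train: np.ndarray,
                      dosages_cand: np.ndarray, lam: float,
                      freqs: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Ridge regression of phenotypes on centered SNP dosages.

    Solves (X'X + lam I) beta = X'(y - ybar) on the training set and returns
    (candidate DGV, per-SNP effects).  With lam = (1 - h2)/h2 * sum(2pq) and
    shared centering frequencies this reproduces GBLUP exactly.  As
    lam -> infinity all effects vanish.
    """
    xt = np.asarray(dosages_train, dtype=np.float64)
    xc = np.asarray(dosages_cand, dtype=np.float64)
    y = np.asarray(y_train, dtype=float)
    if lam < 0:
        raise ValueError("ridge penalty must be non-negative")
    if freqs is None:
        freqs = xt.mean(axis=0) / 2.0
    zt = _center(xt, freqs)
    zc = _center(xc, freqs)
    k = zt.shape[1]
    beta = np.linalg.solve(zt.T @ zt + lam * np.eye(k), zt.T @ (y - y.mean()))
    return zc @ beta, beta
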