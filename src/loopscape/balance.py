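"""Iterative proportional fit (IPF) balancing and distance-decay summaries.

Raw ligation-frequency matrices carry multiplicative per-bin biases
(mappability, GC, restriction-site density). IPF finds one positive weight
per valid bin such that ``normalized[i][j] = raw[i][j] * w_i * w_j`` has
equal row sums. The update is the symmetric Sinkhorn form
``w <- w * sqrt(target / marginal)``, which preserves symmetry at every
iteration. The target marginal is the mean valid marginal of the raw
matrix, so normalized values remain on the scale of the input counts and
stay comparable across samples sequenced to similar depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ContactMatrix

logger = logging.getLogger(__name__)

__all__ = ["BalancedMatrix", "ipf_balance", "distance_decay", "decay_curves"]


@dataclass
class BalancedMatrix:
    """An IPF-normalized contact matrix plus the fitted bin weights."""

    base: ContactMatrix            # normalized values
    weights: np.ndarray            # per-bin w_i; NaN on invalid bins
    n_iterations: int
    converged: bool

    @property
    def values(self) -> np.ndarray:
        return self.base.values

    @property
    def valid_mask(self) -> np.ndarray:
        return self.base.valid_mask

    @property
    def n_bins(self) -> int:
        return self.base.n_bins


def ipf_balance(
    matrix: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> BalancedMatrix:
    """Balance a contact matrix by symmetric iterative proportional fit.

    Bins with zero raw marginal are masked invalid and left all-zero.
    Convergence: coefficient of variation of the valid-bin marginals
    below ``tol``.
    """
    raw = matrix.values
    marginals = raw.sum(axis=0)
    valid = marginals > 0
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid (non-zero-marginal) bins")

    sub = raw[np.ix_(valid, valid)].astype(float)
    n_valid = int(valid.sum())
    target = sub.sum() / n_valid

    w = np.ones(n_valid)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        m = (sub * w[None, :]).sum(axis=1) * w
        cv = m.std() / m.mean()
        if cv < tol:
            converged = True
            break
        w = w * np.sqrt(target / m)
    if not converged:
        logger.warning("IPF did not converge in %d iterations (CV=%.3g)", max_iter, cv)

    normalized = np.zeros_like(raw, dtype=float)
    normalized[np.ix_(valid, valid)] = sub * np.outer(w, w)
    weights = np.full(matrix.n_bins, np.nan)
    weights[valid] = w
    base = ContactMatrix(
        chrom=matrix.chrom,
        resolution=matrix.resolution,
        values=normalized,
        valid_mask=valid,
    )
    return BalancedMatrix(
        base=base, weights=weights, n_iterations=it, converged=converged
    )


def distance_decay(
    matrix: BalancedMatrix | ContactMatrix, max_distance: int | None = None
) -> pd.DataFrame:
    """Median normalized signal per off-diagonal distance (in bins).

    Only pairs of valid bins contribute. Returns a frame with columns
    ``distance`` (>= 1, in bins) and ``median``.
    """
    values = matrix.values
    valid = matrix.valid_mask
    n = values.shape[0]
    if max_distance is None:
        max_distance = n - 1
    rows = []
    for d in range(1, min(max_distance, n - 1) + 1):
        diag = np.diagonal(values, offset=d)
        ok = valid[:-d] & valid[d:]
        if ok.any():
            rows.append({"distance": d, "median": float(np.median(diag[ok]))})
    return pd.DataFrame(rows, columns=["distance", "median"])


def decay_curves(
    matrices: Mapping[str, BalancedMatrix | ContactMatrix],
    exclude_chroms: Sequence[str] = (),
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-chromosome decay curves and their cross-chromosome median.

    ``exclude_chroms`` drops chromosomes before aggregation (used to
    remove a chromosome with library-specific artefacts).
    """
    per_chrom = {
        chrom: distance_decay(m)
        for chrom, m in matrices.items()
        if chrom not in set(exclude_chroms)
    }
    if not per_chrom:
        raise ValueError("no chromosomes left after exclusion")
    merged = pd.concat(
        [df.assign(chrom=c) for c, df in per_chrom.items()], ignore_index=True
    )
    overall = (
        merged.groupby("distance")["median"].median().reset_index()
        .rename(columns={"median": "median_of_medians"})
    )
    return per_chrom, overall
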