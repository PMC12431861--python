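"""A/B compartment eigenvector selection and saddle construction.

Pipeline: expected-normalize the balanced map by distance, take the
Pearson correlation matrix over valid bins, extract the first three
principal eigenvectors, pick the one with the highest absolute Pearson
correlation with a phasing track (GC% or gene density surrogate), and
orient it so that correlation is positive (positive values = A).

The saddle assigns valid bins to equal-occupancy quantiles of the chosen
eigenvector (lowest = strongest B) and averages observed/expected over
every quantile pair, so the upper-left corner holds B-B and the
lower-right A-A preferences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .balance import BalancedMatrix
from .core import ContactMatrix, Track
from .insulation import expected_normalize

__all__ = ["CompartmentResult", "compartment_eigenvector", "saddle"]


@dataclass
class CompartmentResult:
    eigenvectors: np.ndarray          # 3 x n_bins, NaN at invalid bins
    chosen_index: int                 # 1-based
    chosen: Track
    correlation_with_phasing: float
    saddle: np.ndarray | None = None  # n_q x n_q observed/expected means
    quantile_edges: np.ndarray | None = None


def compartment_eigenvector(
    matrix: BalancedMatrix | ContactMatrix,
    phasing: Track,
    n_candidates: int = 3,
) -> CompartmentResult:
    """First three eigenvectors of the O/E Pearson map; pick by phasing."""
    values = matrix.values
    valid = matrix.valid_mask
    n = values.shape[0]
    if valid.sum() < 10:
        raise ValueError("need at least 10 valid bins")
    if phasing.n != n:
        raise ValueError("phasing track binning does not match matrix")

    oe = expected_normalize(values, valid)
    sub = oe[np.ix_(valid, valid)]
    sub = np.nan_to_num(sub, nan=1.0)
    corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr)

    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1][:n_candidates]

    full = np.full((n_candidates, n), np.nan)
    phase_valid = phasing.values[valid]
    rs = []
    for rank, col in enumerate(order):
        v = evecs[:, col]
        full[rank, valid] = v
        ok = ~np.isnan(phase_valid)
        r = stats.pearsonr(v[ok], phase_valid[ok]).statistic if ok.sum() > 2 else 0.0
        rs.append(float(r))
    best = int(np.argmax(np.abs(rs)))
    chosen_vals = full[best].copy()
    r_best = rs[best]
    if r_best < 0:  # orient positive-with-phasing
        chosen_vals = -chosen_vals
        full[best] = chosen_vals
        r_best = -r_best
    chosen = Track(chrom=phasing.chrom, step=phasing.step, values=chosen_vals)
    return CompartmentResult(
        eigenvectors=full,
        chosen_index=best + 1,
        chosen=chosen,
        correlation_with_phasing=r_best,
    )


def saddle(
    matrix: BalancedMatrix | ContactMatrix,
    result: CompartmentResult,
    n_q: int = 50,
) -> CompartmentResult:
    """Attach the n_q x n_q saddle matrix of O/E means by eigenvector quantile."""
    values = matrix.values
    valid = matrix.valid_mask
    ev = result.chosen.values
    ok = valid & ~np.isnan(ev)
    n_valid = int(ok.sum())
    if n_q > n_valid:
        raise ValueError(f"n_q={n_q} exceeds {n_valid} valid bins")

    oe = expected_normalize(values, valid)
    idx = np.nonzero(ok)[0]
    ranks = stats.rankdata(ev[idx], method="ordinal") - 1
    quant = (ranks * n_q // n_valid).astype(int)  # equal-occupancy bins

    sad = np.full((n_q, n_q), np.nan)
    groups = [idx[quant == q] for q in range(n_q)]
    for p in range(n_q):
        for q in range(p, n_q):
            block = oe[np.ix_(groups[p], groups[q])]
            vals = block[~np.isnan(block)]
            if vals.size:
                sad[p, q] = sad[q, p] = float(vals.mean())
    edges = np.quantile(ev[idx], np.linspace(0, 1, n_q + 1))
    result.saddle = sad
    result.quantile_edges = edges
    return result
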