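"""Loop quantification: APA, loop signal/strength, donut background,
loop score (LS), architectural classification and condition-specific calls.

The loop signal is the mean of the 5x5 pixel window around the loop
centroid of a balanced matrix; the loop strength is the sum of the same
window. The local background is the mean of up to 15 randomly drawn 5x5
squares whose centers sit on the Chebyshev ring of radius 8 around the
centroid (the annulus of the donut filter), excluding squares that leave
the matrix or touch the diagonal. LS = log2(signal / background); loops
with LS > 1 whose anchors carry convergently oriented CTCF motifs are
classified architectural.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .balance import BalancedMatrix
from .core import ContactMatrix, Loop

__all__ = [
    "LoopQuant",
    "ApaResult",
    "UnscoreableLoop",
    "loop_signal",
    "donut_candidates",
    "donut_background",
    "loop_score",
    "score_loops",
    "classify_architectural",
    "apa",
    "condition_specific_loops",
]

HALF = 2          # 5x5 windows
RING_RADIUS = 8   # Chebyshev distance of donut square centers
CORE_HALF = 4     # central 9x9 exclusion zone


class UnscoreableLoop(Exception):
    """Raised when a loop's windows cannot be evaluated on this matrix."""


@dataclass
class LoopQuant:
    loop: Loop
    signal_mean: float = float("nan")
    strength_sum: float = float("nan")
    background: float = float("nan")
    ls: float = float("nan")
    n_background_squares: int = 0
    rng_seed: int = 0
    scoreable: bool = True


@dataclass
class ApaResult:
    window_halfwidth: int
    mean_matrix: np.ndarray
    n_loops_used: int
    n_loops_dropped: int
    apa_score: float


def _window_stats(
    values: np.ndarray, valid: np.ndarray, ci: int, cj: int, half: int = HALF
) -> tuple[float, float]:
    """(mean, sum) of the (2*half+1)^2 window centred at (ci, cj).

    Masked cells contribute 0 to the sum and are excluded from the mean's
    denominator. Raises UnscoreableLoop if the window leaves the matrix or
    is entirely masked.
    """
    n = values.shape[0]
    if ci - half < 0 or cj - half < 0 or ci + half >= n or cj + half >= n:
        raise UnscoreableLoop(f"window at ({ci},{cj}) out of bounds")
    win = values[ci - half: ci + half + 1, cj - half: cj + half + 1]
    ok = np.outer(valid[ci - half: ci + half + 1], valid[cj - half: cj + half + 1])
    if not ok.any():
        raise UnscoreableLoop(f"window at ({ci},{cj}) fully masked")
    return float(win[ok].mean()), float(win[ok].sum())


def loop_signal(
    matrix: BalancedMatrix | ContactMatrix, loop: Loop
) -> tuple[float, float]:
    """Mean (loop signal) and sum (loop strength) of the 5x5 centroid window."""
    return _window_stats(
        matrix.values, matrix.valid_mask, loop.centroid_bin_i, loop.centroid_bin_j
    )


def donut_candidates(
    n_bins: int, ci: int, cj: int, ring_radius: int = RING_RADIUS
) -> list[tuple[int, int]]:
    """Centers (dx, dy offsets) of admissible background squares.

    Candidates are all offsets at Chebyshev distance exactly
    ``ring_radius`` from the centroid; a candidate is dropped when its 5x5
    square leaves the matrix, contains any cell on or below the diagonal,
    or overlaps the central 9x9 exclusion zone.
    """
    out = []
    r = ring_radius
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            if max(abs(dx), abs(dy)) != r:
                continue
            bi, bj = ci + dx, cj + dy
            if bi - HALF < 0 or bj - HALF < 0 or bi + HALF >= n_bins or bj + HALF >= n_bins:
                continue
            # reject squares crossing the diagonal (any cell with row >= col)
            if bi + HALF >= bj - HALF:
                continue
            # reject overlap with the central 9x9 core (possible for small radii)
            if max(abs(dx), abs(dy)) <= CORE_HALF + HALF:
                continue
            out.append((dx, dy))
    return out


def donut_background(
    matrix: BalancedMatrix | ContactMatrix,
    loop: Loop,
    n_samples: int = 15,
    rng: np.random.Generator | None = None,
    ring_radius: int = RING_RADIUS,
) -> tuple[float, int]:
    """Mean of per-square means over sampled donut squares.

    Squares are drawn uniformly without replacement; if fewer candidates
    than ``n_samples`` remain after filtering, all are used.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ci, cj = loop.centroid_bin_i, loop.centroid_bin_j
    cands = donut_candidates(matrix.n_bins, ci, cj, ring_radius)
    if not cands:
        raise UnscoreableLoop(f"no donut candidates for loop at ({ci},{cj})")
    k = min(n_samples, len(cands))
    chosen_idx = rng.choice(len(cands), size=k, replace=False)
    means = []
    for idx in chosen_idx:
        dx, dy = cands[idx]
        try:
            m, _ = _window_stats(matrix.values, matrix.valid_mask, ci + dx, cj + dy)
        except UnscoreableLoop:
            continue
        means.append(m)
    if not means:
        raise UnscoreableLoop(f"all donut squares masked for loop at ({ci},{cj})")
    return float(np.mean(means)), len(means)


def loop_score(
    matrix: BalancedMatrix | ContactMatrix,
    loop: Loop,
    rng: np.random.Generator | None = None,
    eps: float = 1e-9,
    n_samples: int = 15,
    rng_seed: int = 0,
) -> LoopQuant:
    """LS = log2((signal_mean + eps) / (background + eps))."""
    quant = LoopQuant(loop=loop, rng_seed=rng_seed)
    try:
        quant.signal_mean, quant.strength_sum = loop_signal(matrix, loop)
        quant.background, quant.n_background_squares = donut_background(
            matrix, loop, n_samples=n_samples, rng=rng
        )
    except UnscoreableLoop:
        quant.scoreable = False
        return quant
    quant.ls = float(
        np.log2((quant.signal_mean + eps) / (quant.background + eps))
    )
    return quant


def score_loops(
    matrix: BalancedMatrix | ContactMatrix,
    loops: Sequence[Loop],
    seed: int = 0,
    eps: float = 1e-9,
    n_samples: int = 15,
) -> list[LoopQuant]:
    """Score every loop with a per-loop RNG stream derived from
    (seed, loop index), so results are independent of loop-list order."""
    quants = []
    for k, loop in enumerate(loops):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        quants.append(
            loop_score(matrix, loop, rng=rng, eps=eps, n_samples=n_samples,
                       rng_seed=k)
        )
    return quants


def classify_architectural(
    quants: Sequence[LoopQuant],
    anchor_motifs: Sequence[tuple[bool, bool]],
    ls_threshold: float = 1.0,
) -> list[LoopQuant]:
    """Architectural = LS strictly above threshold AND convergent motifs.

    ``anchor_motifs[k]`` is (forward motif on anchor5, reverse motif on
    anchor3) for loop k; missing annotation means non-architectural.
    """
    if len(quants) != len(anchor_motifs):
        raise ValueError("one motif annotation required per loop")
    return [
        q
        for q, (fwd5, rev3) in zip(quants, anchor_motifs)
        if q.scoreable and q.ls > ls_threshold and fwd5 and rev3
    ]


def apa(
    matrix: BalancedMatrix | ContactMatrix,
    loops: Sequence[Loop],
    halfwidth: int = 10,
    min_distance_bp: int = 100_000,
) -> ApaResult:
    """Aggregate peak analysis over loops spanning more than the cutoff.

    The APA score is the center pixel of the mean window divided by the
    mean of its lower-left 6x6 corner (the short-distance corner).
    """
    values = matrix.values
    n = matrix.n_bins
    h = halfwidth
    acc = np.zeros((2 * h + 1, 2 * h + 1))
    used = dropped = 0
    for loop in loops:
        if loop.span_bp <= min_distance_bp:
            dropped += 1
            continue
        ci, cj = loop.centroid_bin_i, loop.centroid_bin_j
        if ci - h < 0 or cj - h < 0 or ci + h >= n or cj + h >= n:
            dropped += 1
            continue
        acc += values[ci - h: ci + h + 1, cj - h: cj + h + 1]
        used += 1
    if used == 0:
        raise ValueError("no eligible loops for APA")
    mean_matrix = acc / used
    corner = mean_matrix[-6:, :6]
    apa_score = float(mean_matrix[h, h] / corner.mean())
    return ApaResult(
        window_halfwidth=h,
        mean_matrix=mean_matrix,
        n_loops_used=used,
        n_loops_dropped=dropped,
        apa_score=apa_score,
    )


def condition_specific_loops(
    quants_by_sample: Mapping[str, Sequence[LoopQuant]],
    groups: tuple[Sequence[str], Sequence[str]],
) -> tuple[list[int], list[int]]:
    """Indices of loops consistently weaker / stronger in the second group.

    A loop is *weakened* iff for every (reference sample w, alternate
    sample m) pair both the loop strength and the LS are strictly higher
    in w; *strengthened* is the mirror. Ties break consistency.
    """
    wt_ids, mut_ids = groups
    if not wt_ids or not mut_ids:
        raise ValueError("both sample groups must be non-empty")
    n_loops = len(next(iter(quants_by_sample.values())))
    for s, qs in quants_by_sample.items():
        if len(qs) != n_loops:
            raise ValueError(f"sample {s} scored a different loop list")

    weakened, strengthened = [], []
    for k in range(n_loops):
        if not all(quants_by_sample[s][k].scoreable
                   for s in list(wt_ids) + list(mut_ids)):
            continue
        pairs = [
            (quants_by_sample[w][k], quants_by_sample[m][k])
            for w in wt_ids
            for m in mut_ids
        ]
        if all(qw.strength_sum > qm.strength_sum and qw.ls > qm.ls
               for qw, qm in pairs):
            weakened.append(k)
        elif all(qm.strength_sum > qw.strength_sum and qm.ls > qw.ls
                 for qw, qm in pairs):
            strengthened.append(k)
    return weakened, strengthened
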