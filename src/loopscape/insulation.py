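"""Insulation-score track, insulation-peak calling and differential IS.

For each bin ``i`` three 3x3 squares of the (optionally expected-
normalized) balanced matrix are read: two intra-domain squares U and D
centred on the diagonal at ``(i-d, i-d)`` and ``(i+d, i+d)``, and the
cross square X centred at ``(i-d, i+d)``, whose center lies ``2d`` bins
off the diagonal (d=5 puts it 10 bins out at 10-kb resolution). The
insulation score is

    IS(i) = log2( ((U + D) / 2 + eps) / (X + eps) )

so featureless matrices score ~0 and contact insulators score high.
Peaks of insulation are maximal runs of at least ``min_run`` consecutive
bins with IS strictly above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .balance import BalancedMatrix
from .core import ContactMatrix, Track

__all__ = [
    "InsulationPeak",
    "expected_normalize",
    "insulation_track",
    "insulation_peaks",
    "insulation_delta",
]


@dataclass
class InsulationPeak:
    start_bin: int
    end_bin: int          # inclusive
    mean_is: float
    summit_bin: int       # bin of maximum IS in the run; ties -> leftmost
    delta_is: float = float("nan")

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


def expected_normalize(
    values: np.ndarray, valid: np.ndarray
) -> np.ndarray:
    """Observed/expected with the expected = per-distance mean over valid pairs.

    Cells involving invalid bins become NaN.
    """
    n = values.shape[0]
    oe = np.full_like(values, np.nan, dtype=float)
    for d in range(n):
        diag = np.diagonal(values, offset=d)
        ok = valid[: n - d] & valid[d:]
        if not ok.any():
            continue
        exp = diag[ok].mean()
        if exp <= 0:
            continue
        idx = np.nonzero(ok)[0]
        oe[idx, idx + d] = diag[idx] / exp
        oe[idx + d, idx] = diag[idx] / exp
    return oe


def _square_mean(oe: np.ndarray, ci: int, cj: int, half: int) -> float:
    win = oe[ci - half: ci + half + 1, cj - half: cj + half + 1]
    ok = ~np.isnan(win)
    if not ok.any():
        return float("nan")
    return float(win[ok].mean())


def insulation_track(
    matrix: BalancedMatrix | ContactMatrix,
    s: int = 3,
    d: int = 5,
    expected_normalize_first: bool = True,
    eps: float = 1e-9,
) -> Track:
    """Per-bin insulation score; NaN where the squares leave the matrix."""
    values = matrix.values
    valid = matrix.valid_mask
    n = values.shape[0]
    half = s // 2
    oe = expected_normalize(values, valid) if expected_normalize_first else np.where(
        np.outer(valid, valid), values, np.nan
    )
    is_vals = np.full(n, np.nan)
    reach = d + half
    for i in range(reach, n - reach):
        if not valid[i]:
            continue
        u = _square_mean(oe, i - d, i - d, half)
        dn = _square_mean(oe, i + d, i + d, half)
        x = _square_mean(oe, i - d, i + d, half)
        if np.isnan(u) or np.isnan(dn) or np.isnan(x):
            continue
        is_vals[i] = np.log2(((u + dn) / 2.0 + eps) / (x + eps))
    return Track(chrom=matrix.base.chrom if isinstance(matrix, BalancedMatrix)
                 else matrix.chrom,
                 step=matrix.base.resolution if isinstance(matrix, BalancedMatrix)
                 else matrix.resolution,
                 values=is_vals)


def insulation_peaks(
    track: Track, threshold: float = 0.75, min_run: int = 3
) -> list[InsulationPeak]:
    """Maximal runs of >= min_run consecutive bins with IS > threshold.

    Missing (NaN) bins break runs; the comparison is strict.
    """
    vals = track.values
    peaks: list[InsulationPeak] = []
    run_start = None
    for i in range(len(vals) + 1):
        above = i < len(vals) and not np.isnan(vals[i]) and vals[i] > threshold
        if above and run_start is None:
            run_start = i
        elif not above and run_start is not None:
            run_end = i - 1
            if run_end - run_start + 1 >= min_run:
                run = vals[run_start: run_end + 1]
                peaks.append(
                    InsulationPeak(
                        start_bin=run_start,
                        end_bin=run_end,
                        mean_is=float(run.mean()),
                        summit_bin=run_start + int(np.argmax(run)),
                    )
                )
            run_start = None
    return peaks


def insulation_delta(
    peaks: list[InsulationPeak], track_ref: Track, track_alt: Track
) -> list[InsulationPeak]:
    """Attach per-peak mean IS difference (reference minus alternate).

    Bins missing in either track are excluded from the mean; a peak with
    no co-defined bin gets NaN.
    """
    if track_ref.step != track_alt.step or len(track_ref.values) != len(
        track_alt.values
    ):
        raise ValueError("tracks must share binning")
    out = []
    for p in peaks:
        ref = track_ref.values[p.start_bin: p.end_bin + 1]
        alt = track_alt.values[p.start_bin: p.end_bin + 1]
        ok = ~np.isnan(ref) & ~np.isnan(alt)
        delta = float((ref[ok] - alt[ok]).mean()) if ok.any() else float("nan")
        out.append(
            InsulationPeak(
                start_bin=p.start_bin,
                end_bin=p.end_bin,
                mean_is=p.mean_is,
                summit_bin=p.summit_bin,
                delta_is=delta,
            )
        )
    return out
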