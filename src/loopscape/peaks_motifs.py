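"""PWM scanning, summit motif orientation, peak signal, congruent-change
differential calls, CpG counting, enhancer/promoter definitions and
loop-domain enhancer-flank counting.

Scoring convention: a hit's raw score is the sum over motif positions of
``log(p_base / background_base)``; its relative score rescales that
between the PWM's minimum and maximum attainable raw scores, matching the
"minimum 80% of the best possible score" hit-calling convention. N bases
score as background (log-ratio 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import GenomicInterval, Loop, MotifHit, Peak, PWM, Track

__all__ = [
    "DifferentialCall",
    "pwm_scan",
    "best_motif_at_peak",
    "peak_signal",
    "congruent_change_peaks",
    "count_cpg",
    "define_promoters",
    "annotate_peak_promoter",
    "define_enhancers",
    "smallest_containing_domain",
    "count_flank_enhancers",
    "nearest_distance",
    "annotate_loop_anchor_motifs",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class DifferentialCall:
    peak: Peak
    klass: str                      # gain / loss / unchanged
    change_fractions: list[float]   # per replicate pair, (alt-ref)/ref


def _encode(sequence: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, 4) for b in sequence.upper()], dtype=int)


def _scan_one_strand(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    """Raw log-odds score of every window start on the given encoding."""
    w = pwm.width
    # row 4 = N: scores as background, i.e. log ratio 0
    lod = np.vstack([pwm.log_odds, np.zeros(w)])
    n_win = codes.size - w + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    for k in range(w):
        scores += lod[codes[k: k + n_win], k]
    return scores


def pwm_scan(
    sequence: str,
    pwm: PWM,
    min_relative: float = 0.8,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All positions (both strands) with relative score >= min_relative.

    Reverse-strand hits are reported at their forward-strand window start
    with strand "-". Hits come back sorted by position, "+" before "-".
    """
    codes = _encode(sequence)
    span = pwm.max_score - pwm.min_score
    hits: list[MotifHit] = []
    strands = [("+", pwm)]
    if both_strands:
        strands.append(("-", pwm.reverse_complement()))
    for strand, mat in strands:
        raw = _scan_one_strand(codes, mat)
        rel = (raw - pwm.min_score) / span
        for pos in np.nonzero(rel >= min_relative)[0]:
            hits.append(
                MotifHit(
                    position=int(pos),
                    strand=strand,
                    raw_score=float(raw[pos]),
                    relative_score=float(rel[pos]),
                )
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def best_motif_at_peak(
    peak: Peak,
    genome: Mapping[str, str],
    pwm: PWM,
    window_bp: int = 50,
    min_relative: float = 0.8,
) -> MotifHit | None:
    """Best-scoring motif in the window centred at the peak summit.

    The window is ``[summit - window_bp//2, summit + window_bp//2)``,
    clipped to the chromosome. Ties break to the leftmost hit, then to
    the + strand. Returns None when no hit reaches the threshold.
    """
    seq = genome[peak.interval.chrom]
    half = window_bp // 2
    w_start = max(0, peak.summit - half)
    w_end = min(len(seq), peak.summit + half)
    hits = pwm_scan(seq[w_start:w_end], pwm, min_relative=min_relative)
    if not hits:
        return None
    best = max(hits, key=lambda h: (h.raw_score, -h.position, h.strand == "+"))
    return MotifHit(
        position=w_start + best.position,
        strand=best.strand,
        raw_score=best.raw_score,
        relative_score=best.relative_score,
    )


def peak_signal(track: Track, peak: Peak, mode: str = "auc_200bp") -> float:
    """Coverage summary at a peak summit.

    ``auc_200bp``: sum of per-base values over summit +/- 100 bp, missing
    bases counting 0. ``mean_100bp``: mean over summit +/- 50 bp with
    missing bases excluded. NaN if the window lies fully off-chromosome.
    """
    if mode == "auc_200bp":
        half, agg = 100, "sum"
    elif mode == "mean_100bp":
        half, agg = 50, "mean"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = peak.summit - half, peak.summit + half
    idx_lo = max(0, (lo - track.start) // track.step)
    idx_hi = min(track.n, -(-(hi - track.start) // track.step))
    if idx_hi <= idx_lo:
        return float("nan")
    window = track.values[idx_lo:idx_hi]
    if agg == "sum":
        return float(np.nansum(window) * track.step)
    ok = ~np.isnan(window)
    return float(window[ok].mean()) if ok.any() else float("nan")


def congruent_change_peaks(
    peaks: Sequence[Peak],
    signals_ref: np.ndarray,
    signals_alt: np.ndarray,
    min_change: float = 0.25,
) -> list[DifferentialCall]:
    """Classify peaks by replicate-congruent signal change.

    ``signals_ref`` / ``signals_alt`` are (n_peaks, n_replicates) arrays
    paired by replicate index. Per pair, a gain needs
    ``alt >= (1 + min_change) * ref`` and a loss
    ``alt <= (1 - min_change) * ref``; the peak is classed gain or loss
    only when every replicate pair agrees, otherwise unchanged. A zero
    reference with positive alternate counts as a gain.
    """
    ref = np.atleast_2d(np.asarray(signals_ref, dtype=float))
    alt = np.atleast_2d(np.asarray(signals_alt, dtype=float))
    if ref.shape != alt.shape:
        raise ValueError("replicate counts differ between conditions")
    if ref.shape[0] != len(peaks):
        raise ValueError("one signal row required per peak")
    calls = []
    for k, peak in enumerate(peaks):
        gains = losses = 0
        fracs = []
        for r, a in zip(ref[k], alt[k]):
            if r == 0:
                fracs.append(float("inf") if a > 0 else 0.0)
                if a > 0:
                    gains += 1
                continue
            fracs.append((a - r) / r)
            if a >= (1 + min_change) * r:
                gains += 1
            elif a <= (1 - min_change) * r:
                losses += 1
        n = ref.shape[1]
        klass = "gain" if gains == n else "loss" if losses == n else "unchanged"
        calls.append(DifferentialCall(peak=peak, klass=klass, change_fractions=fracs))
    return calls


def count_cpg(sequence: str) -> int:
    """Number of CG dinucleotide occurrences."""
    s = sequence.upper()
    return sum(1 for i in range(len(s) - 1) if s[i: i + 2] == "CG")


def define_promoters(
    tss_list: Sequence[tuple[str, int]], flank_bp: int = 500
) -> list[GenomicInterval]:
    """Promoter intervals [tss - flank, tss + flank), clipped at zero."""
    return [
        GenomicInterval(chrom, max(0, tss - flank_bp), tss + flank_bp)
        for chrom, tss in tss_list
    ]


def annotate_peak_promoter(
    peak: Peak, tss_list: Sequence[tuple[str, int]], flank_bp: int = 3000
) -> bool:
    """True when the peak overlaps any TSS +/- flank window by >= 1 bp."""
    return any(
        peak.interval.overlaps(p) for p in define_promoters(tss_list, flank_bp)
    )


def define_enhancers(
    open_peaks: Sequence[Peak],
    acetyl_peaks: Sequence[Peak],
    promoters: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Open-chromatin peaks overlapping acetylation but not promoters."""
    out = []
    for p in open_peaks:
        iv = p.interval
        if not any(iv.overlaps(a.interval) for a in acetyl_peaks):
            continue
        if any(iv.overlaps(pr) for pr in promoters):
            continue
        out.append(iv)
    return out


def smallest_containing_domain(
    point: tuple[str, int], loops: Sequence[Loop]
) -> Loop | None:
    """Smallest loop domain (anchor-midpoint span) containing the point.

    The domain is the closed interval between the anchor midpoints; ties
    on span break to the leftmost anchor5.
    """
    chrom, pos = point
    best: Loop | None = None
    for lp in loops:
        if lp.chrom != chrom:
            continue
        if not (lp.anchor5.midpoint <= pos <= lp.anchor3.midpoint):
            continue
        if (
            best is None
            or lp.span_bp < best.span_bp
            or (lp.span_bp == best.span_bp
                and lp.anchor5.start < best.anchor5.start)
        ):
            best = lp
    return best


def count_flank_enhancers(
    domain: Loop,
    enhancers: Sequence[GenomicInterval],
    flank_bp: int = 500_000,
) -> int:
    """Summed enhancer count in the two flanks of a loop domain.

    Flanks are [domain_start - flank, domain_start) and
    [domain_end, domain_end + flank); an enhancer overlapping both flanks
    counts once per flank. Enhancers inside the domain body contribute 0.
    """
    start, end = domain.anchor5.midpoint, domain.anchor3.midpoint
    chrom = domain.chrom
    left = GenomicInterval(chrom, max(0, start - flank_bp), start) \
        if start > 0 else None
    right = GenomicInterval(chrom, end, end + flank_bp)
    total = 0
    for e in enhancers:
        if left is not None and e.overlaps(left):
            total += 1
        if e.overlaps(right):
            total += 1
    return total


def nearest_distance(
    query_intervals: Sequence[GenomicInterval],
    subject_intervals: Sequence[GenomicInterval],
) -> np.ndarray:
    """Midpoint distance to the nearest same-chromosome subject.

    Subjects identical to the query (same coordinates) are excluded; NaN
    when no subject remains on the chromosome.
    """
    out = np.full(len(query_intervals), np.nan)
    for k, q in enumerate(query_intervals):
        dists = [
            abs(q.midpoint - s.midpoint)
            for s in subject_intervals
            if s.chrom == q.chrom
            and not (s.start == q.start and s.end == q.end)
        ]
        if dists:
            out[k] = min(dists)
    return out


def annotate_loop_anchor_motifs(
    loops: Sequence[Loop],
    peaks: Sequence[Peak],
    motif_by_peak: Sequence[MotifHit | None],
) -> list[tuple[bool, bool]]:
    """Per-loop (forward motif on anchor5, reverse motif on anchor3).

    A loop anchor carries an orientation when it overlaps at least one
    peak whose best summit motif has that strand.
    """
    if len(peaks) != len(motif_by_peak):
        raise ValueError("one motif entry required per peak")
    ann = []
    for lp in loops:
        fwd5 = rev3 = False
        for pk, hit in zip(peaks, motif_by_peak):
            if hit is None:
                continue
            if pk.interval.overlaps(lp.anchor5) and hit.strand == "+":
                fwd5 = True
            if pk.interval.overlaps(lp.anchor3) and hit.strand == "-":
                rev3 = True
        ann.append((fwd5, rev3))
    return ann
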