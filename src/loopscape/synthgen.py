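"""Synthetic Hi-C, track, peak and sequence generation with known truth.

The contact-map model composes, per bin pair ``(i, j)``:

* power-law distance decay ``A * (|i-j| + 1) ** -alpha``,
* TAD boundaries that attenuate contacts straddling the boundary bin by a
  factor ``gamma`` in (0, 1],
* focal loops as isotropic Gaussian bumps of peak amplitude ``lam`` and
  spread ``sigma`` (in bins) at the anchor bin pair,
* a two-compartment checkerboard: pairs with different A/B labels are
  scaled by an affinity ``rho`` in (0, 1],
* multiplicative per-bin biases ``b_i * b_j`` (mappability/GC analogue).

The expected map is scaled so the upper triangle sums to ``depth``, and
raw counts are drawn ``Poisson(e_ij)`` for ``i <= j`` then mirrored.
Every generator takes an explicit seed and is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ContactMatrix, GenomicInterval, Loop, Peak, PeakSet, PWM, Track

__all__ = [
    "LoopSpec",
    "BoundarySpec",
    "SimParams",
    "SyntheticTruth",
    "expected_matrix",
    "simulate_contact_map",
    "simulate_phasing_track",
    "simulate_peaks_and_genome",
]


@dataclass(frozen=True)
class LoopSpec:
    bin_i: int
    bin_j: int
    amplitude: float = 4.0   # fold enrichment at the loop centroid
    spread: float = 1.0      # Gaussian sigma in bins


@dataclass(frozen=True)
class BoundarySpec:
    bin: int
    attenuation: float = 0.2  # gamma: multiplier for straddling contacts


@dataclass
class SimParams:
    """Parameters of the synthetic contact-map generator."""

    n_bins: int = 300
    resolution: int = 10_000
    chrom: str = "chrS"
    decay_exponent: float = 1.0
    base_level: float = 1.0
    loops: Sequence[LoopSpec] = field(default_factory=list)
    boundaries: Sequence[BoundarySpec] = field(default_factory=list)
    compartment_labels: np.ndarray | None = None  # per-bin "A"/"B"
    compartment_affinity: float = 1.0             # rho
    biases: np.ndarray | None = None              # per-bin positive b_i
    depth: float = 1e6
    seed: int = 0

    def validate(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.decay_exponent <= 0 or self.base_level <= 0:
            raise ValueError("decay exponent and base level must be positive")
        for lp in self.loops:
            if not (0 <= lp.bin_i < self.n_bins and 0 <= lp.bin_j < self.n_bins):
                raise ValueError(f"loop {lp} outside [0, {self.n_bins})")
            if lp.bin_i >= lp.bin_j:
                raise ValueError(f"loop {lp}: centroid on/below the diagonal")
        for bd in self.boundaries:
            if not 0 < bd.attenuation <= 1:
                raise ValueError("boundary attenuation must be in (0, 1]")
        if not 0 < self.compartment_affinity <= 1:
            raise ValueError("compartment affinity must be in (0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated contact map."""

    params: SimParams
    expected: np.ndarray
    loops: list[Loop]
    boundaries: list[GenomicInterval]
    compartment_labels: np.ndarray | None


def expected_matrix(params: SimParams) -> np.ndarray:
    """Noise-free expected map, scaled so the upper triangle sums to depth."""
    n = params.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    e = params.base_level * (dist + 1.0) ** (-params.decay_exponent)

    for bd in params.boundaries:
        # attenuate only contacts straddling the boundary bin
        left = idx < bd.bin
        right = idx > bd.bin
        straddle = left[:, None] & right[None, :]
        factor = np.where(straddle | straddle.T, bd.attenuation, 1.0)
        e = e * factor

    for lp in params.loops:
        di = idx[:, None] - lp.bin_i
        dj = idx[None, :] - lp.bin_j
        bump = np.exp(-(di**2 + dj**2) / (2.0 * lp.spread**2))
        # mirror the bump across the diagonal so e stays symmetric
        e = e * (1.0 + (lp.amplitude - 1.0) * (bump + bump.T))

    if params.compartment_labels is not None:
        labels = np.asarray(params.compartment_labels)
        same = labels[:, None] == labels[None, :]
        e = e * np.where(same, 1.0, params.compartment_affinity)

    if params.biases is not None:
        b = np.asarray(params.biases, dtype=float)
        e = e * b[:, None] * b[None, :]

    e = e * (params.depth / np.triu(e).sum())
    return e


def simulate_contact_map(params: SimParams) -> tuple[ContactMatrix, SyntheticTruth]:
    """Draw a Poisson contact map from the expected model."""
    params.validate()
    e = expected_matrix(params)
    rng = np.random.default_rng(params.seed)
    n = params.n_bins
    upper = np.triu(rng.poisson(e).astype(float))
    counts = upper + np.triu(upper, k=1).T
    matrix = ContactMatrix(
        chrom=params.chrom, resolution=params.resolution, values=counts
    )
    res = params.resolution
    loops = [
        Loop.from_anchors(
            GenomicInterval(params.chrom, lp.bin_i * res, (lp.bin_i + 1) * res),
            GenomicInterval(params.chrom, lp.bin_j * res, (lp.bin_j + 1) * res),
            resolution=res,
        )
        for lp in params.loops
    ]
    boundaries = [
        GenomicInterval(params.chrom, bd.bin * res, (bd.bin + 1) * res)
        for bd in params.boundaries
    ]
    truth = SyntheticTruth(
        params=params,
        expected=e,
        loops=loops,
        boundaries=boundaries,
        compartment_labels=(
            None if params.compartment_labels is None
            else np.asarray(params.compartment_labels)
        ),
    )
    return matrix, truth


def simulate_phasing_track(
    params: SimParams, noise_sd: float = 0.0, seed: int | None = None
) -> Track:
    """A per-bin phasing signal (GC%-like) correlated with A/B labels.

    Labels encode as +1 (A) / -1 (B); Gaussian noise of the given standard
    deviation controls the correlation magnitude (0 = perfect phasing).
    """
    if params.compartment_labels is None:
        raise ValueError("params carry no compartment labels")
    labels = np.asarray(params.compartment_labels)
    values = np.where(labels == "A", 1.0, -1.0)
    if noise_sd > 0:
        rng = np.random.default_rng(params.seed if seed is None else seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return Track(chrom=params.chrom, step=params.resolution, values=values)


def _sample_motif(pwm: PWM, rng: np.random.Generator) -> str:
    """Sample one sequence from the PWM's per-column distributions."""
    bases = np.array(list("ACGT"))
    cols = [rng.choice(4, p=pwm.probabilities[:, k]) for k in range(pwm.width)]
    return "".join(bases[cols])


_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def simulate_peaks_and_genome(
    n_peaks: int,
    genome_length: int,
    pwm: PWM,
    planted_fraction: float = 1.0,
    fold_change_spec: Mapping[str, tuple[float, float]] | None = None,
    replicates: int = 2,
    seed: int = 0,
    peak_width: int = 400,
    base_signal: float = 10.0,
    noise_sigma: float = 0.1,
    chrom: str = "chrS",
) -> tuple[dict[str, str], PeakSet, pd.DataFrame]:
    """Random genome + peaks with planted motifs and replicate signals.

    ``fold_change_spec`` maps a truth class to ``(fraction, fold)``; the
    default plants 25% gains (x2), 25% losses (x0.5) and 50% stable peaks.
    Per-sample signals are lognormal noise around ``base_signal`` for the
    reference replicates and around ``fold * base_signal`` for the
    alternate replicates (``noise_sigma`` is the sigma of the log-normal;
    0 gives the noiseless limit).
    """
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must be in [0, 1]")
    if pwm.width >= peak_width:
        raise ValueError("motif wider than peak")
    if fold_change_spec is None:
        fold_change_spec = {
            "gain": (0.25, 2.0), "loss": (0.25, 0.5), "stable": (0.5, 1.0)
        }
    rng = np.random.default_rng(seed)
    genome = "".join(rng.choice(list("ACGT"), size=genome_length))

    spacing = genome_length // (n_peaks + 1)
    if spacing <= peak_width:
        raise ValueError("genome too short for the requested peaks")

    classes: list[str] = []
    for name, (frac, _fold) in fold_change_spec.items():
        classes.extend([name] * int(round(frac * n_peaks)))
    classes = (classes + ["stable"] * n_peaks)[:n_peaks]
    rng.shuffle(classes)

    n_planted = int(round(planted_fraction * n_peaks))
    planted = np.zeros(n_peaks, dtype=bool)
    planted[rng.choice(n_peaks, size=n_planted, replace=False)] = True

    genome_list = list(genome)
    peaks: list[Peak] = []
    rows = []
    for k in range(n_peaks):
        summit = (k + 1) * spacing
        start = summit - peak_width // 2
        end = start + peak_width
        strand = "."
        if planted[k]:
            motif = _sample_motif(pwm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                motif = reverse_complement(motif)
            m0 = summit - pwm.width // 2
            genome_list[m0:m0 + pwm.width] = list(motif)
        fold = dict(fold_change_spec)[classes[k]][1]
        signals: dict[str, float] = {}
        for r in range(replicates):
            noise_ref = np.exp(rng.normal(0, noise_sigma)) if noise_sigma > 0 else 1.0
            noise_alt = np.exp(rng.normal(0, noise_sigma)) if noise_sigma > 0 else 1.0
            signals[f"ref_{r + 1}"] = base_signal * noise_ref
            signals[f"alt_{r + 1}"] = base_signal * fold * noise_alt
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, end),
                summit=summit,
                signal_by_sample=signals,
                name=f"peak_{k}",
            )
        )
        rows.append(
            {"peak": f"peak_{k}", "class": classes[k],
             "planted": bool(planted[k]), "strand": strand, "summit": summit}
        )
    truth = pd.DataFrame(rows)
    return {chrom: "".join(genome_list)}, PeakSet(peaks=peaks), truth
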