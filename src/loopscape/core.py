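"""Core domain types shared across the pipeline.

All genomic coordinates in this package are 0-based, half-open (BED
convention). Conversion to and from 1-based inclusive dialects is done
exclusively through :func:`to_one_based` / :func:`from_one_based`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "ContactMatrix",
    "Loop",
    "LoopSet",
    "Peak",
    "PeakSet",
    "Track",
    "PWM",
    "MotifHit",
    "to_one_based",
    "from_one_based",
]


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start + 1, end


def from_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start - 1, end


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ContactMatrix:
    """One chromosome's binned symmetric contact map.

    ``values`` is a dense ``n_bins x n_bins`` non-negative symmetric array.
    ``valid_mask`` flags mappable bins; rows/columns of invalid bins are
    all-zero. By default a bin is invalid when its raw marginal is zero.
    """

    chrom: str
    resolution: int
    values: np.ndarray
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if np.any(self.values < 0):
            raise ValueError("contact matrix must be non-negative")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("contact matrix must be symmetric")
        if self.valid_mask is None:
            self.valid_mask = self.values.sum(axis=0) > 0
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (self.n_bins,):
            raise ValueError("valid_mask length must equal n_bins")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_of(self, pos_bp: int) -> int:
        return pos_bp // self.resolution


@dataclass(frozen=True)
class Loop:
    """A chromatin loop joining two anchors on the same chromosome.

    Centroid bins are the bins containing the anchor midpoints at the
    working matrix resolution; the invariant ``centroid_bin_i <
    centroid_bin_j`` is enforced by ordering the anchors.
    """

    anchor5: GenomicInterval
    anchor3: GenomicInterval
    centroid_bin_i: int
    centroid_bin_j: int

    def __post_init__(self) -> None:
        if self.anchor5.chrom != self.anchor3.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.anchor5.midpoint >= self.anchor3.midpoint:
            raise ValueError("anchor5 midpoint must precede anchor3 midpoint")
        if self.centroid_bin_i >= self.centroid_bin_j:
            raise ValueError("require centroid_bin_i < centroid_bin_j")

    @classmethod
    def from_anchors(
        cls, anchor5: GenomicInterval, anchor3: GenomicInterval, resolution: int
    ) -> "Loop":
        if anchor5.midpoint > anchor3.midpoint:
            anchor5, anchor3 = anchor3, anchor5
        return cls(
            anchor5=anchor5,
            anchor3=anchor3,
            centroid_bin_i=anchor5.midpoint // resolution,
            centroid_bin_j=anchor3.midpoint // resolution,
        )

    @property
    def chrom(self) -> str:
        return self.anchor5.chrom

    @property
    def span_bp(self) -> int:
        """Loop-domain span: distance between the anchor midpoints."""
        return self.anchor3.midpoint - self.anchor5.midpoint


@dataclass
class LoopSet:
    """A list of loops plus bookkeeping from the reader."""

    loops: list[Loop]
    n_interchromosomal_skipped: int = 0

    def __iter__(self):
        return iter(self.loops)

    def __len__(self) -> int:
        return len(self.loops)

    def __getitem__(self, i):
        return self.loops[i]


@dataclass
class Peak:
    """A peak interval with a summit and optional per-sample signals."""

    interval: GenomicInterval
    summit: int
    signal_by_sample: dict[str, float] = field(default_factory=dict)
    name: str = "."

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"[{self.interval.start},{self.interval.end})"
            )


@dataclass
class PeakSet:
    peaks: list[Peak]

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]


@dataclass
class Track:
    """A per-bin (or per-base, step=1) signal vector on one chromosome.

    Missing values are NaN, never silently zero.
    """

    chrom: str
    step: int
    values: np.ndarray
    start: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("track values must be one-dimensional")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def value_at(self, pos_bp: int) -> float:
        idx = (pos_bp - self.start) // self.step
        if idx < 0 or idx >= self.n:
            return float("nan")
        return float(self.values[idx])


_ALPHABET = "ACGT"


@dataclass
class PWM:
    """Position weight matrix over {A,C,G,T} (rows in that order).

    ``probabilities`` is 4 x width with columns summing to one after
    pseudocount regularization; scoring uses log-likelihood ratios against
    ``background``.
    """

    probabilities: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[0] != 4:
            raise ValueError("probabilities must be 4 x width")
        if not np.allclose(self.probabilities.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probabilities.shape[1]

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.01,
                    background: Sequence[float] | None = None) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=0)
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        return cls(probabilities=probs, background=bg)

    @property
    def log_odds(self) -> np.ndarray:
        """4 x width matrix of log(p / background) scores."""
        return np.log(self.probabilities / self.background[:, None])

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[k] for k in self.probabilities.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(
            probabilities=self.probabilities[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
        )


@dataclass(frozen=True)
class MotifHit:
    """A scored, stranded PWM hit in forward-strand coordinates."""

    position: int
    strand: str
    raw_score: float
    relative_score: float
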