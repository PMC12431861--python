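"""Readers and writers for the external formats the pipeline touches.

Contact maps travel as sparse triplet text (``bin_i<TAB>bin_j<TAB>value``)
with an optional HiC-Pro-style sidecar bin table; loops as BEDPE; peaks as
BED/narrowPeak; signal as bedGraph; sequence as FASTA; motifs as JASPAR PFM.
All writers emit deterministic line order so outputs are checksummable.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    PWM,
    ContactMatrix,
    GenomicInterval,
    Loop,
    LoopSet,
    Peak,
    PeakSet,
    Track,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_contact_matrix",
    "write_contact_matrix",
    "read_bedpe",
    "write_bedpe",
    "read_bed_peaks",
    "write_bed_peaks",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_pfm",
    "write_pfm",
]


# ---------------------------------------------------------------------------
# contact matrices

def read_contact_matrix(
    path: str | Path,
    n_bins: int | None = None,
    bins_path: str | Path | None = None,
    chrom: str = "chrS",
    resolution: int = 10_000,
) -> ContactMatrix:
    """Read a sparse triplet-text contact matrix into a dense symmetric array.

    Upper- or lower-triangle entries are mirrored; duplicate ``(i, j)``
    records are summed; bins absent from the input stay zero. ``n_bins``
    may instead come from a sidecar bin table (BED-like:
    ``chrom start end index``), which also fixes ``chrom`` and
    ``resolution``.
    """
    path = Path(path)
    if bins_path is not None:
        bins = pd.read_csv(
            bins_path, sep="\t", header=None,
            names=["chrom", "start", "end", "index"],
        )
        n_bins = len(bins)
        chrom = str(bins["chrom"].iloc[0])
        resolution = int(bins["end"].iloc[0] - bins["start"].iloc[0])
    if n_bins is None:
        raise ValueError("n_bins or bins_path is required")

    values = np.zeros((n_bins, n_bins), dtype=float)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            i, j, v = int(fields[0]), int(fields[1]), float(fields[2])
            if v < 0:
                raise ValueError(f"{path}:{lineno}: negative count {v}")
            if i >= n_bins or j >= n_bins or i < 0 or j < 0:
                raise ValueError(
                    f"{path}:{lineno}: bin index ({i},{j}) out of range "
                    f"for n_bins={n_bins}"
                )
            values[i, j] += v
            if i != j:
                values[j, i] += v
    return ContactMatrix(chrom=chrom, resolution=resolution, values=values)


def write_contact_matrix(
    matrix: ContactMatrix,
    path: str | Path,
    bins_path: str | Path | None = None,
) -> None:
    """Write the upper triangle (incl. diagonal) as sorted triplet text."""
    with open(path, "w") as fh:
        iu, ju = np.nonzero(np.triu(matrix.values))
        for i, j in zip(iu, ju):
            v = matrix.values[i, j]
            fh.write(f"{i}\t{j}\t{v:.10g}\n")
    if bins_path is not None:
        with open(bins_path, "w") as fh:
            for b in range(matrix.n_bins):
                fh.write(
                    f"{matrix.chrom}\t{b * matrix.resolution}\t"
                    f"{(b + 1) * matrix.resolution}\t{b}\n"
                )


# ---------------------------------------------------------------------------
# loops (BEDPE)

def read_bedpe(path: str | Path, resolution: int = 10_000) -> LoopSet:
    """Read loops from BEDPE; anchors are ordered, trans records skipped."""
    loops: list[Loop] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
            try:
                c1, s1, e1 = fields[0], int(fields[1]), int(fields[2])
                c2, s2, e2 = fields[3], int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            if c1 != c2:
                n_skipped += 1
                continue
            loops.append(
                Loop.from_anchors(
                    GenomicInterval(c1, s1, e1),
                    GenomicInterval(c2, s2, e2),
                    resolution=resolution,
                )
            )
    if n_skipped:
        logger.info("skipped %d inter-chromosomal BEDPE records", n_skipped)
    return LoopSet(loops=loops, n_interchromosomal_skipped=n_skipped)


def write_bedpe(loops: Iterable[Loop], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor5, lp.anchor3
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n"
            )


# ---------------------------------------------------------------------------
# peaks (BED / narrowPeak)

def read_bed_peaks(path: str | Path) -> PeakSet:
    """Read peaks from BED or narrowPeak.

    The narrowPeak 10th column, when present and non-negative, is the
    summit offset from ``start``; otherwise the summit defaults to the
    interval midpoint.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
            interval = GenomicInterval(chrom, start, end, strand)
            summit = (start + end) // 2
            if len(fields) >= 10:
                offset = int(fields[9])
                if offset >= 0:
                    summit = start + offset
            peaks.append(Peak(interval=interval, summit=summit, name=name))
    if not peaks:
        logger.warning("no peaks parsed from %s", path)
    return PeakSet(peaks=peaks)


def write_bed_peaks(peaks: Iterable[Peak], path: str | Path,
                    narrow: bool = True) -> None:
    """Write peaks as narrowPeak (default) or BED6."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            if narrow:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t"
                    f"{iv.strand}\t0\t-1\t-1\t{p.summit - iv.start}\n"
                )
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# tracks (bedGraph)

def read_bedgraph(path: str | Path, chrom: str | None = None) -> Track:
    """Read a single-chromosome, fixed-step bedGraph into a Track.

    Gaps in coverage become NaN. The step is inferred from the first
    record; records must be multiples of that step.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    if len(df) == 0:
        logger.warning("empty bedGraph %s", path)
        return Track(chrom=chrom or ".", step=1, values=np.empty(0))
    if chrom is None:
        chrom = str(df["chrom"].iloc[0])
    df = df[df["chrom"] == chrom]
    step = int(df["end"].iloc[0] - df["start"].iloc[0])
    n = int(df["end"].max()) // step
    values = np.full(n, np.nan)
    for start, end, value in zip(df["start"], df["end"], df["value"]):
        values[int(start) // step: int(end) // step] = value
    return Track(chrom=chrom, step=step, values=values)


def write_bedgraph(track: Track, path: str | Path) -> None:
    """Write a Track as bedGraph, omitting NaN (missing) bins."""
    with open(path, "w") as fh:
        for k, v in enumerate(track.values):
            if np.isnan(v):
                continue
            s = track.start + k * track.step
            fh.write(f"{track.chrom}\t{s}\t{s + track.step}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# sequence (FASTA)

_NON_ACGT = re.compile(r"[^ACGT]")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {name: sequence}; non-ACGT characters become N."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = _NON_ACGT.sub("N", str(rec.seq).upper())
    if not seqs:
        logger.warning("no sequences parsed from %s", path)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# motifs (JASPAR PFM)

def read_pfm(path: str | Path, pseudocount: float = 0.01) -> PWM:
    """Read a JASPAR-format position frequency matrix.

    Counts are converted to per-column probabilities with the given
    pseudocount; the background defaults to uniform.
    """
    with open(path) as fh:
        motif = bio_motifs.read(fh, "jaspar")
    counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
    return PWM.from_counts(counts, pseudocount=pseudocount)


def write_pfm(pwm_counts: np.ndarray, name: str, path: str | Path) -> None:
    """Write a 4 x width count matrix in JASPAR PFM format."""
    counts = np.asarray(pwm_counts, dtype=float)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for base, row in zip("ACGT", counts):
            cells = " ".join(f"{v:.2f}" for v in row)
            fh.write(f"{base} [ {cells} ]\n")
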