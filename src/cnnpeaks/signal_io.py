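"""Read alignments, annotation intervals and label files into aligned per-base
vectors; write peak calls as BED6.

All coordinates are 0-based half-open. BAM access requires a coordinate-sorted,
indexed file (``.bai``); annotation is any BED-like whitespace-separated file
whose first three columns are chrom/start/end; labels are a 4-column TSV
``chrom  start  end  label`` with label one of ``peak``, ``nopeak``
(``no-peak``/``noPeak`` accepted), ``ambiguous``.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pysam

from .types import (
    AnnotationTrack,
    DepthTrack,
    GenomicInterval,
    Label,
    LabeledRegion,
    PeakCall,
)

__all__ = ["read_depth", "read_annotation", "read_labels", "write_bed", "read_bed"]

_LABEL_TOKENS = {
    "peak": Label.PEAK,
    "nopeak": Label.NOPEAK,
    "no-peak": Label.NOPEAK,
    "no_peak": Label.NOPEAK,
    "noPeak": Label.NOPEAK,
    "ambiguous": Label.AMBIGUOUS,
}


def read_depth(bam_path: str | os.PathLike, interval: GenomicInterval) -> DepthTrack:
    """Per-base count of aligned reads overlapping each position of *interval*.

    Depth is plain read pileup over aligned blocks: no fragment extension, no
    duplicate removal, no quality filtering. Deterministic for a fixed file.
    """
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if not bam.has_index():
            raise FileNotFoundError(
                f"BAM index not found for {bam_path}; run `samtools index` first"
            )
        if interval.chrom not in bam.references:
            raise KeyError(
                f"chromosome {interval.chrom!r} absent from BAM header of {bam_path}"
            )
        depth = np.zeros(interval.span, dtype=np.float64)
        for read in bam.fetch(interval.chrom, interval.start, interval.end):
            if read.is_unmapped:
                continue
            for bstart, bend in read.get_blocks():
                lo = max(bstart, interval.start) - interval.start
                hi = min(bend, interval.end) - interval.start
                if hi > lo:
                    depth[lo:hi] += 1.0
    return DepthTrack(interval, depth)


def read_annotation(
    annot_path: str | os.PathLike, interval: GenomicInterval
) -> AnnotationTrack:
    """Binary presence track: bit i == 1 iff base i is covered by >=1 record.

    Union semantics — overlapping or abutting records never yield counts > 1.
    """
    bits = np.zeros(interval.span, dtype=np.int8)
    with open(annot_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{annot_path}: line {lineno}: expected >=3 columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{annot_path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end < start:
                raise ValueError(f"{annot_path}: line {lineno}: end < start")
            if chrom != interval.chrom:
                continue
            lo = max(start, interval.start) - interval.start
            hi = min(end, interval.end) - interval.start
            if hi > lo:
                bits[lo:hi] = 1
    return AnnotationTrack(interval, bits)


def read_labels(label_path: str | os.PathLike) -> list[LabeledRegion]:
    """Parse a 4-column label TSV, preserving row order.

    AMBIGUOUS rows are retained as-is here; callers collapse them to NOPEAK
    (via :meth:`LabeledRegion.resolved`) before training or evaluation.
    """
    out: list[LabeledRegion] = []
    with open(label_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(
                    f"{label_path}: line {lineno}: expected 4 columns "
                    "(chrom, start, end, label)"
                )
            token = fields[3].lower()
            if token not in _LABEL_TOKENS:
                raise ValueError(
                    f"{label_path}: line {lineno}: unknown label {fields[3]!r}; "
                    f"accepted: peak, nopeak, ambiguous"
                )
            out.append(
                LabeledRegion(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                    _LABEL_TOKENS[token],
                )
            )
    return out


def write_bed(calls: Sequence[PeakCall], out_path: str | os.PathLike) -> None:
    """Write calls as BED6: chrom, start, end, peak_<k>, score (4 decimals), '.'.

    Calls must already be sorted and non-overlapping per chromosome.
    """
    _check_sorted_disjoint(calls)
    with open(out_path, "w") as fh:
        for k, call in enumerate(calls, start=1):
            iv = call.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{k}\t{call.score:.4f}\t.\n")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Parse the interval columns of a BED file (inverse of write_bed coords)."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 columns")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def _check_sorted_disjoint(calls: Iterable[PeakCall]) -> None:
    last: dict[str, int] = {}
    for call in calls:
        iv = call.interval
        if iv.chrom in last and iv.start < last[iv.chrom]:
            raise ValueError(
                f"calls not sorted/disjoint on {iv.chrom} at {iv.start}"
            )
        last[iv.chrom] = iv.end
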