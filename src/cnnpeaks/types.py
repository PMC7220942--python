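"""Core genomic value types shared across the pipeline.

Coordinates are 0-based half-open everywhere (BAM/BED convention), strand is
ignored: depth and annotation tracks are strand-collapsed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicInterval",
    "Label",
    "LabeledRegion",
    "DepthTrack",
    "AnnotationTrack",
    "PeakCall",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class Label(enum.Enum):
    """Expert call for a labeled segment.

    AMBIGUOUS segments (present in curated benchmark label sets) are mapped to
    NOPEAK before training or evaluation, the standard convention for scoring
    peak callers against curated labels.
    """

    PEAK = "peak"
    NOPEAK = "nopeak"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class LabeledRegion:
    interval: GenomicInterval
    label: Label

    def resolved(self) -> "LabeledRegion":
        """Return the region with AMBIGUOUS collapsed to NOPEAK."""
        if self.label is Label.AMBIGUOUS:
            return LabeledRegion(self.interval, Label.NOPEAK)
        return self


@dataclass
class DepthTrack:
    """Per-base pileup depth over an interval (one count per base)."""

    interval: GenomicInterval
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.depth.ndim != 1 or self.depth.size != self.interval.span:
            raise ValueError(
                f"depth length {self.depth.size} != interval span {self.interval.span}"
            )
        if np.any(self.depth < 0):
            raise ValueError("depth values must be non-negative")


@dataclass
class AnnotationTrack:
    """Binary per-base presence of gene/transcript annotation."""

    interval: GenomicInterval
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.ndim != 1 or self.bits.size != self.interval.span:
            raise ValueError(
                f"bits length {self.bits.size} != interval span {self.interval.span}"
            )
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("annotation bits must be 0/1")


@dataclass(frozen=True)
class PeakCall:
    """A called peak with its sigmoid activation, Poisson tail p-value, and
    combined score = activation * (-log10 p)."""

    interval: GenomicInterval
    activation: float
    pvalue: float
    score: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0.0 < self.activation < 1.0):
            raise ValueError(f"activation must lie in (0,1), got {self.activation}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"pvalue must lie in (0,1], got {self.pvalue}")
        expected = self.activation * (-np.log10(self.pvalue))
        if self.score is None:
            object.__setattr__(self, "score", float(expected))
        elif not np.isclose(self.score, expected, rtol=1e-9, atol=1e-12):
            raise ValueError("score must equal activation * (-log10 pvalue)")
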