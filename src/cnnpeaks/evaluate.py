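"""Label-based evaluation and the relative-distance-to-TSS statistic.

Confusion counts are *label-level*: each expert-labeled segment is one trial.
A PEAK label is a true positive iff at least one called peak shares a base
with it; a NOPEAK label is a false positive iff any call touches it. A single
call overlapping two PEAK labels credits both. AMBIGUOUS labels must be
collapsed to NOPEAK before calling in here.

The relative-distance statistic measures colocalization of peaks with
transcription start sites without a genome: for a peak midpoint p between
consecutive TSS a < b, d = min(p - a, b - p) / (b - a) in [0, 0.5]. Under
independent placement d is uniform; enrichment at TSS piles mass near 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan

import numpy as np

from .types import GenomicInterval, Label, LabeledRegion, PeakCall

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "confusion",
    "metrics",
    "relative_distance",
    "reldist_histogram",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class Metrics:
    """Derived rates; a metric with a zero denominator is NaN (undefined),
    except F1 which is 0 when tp == 0 but calls exist."""

    sensitivity: float
    specificity: float
    precision: float
    f1: float


def _any_overlap(iv: GenomicInterval, calls: list[PeakCall]) -> bool:
    return any(iv.overlaps(c.interval) for c in calls)


def confusion(calls: list[PeakCall], labels: list[LabeledRegion]) -> ConfusionCounts:
    """Count labels by whether any call shares >= 1 base with them."""
    if not labels:
        raise ValueError("labels must be non-empty")
    resolved = [r.resolved() for r in labels]
    by_chrom: dict[str, list[PeakCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    tp = fp = tn = fn = 0
    for region in resolved:
        hit = _any_overlap(region.interval, by_chrom.get(region.interval.chrom, []))
        if region.label is Label.PEAK:
            tp += hit
            fn += not hit
        else:
            fp += hit
            tn += not hit
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> Metrics:
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else nan
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else nan
    prec = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else nan
    if c.tp == 0:
        f1 = 0.0 if (c.fp or c.fn) else nan
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return Metrics(sensitivity=sens, specificity=spec, precision=prec, f1=f1)


def relative_distance(
    peaks: list[GenomicInterval], tss: np.ndarray | list[float]
) -> np.ndarray:
    """Relative distance of each peak midpoint to its flanking TSS pair.

    ``tss`` is a sorted position list on one chromosome (>= 2 sites). Peaks
    whose midpoint falls outside [tss[0], tss[-1]] are skipped.
    """
    tss = np.sort(np.asarray(tss, dtype=np.float64))
    if tss.size == 0:
        raise ValueError("empty TSS list")
    if tss.size < 2:
        raise ValueError("need >= 2 TSS positions per chromosome")
    mids = np.array([p.midpoint for p in peaks], dtype=np.float64)
    inside = (mids >= tss[0]) & (mids <= tss[-1])
    mids = mids[inside]
    if mids.size == 0:
        return np.empty(0)
    right = np.clip(np.searchsorted(tss, mids, side="right"), 1, tss.size - 1)
    a = tss[right - 1]
    b = tss[right]
    d = np.minimum(mids - a, b - mids) / (b - a)
    return d


def reldist_histogram(d: np.ndarray, bins: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width frequency histogram of relative distances over [0, 0.5].

    Returns (frequencies summing to 1, bin edges).
    """
    d = np.asarray(d, dtype=np.float64)
    if d.size == 0:
        raise ValueError("empty relative-distance vector")
    counts, edges = np.histogram(d, bins=bins, range=(0.0, 0.5))
    return counts / counts.sum(), edges
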