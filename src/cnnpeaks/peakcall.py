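"""Apply a trained model across a genome and emit scored peak intervals.

Each chromosome is tiled into non-overlapping windows of ``L * bin_width``
bases, preprocessed exactly as in training, and pushed through the network.
Bins whose probability ``sigmoid(x_i - t_seg(i))`` clears the cutoff form
candidate runs; nearby runs are merged, short ones dropped, and runs touching
a window joint are merged across it. No control/input track is involved
anywhere: the learned thresholds play that role.

Each peak is scored as ``activation * (-log10 p)`` where activation is the
mean per-bin probability over the peak and ``p`` is the upper-tail Poisson
probability of the peak's mean binned depth under a background rate lambda
(contig-wide mean depth, or a local flanking mean floored by it).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import PeakCNN
from .preprocess import ModelInput, SmoothingConfig, bin_to_fixed, smooth
from .signal_io import read_annotation, read_depth, write_bed
from .types import DepthTrack, GenomicInterval, PeakCall

__all__ = [
    "CallingConfig",
    "call_window",
    "poisson_pvalue",
    "score_call",
    "estimate_lambda",
    "call_genome",
]


@dataclass(frozen=True)
class CallingConfig:
    """Interval-extraction and scoring knobs.

    prob_cutoff
        per-bin probability required to enter a peak run (the sigmoid's
        natural decision boundary, 0.5, by default).
    min_peak_bins
        runs shorter than this many bins are dropped.
    merge_gap_bins
        runs separated by at most this many sub-cutoff bins are merged.
    lambda_mode
        "global": contig-wide mean depth; "local": mean over
        ``local_flank_bins`` on each side of the peak, floored by global.
    """

    prob_cutoff: float = 0.5
    min_peak_bins: int = 2
    merge_gap_bins: int = 1
    lambda_mode: str = "global"
    local_flank_bins: int = 50

    def __post_init__(self) -> None:
        if not (0.0 < self.prob_cutoff < 1.0):
            raise ValueError("prob_cutoff must lie strictly inside (0, 1)")
        if self.min_peak_bins < 1:
            raise ValueError("min_peak_bins must be >= 1")
        if self.merge_gap_bins < 0:
            raise ValueError("merge_gap_bins must be >= 0")
        if self.lambda_mode not in ("global", "local"):
            raise ValueError("lambda_mode must be 'global' or 'local'")


def poisson_pvalue(observed: float, lam: float) -> float:
    """Upper-tail P(N >= round(observed)) under Poisson(lam)."""
    if lam <= 0:
        raise ValueError("Poisson rate lambda must be positive")
    if observed < 0:
        raise ValueError("observed depth must be non-negative")
    k = int(round(observed))
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def score_call(
    interval: GenomicInterval, activation: float, observed: float, lam: float
) -> PeakCall:
    """Attach p-value and combined score: activation * (-log10 p)."""
    p = poisson_pvalue(observed, lam)
    return PeakCall(
        interval=interval,
        activation=float(activation),
        pvalue=p,
        score=float(activation) * (-np.log10(p)),
    )


def estimate_lambda(
    context: np.ndarray,
    cfg: CallingConfig | None = None,
    peak_bins: tuple[int, int] | None = None,
) -> float:
    """Background rate from the calling context (binned mean depth vector).

    Global mode: mean over the whole context. Local mode: mean over
    ``local_flank_bins`` on each side of ``peak_bins`` (clipped to the
    context), floored by the global mean so sparse flanks never deflate the
    background.
    """
    cfg = cfg or CallingConfig()
    context = np.asarray(context, dtype=np.float64)
    if context.size == 0:
        raise ValueError("empty calling context")
    global_lam = float(context.mean())
    if global_lam <= 0:
        raise ValueError("all-zero calling context: no background signal")
    if cfg.lambda_mode == "global" or peak_bins is None:
        return global_lam
    lo, hi = peak_bins
    left = context[max(0, lo - cfg.local_flank_bins) : lo]
    right = context[hi : hi + cfg.local_flank_bins]
    flank = np.concatenate([left, right])
    if flank.size == 0:
        return global_lam
    return max(float(flank.mean()), global_lam)


def _runs_above_cutoff(
    probs: np.ndarray, cfg: CallingConfig
) -> list[tuple[int, int]]:
    """Maximal runs of bins with prob >= cutoff, gap-merged then length-filtered."""
    above = probs >= cfg.prob_cutoff
    if not above.any():
        return []
    padded = np.concatenate([[0], above.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] <= cfg.merge_gap_bins:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    return [(s, e) for s, e in merged if e - s >= cfg.min_peak_bins]


def call_window(
    model: PeakCNN,
    inputs: ModelInput,
    cfg: CallingConfig | None = None,
    binned_depth: np.ndarray | None = None,
    lam: float | None = None,
) -> list[PeakCall]:
    """Call and score peaks in one preprocessed window.

    ``binned_depth`` is the raw (unsmoothed) binned depth used for Poisson
    scoring; the smoothed input is used when it is not supplied. ``lam``
    overrides the background rate (otherwise estimated from the window).
    """
    cfg = cfg or CallingConfig()
    out = model.forward(inputs)
    depth = (
        np.asarray(binned_depth, dtype=np.float64)
        if binned_depth is not None
        else inputs.x
    )
    calls: list[PeakCall] = []
    for lo, hi in _runs_above_cutoff(out.probabilities, cfg):
        background = (
            lam
            if lam is not None
            else estimate_lambda(depth, cfg, peak_bins=(lo, hi))
        )
        iv = GenomicInterval(
            inputs.anchor.chrom,
            inputs.anchor.start + int(round(lo * inputs.bin_width)),
            inputs.anchor.start + int(round(hi * inputs.bin_width)),
        )
        # the sigmoid saturates to 1.0 in float64 for strong peaks; keep the
        # activation inside the open interval the call type requires
        act = float(np.clip(out.probabilities[lo:hi].mean(), 1e-12, 1 - 1e-12))
        calls.append(
            score_call(
                iv,
                activation=act,
                observed=float(depth[lo:hi].mean()),
                lam=background,
            )
        )
    return calls


def _merge_adjacent(calls: list[PeakCall], lam: float) -> list[PeakCall]:
    """Merge abutting/overlapping calls (window joints), length-weighted."""
    if not calls:
        return []
    calls = sorted(calls, key=lambda c: (c.interval.chrom, c.interval.start))
    merged: list[PeakCall] = []
    for call in calls:
        if merged and (
            call.interval.chrom == merged[-1].interval.chrom
            and call.interval.start <= merged[-1].interval.end
        ):
            prev = merged.pop()
            w1, w2 = prev.interval.span, call.interval.span
            iv = GenomicInterval(
                prev.interval.chrom,
                prev.interval.start,
                max(prev.interval.end, call.interval.end),
            )
            act = (prev.activation * w1 + call.activation * w2) / (w1 + w2)
            # both parts share one background rate; keep the stronger tail
            p = min(prev.pvalue, call.pvalue)
            merged.append(
                PeakCall(iv, act, p, float(act) * float(-np.log10(p)))
            )
        else:
            merged.append(call)
    return merged


def call_track(
    model: PeakCNN,
    depth: DepthTrack,
    annotation=None,
    cfg: CallingConfig | None = None,
    smoothing: SmoothingConfig | None = None,
    bin_width: int = 10,
) -> list[PeakCall]:
    """Tile an in-memory depth track into windows, call each, merge joints.

    Same semantics as :func:`call_genome` but starting from a DepthTrack
    (e.g. a synthetic contig) instead of a BAM file.
    """
    from .preprocess import bin_annotation
    from .types import AnnotationTrack

    cfg = cfg or CallingConfig()
    smoothing = smoothing or SmoothingConfig()
    L = model.cfg.window_bins
    span = L * bin_width
    contig = depth.interval
    calls: list[PeakCall] = []
    window_means: list[float] = []
    windows = []
    for start in range(contig.start, contig.end - span + 1, span):
        iv = GenomicInterval(contig.chrom, start, start + span)
        sl = slice(start - contig.start, start - contig.start + span)
        wtrack = DepthTrack(iv, depth.depth[sl])
        annot = (
            AnnotationTrack(iv, annotation.bits[sl]) if annotation is not None else None
        )
        inputs = smooth(wtrack, smoothing, L, annotation=annot)
        binned = bin_to_fixed(wtrack, L)
        window_means.append(float(binned.mean()))
        windows.append((inputs, binned))
    if not windows:
        return []
    contig_lam = float(np.mean(window_means))
    if contig_lam <= 0:
        return []
    for inputs, binned in windows:
        lam = contig_lam if cfg.lambda_mode == "global" else None
        calls.extend(call_window(model, inputs, cfg, binned_depth=binned, lam=lam))
    return _merge_adjacent(calls, contig_lam)


def call_genome(
    model: PeakCNN,
    bam_path: str | os.PathLike,
    annot_path: str | os.PathLike | None,
    out_path: str | os.PathLike,
    cfg: CallingConfig | None = None,
    smoothing: SmoothingConfig | None = None,
    bin_width: int = 10,
    chroms: list[str] | None = None,
) -> list[PeakCall]:
    """Tile every chromosome, call, merge across joints, write sorted BED6.

    The calling path takes a single alignment file: no control track exists
    anywhere in this pipeline.
    """
    import pysam

    cfg = cfg or CallingConfig()
    smoothing = smoothing or SmoothingConfig()
    L = model.cfg.window_bins
    span = L * bin_width
    all_calls: list[PeakCall] = []
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        targets = [
            (name, length)
            for name, length in zip(bam.references, bam.lengths)
            if chroms is None or name in chroms
        ]
    for chrom, length in targets:
        if length < span:
            continue
        chrom_calls: list[PeakCall] = []
        depth_means: list[float] = []
        windows = []
        for start in range(0, length - span + 1, span):
            iv = GenomicInterval(chrom, start, start + span)
            track = read_depth(bam_path, iv)
            annot = read_annotation(annot_path, iv) if annot_path else None
            inputs = smooth(track, smoothing, L, annotation=annot)
            binned = bin_to_fixed(track, L)
            depth_means.append(float(binned.mean()))
            windows.append((inputs, binned))
        if not windows:
            continue
        contig_lam = float(np.mean(depth_means))
        for inputs, binned in windows:
            if cfg.lambda_mode == "global":
                lam = contig_lam if contig_lam > 0 else None
                if lam is None:
                    continue  # zero-depth window set: nothing to call
                chrom_calls.extend(
                    call_window(model, inputs, cfg, binned_depth=binned, lam=lam)
                )
            else:
                if binned.sum() == 0:
                    continue
                chrom_calls.extend(
                    call_window(model, inputs, cfg, binned_depth=binned)
                )
        all_calls.extend(_merge_adjacent(chrom_calls, contig_lam))
    all_calls.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    write_bed(all_calls, out_path)
    return all_calls
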