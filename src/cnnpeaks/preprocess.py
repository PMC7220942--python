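"""Convert per-base depth + annotation into fixed-length smoothed model inputs.

A labeled or tiled genomic window of arbitrary span is reduced to ``L`` bins
(12,000 by default) so windows of different sizes share one input shape. The
binned depth is then smoothed the way a human inspecting a browser track
perceives it: a stride-1 max-pool (width ``w`` bins) followed by convolution
with a normalized Gaussian kernel (``M`` taps, scale ``sigma`` bins).

Pipeline order is bin -> max-pool -> Gaussian; the annotation vector is binned
in lockstep (a bin is 1 if any of its bases is annotated) but never smoothed.

Edge handling: the max-pool window is clipped at the ends; the convolution
zero-pads. Both preserve length (stride 1 throughout).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import AnnotationTrack, DepthTrack, GenomicInterval

__all__ = [
    "DEFAULT_WINDOW_BINS",
    "SmoothingConfig",
    "ModelInput",
    "bin_to_fixed",
    "bin_annotation",
    "max_pool_smooth",
    "gaussian_filter",
    "convolve_same",
    "smooth",
]

DEFAULT_WINDOW_BINS = 12_000


@dataclass(frozen=True)
class SmoothingConfig:
    """Smoothing hyperparameters, all in bin units.

    pool_width
        max-pool window ``w``; position n pools indices [n-w//2, n+w//2].
    filter_size
        Gaussian tap count ``M`` (odd).
    filter_sigma
        Gaussian scale in bins.
    """

    pool_width: int = 5
    filter_size: int = 11
    filter_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.pool_width < 1:
            raise ValueError("pool_width must be >= 1")
        if self.filter_size < 1 or self.filter_size % 2 == 0:
            raise ValueError("filter_size must be a positive odd integer")
        if self.filter_sigma <= 0:
            raise ValueError("filter_sigma must be positive")


@dataclass
class ModelInput:
    """Fixed-length network input: smoothed binned depth + binned annotation."""

    x: np.ndarray
    lam: np.ndarray
    anchor: GenomicInterval
    bin_width: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.lam = np.asarray(self.lam, dtype=np.float64)
        if self.x.shape != self.lam.shape or self.x.ndim != 1:
            raise ValueError("x and lam must be 1-D vectors of equal length")
        if np.any(self.x < 0):
            raise ValueError("smoothed depth must be non-negative")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    def __len__(self) -> int:
        return self.x.size


def _bin_edges(span: int, L: int) -> np.ndarray:
    # L+1 near-equal partition boundaries of [0, span)
    return np.round(np.arange(L + 1) * span / L).astype(np.intp)


def bin_to_fixed(track: DepthTrack, L: int | None = None) -> np.ndarray:
    """Partition the track into L near-equal contiguous bins; value = mean depth.

    Raises if the interval span is smaller than L: such a window should be
    extended with additional labeled sequence or simply eliminated.
    """
    if L is None:
        L = DEFAULT_WINDOW_BINS
    span = track.interval.span
    if span < L:
        raise ValueError(
            f"window span {span} < {L} bins: extend the window or eliminate it"
        )
    edges = _bin_edges(span, L)
    sums = np.add.reduceat(track.depth, edges[:-1])
    widths = np.diff(edges)
    return sums / widths


def bin_annotation(track: AnnotationTrack, L: int | None = None) -> np.ndarray:
    """Bin a binary annotation track by max: any annotated base -> bin is 1."""
    if L is None:
        L = DEFAULT_WINDOW_BINS
    span = track.interval.span
    if span < L:
        raise ValueError(
            f"window span {span} < {L} bins: extend the window or eliminate it"
        )
    edges = _bin_edges(span, L)
    return np.maximum.reduceat(track.bits.astype(np.float64), edges[:-1])


def max_pool_smooth(v: np.ndarray, w: int) -> np.ndarray:
    """Stride-1 max-pool: out[n] = max v[n-w//2 .. n+w//2], clipped at the edges."""
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot max-pool an empty vector")
    if w < 1:
        raise ValueError("pool width must be >= 1")
    half = w // 2
    if half == 0:
        return v.copy()
    n = v.size
    out = np.empty_like(v)
    # cumulative running max trick would not handle two-sided windows; the
    # sliding-window view is O(n*w) but w is a handful of bins.
    pad = np.full(half, -np.inf)
    vp = np.concatenate([pad, v, pad])
    windows = np.lib.stride_tricks.sliding_window_view(vp, 2 * half + 1)
    np.max(windows, axis=1, out=out)
    return out


def gaussian_filter(M: int, sigma: float) -> np.ndarray:
    """Symmetric normalized Gaussian kernel: M odd taps, coefficients sum to 1."""
    if M < 1 or M % 2 == 0:
        raise ValueError("filter size M must be a positive odd integer")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    m = np.arange(M) - M // 2
    u = np.exp(-(m.astype(np.float64) ** 2) / (2.0 * sigma**2))
    return u / u.sum()


def convolve_same(v: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Length-preserving 1-D convolution with an odd filter, zero-padded edges."""
    v = np.asarray(v, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    if u.size % 2 == 0:
        raise ValueError("filter length must be odd")
    if u.size > v.size:
        raise ValueError(f"filter length {u.size} exceeds signal length {v.size}")
    return np.convolve(v, u, mode="same")


def smooth(
    track: DepthTrack,
    cfg: SmoothingConfig | None = None,
    L: int | None = None,
    annotation: AnnotationTrack | None = None,
) -> ModelInput:
    """Full preprocessing: bin to L, max-pool, Gaussian-convolve.

    The annotation track, if given, must cover the same interval; it is binned
    (by max) but not smoothed. Absent annotation yields an all-zero lam vector.
    """
    if cfg is None:
        cfg = SmoothingConfig()
    if L is None:
        L = DEFAULT_WINDOW_BINS
    binned = bin_to_fixed(track, L)
    pooled = max_pool_smooth(binned, cfg.pool_width)
    x = convolve_same(pooled, gaussian_filter(cfg.filter_size, cfg.filter_sigma))
    # zero-padding can introduce tiny negative round-off at the edges
    np.clip(x, 0.0, None, out=x)
    if annotation is not None:
        if annotation.interval != track.interval:
            raise ValueError("annotation interval differs from depth interval")
        lam = bin_annotation(annotation, L)
    else:
        lam = np.zeros(L, dtype=np.float64)
    return ModelInput(
        x=x,
        lam=lam,
        anchor=track.interval,
        bin_width=track.interval.span / L,
    )
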