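"""Training objective and loop: class-weighted cross-entropy, Top-K selection,
Adam.

Peak bins are rare, so an unweighted objective is minimized by calling
"no-peak" everywhere. Two corrections are applied:

* the positive-class term is weighted by ``w`` = (# negative labeled bins) /
  (# positive labeled bins), so missed peaks cost as much in aggregate as
  false calls;
* only the ``kappa`` *largest* per-bin losses of each window enter the
  objective (Top-K), focusing each step on the worst-predicted bins. With
  ``kappa`` equal to the full window this reduces to the ordinary mean;
  the default is half the output length.

Supervision is sparse: experts label some intervals of a window as peak or
no-peak and leave the rest unlabeled. Unlabeled bins are masked out of both
the loss and the Top-K ranking, and the per-window ``kappa`` is capped at the
number of labeled bins.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np

from .model import PeakCNN, expand_thresholds
from .nn import autodiff as ad
from .nn.layers import Adam
from .preprocess import ModelInput
from .types import Label, LabeledRegion

__all__ = [
    "TrainingExample",
    "LossConfig",
    "class_weight",
    "weighted_ce",
    "topk_loss",
    "rasterize_labels",
    "make_example",
    "train",
]

_EPS = 1e-7


@dataclass
class TrainingExample:
    """One window of supervision: model input, per-bin targets, label mask."""

    input: ModelInput
    y: np.ndarray  # (L,) float 0/1; 1 == peak bin
    mask: np.ndarray  # (L,) bool; True == bin lies in a labeled interval

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        L = len(self.input)
        if self.y.shape != (L,) or self.mask.shape != (L,):
            raise ValueError("y/mask length must match the model input")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("y must be binary")

    @property
    def n_labeled(self) -> int:
        return int(self.mask.sum())


@dataclass
class LossConfig:
    """Objective and optimizer settings.

    kappa_fraction
        Top-K size as a fraction of the window length (default 0.5, i.e.
        kappa = L/2), additionally capped per window at its labeled-bin count.
    class_weight_mode
        "global": one w over the whole training set; "per_batch": recomputed
        from each minibatch.
    """

    kappa_fraction: float = 0.5
    class_weight_mode: str = "global"
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.kappa_fraction <= 1.0):
            raise ValueError("kappa_fraction must lie in (0, 1]")
        if self.class_weight_mode not in ("global", "per_batch"):
            raise ValueError("class_weight_mode must be 'global' or 'per_batch'")


def class_weight(examples: list[TrainingExample]) -> float:
    """w = (# negative labeled bins) / (# positive labeled bins)."""
    pos = sum(float(ex.y[ex.mask].sum()) for ex in examples)
    labeled = sum(ex.n_labeled for ex in examples)
    if labeled == 0:
        raise ValueError("no labeled bins in the training set")
    if pos == 0:
        raise ValueError(
            "no positive (peak) labeled bins: the class weight w = neg/pos is "
            "undefined; add peak labels"
        )
    return (labeled - pos) / pos


def weighted_ce(
    y: np.ndarray, h: np.ndarray, w: float, mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-bin weighted cross-entropy losses.

    loss_i = -[ y_i log(h_i) w + (1 - y_i) log(1 - h_i) ]

    Predictions h at exactly 0 or 1 are clamped to [eps, 1-eps] (eps = 1e-7).
    Masked-out bins get loss 0 (and are excluded from Top-K ranking upstream).
    """
    y = np.asarray(y, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    if y.shape != h.shape:
        raise ValueError("y and h must have equal length")
    if np.any((h <= 0.0) | (h >= 1.0)):
        print("weighted_ce: clamping predictions to (0,1)", file=sys.stderr)
        h = np.clip(h, _EPS, 1.0 - _EPS)
    loss = -(y * np.log(h) * w + (1.0 - y) * np.log1p(-h))
    if mask is not None:
        loss = np.where(np.asarray(mask, dtype=bool), loss, 0.0)
    return loss


def topk_loss(per_bin: np.ndarray, kappa: int, mask: np.ndarray | None = None) -> float:
    """Mean of the kappa largest per-bin losses (among unmasked bins)."""
    per_bin = np.asarray(per_bin, dtype=np.float64)
    if mask is not None:
        per_bin = per_bin[np.asarray(mask, dtype=bool)]
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    if kappa > per_bin.size:
        raise ValueError(
            f"kappa ({kappa}) exceeds the number of unmasked bins ({per_bin.size})"
        )
    if kappa == per_bin.size:
        return float(per_bin.mean())
    top = np.partition(per_bin, -kappa)[-kappa:]
    return float(top.mean())


def rasterize_labels(
    regions: list[LabeledRegion], anchor_start: int, L: int, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin targets and mask for a window of L bins starting at anchor_start.

    A bin is *labeled* iff more than half of its bases lie inside labeled
    intervals, and *positive* iff more than half lie inside PEAK intervals.
    AMBIGUOUS regions are collapsed to NOPEAK first.
    """
    edges = anchor_start + np.round(np.arange(L + 1) * bin_width).astype(np.int64)
    peak_cov = np.zeros(L)
    label_cov = np.zeros(L)
    widths = np.maximum(np.diff(edges), 1)
    for region in regions:
        region = region.resolved()
        iv = region.interval
        lo = np.clip(iv.start, edges[:-1], edges[1:])
        hi = np.clip(iv.end, edges[:-1], edges[1:])
        cov = np.maximum(hi - lo, 0)
        label_cov += cov
        if region.label is Label.PEAK:
            peak_cov += cov
    mask = label_cov / widths > 0.5
    y = (peak_cov / widths > 0.5).astype(np.float64)
    return y, mask


def make_example(
    inputs: ModelInput, regions: list[LabeledRegion]
) -> TrainingExample:
    """Build a TrainingExample from a preprocessed window and the label set
    (only regions on the window's chromosome contribute)."""
    here = [r for r in regions if r.interval.chrom == inputs.anchor.chrom]
    y, mask = rasterize_labels(
        here, inputs.anchor.start, len(inputs), inputs.bin_width
    )
    return TrainingExample(input=inputs, y=y, mask=mask)


def _batch_loss(
    model: PeakCNN,
    batch: list[TrainingExample],
    w: float,
    kappa: int,
    training: bool,
) -> ad.Tensor:
    """Differentiable Top-K weighted cross-entropy for a minibatch."""
    L = model.cfg.window_bins
    reps = L // model.cfg.threshold_segments
    x = np.stack([ex.input.x for ex in batch])
    lam = np.stack([ex.input.lam for ex in batch])
    y = np.stack([ex.y for ex in batch])
    mask = np.stack([ex.mask for ex in batch])
    t = model.thresholds_tensor(x, lam, training=training)  # (N, S)
    texp = ad.repeat_interleave(t, reps)  # (N, L)
    # logits z = x - t_seg(i); x is a constant w.r.t. the parameters
    z = ad.sub(ad.Tensor(x), texp)
    per_bin = ad.weighted_bce_from_logits(z, y, w)
    return ad.topk_masked_mean(per_bin, mask, kappa)


def train(
    model: PeakCNN,
    examples: list[TrainingExample],
    cfg: LossConfig | None = None,
    log_path: str | None = None,
) -> list[float]:
    """Minibatch Adam on the Top-K objective; returns per-epoch mean loss.

    Windows with no labeled bins are dropped up front. The seed fixes epoch
    shuffling; pair it with a seeded ``build_model`` for end-to-end
    reproducibility. Raises on non-finite loss (divergence).
    """
    cfg = cfg or LossConfig()
    usable = [ex for ex in examples if ex.n_labeled > 0]
    if not usable:
        raise ValueError("no training windows contain labeled bins")
    w_global = class_weight(usable)
    kappa = max(1, round(cfg.kappa_fraction * model.cfg.window_bins))
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history: list[float] = []
    log_fh = open(log_path, "w") if log_path else None
    try:
        if log_fh:
            log_fh.write("epoch\tmean_loss\n")
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(usable))
            losses = []
            for start in range(0, len(usable), cfg.batch_size):
                batch = [usable[i] for i in order[start : start + cfg.batch_size]]
                w = (
                    class_weight(batch)
                    if cfg.class_weight_mode == "per_batch"
                    else w_global
                )
                loss = _batch_loss(model, batch, w, kappa, training=True)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}: loss={loss.data}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            mean_loss = float(np.mean(losses))
            history.append(mean_loss)
            print(f"epoch {epoch + 1}/{cfg.epochs} loss {mean_loss:.5f}", file=sys.stderr)
            if log_fh:
                log_fh.write(f"{epoch + 1}\t{mean_loss:.8f}\n")
    finally:
        if log_fh:
            log_fh.close()
    return history
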