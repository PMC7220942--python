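"""Model/Results front end over the training and calling machinery.

:class:`PeakCallingModel` is constructed from data (preprocessed training
windows, or tracks via :meth:`PeakCallingModel.from_tracks`); ``fit()`` runs
the Adam/Top-K loop and returns a :class:`PeakCallingResults` carrying the
trained network, the loss history and diagnostics, with ``predict``, ``call``
and ``summary`` hanging off it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import ArchitectureConfig, ModelOutput, PeakCNN, build_model
from .peakcall import CallingConfig, call_track
from .preprocess import ModelInput, SmoothingConfig, smooth
from .training import (
    LossConfig,
    TrainingExample,
    class_weight,
    make_example,
    train,
)
from .types import AnnotationTrack, DepthTrack, GenomicInterval, LabeledRegion, PeakCall

__all__ = ["PeakCallingModel", "PeakCallingResults", "windows_from_tracks"]


def windows_from_tracks(
    depth: DepthTrack,
    annotation: AnnotationTrack | None,
    window_bins: int,
    bin_width: int,
    smoothing: SmoothingConfig | None = None,
) -> list[ModelInput]:
    """Tile a contig into consecutive windows of ``window_bins * bin_width``
    bases and preprocess each one."""
    smoothing = smoothing or SmoothingConfig()
    span = window_bins * bin_width
    contig = depth.interval
    out: list[ModelInput] = []
    for start in range(contig.start, contig.end - span + 1, span):
        iv = GenomicInterval(contig.chrom, start, start + span)
        sl = slice(start - contig.start, start - contig.start + span)
        wtrack = DepthTrack(iv, depth.depth[sl])
        annot = (
            AnnotationTrack(iv, annotation.bits[sl])
            if annotation is not None
            else None
        )
        out.append(smooth(wtrack, smoothing, window_bins, annotation=annot))
    return out


class PeakCallingModel:
    """Threshold-learning peak caller specified by its training windows.

    Parameters
    ----------
    examples
        Labeled training windows (windows without any labeled bin are kept
        but ignored by the objective).
    arch, loss
        Architecture and objective settings; defaults are the package
        defaults with ``window_bins`` taken from the data.
    """

    def __init__(
        self,
        examples: list[TrainingExample],
        arch: ArchitectureConfig | None = None,
        loss: LossConfig | None = None,
    ):
        if not examples:
            raise ValueError("need at least one training window")
        L = len(examples[0].input)
        if any(len(ex.input) != L for ex in examples):
            raise ValueError("all training windows must share one length")
        if arch is None:
            arch = ArchitectureConfig(window_bins=L)
        elif arch.window_bins != L:
            raise ValueError(
                f"architecture window_bins {arch.window_bins} != data length {L}"
            )
        self.examples = examples
        self.arch = arch
        self.loss = loss or LossConfig()

    @classmethod
    def from_tracks(
        cls,
        depth: DepthTrack,
        annotation: AnnotationTrack | None,
        labels: list[LabeledRegion],
        window_bins: int = 2_000,
        bin_width: int = 10,
        smoothing: SmoothingConfig | None = None,
        arch: ArchitectureConfig | None = None,
        loss: LossConfig | None = None,
    ) -> "PeakCallingModel":
        """Tile tracks into windows and rasterize the expert labels."""
        windows = windows_from_tracks(depth, annotation, window_bins, bin_width, smoothing)
        examples = [make_example(wi, labels) for wi in windows]
        return cls(examples, arch=arch, loss=loss)

    def fit(self, seed: int | None = None, log_path: str | None = None) -> "PeakCallingResults":
        """Train with Adam on the Top-K weighted cross-entropy objective."""
        loss_cfg = self.loss if seed is None else replace(self.loss, seed=seed)
        init_seed = loss_cfg.seed
        net = build_model(self.arch, seed=init_seed)
        history = train(net, self.examples, loss_cfg, log_path=log_path)
        return PeakCallingResults(self, net, history, loss_cfg)


@dataclass
class PeakCallingResults:
    """A fitted peak caller: trained network + training diagnostics."""

    model: PeakCallingModel
    network: PeakCNN
    loss_history: list[float]
    loss_config: LossConfig

    def predict(self, inputs: ModelInput) -> ModelOutput:
        """Per-segment thresholds and per-bin peak probabilities for a window."""
        return self.network.forward(inputs)

    def call(
        self,
        depth: DepthTrack,
        annotation: AnnotationTrack | None = None,
        cfg: CallingConfig | None = None,
        smoothing: SmoothingConfig | None = None,
        bin_width: int = 10,
    ) -> list[PeakCall]:
        """Call scored peaks over a depth track with the fitted network."""
        return call_track(
            self.network, depth, annotation, cfg=cfg, smoothing=smoothing,
            bin_width=bin_width,
        )

    def summary(self) -> str:
        """Plain-text fit summary."""
        m = self.model
        labeled = [ex for ex in m.examples if ex.n_labeled > 0]
        n_pos = int(sum(ex.y[ex.mask].sum() for ex in labeled))
        n_lab = int(sum(ex.n_labeled for ex in labeled))
        w = class_weight(labeled) if n_pos else float("nan")
        lines = [
            "Peak-calling model fit",
            "=" * 46,
            f"{'training windows':<30}{len(m.examples):>16}",
            f"{'  with labeled bins':<30}{len(labeled):>16}",
            f"{'labeled bins':<30}{n_lab:>16}",
            f"{'  positive (peak) bins':<30}{n_pos:>16}",
            f"{'class weight w (neg/pos)':<30}{w:>16.3f}",
            f"{'window bins (L)':<30}{m.arch.window_bins:>16}",
            f"{'threshold segments (S)':<30}{m.arch.threshold_segments:>16}",
            f"{'network parameters':<30}{self.network.num_parameters():>16}",
            f"{'epochs':<30}{self.loss_config.epochs:>16}",
            f"{'kappa fraction':<30}{self.loss_config.kappa_fraction:>16.2f}",
            f"{'first-epoch loss':<30}{self.loss_history[0]:>16.5f}",
            f"{'final-epoch loss':<30}{self.loss_history[-1]:>16.5f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.network.save(path)
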