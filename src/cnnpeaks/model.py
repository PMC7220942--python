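"""The 1-D Inception-style network that learns per-segment calling thresholds.

Instead of classifying every bin directly, the network reads a whole window of
smoothed coverage (plus the binary annotation track) and emits one *threshold*
per genomic segment — ``S`` thresholds for a window of ``L`` bins, each
governing ``L/S`` consecutive bins. The per-bin peak probability is then

    p_i = sigmoid(x_i - t_seg(i))

where ``x`` is the smoothed input signal itself. Keeping the output at ``S``
values rather than ``L`` keeps the head small; the broadcast expansion back to
``L`` restores per-bin resolution.

Topology: a conventional convolution stem on each input followed by a stride-1
max-pool, then seven concatenation modules — two A-modules (convolution +
max-pool + average-pool branches), three B-modules (three convolution branches
only, which stops the channel count growing with depth), and two C-modules
(four wider, stride-2 convolution branches, upsampled back to full length) —
with additive residual connections between successive modules and batch
normalization inside the branches. The head average-pools the feature map
from L positions down to S segments and applies two fully connected layers
*position-wise* (1x1 convolutions, weights shared across segments) to produce
the S thresholds. Sharing the head across segments means every labeled
segment trains the threshold rule for all segments — supervision is sparse,
so a per-segment head would leave most thresholds untrained.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import Tensor, autodiff as ad
from .nn.layers import BatchNorm1d, Conv1d, Layer
from .preprocess import ModelInput

__all__ = [
    "ArchitectureConfig",
    "ModelOutput",
    "PeakCNN",
    "build_model",
    "expand_thresholds",
    "sigmoid",
]

sigmoid = ad._sigmoid


@dataclass(frozen=True)
class ArchitectureConfig:
    """Shape of the network. ``window_bins`` must be divisible by
    ``threshold_segments``; defaults are desk-scale, every field is open."""

    window_bins: int = 12_000
    threshold_segments: int = 400
    stem_kernel: int = 7
    stem_channels: int = 8
    stem_pool_width: int = 3
    module_sequence: tuple[str, ...] = ("A", "A", "B", "B", "B", "C", "C")
    channels_per_branch: int = 16
    a_kernel: int = 3
    a_pool_width: int = 3
    b_kernels: tuple[int, ...] = (1, 3, 5)
    c_kernels: tuple[int, ...] = (7, 11, 15, 21)
    c_stride: int = 2
    head_hidden: int = 64
    use_residual: bool = True
    use_batchnorm: bool = True

    def __post_init__(self) -> None:
        if self.window_bins % self.threshold_segments:
            raise ValueError(
                f"window_bins ({self.window_bins}) must be divisible by "
                f"threshold_segments ({self.threshold_segments})"
            )
        if not set(self.module_sequence) <= {"A", "B", "C"}:
            raise ValueError("module_sequence entries must be A, B or C")
        if self.window_bins % self.c_stride:
            raise ValueError("window_bins must be divisible by c_stride")


@dataclass
class ModelOutput:
    """Forward-pass result for one window."""

    thresholds: np.ndarray  # (S,)
    probabilities: np.ndarray  # (L,), strictly inside (0, 1)


def expand_thresholds(t: np.ndarray, L: int) -> np.ndarray:
    """Broadcast S segment thresholds over L bins (each repeated L/S times)."""
    t = np.asarray(t, dtype=np.float64)
    S = t.shape[-1]
    if L % S:
        raise ValueError(f"L ({L}) not divisible by number of segments ({S})")
    return np.repeat(t, L // S, axis=-1)


class _Branch(Layer):
    """conv (+ batchnorm) + relu."""

    def __init__(self, cin, cout, k, stride, use_bn, rng):
        self.conv = Conv1d(cin, cout, k, stride=stride, rng=rng)
        self.bn = BatchNorm1d(cout) if use_bn else None

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = self.conv(x)
        if self.bn is not None:
            h = self.bn(h, training)
        return ad.relu(h)

    def parameters(self):
        p = self.conv.parameters()
        if self.bn is not None:
            p += self.bn.parameters()
        return p

    def state_arrays(self):
        out = {f"conv.{k}": v for k, v in self.conv.state_arrays().items()}
        if self.bn is not None:
            out.update({f"bn.{k}": v for k, v in self.bn.state_arrays().items()})
        return out

    def load_state_arrays(self, state, prefix=""):
        self.conv.load_state_arrays(state, prefix=f"{prefix}conv.")
        if self.bn is not None:
            self.bn.load_state_arrays(state, prefix=f"{prefix}bn.")


class _InceptionModule(Layer):
    def __init__(self, tag: str, cin: int, cfg: ArchitectureConfig, rng):
        self.tag = tag
        cb = cfg.channels_per_branch
        self.cfg = cfg
        if tag == "A":
            self.branches = [_Branch(cin, cb, cfg.a_kernel, 1, cfg.use_batchnorm, rng)]
            self.out_channels = cb + 2 * cin  # conv + max-pool + avg-pool passthrough
        elif tag == "B":
            self.branches = [
                _Branch(cin, cb, k, 1, cfg.use_batchnorm, rng) for k in cfg.b_kernels
            ]
            self.out_channels = cb * len(cfg.b_kernels)
        elif tag == "C":
            self.branches = [
                _Branch(cin, cb, k, cfg.c_stride, cfg.use_batchnorm, rng)
                for k in cfg.c_kernels
            ]
            self.out_channels = cb * len(cfg.c_kernels)
        else:  # pragma: no cover - guarded by config validation
            raise ValueError(tag)
        self.project = (
            Conv1d(cin, self.out_channels, 1, rng=rng)
            if cfg.use_residual and cin != self.out_channels
            else None
        )
        self.use_residual = cfg.use_residual

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        cfg = self.cfg
        L = x.data.shape[2]
        outs = [b(x, training) for b in self.branches]
        if self.tag == "A":
            outs.append(ad.maxpool1d(x, cfg.a_pool_width))
            outs.append(ad.avgpool1d(x, cfg.a_pool_width))
        if self.tag == "C":
            outs = [
                ad.upsample_nearest(o, cfg.c_stride, target_len=L) for o in outs
            ]
        h = ad.concat(outs, axis=1)
        if self.use_residual:
            skip = self.project(x) if self.project is not None else x
            h = ad.add(h, skip)
        return h

    def parameters(self):
        p = []
        for b in self.branches:
            p += b.parameters()
        if self.project is not None:
            p += self.project.parameters()
        return p

    def state_arrays(self):
        out = {}
        for i, b in enumerate(self.branches):
            out.update({f"branches.{i}.{k}": v for k, v in b.state_arrays().items()})
        if self.project is not None:
            out.update({f"project.{k}": v for k, v in self.project.state_arrays().items()})
        return out

    def load_state_arrays(self, state, prefix=""):
        for i, b in enumerate(self.branches):
            b.load_state_arrays(state, prefix=f"{prefix}branches.{i}.")
        if self.project is not None:
            self.project.load_state_arrays(state, prefix=f"{prefix}project.")


class PeakCNN(Layer):
    """Threshold-learning network over (smoothed depth, annotation) windows."""

    def __init__(self, cfg: ArchitectureConfig, seed: int | None = None):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.stem_x = Conv1d(1, cfg.stem_channels, cfg.stem_kernel, rng=rng)
        self.stem_lam = Conv1d(1, cfg.stem_channels, cfg.stem_kernel, rng=rng)
        cin = 2 * cfg.stem_channels
        self.modules: list[_InceptionModule] = []
        for tag in cfg.module_sequence:
            mod = _InceptionModule(tag, cin, cfg, rng)
            self.modules.append(mod)
            cin = mod.out_channels
        self.head1 = Conv1d(cin, cfg.head_hidden, 1, rng=rng)
        self.head2 = Conv1d(cfg.head_hidden, 1, 1, rng=rng)

    # -- forward ---------------------------------------------------------

    def thresholds_tensor(
        self, x: np.ndarray, lam: np.ndarray, training: bool = False
    ) -> Tensor:
        """Batched forward to the threshold head. x, lam: (N, L) arrays."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        lam = np.atleast_2d(np.asarray(lam, dtype=np.float64))
        if not (np.isfinite(x).all() and np.isfinite(lam).all()):
            raise ValueError("network input contains non-finite values")
        if x.shape[1] != self.cfg.window_bins:
            raise ValueError(
                f"input length {x.shape[1]} != window_bins {self.cfg.window_bins}"
            )
        xt = Tensor(x[:, None, :])
        lt = Tensor(lam[:, None, :])
        hx = ad.relu(self.stem_x(xt))
        hl = ad.relu(self.stem_lam(lt))
        h = ad.concat([hx, hl], axis=1)
        h = ad.maxpool1d(h, self.cfg.stem_pool_width)
        for mod in self.modules:
            h = mod(h, training)
        seg = ad.block_mean_pool(
            h, self.cfg.window_bins // self.cfg.threshold_segments
        )  # (N, C, S)
        hid = ad.relu(self.head1(seg))
        t = self.head2(hid)  # (N, 1, S)
        return ad.channel_mean(t)  # (N, S)

    def forward(self, inputs: ModelInput) -> ModelOutput:
        """Deterministic single-window evaluation (running batch statistics)."""
        t = self.thresholds_tensor(inputs.x, inputs.lam, training=False).data[0]
        expanded = expand_thresholds(t, self.cfg.window_bins)
        probs = sigmoid(inputs.x - expanded)
        return ModelOutput(thresholds=t, probabilities=probs)

    __call__ = forward

    # -- bookkeeping -----------------------------------------------------

    def parameters(self) -> list[Tensor]:
        p = self.stem_x.parameters() + self.stem_lam.parameters()
        for mod in self.modules:
            p += mod.parameters()
        return p + self.head1.parameters() + self.head2.parameters()

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self):
        out = {}
        for name, layer in [("stem_x", self.stem_x), ("stem_lam", self.stem_lam),
                            ("head1", self.head1), ("head2", self.head2)]:
            out.update({f"{name}.{k}": v for k, v in layer.state_arrays().items()})
        for i, mod in enumerate(self.modules):
            out.update({f"modules.{i}.{k}": v for k, v in mod.state_arrays().items()})
        return out

    def load_state_arrays(self, state, prefix=""):
        for name, layer in [("stem_x", self.stem_x), ("stem_lam", self.stem_lam),
                            ("head1", self.head1), ("head2", self.head2)]:
            layer.load_state_arrays(state, prefix=f"{prefix}{name}.")
        for i, mod in enumerate(self.modules):
            mod.load_state_arrays(state, prefix=f"{prefix}modules.{i}.")

    # -- persistence -----------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        """Single-file checkpoint: architecture JSON + weight arrays (npz)."""
        state = self.state_arrays()
        cfg = asdict(self.cfg)
        cfg["module_sequence"] = list(cfg["module_sequence"])
        cfg["b_kernels"] = list(cfg["b_kernels"])
        cfg["c_kernels"] = list(cfg["c_kernels"])
        np.savez(
            path,
            __architecture__=np.frombuffer(
                json.dumps(cfg).encode(), dtype=np.uint8
            ),
            **state,
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "PeakCNN":
        with np.load(path) as data:
            cfg_json = bytes(data["__architecture__"]).decode()
            raw = json.loads(cfg_json)
            for key in ("module_sequence", "b_kernels", "c_kernels"):
                raw[key] = tuple(raw[key])
            model = cls(ArchitectureConfig(**raw))
            model.load_state_arrays(
                {k: v for k, v in data.items() if k != "__architecture__"}
            )
        return model


def build_model(cfg: ArchitectureConfig | None = None, seed: int | None = None) -> PeakCNN:
    """Construct a PeakCNN with reproducible initialization."""
    return PeakCNN(cfg or ArchitectureConfig(), seed=seed)
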