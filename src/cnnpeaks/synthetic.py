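"""Synthetic coverage tracks with known ground truth.

Emulates the statistical structure the caller assumes: per-base depth is
Poisson — a background rate ``lambda_bg`` outside peaks and an elevated
``lambda_peak`` inside disjoint peak intervals — plus occasional short
high-depth artifacts that are *not* peaks (mimicking mapping noise). A ~2 kb
annotation record is co-located with a configurable fraction of peaks
(defaults to 0.66, the share of expert-labeled peaks found near RefSeq TSS in
real ChIP-seq label sets), with further records scattered elsewhere. Expert
labels are emulated by tagging every peak interval PEAK and an equal number
of random peak-free intervals NOPEAK.

Two fidelity tiers: ``simulate_track`` draws independent per-base counts
(fast, no autocorrelation); ``simulate_bam`` converts a track into aligned
single-end reads whose pileup reproduces it within Poisson thinning, giving
read-length autocorrelation and a real indexed BAM for I/O tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pysam

from .types import (
    AnnotationTrack,
    DepthTrack,
    GenomicInterval,
    Label,
    LabeledRegion,
)

__all__ = ["SimConfig", "simulate_track", "simulate_bam", "save_simulation"]

ANNOT_WIDTH = 2_000  # bases per synthetic annotation record
SPIKE_MAX_WIDTH = 50  # bases; artifacts are at most this wide
SPIKE_RATE_MULT = 5.0  # artifact depth rate = mult * lambda_bg


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic contig.

    The default "easy regime" (strong 10x enrichment, 20 peaks of 0.5-2 kb on
    2 Mb) is the reference condition for end-to-end recovery experiments.
    ``noise_spikes`` is the expected artifact count per megabase.
    """

    contig_length: int = 2_000_000
    n_peaks: int = 20
    peak_width_range: tuple[int, int] = (500, 2_000)
    lambda_bg: float = 2.0
    lambda_peak: float = 20.0
    tss_fraction: float = 0.66
    noise_spikes: float = 1.0
    chrom: str = "chrS"
    seed: int = 1337

    def __post_init__(self) -> None:
        lo, hi = self.peak_width_range
        if not (0 < lo <= hi):
            raise ValueError("peak widths must be positive with min <= max")
        if self.n_peaks > 0 and self.lambda_peak <= self.lambda_bg:
            raise ValueError("lambda_peak must exceed lambda_bg (learnable regime)")
        if not (0.0 <= self.tss_fraction <= 1.0):
            raise ValueError("tss_fraction must lie in [0, 1]")
        if self.n_peaks < 0 or self.contig_length <= 0:
            raise ValueError("n_peaks and contig_length must be non-negative/positive")


def _place_disjoint(
    rng: np.random.Generator,
    n: int,
    width_range: tuple[int, int],
    contig: int,
    forbidden: list[tuple[int, int]] | None = None,
    max_tries: int = 200,
) -> list[tuple[int, int]]:
    """Sample n disjoint uniformly-placed intervals, avoiding *forbidden*.

    Each interval is placed by rejection against everything already occupied;
    placement order is randomized width order, deterministic per rng state.
    """
    if n == 0:
        return []
    lo, hi = width_range
    widths = rng.integers(lo, hi + 1, size=n)
    occupied: list[tuple[int, int]] = sorted(forbidden or [])
    placed: list[tuple[int, int]] = []
    for w in widths:
        w = int(w)
        if w > contig:
            raise ValueError(
                f"interval width {w} exceeds the contig ({contig} bases)"
            )
        for _ in range(max_tries):
            s = int(rng.integers(0, contig - w + 1))
            e = s + w
            if not any(s < fe and fs < e for fs, fe in occupied):
                occupied.append((s, e))
                placed.append((s, e))
                break
        else:
            raise ValueError(
                f"could not place {n} disjoint intervals of width {width_range} "
                f"on a contig of {contig} bases"
            )
    return sorted(placed)


def simulate_track(
    cfg: SimConfig | None = None,
) -> tuple[DepthTrack, AnnotationTrack, list[LabeledRegion], list[GenomicInterval]]:
    """Generate (depth, annotation, labels, truth-peak intervals).

    Deterministic per ``cfg.seed``: identical configs give bitwise-identical
    arrays and interval lists.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    contig = GenomicInterval(cfg.chrom, 0, cfg.contig_length)

    peaks = _place_disjoint(rng, cfg.n_peaks, cfg.peak_width_range, cfg.contig_length)
    depth = rng.poisson(cfg.lambda_bg, size=cfg.contig_length).astype(np.float64)
    for s, e in peaks:
        depth[s:e] = rng.poisson(cfg.lambda_peak, size=e - s)

    # short unlabeled artifacts outside peaks
    n_spikes = rng.poisson(cfg.noise_spikes * cfg.contig_length / 1e6)
    spikes = (
        _place_disjoint(
            rng, int(n_spikes), (10, SPIKE_MAX_WIDTH), cfg.contig_length,
            forbidden=peaks,
        )
        if n_spikes
        else []
    )
    for s, e in spikes:
        depth[s:e] = rng.poisson(SPIKE_RATE_MULT * cfg.lambda_bg, size=e - s)

    # annotation: ~2 kb records centered on a tss_fraction share of peaks,
    # plus as many records again scattered at random
    bits = np.zeros(cfg.contig_length, dtype=np.int8)
    n_co = int(round(cfg.tss_fraction * cfg.n_peaks))
    co_idx = rng.choice(cfg.n_peaks, size=n_co, replace=False) if cfg.n_peaks else []
    for i in co_idx:
        s, e = peaks[i]
        center = (s + e) // 2
        a = max(0, center - ANNOT_WIDTH // 2)
        bits[a : min(cfg.contig_length, a + ANNOT_WIDTH)] = 1
    n_extra = max(0, cfg.n_peaks - n_co)
    for _ in range(n_extra):
        a = int(rng.integers(0, max(1, cfg.contig_length - ANNOT_WIDTH)))
        bits[a : a + ANNOT_WIDTH] = 1

    labels = [
        LabeledRegion(GenomicInterval(cfg.chrom, s, e), Label.PEAK) for s, e in peaks
    ]
    negatives = _place_disjoint(
        rng, cfg.n_peaks, cfg.peak_width_range, cfg.contig_length, forbidden=peaks
    )
    labels += [
        LabeledRegion(GenomicInterval(cfg.chrom, s, e), Label.NOPEAK)
        for s, e in negatives
    ]

    truth = [GenomicInterval(cfg.chrom, s, e) for s, e in peaks]
    return (
        DepthTrack(contig, depth),
        AnnotationTrack(contig, bits),
        labels,
        truth,
    )


def simulate_bam(
    track: DepthTrack,
    read_length: int = 50,
    out_path: str | os.PathLike = "synthetic.bam",
    seed: int = 0,
) -> str:
    """Write an indexed coordinate-sorted BAM whose pileup reproduces *track*.

    Read starts at base i are drawn Poisson(depth[i] / read_length), so the
    expected pileup matches the target depth up to edge effects over the last
    read length of the contig.
    """
    contig = track.interval
    if read_length > contig.span:
        raise ValueError("read_length exceeds contig length")
    rng = np.random.default_rng(seed)
    usable = contig.span - read_length + 1
    starts_per_base = rng.poisson(track.depth[:usable] / read_length)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": contig.chrom, "LN": contig.span}],
    }
    out_path = str(out_path)
    n_read = 0
    with pysam.AlignmentFile(out_path, "wb", header=header) as bam:
        for pos in np.flatnonzero(starts_per_base):
            for _ in range(int(starts_per_base[pos])):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"simread_{n_read}"
                a.query_sequence = "A" * read_length
                a.reference_name = contig.chrom
                a.reference_start = int(pos)
                a.mapping_quality = 60
                a.cigarstring = f"{read_length}M"
                a.flag = 0
                bam.write(a)
                n_read += 1
    pysam.index(out_path)
    return out_path


def save_simulation(
    out_dir: str | os.PathLike,
    cfg: SimConfig | None = None,
    with_bam: bool = False,
    read_length: int = 50,
) -> dict[str, str]:
    """Materialize a simulation as plain-text files (plus optional BAM).

    Writes depth.bedgraph, annotation.bed, labels.tsv, truth.bed; returns the
    path of each artifact keyed by name.
    """
    cfg = cfg or SimConfig()
    os.makedirs(out_dir, exist_ok=True)
    depth, annot, labels, truth = simulate_track(cfg)
    paths = {name: os.path.join(str(out_dir), fname) for name, fname in [
        ("depth", "depth.bedgraph"),
        ("annotation", "annotation.bed"),
        ("labels", "labels.tsv"),
        ("truth", "truth.bed"),
    ]}

    with open(paths["depth"], "w") as fh:
        d = depth.depth
        change = np.flatnonzero(np.diff(d)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [d.size]])
        for s, e in zip(starts, ends):
            fh.write(f"{cfg.chrom}\t{s}\t{e}\t{d[s]:g}\n")

    with open(paths["annotation"], "w") as fh:
        b = annot.bits
        change = np.flatnonzero(np.diff(b)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [b.size]])
        for s, e in zip(starts, ends):
            if b[s]:
                fh.write(f"{cfg.chrom}\t{s}\t{e}\n")

    with open(paths["labels"], "w") as fh:
        for region in labels:
            iv = region.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{region.label.value}\n")

    with open(paths["truth"], "w") as fh:
        for iv in truth:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    if with_bam:
        paths["bam"] = os.path.join(str(out_dir), "synthetic.bam")
        simulate_bam(depth, read_length=read_length, out_path=paths["bam"],
                     seed=cfg.seed + 1)
    return paths
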