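"""Shared fixtures: synthetic BAMs built in tmp dirs, tiny network configs."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from cnnpeaks.model import ArchitectureConfig, build_model


def make_bam(path, reads, chrom="chr1", chrom_len=1000, read_len=None):
    """Write an indexed BAM from (start, length) tuples (sorted internally)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": chrom_len}],
    }
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, (start, length) in enumerate(sorted(reads)):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"r{i}"
            a.query_sequence = "A" * length
            a.reference_name = chrom
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{length}M"
            a.flag = 0
            bam.write(a)
    pysam.index(path)
    return path


@pytest.fixture
def bam_factory(tmp_path):
    def _make(reads, chrom="chr1", chrom_len=1000, name="test.bam"):
        return make_bam(tmp_path / name, reads, chrom=chrom, chrom_len=chrom_len)

    return _make


TINY_ARCH = ArchitectureConfig(
    window_bins=40,
    threshold_segments=4,
    stem_channels=2,
    channels_per_branch=2,
    head_hidden=8,
)


@pytest.fixture(scope="session")
def tiny_model():
    """A small untrained network for shape/contract tests."""
    return build_model(TINY_ARCH, seed=0)
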