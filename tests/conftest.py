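from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from nanomsp.io_formats import ManifestEntry, SampleManifest


def make_bedmethyl_line(chrom, pos, depth, pct, strand="+"):
    return (
        f"{chrom}\t{pos}\t{pos + 1}\t5mC\t{min(depth, 1000)}\t{strand}\t"
        f"{pos}\t{pos + 1}\t0,0,0\t{depth}\t{pct:.2f}"
    )


@pytest.fixture
def write_bedmethyl_file(tmp_path):
    """Factory writing a bedmethyl file from (pos, depth, pct[, strand])
    tuples; returns the path."""

    counter = iter(range(10_000))

    def _write(rows, chrom="chr1", name=None):
        name = name or f"sample_{next(counter)}"
        path = tmp_path / f"{name}.bedmethyl"
        lines = []
        for row in rows:
            pos, depth, pct = row[:3]
            strand = row[3] if len(row) > 3 else "+"
            lines.append(make_bedmethyl_line(chrom, pos, depth, pct, strand))
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return path

    return _write


@pytest.fixture
def manifest_3v3():
    return SampleManifest(
        [ManifestEntry(f"tumor_{i}", "tumor") for i in range(1, 4)]
        + [ManifestEntry(f"control_{i}", "control") for i in range(1, 4)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
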