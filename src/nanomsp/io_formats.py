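"""Readers and writers for the genomic file formats consumed by the pipeline.

Handles the extended-BED "bedmethyl" dialect emitted by nanopore
modified-base pileup tools (column 10 = valid coverage, column 11 =
percent modified), plain BED interval files, FASTA, sample manifests and
chromosome-size tables.  All internal coordinates are 0-based half-open
(BED native); human-readable reports print 1-based inclusive.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class CpGSiteMeasurement:
    """Methylation call summary for one CpG site in one sample.

    ``pos`` is the 0-based position of the C of the CpG dinucleotide on
    the forward strand once strands have been aggregated; before
    aggregation a ``-`` record sits at the G (``pos`` of the C plus one).
    """

    chrom: str
    pos: int
    depth: int
    meth_pct: float
    sample_id: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0.0 <= self.meth_pct <= 100.0):
            raise ValueError(f"meth_pct {self.meth_pct} outside [0, 100]")


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    group: str  # "tumor" | "control"
    path: str | None = None


@dataclass
class SampleManifest:
    """Sample sheet labeling each sample tumor or control."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        for e in self.entries:
            if e.group not in {"tumor", "control"}:
                raise ValueError(f"unknown group {e.group!r} for {e.sample_id}")
        if not self.tumor_ids or not self.control_ids:
            raise ValueError("manifest needs at least one tumor and one control sample")

    @property
    def tumor_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries if e.group == "tumor"]

    @property
    def control_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries if e.group == "control"]

    def group_of(self, sample_id: str) -> str:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e.group
        raise KeyError(f"sample {sample_id!r} not in manifest")


@dataclass
class BedmethylParseReport:
    path: str
    n_rows: int = 0
    n_kept: int = 0
    n_dropped_low_depth: int = 0


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _open_text(path: str | os.PathLike) -> TextIO:
    """Open a possibly gzip-compressed text file."""
    path = os.fspath(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


# ---------------------------------------------------------------------------
# bedmethyl
# ---------------------------------------------------------------------------


def read_bedmethyl(
    path: str | os.PathLike,
    min_depth: int = 1,
    sample_id: str | None = None,
    report: BedmethylParseReport | None = None,
) -> Iterator[CpGSiteMeasurement]:
    """Stream strand-tagged CpG measurements from a bedmethyl file.

    Expects the extended-BED dialect with >= 11 tab-separated columns
    where column 10 is the count of valid modification calls and column
    11 the percent of calls methylated.  Rows with depth below
    ``min_depth`` are dropped and counted in ``report``.

    Raises
    ------
    FormatError
        On missing columns, non-numeric coverage/percent, or percent
        outside [0, 100]; the message names the offending line.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    if sample_id is None:
        sample_id = Path(os.fspath(path)).name.split(".")[0]
    if report is None:
        report = BedmethylParseReport(path=os.fspath(path))
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 11 columns, got {len(fields)}"
                )
            report.n_rows += 1
            chrom = fields[0]
            try:
                start = int(fields[1])
                depth = int(fields[9])
                meth_pct = float(fields[10])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if not (0.0 <= meth_pct <= 100.0):
                raise FormatError(
                    f"{path}: line {lineno}: percent methylated {meth_pct} "
                    "outside [0, 100]"
                )
            strand = fields[5] if fields[5] in {"+", "-"} else "."
            if depth < min_depth:
                report.n_dropped_low_depth += 1
                continue
            report.n_kept += 1
            yield CpGSiteMeasurement(
                chrom=chrom,
                pos=start,
                depth=depth,
                meth_pct=meth_pct,
                sample_id=sample_id,
                strand=strand,
            )


def aggregate_cpg_strands(
    records: Iterable[CpGSiteMeasurement],
) -> Iterator[CpGSiteMeasurement]:
    """Merge the two strands of each CpG into one forward-strand site.

    A ``+`` record at position p and a ``-`` record at p+1 (same chrom
    and sample) merge into one site at p with summed depth and a
    depth-weighted mean percent.  Unpaired records pass through
    unchanged.  Input must be sorted by (chrom, pos).
    """
    pending: CpGSiteMeasurement | None = None
    last_key: tuple[str, int] | None = None
    for rec in records:
        key = (rec.chrom, rec.pos)
        if last_key is not None and (rec.chrom, rec.pos) < last_key:
            raise ValueError(
                f"records not sorted by (chrom, pos) at {rec.chrom}:{rec.pos}"
            )
        last_key = key
        if pending is not None:
            if (
                rec.strand == "-"
                and pending.strand == "+"
                and rec.chrom == pending.chrom
                and rec.pos == pending.pos + 1
                and rec.sample_id == pending.sample_id
            ):
                depth = pending.depth + rec.depth
                if depth > 0:
                    pct = (
                        pending.depth * pending.meth_pct + rec.depth * rec.meth_pct
                    ) / depth
                else:
                    pct = 0.0
                yield replace(pending, depth=depth, meth_pct=pct, strand=".")
                pending = None
                continue
            yield pending
            pending = None
        if rec.strand == "+":
            pending = rec
        else:
            yield rec
    if pending is not None:
        yield pending


def write_bedmethyl(
    records: Iterable[CpGSiteMeasurement], path: str | os.PathLike
) -> None:
    """Write measurements back out in the extended-BED bedmethyl dialect.

    Round-trips through :func:`read_bedmethyl` (coordinates and depths
    bit-exact, percents to two decimals as emitted by pileup tools).
    """
    with open(path, "wt") as fh:
        for rec in records:
            strand = rec.strand if rec.strand in {"+", "-"} else "+"
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.pos + 1}\t5mC\t"
                f"{min(rec.depth, 1000)}\t{strand}\t{rec.pos}\t{rec.pos + 1}\t"
                f"0,0,0\t{rec.depth}\t{rec.meth_pct:.2f}\n"
            )


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------


def read_bed_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a BED3+ file into sorted 0-based half-open intervals."""
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "."
            out.append(GenomicInterval(fields[0], start, end, name=name, strand=strand))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed_intervals(
    intervals: Sequence[GenomicInterval], path: str | os.PathLike
) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def expand_target_regions(
    islands: Sequence[GenomicInterval],
    buffer: int,
    chrom_sizes: Mapping[str, int],
) -> list[GenomicInterval]:
    """Grow each interval by ``buffer`` nt on both sides, clip to the
    chromosome, and merge overlapping or touching results."""
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    expanded: list[GenomicInterval] = []
    for iv in islands:
        if iv.chrom not in chrom_sizes:
            raise ValueError(f"chromosome {iv.chrom!r} missing from chrom_sizes")
        size = chrom_sizes[iv.chrom]
        start = max(0, iv.start - buffer)
        end = min(size, iv.end + buffer)
        if start < end:
            expanded.append(GenomicInterval(iv.chrom, start, end, name=iv.name))
    expanded.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in expanded:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end, name=prev.name)
        else:
            merged.append(iv)
    return merged


def mean_region_depth(
    records: Iterable[CpGSiteMeasurement],
    regions: Sequence[GenomicInterval],
) -> dict[GenomicInterval, float]:
    """Mean CpG-site depth per region.  Regions without sites are absent
    from the result."""
    sums: dict[GenomicInterval, list[float]] = {}
    recs = list(records)
    for region in regions:
        for rec in recs:
            if region.contains(rec.chrom, rec.pos):
                sums.setdefault(region, []).append(rec.depth)
    return {region: sum(v) / len(v) for region, v in sums.items()}


# ---------------------------------------------------------------------------
# scored-region BED output
# ---------------------------------------------------------------------------


def write_regions_bed(regions: Sequence, path: str | os.PathLike) -> None:
    """Write scored amplicon regions as BED6 plus a raw-score column.

    Column 5 carries the score clamped to [0, 1000] per the BED spec;
    column 7 preserves the raw score.  Output round-trips through
    :func:`read_bed_intervals`.
    """
    with open(path, "wt") as fh:
        for i, region in enumerate(regions):
            span = region.span
            score = float(region.score) if region.score is not None else 0.0
            clamped = int(max(0, min(1000, round(score))))
            name = span.name or f"region_{i + 1}"
            fh.write(
                f"{span.chrom}\t{span.start}\t{span.end}\t{name}\t"
                f"{clamped}\t+\t{score:.6g}\n"
            )


# ---------------------------------------------------------------------------
# manifests, chrom sizes, FASTA
# ---------------------------------------------------------------------------


def read_manifest(path: str | os.PathLike) -> SampleManifest:
    """Read a sample manifest TSV: sample_id, group, [path]."""
    entries: list[ManifestEntry] = []
    base = Path(os.fspath(path)).parent
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "sample_id":  # header
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected >= 2 columns")
            file_path = fields[2] if len(fields) > 2 and fields[2] else None
            if file_path is not None and not os.path.isabs(file_path):
                file_path = str(base / file_path)
            entries.append(ManifestEntry(fields[0], fields[1].lower(), file_path))
    return SampleManifest(entries)


def write_manifest(manifest: SampleManifest, path: str | os.PathLike) -> None:
    with open(path, "wt") as fh:
        fh.write("sample_id\tgroup\tpath\n")
        for e in manifest.entries:
            fh.write(f"{e.sample_id}\t{e.group}\t{e.path or ''}\n")


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column chrom-sizes TSV."""
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return sizes


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an uppercase {name: sequence} mapping."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in seqs:
                raise FormatError(f"{path}: duplicate sequence name {record.id!r}")
            seqs[record.id] = str(record.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
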