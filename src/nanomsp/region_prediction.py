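"""Prediction of tumor-vs-control differentially methylated primer regions.

The caller scans per-CpG methylation calls for sites that are methylated
in at least one tumor sample while staying unmethylated across all
control samples, groups such sites into primer-length windows, pairs
windows into amplicon-sized regions, scores each region by tumor
methylation and coverage, and finally keeps the best region of each
overlapping cluster.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .io_formats import (
    CpGSiteMeasurement,
    GenomicInterval,
    SampleManifest,
    aggregate_cpg_strands,
    read_bedmethyl,
)


@dataclass
class PredictionConfig:
    """Tunable thresholds for region prediction.

    Defaults mirror the upstream caller's printed option names:
    ``--min-cpgs 3 --max-meth-control 10 --min-primer-length 18
    --max-primer-length 24 --min-amplicon-length 60
    --max-amplicon-length 400``.

    ``min_meth_tumor`` quantifies "methylated in at least one tumor
    sample"; 50% (a conventional hemimethylation midpoint) is this
    implementation's choice and is deliberately exposed here.
    """

    min_cpgs: int = 3
    max_meth_control: float = 10.0
    min_primer_len: int = 18
    max_primer_len: int = 24
    min_amplicon_len: int = 60
    max_amplicon_len: int = 400
    min_meth_tumor: float = 50.0
    min_site_depth: int = 5
    score_threshold: float = 0.0
    strand_aggregate: bool = True
    parse_min_depth: int = 1

    def __post_init__(self) -> None:
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")
        for lo, hi, label in (
            (self.min_primer_len, self.max_primer_len, "primer length"),
            (self.min_amplicon_len, self.max_amplicon_len, "amplicon length"),
        ):
            if not (0 < lo <= hi):
                raise ValueError(f"invalid {label} bounds [{lo}, {hi}]")
        for pct, label in (
            (self.max_meth_control, "max_meth_control"),
            (self.min_meth_tumor, "min_meth_tumor"),
        ):
            if not (0.0 <= pct <= 100.0):
                raise ValueError(f"{label} {pct} outside [0, 100]")
        if self.min_site_depth < 0:
            raise ValueError("min_site_depth must be >= 0")


class CpGStatus(enum.Enum):
    ELIGIBLE = "eligible"
    LOW_DEPTH = "low_depth"
    CONTROL_METHYLATED = "control_methylated"
    TUMOR_UNMETHYLATED = "tumor_unmethylated"


@dataclass(frozen=True)
class PrimerSiteCandidate:
    """A primer-length window holding a maximal group of eligible CpGs."""

    interval: GenomicInterval
    cpg_positions: tuple[int, ...]

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class MSPRegion:
    """A pair of candidate primer sites spanning one amplicon."""

    fwd_site: PrimerSiteCandidate
    rev_site: PrimerSiteCandidate
    span: GenomicInterval
    score: float | None = None

    @property
    def cpg_positions(self) -> tuple[int, ...]:
        return self.fwd_site.cpg_positions + self.rev_site.cpg_positions


@dataclass
class PredictionReport:
    """Per-stage record counts for one prediction run."""

    n_records: int = 0
    n_sites: int = 0
    n_eligible: int = 0
    n_primer_sites: int = 0
    n_regions: int = 0
    n_above_threshold: int = 0
    n_selected: int = 0
    status_counts: dict[str, int] = field(default_factory=dict)
    island_overlap_fraction: float | None = None


@dataclass
class PredictionResult:
    regions: list[MSPRegion]
    pre_cluster_regions: list[MSPRegion]
    report: PredictionReport


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def classify_cpg_status(
    tumor: Sequence[CpGSiteMeasurement],
    control: Sequence[CpGSiteMeasurement],
    cfg: PredictionConfig,
) -> CpGStatus:
    """Classify one CpG site from its per-sample measurements.

    Eligible iff every sample has depth >= ``min_site_depth``, every
    control sample has meth_pct <= ``max_meth_control`` and at least one
    tumor sample has meth_pct >= ``min_meth_tumor``.
    """
    if not tumor or not control:
        raise ValueError("classify_cpg_status needs >= 1 tumor and >= 1 control measurement")
    if any(m.depth < cfg.min_site_depth for m in (*tumor, *control)):
        return CpGStatus.LOW_DEPTH
    if any(m.meth_pct > cfg.max_meth_control for m in control):
        return CpGStatus.CONTROL_METHYLATED
    if not any(m.meth_pct >= cfg.min_meth_tumor for m in tumor):
        return CpGStatus.TUMOR_UNMETHYLATED
    return CpGStatus.ELIGIBLE


def find_primer_sites(
    positions: Sequence[int],
    cfg: PredictionConfig,
    chrom: str = "chr",
) -> list[PrimerSiteCandidate]:
    """Group eligible CpG positions into primer-length windows.

    For each anchor CpG, the maximal run of eligible CpGs whose
    dinucleotides fit in a ``max_primer_len`` window is taken; runs with
    at least ``min_cpgs`` CpGs that are not subsets of the previous run
    become candidates.  The candidate interval starts at the first CpG
    and is extended to ``min_primer_len`` when the run is shorter.
    """
    pos = sorted(positions)
    if pos != list(positions):
        raise ValueError("positions must be sorted ascending")
    out: list[PrimerSiteCandidate] = []
    n = len(pos)
    j = 0
    prev_j = -1
    for i in range(n):
        if j < i:
            j = i
        # widest run anchored at i: CpG dinucleotide occupies [p, p+2)
        while j + 1 < n and pos[j + 1] + 2 - pos[i] <= cfg.max_primer_len:
            j += 1
        if j - i + 1 < cfg.min_cpgs:
            continue
        if j == prev_j:  # subset of the previous (wider) run
            continue
        prev_j = j
        length = max(cfg.min_primer_len, pos[j] + 2 - pos[i])
        out.append(
            PrimerSiteCandidate(
                interval=GenomicInterval(chrom, pos[i], pos[i] + length),
                cpg_positions=tuple(pos[i : j + 1]),
            )
        )
    return out


def pair_sites_to_regions(
    sites: Sequence[PrimerSiteCandidate],
    cfg: PredictionConfig,
) -> list[MSPRegion]:
    """Pair non-overlapping primer sites into amplicon-length regions.

    Every ordered pair (a, b) with a.end <= b.start whose outer span
    b.end - a.start lies within the amplicon bounds yields one region.
    """
    ordered = sorted(sites, key=lambda s: (s.start, s.end))
    out: list[MSPRegion] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if b.start - a.start > cfg.max_amplicon_len:
                break
            span_len = b.end - a.start
            if (
                b.start < a.end
                or span_len < cfg.min_amplicon_len
                or span_len > cfg.max_amplicon_len
            ):
                continue
            span = GenomicInterval(a.interval.chrom, a.start, b.end)
            out.append(MSPRegion(fwd_site=a, rev_site=b, span=span))
    return out


def score_region(
    region: MSPRegion,
    calls: Mapping[int, Mapping[str, CpGSiteMeasurement]],
    tumor_ids: Sequence[str],
) -> float:
    """Score a region by tumor methylation and coverage.

    score = sum over tumor samples and over the CpGs of both primer
    sites of (meth_pct / 100) * depth.  Monotone non-decreasing in every
    methylation percentage and depth.
    """
    total = 0.0
    for pos in region.cpg_positions:
        per_sample = calls.get(pos)
        if per_sample is None:
            raise ValueError(f"no measurements at CpG {pos}")
        for sid in tumor_ids:
            m = per_sample.get(sid)
            if m is None:
                raise ValueError(f"missing measurement for sample {sid!r} at CpG {pos}")
            total += (m.meth_pct / 100.0) * m.depth
    return total


def cluster_and_select(
    regions: Sequence[MSPRegion],
    score_threshold: float = 0.0,
) -> list[MSPRegion]:
    """Keep the best region of each overlapping cluster.

    Regions scoring below the threshold are removed; survivors are
    processed greedily in descending score order (ties: longer span,
    then smaller start) and suppressed when their span overlaps an
    already-selected region.
    """
    kept = [r for r in regions if r.score is not None and r.score >= score_threshold]
    kept.sort(key=lambda r: (-r.score, -(len(r.span)), r.span.chrom, r.span.start))
    selected: list[MSPRegion] = []
    for region in kept:
        if any(region.span.overlaps(s.span) for s in selected):
            continue
        selected.append(region)
    selected.sort(key=lambda r: (r.span.chrom, r.span.start, r.span.end))
    return selected


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def _collect_calls(
    manifest: SampleManifest,
    cfg: PredictionConfig,
    paths: Mapping[str, str] | None = None,
) -> tuple[dict[str, dict[int, dict[str, CpGSiteMeasurement]]], int]:
    """Read every sample's bedmethyl into {chrom: {pos: {sample: rec}}}."""
    calls: dict[str, dict[int, dict[str, CpGSiteMeasurement]]] = {}
    n_records = 0
    for entry in manifest.entries:
        path = paths[entry.sample_id] if paths else entry.path
        if path is None:
            raise ValueError(f"no bedmethyl path for sample {entry.sample_id!r}")
        stream = read_bedmethyl(path, min_depth=cfg.parse_min_depth, sample_id=entry.sample_id)
        records: Iterable[CpGSiteMeasurement] = stream
        if cfg.strand_aggregate:
            records = aggregate_cpg_strands(records)
        for rec in records:
            n_records += 1
            calls.setdefault(rec.chrom, {}).setdefault(rec.pos, {})[entry.sample_id] = rec
    return calls, n_records


def predict_msp_regions(
    manifest: SampleManifest,
    cfg: PredictionConfig | None = None,
    islands: Sequence[GenomicInterval] | None = None,
    paths: Mapping[str, str] | None = None,
) -> PredictionResult:
    """Run the full prediction pipeline.

    read -> aggregate -> classify -> find sites -> pair -> score ->
    threshold/cluster.  ``paths`` may override the manifest's bedmethyl
    paths.  When ``islands`` is given, the report carries the fraction
    of scored regions overlapping an island.
    """
    cfg = cfg or PredictionConfig()
    report = PredictionReport()
    calls, report.n_records = _collect_calls(manifest, cfg, paths)
    tumor_ids, control_ids = manifest.tumor_ids, manifest.control_ids

    status_counts: dict[str, int] = {s.value: 0 for s in CpGStatus}
    all_regions: list[MSPRegion] = []
    for chrom in sorted(calls):
        per_pos = calls[chrom]
        report.n_sites += len(per_pos)
        eligible: list[int] = []
        for pos in sorted(per_pos):
            per_sample = per_pos[pos]
            tumor = [per_sample[s] for s in tumor_ids if s in per_sample]
            control = [per_sample[s] for s in control_ids if s in per_sample]
            if not tumor or not control:
                status_counts[CpGStatus.LOW_DEPTH.value] += 1
                continue
            if len(tumor) < len(tumor_ids) or len(control) < len(control_ids):
                # a sample with no call at this site cannot satisfy the
                # all-samples depth criterion
                status_counts[CpGStatus.LOW_DEPTH.value] += 1
                continue
            status = classify_cpg_status(tumor, control, cfg)
            status_counts[status.value] += 1
            if status is CpGStatus.ELIGIBLE:
                eligible.append(pos)
        sites = find_primer_sites(eligible, cfg, chrom=chrom)
        report.n_primer_sites += len(sites)
        regions = pair_sites_to_regions(sites, cfg)
        scored = [
            replace(r, score=score_region(r, per_pos, tumor_ids)) for r in regions
        ]
        all_regions.extend(scored)

    report.status_counts = status_counts
    report.n_eligible = status_counts[CpGStatus.ELIGIBLE.value]
    report.n_regions = len(all_regions)
    report.n_above_threshold = sum(
        1 for r in all_regions if r.score >= cfg.score_threshold
    )
    if islands is not None and all_regions:
        n_overlap = sum(
            1
            for r in all_regions
            if any(r.span.overlaps(isl) for isl in islands)
        )
        report.island_overlap_fraction = n_overlap / len(all_regions)
    selected = cluster_and_select(all_regions, cfg.score_threshold)
    report.n_selected = len(selected)
    return PredictionResult(
        regions=selected, pre_cluster_regions=all_regions, report=report
    )


def validate_region(
    region: MSPRegion,
    calls: Mapping[int, Mapping[str, CpGSiteMeasurement]],
    manifest: SampleManifest,
    cfg: PredictionConfig,
) -> list[str]:
    """Re-check every config bound for one emitted region against raw
    calls; returns a list of violations (empty = valid)."""
    problems: list[str] = []
    for site in (region.fwd_site, region.rev_site):
        length = len(site.interval)
        if not (cfg.min_primer_len <= length <= cfg.max_primer_len):
            problems.append(f"site length {length} outside primer bounds")
        if len(site.cpg_positions) < cfg.min_cpgs:
            problems.append(f"site has {len(site.cpg_positions)} CpGs < {cfg.min_cpgs}")
        for pos in site.cpg_positions:
            if not site.interval.contains(site.interval.chrom, pos):
                problems.append(f"CpG {pos} outside site interval")
            per_sample = calls.get(pos, {})
            tumor = [per_sample[s] for s in manifest.tumor_ids if s in per_sample]
            control = [per_sample[s] for s in manifest.control_ids if s in per_sample]
            if (
                len(tumor) < len(manifest.tumor_ids)
                or len(control) < len(manifest.control_ids)
                or classify_cpg_status(tumor, control, cfg) is not CpGStatus.ELIGIBLE
            ):
                problems.append(f"CpG {pos} not eligible")
    span_len = len(region.span)
    if not (cfg.min_amplicon_len <= span_len <= cfg.max_amplicon_len):
        problems.append(f"span length {span_len} outside amplicon bounds")
    if region.fwd_site.end > region.rev_site.start:
        problems.append("primer sites overlap")
    return problems
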