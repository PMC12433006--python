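"""Synthetic fixtures emulating every input the pipeline consumes.

Generates a reference with GC-rich CpG islands in AT-rich background, a
set of planted differentially methylated (DM) islands, per-sample
bedmethyl files with negative-binomial depth and binomial methylation
counts under a linear tumor-purity mixture, and qPCR CT tables whose
target CT decreases with the methylation fraction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    GenomicInterval,
    ManifestEntry,
    SampleManifest,
    write_bed_intervals,
    write_fasta,
    write_manifest,
)


@dataclass
class SimulationConfig:
    """Knobs for the fixture generator.

    Island length and GC defaults echo genome-wide CpG-island annotation
    summaries (mean length 777 nt, GC 67%); the depth regime and the
    3 tumor / 3 control design echo a small nanopore pilot with ~10-30x
    island coverage and 70-80% tumor cell content.
    """

    seed: int = 0
    chrom: str = "chr1"
    n_islands: int = 20
    island_len_mean: float = 777.0
    island_len_sd: float = 120.0
    island_min_len: int = 200
    island_gc: float = 0.67
    background_gc: float = 0.30
    spacer_len: int = 1000
    cpg_spacing: int = 8
    dm_fraction: float = 0.5
    p_meth_tumor: float = 0.9
    p_meth_control: float = 0.02
    purity_range: tuple[float, float] = (0.7, 0.8)
    depth_mean: float = 15.0
    depth_dispersion: float = 10.0
    n_tumor: int = 3
    n_control: int = 3
    split_strands: bool = True
    # qPCR signal model
    ct_ref_mean: float = 20.0
    ct_ref_sd: float = 0.5
    qpcr_base_delta: float = 20.0
    qpcr_slope: float = 18.0
    qpcr_sigma: float = 1.0
    qpcr_censor_ct: float = 43.0

    def __post_init__(self) -> None:
        for p, label in (
            (self.p_meth_tumor, "p_meth_tumor"),
            (self.p_meth_control, "p_meth_control"),
            (self.dm_fraction, "dm_fraction"),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{label} {p} outside [0, 1]")
        lo, hi = self.purity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"purity_range {self.purity_range} outside [0, 1]")
        if self.n_tumor < 1 or self.n_control < 1:
            raise ValueError("need >= 1 tumor and >= 1 control sample")


@dataclass
class SimulatedReference:
    genome: dict[str, str]
    islands: list[GenomicInterval]
    dm_islands: list[GenomicInterval]  # subset flagged differentially methylated

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}


@dataclass
class SimulatedMethylome:
    reference: SimulatedReference
    manifest: SampleManifest
    purities: dict[str, float]  # tumor purity per sample (controls: 0.0)
    bedmethyl_paths: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=n, p=p))


def _island_sequence(rng: np.random.Generator, length: int, gc: float, spacing: int) -> str:
    """Island sequence with a CG planted every ``spacing`` nt; remaining
    bases drawn at the island GC level (incidental extra CpGs allowed)."""
    bases = _random_bases(rng, length, gc)
    for start in range(0, length - 1, spacing):
        bases[start] = "C"
        bases[start + 1] = "G"
    return "".join(bases)


def simulate_reference(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedReference:
    """Build a single-chromosome reference with embedded CpG islands and
    a planted-truth DM subset (first ``dm_fraction`` of islands after a
    seeded shuffle)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    parts: list[str] = []
    islands: list[GenomicInterval] = []
    pos = 0
    n_dm = round(cfg.n_islands * cfg.dm_fraction)
    dm_idx = set(rng.permutation(cfg.n_islands)[:n_dm].tolist())
    for i in range(cfg.n_islands):
        spacer = "".join(_random_bases(rng, cfg.spacer_len, cfg.background_gc))
        parts.append(spacer)
        pos += cfg.spacer_len
        length = int(
            max(cfg.island_min_len, round(rng.normal(cfg.island_len_mean, cfg.island_len_sd)))
        )
        parts.append(_island_sequence(rng, length, cfg.island_gc, cfg.cpg_spacing))
        name = f"island_{i + 1}" + ("_dm" if i in dm_idx else "")
        islands.append(GenomicInterval(cfg.chrom, pos, pos + length, name=name))
        pos += length
    parts.append("".join(_random_bases(rng, cfg.spacer_len, cfg.background_gc)))
    genome = {cfg.chrom: "".join(parts)}
    dm = [iv for i, iv in enumerate(islands) if i in dm_idx]
    return SimulatedReference(genome=genome, islands=islands, dm_islands=dm)


# ---------------------------------------------------------------------------
# bedmethyl
# ---------------------------------------------------------------------------


def _negbin(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    # NB parameterized by mean and dispersion (number of failures r):
    # var = mean + mean^2 / r
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def find_cpg_positions(seq: str) -> list[int]:
    """0-based positions of the C of every CG dinucleotide."""
    out = []
    start = seq.find("CG")
    while start != -1:
        out.append(start)
        start = seq.find("CG", start + 1)
    return out


def methylation_probability(
    in_dm_island: bool, group: str, purity: float, cfg: SimulationConfig
) -> float:
    """Linear two-population purity mixture of tumor and control
    methylation probabilities."""
    if group == "tumor" and in_dm_island:
        return purity * cfg.p_meth_tumor + (1.0 - purity) * cfg.p_meth_control
    return cfg.p_meth_control


def _bedmethyl_row(chrom: str, pos: int, strand: str, depth: int, meth: int) -> str:
    pct = 100.0 * meth / depth if depth > 0 else 0.0
    return (
        f"{chrom}\t{pos}\t{pos + 1}\t5mC\t{min(depth, 1000)}\t{strand}\t"
        f"{pos}\t{pos + 1}\t0,0,0\t{depth}\t{pct:.2f}\n"
    )


def simulate_bedmethyl(
    reference: SimulatedReference,
    cfg: SimulationConfig,
    outdir: str | os.PathLike,
    rng: np.random.Generator | None = None,
) -> SimulatedMethylome:
    """Write one bedmethyl file per sample plus a manifest TSV.

    Per CpG and sample, depth ~ NegBin(mean, dispersion) and the
    methylated count ~ Binomial(depth, p) with p from the purity
    mixture.  With ``split_strands`` each strand gets an independent
    half-mean depth draw (+ record at the C, - record at the G).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sample_ids = [f"tumor_{i + 1}" for i in range(cfg.n_tumor)]
    sample_ids += [f"control_{i + 1}" for i in range(cfg.n_control)]
    groups = ["tumor"] * cfg.n_tumor + ["control"] * cfg.n_control
    lo, hi = cfg.purity_range
    purities = {
        sid: (float(rng.uniform(lo, hi)) if grp == "tumor" else 0.0)
        for sid, grp in zip(sample_ids, groups)
    }

    dm = reference.dm_islands
    entries: list[ManifestEntry] = []
    paths: dict[str, str] = {}
    for sid, grp in zip(sample_ids, groups):
        path = outdir / f"{sid}.bedmethyl"
        with open(path, "wt") as fh:
            for chrom, seq in reference.genome.items():
                for pos in find_cpg_positions(seq):
                    in_dm = any(iv.contains(chrom, pos) for iv in dm)
                    p = methylation_probability(in_dm, grp, purities[sid], cfg)
                    if cfg.split_strands:
                        for strand, at in (("+", pos), ("-", pos + 1)):
                            depth = int(
                                _negbin(rng, cfg.depth_mean / 2, cfg.depth_dispersion, 1)[0]
                            )
                            meth = int(rng.binomial(depth, p)) if depth else 0
                            fh.write(_bedmethyl_row(chrom, at, strand, depth, meth))
                    else:
                        depth = int(_negbin(rng, cfg.depth_mean, cfg.depth_dispersion, 1)[0])
                        meth = int(rng.binomial(depth, p)) if depth else 0
                        fh.write(_bedmethyl_row(chrom, pos, "+", depth, meth))
        entries.append(ManifestEntry(sid, grp, str(path)))
        paths[sid] = str(path)

    manifest = SampleManifest(entries)
    write_manifest(manifest, outdir / "manifest.tsv")
    return SimulatedMethylome(
        reference=reference, manifest=manifest, purities=purities, bedmethyl_paths=paths
    )


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_qpcr(
    methylome: SimulatedMethylome,
    cfg: SimulationConfig,
    path: str | os.PathLike,
    markers: list[tuple[str, bool]] | None = None,
    rng: np.random.Generator | None = None,
) -> None:
    """Write a CT table TSV (sample_id, marker, ct_target, ct_ref).

    ct_ref ~ Normal(ct_ref_mean, ct_ref_sd); ct_target = ct_ref +
    base_delta - slope * methylation_fraction + Normal(0, sigma),
    censored above the cycle maximum.  ``markers`` is a list of
    (name, is_differentially_methylated); default one DM marker per
    planted DM island.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    if markers is None:
        markers = [(iv.name or f"dm_{i}", True) for i, iv in enumerate(methylome.reference.dm_islands)]
    with open(path, "wt") as fh:
        fh.write("sample_id\tmarker\tct_target\tct_ref\n")
        for entry in methylome.manifest.entries:
            purity = methylome.purities[entry.sample_id]
            for name, is_dm in markers:
                frac = methylation_probability(is_dm, entry.group, purity, cfg)
                ct_ref = float(rng.normal(cfg.ct_ref_mean, cfg.ct_ref_sd))
                ct_target = (
                    ct_ref
                    + cfg.qpcr_base_delta
                    - cfg.qpcr_slope * frac
                    + float(rng.normal(0.0, cfg.qpcr_sigma))
                )
                target = "NA" if ct_target > cfg.qpcr_censor_ct else f"{ct_target:.4f}"
                fh.write(f"{entry.sample_id}\t{name}\t{target}\t{ct_ref:.4f}\n")


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------


def simulate_all(cfg: SimulationConfig, outdir: str | os.PathLike) -> SimulatedMethylome:
    """Generate reference FASTA, island/truth BEDs, bedmethyl files,
    manifest and CT table into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    reference = simulate_reference(cfg, rng)
    write_fasta(reference.genome, outdir / "reference.fa")
    write_bed_intervals(reference.islands, outdir / "islands.bed")
    write_bed_intervals(reference.dm_islands, outdir / "truth_dm.bed")
    with open(outdir / "reference.chrom.sizes", "wt") as fh:
        for chrom, size in reference.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    methylome = simulate_bedmethyl(reference, cfg, outdir, rng=rng)
    simulate_qpcr(methylome, cfg, outdir / "ct_table.tsv", rng=rng)
    return methylome
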