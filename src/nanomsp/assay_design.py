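"""In-silico bisulfite conversion and constraint-based MSP oligo design.

Primers and hydrolysis probes are designed against the methylated-allele
bisulfite-converted template of a predicted region (plus flanks), under
the assay's constraint rules: primer length 14-22 nt ending preferably
on C, amplicons of 80-400 bp with at least three CpGs, melting
temperature difference below 5 degC, probes 20-30 nt near the forward
primer's 3' end with no 5' guanine, no palindrome, and a Tm 5-10 degC
above the primers.  Dimer and hairpin checks are ungapped
complementarity-run heuristics, not thermodynamic folding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_formats import GenomicInterval

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# bisulfite conversion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BisulfiteTemplate:
    """A sequence with its bisulfite conversion and tracked C positions.

    ``cpg_positions`` hold retained (methylated) Cs; ``converted_positions``
    hold C->T conversions.  Both index into the designed strand: the
    sequence as given for OT (original top), its reverse complement for
    OB (original bottom).
    """

    source_seq: str
    converted_seq: str
    strand: str  # "OT" | "OB"
    allele: str  # "methylated" | "unmethylated"
    cpg_positions: tuple[int, ...]
    converted_positions: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.converted_seq)


def bisulfite_convert(seq: str, allele: str = "methylated", strand: str = "OT") -> BisulfiteTemplate:
    """Convert a DNA sequence as bisulfite treatment would.

    Unmethylated cytosines deaminate to uracil and read as T; on the
    methylated allele, Cs of CpG dinucleotides are protected and remain
    C.  OT operates on the sequence as given, OB on its reverse
    complement.  N passes through.
    """
    if allele not in {"methylated", "unmethylated"}:
        raise ValueError(f"unknown allele {allele!r}")
    if strand not in {"OT", "OB"}:
        raise ValueError(f"unknown strand {strand!r}")
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    work = seq if strand == "OT" else reverse_complement(seq)
    out = list(work)
    cpg: list[int] = []
    converted: list[int] = []
    for i, base in enumerate(work):
        if base != "C":
            continue
        protected = (
            allele == "methylated" and i + 1 < len(work) and work[i + 1] == "G"
        )
        if protected:
            cpg.append(i)
        else:
            out[i] = "T"
            converted.append(i)
    return BisulfiteTemplate(
        source_seq=work,
        converted_seq="".join(out),
        strand=strand,
        allele=allele,
        cpg_positions=tuple(cpg),
        converted_positions=tuple(converted),
    )


# ---------------------------------------------------------------------------
# oligo arithmetic
# ---------------------------------------------------------------------------


def gc_content(seq: str) -> float:
    """Percent G+C of a sequence."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str, method: str = "wallace") -> float:
    """Melting temperature in degC.

    ``wallace``: 2*(A+T) + 4*(G+C).  ``nearest_neighbor``: the standard
    thermodynamic sum (delegated to Biopython's Tm_NN with its default
    parameter table).
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    if method == "wallace":
        at = seq.count("A") + seq.count("T")
        gc = seq.count("G") + seq.count("C")
        return 2.0 * at + 4.0 * gc
    if method == "nearest_neighbor":
        from Bio.SeqUtils import MeltingTemp

        return float(MeltingTemp.Tm_NN(seq))
    raise ValueError(f"unknown Tm method {method!r}")


def is_palindrome(seq: str, min_len: int = 6) -> bool:
    """True iff some substring of length >= min_len equals its own
    reverse complement (only even lengths can)."""
    seq = seq.upper()
    lo = min_len + (min_len % 2)
    for length in range(lo, len(seq) + 1, 2):
        for i in range(len(seq) - length + 1):
            sub = seq[i : i + length]
            if sub == reverse_complement(sub):
                return True
    return False


def max_complementary_run(a: str, b: str) -> int:
    """Length of the longest ungapped complementary duplex between two
    oligos (longest common substring of ``a`` and revcomp(``b``))."""
    return _longest_common_substring(a.upper(), reverse_complement(b.upper()))


def three_prime_complementary_run(a: str, b: str) -> int:
    """Longest suffix of ``a`` whose reverse complement occurs in ``b``
    (a 3'-anchored cross-dimer seed)."""
    a, b = a.upper(), b.upper()
    best = 0
    for k in range(1, len(a) + 1):
        if reverse_complement(a[-k:]) in b:
            best = k
        else:
            break
    return best


def hairpin_run(seq: str) -> int:
    """Longest complementary run of an oligo against itself."""
    return max_complementary_run(seq, seq)


def _longest_common_substring(a: str, b: str) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


# ---------------------------------------------------------------------------
# configuration and oligo types
# ---------------------------------------------------------------------------


@dataclass
class DesignConfig:
    """Constraint thresholds for primer and probe design."""

    primer_min_len: int = 14
    primer_max_len: int = 22
    min_cpg_per_primer: int = 1
    min_converted_c_per_primer: int = 1
    gc_min: float = 50.0
    gc_max: float = 70.0
    tm_min: float = 40.0
    tm_max: float = 72.0
    tm_method: str = "wallace"
    max_tm_diff: float = 5.0
    amplicon_min_len: int = 80
    amplicon_max_len: int = 400
    min_amplicon_cpg: int = 3
    ideal_converted_c: int = 4
    dimer_max_run: int = 8
    dimer_max_run_3p: int = 4
    flank: int = 200
    max_candidates_per_side: int = 50
    max_pairs: int = 100
    probe_min_len: int = 20
    probe_max_len: int = 30
    probe_max_offset: int = 10
    probe_tm_above_min: float = 5.0
    probe_tm_above_max: float = 10.0
    probe_gc_target: float = 50.0
    palindrome_min_len: int = 6

    def __post_init__(self) -> None:
        if not (0 < self.primer_min_len <= self.primer_max_len):
            raise ValueError("invalid primer length bounds")
        if not (0 < self.probe_min_len <= self.probe_max_len):
            raise ValueError("invalid probe length bounds")
        if not (0 < self.amplicon_min_len <= self.amplicon_max_len):
            raise ValueError("invalid amplicon length bounds")


@dataclass(frozen=True)
class PrimerOligo:
    """A candidate primer in bisulfite space (sequence is 5'->3')."""

    sequence: str
    start: int  # template coordinates of the binding region
    end: int
    orientation: str  # "fwd" | "rev"
    gc_pct: float
    tm: float
    n_cpg: int
    n_converted_c: int
    ends_on_c: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CompatibilityReport:
    tm_diff: float
    dimer_run: int
    three_prime_run: int
    fwd_hairpin_run: int
    rev_hairpin_run: int
    failures: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.failures


@dataclass(frozen=True)
class PrimerPair:
    fwd: PrimerOligo
    rev: PrimerOligo
    amplicon_len: int
    amplicon_n_cpg: int
    amplicon_n_converted_c: int
    tm_diff: float
    compatibility: CompatibilityReport
    rank_score: float = 0.0


@dataclass(frozen=True)
class Probe:
    sequence: str
    start: int
    end: int
    gc_pct: float
    tm: float
    offset: int  # nt between fwd primer 3' end and probe 5' end
    label: str = "FAM"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DesignResult:
    pairs: list[PrimerPair]
    diagnostics: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def _count_in(positions: Sequence[int], start: int, end: int) -> int:
    return sum(1 for p in positions if start <= p < end)


def _count_cpg_in(positions: Sequence[int], start: int, end: int) -> int:
    # a CpG counts only when its full dinucleotide [p, p+2) lies inside
    # (keeps counts strand-symmetric at interval boundaries)
    return sum(1 for p in positions if start <= p and p + 2 <= end)


def enumerate_primers(
    template: BisulfiteTemplate,
    window: tuple[int, int],
    orientation: str,
    cfg: DesignConfig | None = None,
) -> list[PrimerOligo]:
    """All primer candidates of length 14-22 binding inside ``window``.

    Forward primers read the converted sequence as-is; reverse primers
    are its reverse complement.  CpG and converted-C counts refer to
    template positions covered by the binding region.  Candidates must
    carry at least ``min_cpg_per_primer`` CpGs (methylation
    discrimination) and one converted C (bisulfite specificity), and
    fall inside the configured GC and Tm bands.
    """
    cfg = cfg or DesignConfig()
    if orientation not in {"fwd", "rev"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    w_start, w_end = window
    if not (0 <= w_start <= w_end <= len(template)):
        raise ValueError(f"window {window} outside template of length {len(template)}")
    out: list[PrimerOligo] = []
    for length in range(cfg.primer_min_len, cfg.primer_max_len + 1):
        for start in range(w_start, w_end - length + 1):
            end = start + length
            n_cpg = _count_cpg_in(template.cpg_positions, start, end)
            if n_cpg < cfg.min_cpg_per_primer:
                continue
            n_conv = _count_in(template.converted_positions, start, end)
            if n_conv < cfg.min_converted_c_per_primer:
                continue
            binding = template.converted_seq[start:end]
            if "N" in binding:
                continue
            seq = binding if orientation == "fwd" else reverse_complement(binding)
            gc = gc_content(seq)
            if not (cfg.gc_min <= gc <= cfg.gc_max):
                continue
            tm = melting_temperature(seq, cfg.tm_method)
            if not (cfg.tm_min <= tm <= cfg.tm_max):
                continue
            out.append(
                PrimerOligo(
                    sequence=seq,
                    start=start,
                    end=end,
                    orientation=orientation,
                    gc_pct=gc,
                    tm=tm,
                    n_cpg=n_cpg,
                    n_converted_c=n_conv,
                    ends_on_c=seq.endswith("C"),
                )
            )
    return out


def check_pair_compatibility(
    fwd: PrimerOligo,
    rev: PrimerOligo,
    cfg: DesignConfig | None = None,
) -> CompatibilityReport:
    """Cross-dimer, 3'-complementarity, hairpin and Tm-difference checks."""
    cfg = cfg or DesignConfig()
    failures: list[str] = []
    tm_diff = abs(fwd.tm - rev.tm)
    if tm_diff >= cfg.max_tm_diff:
        failures.append("tm_diff")
    dimer = max_complementary_run(fwd.sequence, rev.sequence)
    if dimer > cfg.dimer_max_run:
        failures.append("dimer")
    run3p = max(
        three_prime_complementary_run(fwd.sequence, rev.sequence),
        three_prime_complementary_run(rev.sequence, fwd.sequence),
    )
    if run3p > cfg.dimer_max_run_3p:
        failures.append("three_prime")
    fwd_hp = hairpin_run(fwd.sequence)
    rev_hp = hairpin_run(rev.sequence)
    if fwd_hp > cfg.dimer_max_run or rev_hp > cfg.dimer_max_run:
        failures.append("hairpin")
    return CompatibilityReport(
        tm_diff=tm_diff,
        dimer_run=dimer,
        three_prime_run=run3p,
        fwd_hairpin_run=fwd_hp,
        rev_hairpin_run=rev_hp,
        failures=tuple(failures),
    )


# ---------------------------------------------------------------------------
# pair and probe design
# ---------------------------------------------------------------------------


def _pair_rank_score(pair: PrimerPair, cfg: DesignConfig) -> float:
    score = 0.0
    if pair.amplicon_n_converted_c >= cfg.ideal_converted_c:
        score += 2.0
    for oligo in (pair.fwd, pair.rev):
        score += 1.0 - min(abs(oligo.gc_pct - 60.0), 20.0) / 20.0
        if oligo.ends_on_c:
            score += 1.0
    score += 0.1 * pair.amplicon_n_cpg
    return score


def design_primer_pairs(
    region_span: GenomicInterval,
    reference: Mapping[str, str],
    cfg: DesignConfig | None = None,
) -> DesignResult:
    """Design ranked MSP primer pairs for one predicted region.

    The region span plus ``cfg.flank`` nt on each side is extracted from
    the reference and bisulfite-converted on the methylated allele
    (original top strand).  Forward primers are enumerated over the left
    flank plus the region, reverse primers over the region plus the
    right flank; pairs pass the hard filters (amplicon length, amplicon
    CpG count, Tm difference, dimer compatibility) and are ranked by a
    deterministic soft score.
    """
    cfg = cfg or DesignConfig()
    chrom_seq = reference[region_span.chrom]
    if hasattr(chrom_seq, "__getitem__") and not isinstance(chrom_seq, str):
        chrom_seq = str(chrom_seq[:])
    flank_start = max(0, region_span.start - cfg.flank)
    flank_end = min(len(chrom_seq), region_span.end + cfg.flank)
    seq = chrom_seq[flank_start:flank_end].upper()
    template = bisulfite_convert(seq, allele="methylated", strand="OT")
    offset = region_span.start - flank_start
    region_len = len(region_span)

    fwd_window = (0, min(len(template), offset + region_len))
    rev_window = (offset, len(template))
    fwd_cands = enumerate_primers(template, fwd_window, "fwd", cfg)
    rev_cands = enumerate_primers(template, rev_window, "rev", cfg)

    diagnostics: dict[str, int] = {
        "n_fwd_candidates": len(fwd_cands),
        "n_rev_candidates": len(rev_cands),
    }

    def _cand_key(o: PrimerOligo):
        return (not o.ends_on_c, abs(o.gc_pct - 60.0), o.start, o.end)

    fwd_cands = sorted(fwd_cands, key=_cand_key)[: cfg.max_candidates_per_side]
    rev_cands = sorted(rev_cands, key=_cand_key)[: cfg.max_candidates_per_side]

    pairs: list[PrimerPair] = []
    fail = diagnostics
    for name in ("amplicon_len", "overlap", "amplicon_cpg", "tm_diff", "compatibility"):
        fail.setdefault(f"fail_{name}", 0)
    for f in fwd_cands:
        for r in rev_cands:
            amplicon_len = r.end - f.start
            if not (cfg.amplicon_min_len <= amplicon_len <= cfg.amplicon_max_len):
                fail["fail_amplicon_len"] += 1
                continue
            if r.start < f.end:
                fail["fail_overlap"] += 1
                continue
            n_cpg = _count_cpg_in(template.cpg_positions, f.start, r.end)
            if n_cpg < cfg.min_amplicon_cpg:
                fail["fail_amplicon_cpg"] += 1
                continue
            tm_diff = abs(f.tm - r.tm)
            if tm_diff >= cfg.max_tm_diff:
                fail["fail_tm_diff"] += 1
                continue
            compat = check_pair_compatibility(f, r, cfg)
            if not compat.passed:
                fail["fail_compatibility"] += 1
                continue
            n_conv = _count_in(template.converted_positions, f.start, r.end)
            pair = PrimerPair(
                fwd=f,
                rev=r,
                amplicon_len=amplicon_len,
                amplicon_n_cpg=n_cpg,
                amplicon_n_converted_c=n_conv,
                tm_diff=tm_diff,
                compatibility=compat,
            )
            pairs.append(
                PrimerPair(**{**pair.__dict__, "rank_score": _pair_rank_score(pair, cfg)})
            )
    pairs.sort(
        key=lambda p: (
            -p.rank_score,
            p.amplicon_len,
            p.fwd.start,
            p.rev.start,
            p.fwd.sequence,
            p.rev.sequence,
        )
    )
    return DesignResult(pairs=pairs[: cfg.max_pairs], diagnostics=diagnostics)


def design_probe(
    pair: PrimerPair,
    template: BisulfiteTemplate,
    cfg: DesignConfig | None = None,
) -> tuple[list[Probe], dict[str, int]]:
    """Design ranked hydrolysis probes for one primer pair.

    Candidates are 20-30 nt substrings of the converted sequence (same
    strand as the forward primer) starting within ``probe_max_offset``
    nt of the forward primer's 3' end and ending before the reverse
    primer site.  Hard filters: no 5' G, no palindrome, Tm between 5 and
    10 degC above the hotter primer, no long complementary run against
    either primer or itself.  Ranked by GC proximity to 50%.
    """
    cfg = cfg or DesignConfig()
    max_tm = max(pair.fwd.tm, pair.rev.tm)
    lo, hi = max_tm + cfg.probe_tm_above_min, max_tm + cfg.probe_tm_above_max
    diagnostics = {
        "fail_5prime_g": 0,
        "fail_palindrome": 0,
        "fail_tm_band": 0,
        "fail_dimer": 0,
    }
    out: list[Probe] = []
    for start in range(pair.fwd.end, pair.fwd.end + cfg.probe_max_offset + 1):
        for length in range(cfg.probe_min_len, cfg.probe_max_len + 1):
            end = start + length
            if end > pair.rev.start:
                continue
            seq = template.converted_seq[start:end]
            if "N" in seq:
                continue
            if seq.startswith("G"):
                diagnostics["fail_5prime_g"] += 1
                continue
            if is_palindrome(seq, cfg.palindrome_min_len):
                diagnostics["fail_palindrome"] += 1
                continue
            tm = melting_temperature(seq, cfg.tm_method)
            if not (lo <= tm <= hi):
                diagnostics["fail_tm_band"] += 1
                continue
            if (
                max_complementary_run(seq, pair.fwd.sequence) > cfg.dimer_max_run
                or max_complementary_run(seq, pair.rev.sequence) > cfg.dimer_max_run
                or hairpin_run(seq) > cfg.dimer_max_run
            ):
                diagnostics["fail_dimer"] += 1
                continue
            out.append(
                Probe(
                    sequence=seq,
                    start=start,
                    end=end,
                    gc_pct=gc_content(seq),
                    tm=tm,
                    offset=start - pair.fwd.end,
                )
            )
    out.sort(key=lambda p: (abs(p.gc_pct - cfg.probe_gc_target), p.start, p.end))
    return out, diagnostics
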