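"""Independent brute-force oracles used to cross-check the package.

Everything here deliberately re-derives results from first principles
(exhaustive enumeration, closed forms) without calling the code paths it
checks.
"""

from __future__ import annotations

import itertools
import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# region prediction
# ---------------------------------------------------------------------------


def brute_force_eligible(tumor, control, cfg):
    """Eligibility of one CpG directly from the rule sentences.

    tumor / control: lists of (depth, meth_pct).
    """
    if any(d < cfg.min_site_depth for d, _ in tumor + control):
        return False
    if any(m > cfg.max_meth_control for _, m in control):
        return False
    return any(m >= cfg.min_meth_tumor for _, m in tumor)


def brute_force_primer_windows(positions, cfg):
    """All maximal CpG index runs fitting a primer window, as
    (interval_start, interval_end, cpg_tuple) triples."""
    pos = sorted(positions)
    n = len(pos)
    runs = [
        (i, j)
        for i in range(n)
        for j in range(i, n)
        if pos[j] + 2 - pos[i] <= cfg.max_primer_len and j - i + 1 >= cfg.min_cpgs
    ]
    maximal = [
        (i, j)
        for (i, j) in runs
        if not any((i2 <= i and j <= j2 and (i2, j2) != (i, j)) for (i2, j2) in runs)
    ]
    out = []
    for i, j in maximal:
        length = max(cfg.min_primer_len, pos[j] + 2 - pos[i])
        out.append((pos[i], pos[i] + length, tuple(pos[i : j + 1])))
    return sorted(out)


def brute_force_regions(positions, cfg):
    """All (fwd_window, rev_window) pairs with a legal amplicon span, as
    (span_start, span_end, fwd_cpgs, rev_cpgs) tuples."""
    windows = brute_force_primer_windows(positions, cfg)
    out = []
    for a, b in itertools.permutations(windows, 2):
        if a[0] >= b[0]:
            continue
        if a[1] > b[0]:  # overlap
            continue
        span = b[1] - a[0]
        if cfg.min_amplicon_len <= span <= cfg.max_amplicon_len:
            out.append((a[0], b[1], a[2], b[2]))
    return sorted(out)


def brute_force_score(region_cpgs, tumor_values):
    """tumor_values: {sample: {pos: (depth, meth_pct)}}."""
    return sum(
        (tumor_values[s][p][1] / 100.0) * tumor_values[s][p][0]
        for s in tumor_values
        for p in region_cpgs
    )


def greedy_select(scored, threshold):
    """scored: list of (score, start, end); returns selected sublist."""
    kept = [r for r in scored if r[0] >= threshold]
    kept.sort(key=lambda r: (-r[0], -(r[2] - r[1]), r[1]))
    out = []
    for r in kept:
        if all(r[2] <= s[1] or s[2] <= r[1] for s in out):
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def brute_force_cutpoint(tumors, controls):
    """Exhaustive Youden search over all real thresholds.

    Scans every midpoint plus +/-inf; returns (J, sens, spec, cutpoint)
    of the maximizer with ties broken by higher specificity then lower
    cutpoint.
    """
    values = sorted(set(tumors) | set(controls))
    candidates = (
        [-math.inf] + [(a + b) / 2 for a, b in zip(values, values[1:])] + [math.inf]
    )
    best = None
    for c in candidates:
        sens = sum(t <= c for t in tumors) / len(tumors)
        spec = sum(v > c for v in controls) / len(controls)
        j = sens + spec - 1
        key = (-j, -spec, c)
        if best is None or key < best[0]:
            best = (key, (j, sens, spec, c))
    return best[1]


def pair_count_auc(tumors, controls):
    """AUC by exhaustive pair counting (lower value = tumor-like)."""
    wins = sum(
        1.0 if t < c else (0.5 if t == c else 0.0) for t in tumors for c in controls
    )
    return wins / (len(tumors) * len(controls))


def mann_whitney_auc(tumors, controls):
    """AUC via the rank-sum identity AUC = U / (n1*n2)."""
    from scipy.stats import rankdata

    pooled = list(controls) + list(tumors)
    ranks = rankdata(pooled)
    r_control = sum(ranks[: len(controls)])
    u_control = r_control - len(controls) * (len(controls) + 1) / 2
    return u_control / (len(tumors) * len(controls))


def welch_p_value(x, y):
    """Closed-form Welch two-sided t-test."""
    import numpy as np
    from scipy.stats import t as t_dist

    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t_stat = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return 2 * t_dist.sf(abs(t_stat), df)


# ---------------------------------------------------------------------------
# assay design
# ---------------------------------------------------------------------------


def brute_force_convert(seq, allele):
    """Character-by-character bisulfite conversion of the top strand."""
    out = []
    for i, b in enumerate(seq):
        if b == "C":
            if allele == "methylated" and i + 1 < len(seq) and seq[i + 1] == "G":
                out.append("C")
            else:
                out.append("T")
        else:
            out.append(b)
    return "".join(out)


def brute_force_primer_substrings(converted, cpgs, convs, window, orientation, cfg):
    """Every substring passing the primer filters, as a set of
    (start, end, sequence) triples."""
    out = set()
    w0, w1 = window
    for start in range(w0, w1):
        for end in range(start + cfg.primer_min_len, min(w1, start + cfg.primer_max_len) + 1):
            sub = converted[start:end]
            if len(sub) < cfg.primer_min_len or "N" in sub:
                continue
            n_cpg = sum(start <= p and p + 2 <= end for p in cpgs)
            n_conv = sum(start <= p < end for p in convs)
            seq = sub if orientation == "fwd" else revcomp(sub)
            gc = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
            tm = 2.0 * (seq.count("A") + seq.count("T")) + 4.0 * (
                seq.count("G") + seq.count("C")
            )
            if (
                n_cpg >= cfg.min_cpg_per_primer
                and n_conv >= cfg.min_converted_c_per_primer
                and cfg.gc_min <= gc <= cfg.gc_max
                and cfg.tm_min <= tm <= cfg.tm_max
            ):
                out.add((start, end, seq))
    return out


def max_comp_run(a, b):
    """Longest ungapped complementary duplex, by explicit alignment scan."""
    rb = revcomp(b)
    best = 0
    for i in range(len(a)):
        for j in range(len(rb)):
            k = 0
            while i + k < len(a) and j + k < len(rb) and a[i + k] == rb[j + k]:
                k += 1
            best = max(best, k)
    return best


def revalidate_pair(pair, template, cfg):
    """Re-check every primer-pair constraint from the rule list; returns
    a list of violations."""
    problems = []
    for oligo in (pair.fwd, pair.rev):
        if not (cfg.primer_min_len <= len(oligo.sequence) <= cfg.primer_max_len):
            problems.append("primer length")
        if oligo.n_cpg < cfg.min_cpg_per_primer:
            problems.append("primer cpg")
        if oligo.n_converted_c < 1:
            problems.append("primer converted C")
        expected = template.converted_seq[oligo.start : oligo.end]
        if oligo.orientation == "rev":
            expected = revcomp(expected)
        if oligo.sequence != expected:
            problems.append("sequence mismatch")
    if not (cfg.amplicon_min_len <= pair.amplicon_len <= cfg.amplicon_max_len):
        problems.append("amplicon length")
    n_cpg = sum(pair.fwd.start <= p and p + 2 <= pair.rev.end for p in template.cpg_positions)
    if n_cpg < cfg.min_amplicon_cpg:
        problems.append("amplicon cpg")
    if abs(pair.fwd.tm - pair.rev.tm) >= cfg.max_tm_diff:
        problems.append("tm diff")
    if max_comp_run(pair.fwd.sequence, pair.rev.sequence) > cfg.dimer_max_run:
        problems.append("dimer")
    return problems


def revalidate_probe(probe, pair, cfg):
    problems = []
    if not (cfg.probe_min_len <= len(probe.sequence) <= cfg.probe_max_len):
        problems.append("probe length")
    if probe.sequence.startswith("G"):
        problems.append("5' G")
    if has_palindrome(probe.sequence, cfg.palindrome_min_len):
        problems.append("palindrome")
    max_tm = max(pair.fwd.tm, pair.rev.tm)
    if not (max_tm + cfg.probe_tm_above_min <= probe.tm <= max_tm + cfg.probe_tm_above_max):
        problems.append("tm band")
    if probe.offset > cfg.probe_max_offset or probe.offset < 0:
        problems.append("offset")
    return problems


def has_palindrome(seq, min_len):
    for length in range(min_len, len(seq) + 1):
        for i in range(len(seq) - length + 1):
            sub = seq[i : i + length]
            if sub == revcomp(sub):
                return True
    return False
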