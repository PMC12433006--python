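"""Marker validation statistics for qPCR CT tables.

Normalizes target CT values against the reference assay (delta CT =
CT_target - CT_reference), compares tumor and control groups with
Welch's t-test plus Bonferroni correction, and scores each marker with a
Youden-optimal delta-CT cutpoint, sensitivity, specificity and AUC.
Lower delta CT means more methylated template (earlier amplification),
so samples classify as tumor when delta CT falls at or below the
cutpoint.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats as _scipy_stats

from .io_formats import FormatError, SampleManifest, _open_text

#: CT value imputed for censored (no-amplification) wells: the assay's
#: total cycle count.
DEFAULT_CENSOR_CT = 43.0

_CENSORED_TOKENS = {"", "na", "nan", "n/a", "none", "undetermined", "censored", "-"}


@dataclass(frozen=True)
class QPCRMeasurement:
    """One well pair: target and reference CT for a (sample, marker)."""

    sample_id: str
    marker: str
    ct_target: float | None  # None = censored / no amplification
    ct_ref: float

    def __post_init__(self) -> None:
        if self.ct_target is not None and self.ct_target <= 0:
            raise ValueError("ct_target must be > 0 when present")
        if self.ct_ref <= 0:
            raise ValueError("ct_ref must be > 0")


@dataclass(frozen=True)
class DeltaCtRecord:
    sample_id: str
    marker: str
    group: str  # "tumor" | "control"
    delta_ct: float
    censored: bool = False


@dataclass(frozen=True)
class CutpointResult:
    marker: str
    cutpoint: float
    sensitivity: float
    specificity: float
    youden_j: float
    auc: float
    direction: str = "tumor if dCT <= cutpoint"


@dataclass(frozen=True)
class MarkerTestResult:
    marker: str
    tumor_mean: float
    tumor_sd: float
    control_mean: float
    control_sd: float
    statistic: float
    p_raw: float
    p_adj: float | None = None


@dataclass(frozen=True)
class MarkerSummary:
    marker: str
    n_tumor: int
    n_control: int
    tumor_min: float
    tumor_max: float
    tumor_range: float
    control_min: float
    control_max: float
    control_range: float
    test: MarkerTestResult
    cutpoint: CutpointResult
    separated: bool  # min control dCT > max tumor dCT


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------


def read_ct_table(path: str | os.PathLike) -> list[QPCRMeasurement]:
    """Read a TSV CT table: sample_id, marker, ct_target, ct_ref.

    A missing / non-numeric ct_target token (e.g. ``NA``,
    ``Undetermined``) marks a censored well.
    """
    out: list[QPCRMeasurement] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "sample_id":
                continue
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            sample_id, marker, raw_target, raw_ref = fields[:4]
            ct_target: float | None
            if raw_target.strip().lower() in _CENSORED_TOKENS:
                ct_target = None
            else:
                try:
                    ct_target = float(raw_target)
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: bad ct_target {raw_target!r}"
                    ) from None
            try:
                ct_ref = float(raw_ref)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: bad ct_ref {raw_ref!r}"
                ) from None
            out.append(QPCRMeasurement(sample_id, marker, ct_target, ct_ref))
    return out


def compute_delta_ct(
    measurements: Iterable[QPCRMeasurement],
    manifest: SampleManifest,
    censor_ct: float = DEFAULT_CENSOR_CT,
) -> list[DeltaCtRecord]:
    """delta CT = CT_target - CT_reference, with group labels joined
    from the manifest.  Censored targets are imputed at ``censor_ct``
    (the total cycle count) and flagged."""
    out: list[DeltaCtRecord] = []
    for m in measurements:
        if m.ct_ref is None or (isinstance(m.ct_ref, float) and math.isnan(m.ct_ref)):
            raise ValueError(f"missing reference CT for sample {m.sample_id!r}")
        group = manifest.group_of(m.sample_id)
        censored = m.ct_target is None
        target = censor_ct if censored else m.ct_target
        out.append(
            DeltaCtRecord(
                sample_id=m.sample_id,
                marker=m.marker,
                group=group,
                delta_ct=target - m.ct_ref,
                censored=censored,
            )
        )
    return out


def _split_groups(records: Sequence[DeltaCtRecord]) -> tuple[list[float], list[float]]:
    tumors = [r.delta_ct for r in records if r.group == "tumor"]
    controls = [r.delta_ct for r in records if r.group == "control"]
    return tumors, controls


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def group_test(records: Sequence[DeltaCtRecord]) -> MarkerTestResult:
    """Welch two-sample two-sided t-test on delta CT by group."""
    markers = {r.marker for r in records}
    if len(markers) != 1:
        raise ValueError(f"group_test expects one marker, got {sorted(markers)}")
    marker = markers.pop()
    tumors, controls = _split_groups(records)
    if len(tumors) < 2 or len(controls) < 2:
        raise ValueError(f"marker {marker!r}: each group needs >= 2 records")
    import numpy as np

    t_arr, c_arr = np.asarray(tumors), np.asarray(controls)
    if t_arr.var(ddof=1) == 0.0 and c_arr.var(ddof=1) == 0.0:
        raise ValueError(f"marker {marker!r}: zero variance in both groups")
    res = _scipy_stats.ttest_ind(t_arr, c_arr, equal_var=False)
    return MarkerTestResult(
        marker=marker,
        tumor_mean=float(t_arr.mean()),
        tumor_sd=float(t_arr.std(ddof=1)),
        control_mean=float(c_arr.mean()),
        control_sd=float(c_arr.std(ddof=1)),
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
    )


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """p_adj_i = min(1, m * p_i); ``m`` defaults to the list length."""
    if m is None:
        m = len(p_values)
    if m < 0:
        raise ValueError("m must be >= 0")
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in p_values]


def roc_auc(records: Sequence[DeltaCtRecord]) -> float:
    """AUC with orientation "lower delta CT indicates tumor".

    AUC = (#pairs with tumor < control + 0.5 * ties) / (n_t * n_c).
    """
    tumors, controls = _split_groups(records)
    if not tumors or not controls:
        raise ValueError("roc_auc needs >= 1 record per group")
    wins = 0.0
    for t in tumors:
        for c in controls:
            if t < c:
                wins += 1.0
            elif t == c:
                wins += 0.5
    return wins / (len(tumors) * len(controls))


def youden_optimal_cutpoint(records: Sequence[DeltaCtRecord]) -> CutpointResult:
    """Delta-CT cutpoint maximizing Youden's J = sens + spec - 1.

    Candidates are midpoints between adjacent distinct sorted values
    plus -inf/+inf; a sample classifies as tumor iff its delta CT is <=
    the cutpoint.  Ties are broken by higher specificity, then lower
    cutpoint.
    """
    markers = {r.marker for r in records}
    marker = markers.pop() if len(markers) == 1 else ",".join(sorted(markers))
    tumors, controls = _split_groups(records)
    if not tumors or not controls:
        raise ValueError("youden_optimal_cutpoint needs >= 1 record per group")
    values = sorted(set(tumors) | set(controls))
    candidates = [-math.inf]
    candidates += [(a + b) / 2.0 for a, b in zip(values, values[1:])]
    candidates.append(math.inf)
    best: tuple[float, float, float] | None = None  # (-J, -spec, cutpoint)
    best_stats: tuple[float, float, float] | None = None
    for c in candidates:
        sens = sum(1 for t in tumors if t <= c) / len(tumors)
        spec = sum(1 for v in controls if v > c) / len(controls)
        j = sens + spec - 1.0
        key = (-j, -spec, c)
        if best is None or key < best:
            best = key
            best_stats = (c, sens, spec)
    assert best_stats is not None
    cutpoint, sens, spec = best_stats
    return CutpointResult(
        marker=marker,
        cutpoint=cutpoint,
        sensitivity=sens,
        specificity=spec,
        youden_j=sens + spec - 1.0,
        auc=roc_auc(records),
    )


def summarize_markers(
    records: Sequence[DeltaCtRecord],
    n_tests: int | None = None,
) -> list[MarkerSummary]:
    """Per-marker summary: descriptive group statistics, Welch test with
    Bonferroni adjustment (m = number of markers unless overridden),
    Youden cutpoint block, and a separation flag that is true when the
    minimum control delta CT exceeds the maximum tumor delta CT."""
    by_marker: dict[str, list[DeltaCtRecord]] = {}
    for r in records:
        by_marker.setdefault(r.marker, []).append(r)
    if not by_marker:
        raise ValueError("no records")
    markers = sorted(by_marker)
    tests = {m: group_test(by_marker[m]) for m in markers}
    adj = bonferroni_adjust([tests[m].p_raw for m in markers], n_tests or len(markers))
    out: list[MarkerSummary] = []
    for m, p_adj in zip(markers, adj):
        recs = by_marker[m]
        tumors, controls = _split_groups(recs)
        test = MarkerTestResult(**{**tests[m].__dict__, "p_adj": p_adj})
        out.append(
            MarkerSummary(
                marker=m,
                n_tumor=len(tumors),
                n_control=len(controls),
                tumor_min=min(tumors),
                tumor_max=max(tumors),
                tumor_range=max(tumors) - min(tumors),
                control_min=min(controls),
                control_max=max(controls),
                control_range=max(controls) - min(controls),
                test=test,
                cutpoint=youden_optimal_cutpoint(recs),
                separated=min(controls) > max(tumors),
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[MarkerSummary]):
    """Flatten marker summaries into a pandas DataFrame (one row per
    marker) for TSV output."""
    import pandas as pd

    rows = []
    for s in summaries:
        rows.append(
            {
                "marker": s.marker,
                "n_tumor": s.n_tumor,
                "n_control": s.n_control,
                "tumor_mean": s.test.tumor_mean,
                "tumor_sd": s.test.tumor_sd,
                "tumor_min": s.tumor_min,
                "tumor_max": s.tumor_max,
                "tumor_range": s.tumor_range,
                "control_mean": s.test.control_mean,
                "control_sd": s.test.control_sd,
                "control_min": s.control_min,
                "control_max": s.control_max,
                "control_range": s.control_range,
                "p_raw": s.test.p_raw,
                "p_adj": s.test.p_adj,
                "cutpoint": s.cutpoint.cutpoint,
                "sensitivity": s.cutpoint.sensitivity,
                "specificity": s.cutpoint.specificity,
                "youden_j": s.cutpoint.youden_j,
                "auc": s.cutpoint.auc,
                "separated": s.separated,
            }
        )
    return pd.DataFrame(rows)
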