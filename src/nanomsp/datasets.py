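"""Small bundled example datasets.

The example delta-CT table comes from a six-sample MSP pilot (three
tumor, three control tissue samples) across six candidate markers; it is
used in the documentation, the test suite and the acceptance report.
"""

from __future__ import annotations

from .io_formats import ManifestEntry, SampleManifest
from .msp_stats import DeltaCtRecord

_CONTROL_SAMPLES = ("T-0025-N", "T-0045-N", "T-0099-N")
_TUMOR_SAMPLES = ("T-0044-C", "T-0085-C", "T-0126-C")

_MARKERS = ("FLI1", "LHX8", "USP44", "KCNB1", "ZNF529", "URAD")

# rows: samples (controls then tumors); columns: markers, delta CT cycles
_DELTA_CT = {
    "T-0025-N": (20.82, 8.01, 9.29, 12.87, 20.82, 4.71),
    "T-0045-N": (19.03, 16.40, 9.74, 19.03, 13.85, 8.08),
    "T-0099-N": (11.93, 7.13, 8.76, 9.34, 9.92, 9.45),
    "T-0044-C": (0.73, 0.46, 1.24, 0.18, 3.41, 1.97),
    "T-0085-C": (2.91, 1.56, 2.42, 2.58, 4.98, 1.75),
    "T-0126-C": (7.16, 1.83, 7.14, 19.80, 4.02, 2.09),
}


def example_manifest() -> SampleManifest:
    """Manifest for the bundled six-sample MSP pilot."""
    entries = [ManifestEntry(s, "control") for s in _CONTROL_SAMPLES]
    entries += [ManifestEntry(s, "tumor") for s in _TUMOR_SAMPLES]
    return SampleManifest(entries)


def example_delta_ct(markers: tuple[str, ...] | None = None) -> list[DeltaCtRecord]:
    """Delta-CT records of the bundled six-sample MSP pilot.

    Parameters
    ----------
    markers
        Restrict to a subset of marker names; default all six.
    """
    wanted = markers or _MARKERS
    unknown = set(wanted) - set(_MARKERS)
    if unknown:
        raise KeyError(f"unknown markers: {sorted(unknown)}")
    out: list[DeltaCtRecord] = []
    for sample, values in _DELTA_CT.items():
        group = "control" if sample in _CONTROL_SAMPLES else "tumor"
        for marker, value in zip(_MARKERS, values):
            if marker in wanted:
                out.append(DeltaCtRecord(sample, marker, group, value))
    return out
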