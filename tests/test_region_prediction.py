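import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanomsp.io_formats import (
    CpGSiteMeasurement,
    GenomicInterval,
    ManifestEntry,
    SampleManifest,
)
from nanomsp.region_prediction import (
    CpGStatus,
    MSPRegion,
    PredictionConfig,
    PrimerSiteCandidate,
    classify_cpg_status,
    cluster_and_select,
    find_primer_sites,
    pair_sites_to_regions,
    predict_msp_regions,
    score_region,
    validate_region,
)

import oracles


def _m(pct, depth=20, sample="s", pos=100):
    return CpGSiteMeasurement("chr1", pos, depth, pct, sample)


CFG = PredictionConfig()


class TestClassify:
    def test_eligible(self):
        assert (
            classify_cpg_status(
                [_m(90), _m(88), _m(92)], [_m(2), _m(5), _m(0)], CFG
            )
            is CpGStatus.ELIGIBLE
        )

    def test_control_methylated(self):
        assert (
            classify_cpg_status([_m(90)], [_m(15), _m(2)], CFG)
            is CpGStatus.CONTROL_METHYLATED
        )

    def test_control_at_threshold_is_ok(self):
        assert classify_cpg_status([_m(90)], [_m(10.0)], CFG) is CpGStatus.ELIGIBLE

    def test_tumor_unmethylated(self):
        assert (
            classify_cpg_status([_m(30), _m(30), _m(30)], [_m(0)], CFG)
            is CpGStatus.TUMOR_UNMETHYLATED
        )

    def test_low_depth(self):
        assert classify_cpg_status([_m(90, depth=4)], [_m(0)], CFG) is CpGStatus.LOW_DEPTH

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            classify_cpg_status([], [_m(0)], CFG)

    @given(
        st.lists(st.tuples(st.integers(0, 60), st.floats(0, 100)), min_size=1, max_size=5),
        st.lists(st.tuples(st.integers(0, 60), st.floats(0, 100)), min_size=1, max_size=5),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_rule_oracle(self, tumor, control):
        got = classify_cpg_status(
            [_m(p, depth=d) for d, p in tumor],
            [_m(p, depth=d) for d, p in control],
            CFG,
        )
        assert (got is CpGStatus.ELIGIBLE) == oracles.brute_force_eligible(
            tumor, control, CFG
        )


class TestFindPrimerSites:
    def test_three_cpgs_close(self):
        sites = find_primer_sites([110, 115, 120], CFG)
        assert len(sites) >= 1
        s = sites[0]
        assert set(s.cpg_positions) == {110, 115, 120}
        assert CFG.min_primer_len <= len(s.interval) <= CFG.max_primer_len
        for p in s.cpg_positions:
            assert s.interval.start <= p < s.interval.end

    def test_two_cpgs_insufficient(self):
        assert find_primer_sites([110, 150], CFG) == []

    def test_no_24nt_window_holds_three(self):
        assert find_primer_sites([110, 115, 140], CFG) == []

    def test_empty(self):
        assert find_primer_sites([], CFG) == []

    def test_unsorted_raises(self):
        with pytest.raises(ValueError):
            find_primer_sites([120, 110], CFG)

    @given(st.sets(st.integers(0, 300), max_size=40))
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force(self, positions):
        positions = sorted(positions)
        got = [
            (s.interval.start, s.interval.end, s.cpg_positions)
            for s in find_primer_sites(positions, CFG)
        ]
        assert sorted(got) == oracles.brute_force_primer_windows(positions, CFG)


def _site(start, end, cpgs=None, chrom="chr1"):
    return PrimerSiteCandidate(
        GenomicInterval(chrom, start, end), tuple(cpgs or (start, start + 6, start + 12))
    )


class TestPairSites:
    def test_valid_pair(self):
        regions = pair_sites_to_regions([_site(100, 120), _site(150, 172)], CFG)
        assert len(regions) == 1
        assert (regions[0].span.start, regions[0].span.end) == (100, 172)

    def test_span_too_short(self):
        assert pair_sites_to_regions([_site(100, 120), _site(130, 150)], CFG) == []

    def test_span_too_long(self):
        assert pair_sites_to_regions([_site(100, 120), _site(550, 572)], CFG) == []

    def test_overlapping_sites_skipped(self):
        assert pair_sites_to_regions([_site(100, 122), _site(110, 132)], CFG) == []

    def test_short_later_site_not_missed(self):
        # a long second site overflows the span but a shorter third fits
        sites = [_site(0, 18), _site(382, 406, (382, 388, 394)), _site(382, 400)]
        regions = pair_sites_to_regions(sites, CFG)
        assert [(r.span.start, r.span.end) for r in regions] == [(0, 400)]


class TestScoreRegion:
    @staticmethod
    def _calls(cpgs, samples, pct, depth):
        return {p: {s: _m(pct, depth, s, p) for s in samples} for p in cpgs}

    def test_uniform(self):
        cpgs = [100, 106, 112, 150, 156, 162]
        region = MSPRegion(
            _site(100, 118, cpgs[:3]),
            _site(150, 168, cpgs[3:]),
            GenomicInterval("chr1", 100, 168),
        )
        calls = self._calls(cpgs, ["t1", "t2", "t3"], 90.0, 20)
        assert score_region(region, calls, ["t1", "t2", "t3"]) == pytest.approx(324.0)

    def test_zero_methylation(self):
        cpgs = [100, 106, 112, 150, 156, 162]
        region = MSPRegion(
            _site(100, 118, cpgs[:3]), _site(150, 168, cpgs[3:]),
            GenomicInterval("chr1", 100, 168),
        )
        calls = self._calls(cpgs, ["t1"], 0.0, 20)
        assert score_region(region, calls, ["t1"]) == 0.0

    def test_linearity_in_depth(self):
        cpgs = [100, 106, 112, 150, 156, 162]
        region = MSPRegion(
            _site(100, 118, cpgs[:3]), _site(150, 168, cpgs[3:]),
            GenomicInterval("chr1", 100, 168),
        )
        s1 = score_region(region, self._calls(cpgs, ["t1"], 45.0, 10), ["t1"])
        s2 = score_region(region, self._calls(cpgs, ["t1"], 45.0, 20), ["t1"])
        assert s2 == pytest.approx(2 * s1)

    def test_missing_measurement_errors(self):
        region = MSPRegion(
            _site(100, 118), _site(150, 168), GenomicInterval("chr1", 100, 168)
        )
        with pytest.raises(ValueError):
            score_region(region, {}, ["t1"])


class TestClusterAndSelect:
    @staticmethod
    def _scored(score, start, end):
        return MSPRegion(
            _site(start, start + 18),
            _site(end - 18, end),
            GenomicInterval("chr1", start, end),
            score=score,
        )

    def test_greedy_overlap_suppression(self):
        a = self._scored(9000, 0, 200)
        b = self._scored(7000, 100, 300)
        c = self._scored(6500, 500, 700)
        out = cluster_and_select([a, b, c], 0.0)
        assert [(r.span.start, r.span.end) for r in out] == [(0, 200), (500, 700)]

    def test_all_below_threshold(self):
        assert cluster_and_select([self._scored(10, 0, 200)], 100.0) == []

    def test_disjoint_equal_scores_both_kept(self):
        a, b = self._scored(50, 0, 100), self._scored(50, 200, 300)
        assert len(cluster_and_select([a, b], 0.0)) == 2

    @given(
        st.lists(
            st.tuples(st.floats(0, 100), st.integers(0, 500), st.integers(60, 120)),
            max_size=20,
        ),
        st.floats(0, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_greedy_oracle(self, raw, threshold):
        regions = [self._scored(s, start, start + l) for s, start, l in raw]
        got = {
            (r.score, r.span.start, r.span.end)
            for r in cluster_and_select(regions, threshold)
        }
        want = set(
            oracles.greedy_select(
                [(r.score, r.span.start, r.span.end) for r in regions], threshold
            )
        )
        assert got == want


class TestMonotonicity:
    """More permissive configs can only report more regions."""

    @staticmethod
    def _fixture(rng, n=30):
        positions = sorted(rng.choice(2000, size=n, replace=False).tolist())
        return positions

    def test_min_cpgs(self, rng):
        positions = self._fixture(rng)
        counts = []
        for k in (2, 3, 4):
            cfg = PredictionConfig(min_cpgs=k)
            counts.append(len(pair_sites_to_regions(find_primer_sites(positions, cfg), cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_max_meth_control(self, manifest_3v3, write_bedmethyl_file):
        rng = np.random.default_rng(7)
        positions = sorted(rng.choice(600, size=40, replace=False).tolist())
        paths = {}
        for sid in manifest_3v3.tumor_ids:
            paths[sid] = write_bedmethyl_file([(p, 20, 90.0) for p in positions], name=sid)
        for sid in manifest_3v3.control_ids:
            rows = [(p, 20, float(rng.uniform(0, 20))) for p in positions]
            paths[sid] = write_bedmethyl_file(rows, name=sid)
        counts = []
        for max_ctrl in (20.0, 10.0, 5.0, 0.0):
            cfg = PredictionConfig(max_meth_control=max_ctrl)
            res = predict_msp_regions(manifest_3v3, cfg, paths=paths)
            counts.append(len(res.pre_cluster_regions))
        assert counts == sorted(counts, reverse=True)


class TestPredictPipeline:
    def _dm_fixture(self, manifest, write_bedmethyl_file):
        """One hypermethylated island plus one non-differential island.

        16 CpGs spaced 6 nt span 92 nt, enough for two disjoint primer
        windows at the default 60-nt minimum amplicon length.
        """
        dm_cpgs = [1000 + 6 * i for i in range(16)]
        flat_cpgs = [5000 + 6 * i for i in range(16)]
        paths = {}
        for sid in manifest.tumor_ids:
            rows = [(p, 20, 90.0) for p in dm_cpgs] + [(p, 20, 90.0) for p in flat_cpgs]
            paths[sid] = write_bedmethyl_file(rows, name=sid)
        for sid in manifest.control_ids:
            rows = [(p, 20, 2.0) for p in dm_cpgs] + [(p, 20, 90.0) for p in flat_cpgs]
            paths[sid] = write_bedmethyl_file(rows, name=sid)
        return dm_cpgs, flat_cpgs, paths

    def test_dm_island_only(self, manifest_3v3, write_bedmethyl_file):
        dm_cpgs, flat_cpgs, paths = self._dm_fixture(manifest_3v3, write_bedmethyl_file)
        res = predict_msp_regions(manifest_3v3, PredictionConfig(), paths=paths)
        assert res.regions
        for r in res.regions:
            assert r.span.start >= dm_cpgs[0] and r.span.end <= dm_cpgs[-1] + 24
        assert all(r.span.start < 2000 for r in res.pre_cluster_regions)

    def test_island_overlap_fraction(self, manifest_3v3, write_bedmethyl_file):
        dm_cpgs, _, paths = self._dm_fixture(manifest_3v3, write_bedmethyl_file)
        islands = [GenomicInterval("chr1", 900, 1200)]
        res = predict_msp_regions(
            manifest_3v3, PredictionConfig(), islands=islands, paths=paths
        )
        assert res.report.island_overlap_fraction == 1.0

    def test_all_control_manifest_rejected(self):
        with pytest.raises(ValueError):
            SampleManifest([ManifestEntry("c1", "control"), ManifestEntry("c2", "control")])

    def test_emitted_regions_revalidate(self, manifest_3v3, write_bedmethyl_file):
        from nanomsp.region_prediction import _collect_calls

        _, _, paths = self._dm_fixture(manifest_3v3, write_bedmethyl_file)
        cfg = PredictionConfig()
        res = predict_msp_regions(manifest_3v3, cfg, paths=paths)
        calls, _ = _collect_calls(manifest_3v3, cfg, paths)
        for region in res.pre_cluster_regions:
            assert validate_region(region, calls["chr1"], manifest_3v3, cfg) == []

    def test_report_counts(self, manifest_3v3, write_bedmethyl_file):
        _, _, paths = self._dm_fixture(manifest_3v3, write_bedmethyl_file)
        res = predict_msp_regions(manifest_3v3, PredictionConfig(), paths=paths)
        assert res.report.n_sites == 32
        assert res.report.n_eligible == 16
        assert res.report.n_regions == len(res.pre_cluster_regions)
        assert res.report.n_selected == len(res.regions)


def random_prediction_fixture(rng, manifest, write_bedmethyl_file, max_span=5000, max_cpgs=50):
    """Random raw bedmethyl fixture; returns (paths, per-site truth)."""
    n = int(rng.integers(0, max_cpgs + 1))
    positions = sorted(rng.choice(max_span, size=n, replace=False).tolist())
    truth = {}
    paths = {}
    per_sample_rows = {sid: [] for sid in manifest.tumor_ids + manifest.control_ids}
    for p in positions:
        tumor, control = [], []
        for sid in manifest.tumor_ids:
            d = int(rng.integers(0, 40))
            pct = float(rng.choice([0.0, 5.0, 30.0, 60.0, 95.0]))
            tumor.append((d, pct))
            per_sample_rows[sid].append((p, d, pct))
        for sid in manifest.control_ids:
            d = int(rng.integers(0, 40))
            pct = float(rng.choice([0.0, 2.0, 8.0, 12.0, 50.0]))
            control.append((d, pct))
            per_sample_rows[sid].append((p, d, pct))
        truth[p] = (tumor, control)
    for sid, rows in per_sample_rows.items():
        paths[sid] = write_bedmethyl_file(rows, name=sid)
    return paths, truth


class TestOracleEquivalence:
    def test_pipeline_equals_brute_force(self, manifest_3v3, write_bedmethyl_file, rng):
        cfg = PredictionConfig()
        for _ in range(20):
            paths, truth = random_prediction_fixture(rng, manifest_3v3, write_bedmethyl_file)
            eligible = [
                p
                for p, (tumor, control) in sorted(truth.items())
                if oracles.brute_force_eligible(tumor, control, cfg)
            ]
            want = oracles.brute_force_regions(eligible, cfg)
            res = predict_msp_regions(manifest_3v3, cfg, paths=paths)
            got = sorted(
                (r.span.start, r.span.end, r.fwd_site.cpg_positions, r.rev_site.cpg_positions)
                for r in res.pre_cluster_regions
            )
            assert got == want
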