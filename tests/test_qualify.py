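import numpy as np
import pytest

import rarecnv as rc
from rarecnv.qualify import (
    STATUS_CARRIER,
    STATUS_NON_CARRIER,
    STATUS_RECIPROCAL,
    STATUS_UNCALLABLE,
    QualificationRules,
)

RULES = QualificationRules()


@pytest.mark.parametrize("cn,vclass,expected", [
    (1, "loss", True), (0, "loss", True), (2, "loss", False),
    (3, "loss", False), (3, "gain", True), (4, "gain", True),
    (2, "gain", False), (1, "gain", False),
])
def test_matches_class(cn, vclass, expected):
    assert rc.matches_class(cn, vclass) is expected


def _qualify(calls, region, pm, rules=RULES):
    ix = rc.build_region_probe_index([region], pm)
    return rc.qualify_sample_region(calls, region, ix, pm, rules)


class TestFullSpanRule:
    def test_spanning_deletion_qualifies(self, small_region):
        region, pm = small_region
        call = rc.SegmentCall("s", region.chrom, region.start - 8000,
                              region.end + 8000, 1, 5)
        res = _qualify([call], region, pm)
        assert res.status == STATUS_CARRIER
        assert not res.provisional

    def test_one_bp_short_of_region_start_fails(self, small_region):
        """A deletion starting 1 bp inside the region violates the
        full-span requirement even with ample probe support."""
        region, pm = small_region
        call = rc.SegmentCall("s", region.chrom, region.start + 1,
                              region.end + 8000, 1, 5)
        res = _qualify([call], region, pm)
        assert res.status == STATUS_NON_CARRIER

    def test_too_few_supporting_probes_discarded(self, small_region):
        """A spanning call over a 1-probe stretch fails the 3-consecutive-
        probe filter when it covers fewer than 3 array probes."""
        region, pm = small_region
        # region probes are at start/mid/end; restrict call to the middle one
        mid = (region.start + region.end) // 2
        tight = rc.RegionDefinition("tiny", region.chrom, mid - 1, mid + 1,
                                    "loss", 0)
        call = rc.SegmentCall("s", region.chrom, mid - 1, mid + 1, 1, 1)
        res = _qualify([call], tight, pm)
        assert res.status == STATUS_NON_CARRIER

    def test_small_region_qualifies_via_flank_probes(self):
        """A 1-probe region can still yield a carrier when the spanning
        call extends over flanking probes (3 consecutive in region+flank)."""
        region = rc.RegionDefinition("r1p", "chr4", 2_000_000, 2_010_000,
                                     "loss", 100_000)
        pm = rc.simulate.synthesize_probe_map([region], {"r1p": 1},
                                              flank_spacing=5000)
        call = rc.SegmentCall("s", "chr4", 1_990_000, 2_020_000, 1, 3)
        res = _qualify([call], region, pm)
        assert res.status == STATUS_CARRIER

    def test_wrong_class_not_counted(self, small_region):
        region, pm = small_region
        dup = rc.SegmentCall("s", region.chrom, region.start - 8000,
                             region.end + 8000, 3, 5)
        assert _qualify([dup], region, pm).status == STATUS_NON_CARRIER

    def test_flank_splitting_invariance(self, small_region):
        """Splitting a spanning call's flank overhangs into separate
        segments outside the region leaves qualification unchanged."""
        region, pm = small_region
        whole = [rc.SegmentCall("s", region.chrom, region.start - 16000,
                                region.end + 16000, 1, 7)]
        split = [
            rc.SegmentCall("s", region.chrom, region.start - 16000,
                           region.start - 15000, 1, 1),
            rc.SegmentCall("s", region.chrom, region.start - 8000,
                           region.end + 8000, 1, 5),
            rc.SegmentCall("s", region.chrom, region.end + 15000,
                           region.end + 16000, 1, 1),
        ]
        assert (_qualify(whole, region, pm).status
                == _qualify(split, region, pm).status == STATUS_CARRIER)


class TestMergeMode:
    def _probe_pos(self, pm, region):
        return pm.positions_in(region.chrom, region.start, region.end)

    def test_full_coverage_is_provisional_carrier(self, merge_region):
        region, pm = merge_region
        call = rc.SegmentCall("s", region.chrom, region.start - 1000,
                              region.end + 1000, 1, 28)
        res = _qualify([call], region, pm)
        assert res.status == STATUS_CARRIER
        assert res.provisional
        assert res.supporting_probes == 28

    def test_fragments_covering_15_of_28_qualify(self, merge_region):
        """15/28 > 50% of in-region probes altered across two fragments."""
        region, pm = merge_region
        pos = self._probe_pos(pm, region)
        calls = [
            rc.SegmentCall("s", region.chrom, int(pos[0]), int(pos[7]), 1, 8),
            rc.SegmentCall("s", region.chrom, int(pos[21]), int(pos[27]), 1, 7),
        ]
        res = _qualify(calls, region, pm)
        assert res.status == STATUS_CARRIER
        assert res.supporting_probes == 15

    def test_fragments_covering_14_of_28_do_not_qualify(self, merge_region):
        """'over 50%' is strict: exactly half does not qualify."""
        region, pm = merge_region
        pos = self._probe_pos(pm, region)
        calls = [
            rc.SegmentCall("s", region.chrom, int(pos[0]), int(pos[6]), 1, 7),
            rc.SegmentCall("s", region.chrom, int(pos[21]), int(pos[27]), 1, 7),
        ]
        assert _qualify(calls, region, pm).status == STATUS_NON_CARRIER

    def test_overlapping_fragments_not_double_counted(self, merge_region):
        region, pm = merge_region
        pos = self._probe_pos(pm, region)
        # two segments covering the same 10 probes: union is 10 <= 14
        calls = [
            rc.SegmentCall("s", region.chrom, int(pos[0]), int(pos[9]), 1, 10),
            rc.SegmentCall("s", region.chrom, int(pos[0]), int(pos[9]), 1, 10),
        ]
        assert _qualify(calls, region, pm).status == STATUS_NON_CARRIER

    def test_monotone_under_added_segments(self, merge_region):
        """Adding another matching-class segment never turns a merge-mode
        carrier into a non-carrier (probe unions only grow)."""
        region, pm = merge_region
        pos = self._probe_pos(pm, region)
        rng = np.random.default_rng(0)
        for _ in range(50):
            i, j = sorted(rng.integers(0, 28, 2))
            base = [rc.SegmentCall("s", region.chrom, int(pos[0]),
                                   int(pos[16]), 1, 17)]
            extra = rc.SegmentCall("s", region.chrom, int(pos[i]),
                                   int(pos[j]), 1, j - i + 1)
            assert _qualify(base, region, pm).status == STATUS_CARRIER
            assert _qualify(base + [extra], region, pm).status == STATUS_CARRIER


class TestReciprocal:
    def test_duplication_at_loss_region_is_reciprocal(self, small_region):
        region, pm = small_region
        ix = rc.build_region_probe_index([region], pm)
        dup = rc.SegmentCall("s", region.chrom, region.start - 8000,
                             region.end + 8000, 3, 5)
        res = rc.qualify_reciprocal([dup], region, ix, pm, RULES)
        assert res.status == STATUS_RECIPROCAL

    def test_no_calls_is_non_carrier(self, small_region):
        region, pm = small_region
        ix = rc.build_region_probe_index([region], pm)
        assert rc.qualify_reciprocal([], region, ix, pm,
                                     RULES).status == STATUS_NON_CARRIER

    def test_expected_class_not_counted_as_reciprocal(self, small_region):
        region, pm = small_region
        ix = rc.build_region_probe_index([region], pm)
        dele = rc.SegmentCall("s", region.chrom, region.start - 8000,
                              region.end + 8000, 1, 5)
        assert rc.qualify_reciprocal([dele], region, ix, pm,
                                     RULES).status == STATUS_NON_CARRIER


class TestCarrierMatrix:
    def test_excluded_sample_never_counted(self, small_region):
        region, pm = small_region
        phen = [
            rc.SampleRecord("s1", "cc", "case_obese_child", "M", 10, 35.0),
            rc.SampleRecord("s2", "cc", "case_obese_child", "F", 10, 36.0,
                            excluded=True, exclusion_reason="known_variant"),
        ]
        call = lambda sid: rc.SegmentCall(sid, region.chrom,
                                          region.start - 8000,
                                          region.end + 8000, 1, 5)
        ix = rc.build_region_probe_index([region], pm)
        m = rc.build_carrier_matrix([call("s1"), call("s2")], phen, [region],
                                    ix, pm)
        assert m.statuses.at["s2", region.region_id] == STATUS_CARRIER
        assert m.carriers(region.region_id) == ["s1"]
        assert int(m.counts_by(region.region_id, "group").sum()) == 1

    def test_zero_probe_region_all_uncallable(self):
        region = rc.RegionDefinition("r0", "chr6", 100, 200, "loss")
        pm = rc.ProbeMap.from_records([("chr1", 50, "p")])
        ix = rc.build_region_probe_index([region], pm)
        phen = [rc.SampleRecord("s1", "c", "population", "M", 31, 24.0)]
        m = rc.build_carrier_matrix([], phen, [region], ix, pm)
        assert (m.statuses["r0"] == STATUS_UNCALLABLE).all()
        assert int(m.counts_by("r0", "group").sum()) == 0

    def test_output_independent_of_call_order(self, merge_region):
        region, pm = merge_region
        pos = pm.positions_in(region.chrom, region.start, region.end)
        calls = [
            rc.SegmentCall("s1", region.chrom, int(pos[0]), int(pos[9]), 1, 10),
            rc.SegmentCall("s1", region.chrom, int(pos[12]), int(pos[27]), 1, 16),
            rc.SegmentCall("s1", region.chrom, int(pos[3]), int(pos[5]), 3, 3),
        ]
        phen = [rc.SampleRecord("s1", "c", "population", "M", 31, 24.0)]
        ix = rc.build_region_probe_index([region], pm)
        m1 = rc.build_carrier_matrix(calls, phen, [region], ix, pm)
        m2 = rc.build_carrier_matrix(calls[::-1], phen, [region], ix, pm)
        assert m1.statuses.equals(m2.statuses)
        assert m1.supporting_probes.equals(m2.supporting_probes)
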