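"""Region-level carrier qualification from segment-level copy-number calls.

Upstream CNV callers emit per-sample copy-number segments.  Whether a sample
counts as a *carrier* at a candidate region is decided here by rules that
mirror standard practice for array-based rare-CNV replication:

* only segments of the region's expected class (loss/gain) are considered,
  and a segment must be supported by at least ``min_consecutive_probes``
  consecutive array probes (counted over the region plus its flanks, so a
  1- or 2-probe region can still yield a qualified call);
* regions with few probes (below ``merge_min_probes``) require a single
  segment spanning the entire region — fragmented or partial calls do not
  qualify;
* probe-dense regions (``merge_min_probes`` or more) use *merge mode*:
  high-sensitivity callers often split one large event into several
  segments, so same-class segments are unioned and the sample is a
  provisional carrier when more than ``merge_fraction`` of in-region probes
  are altered.  Merge-mode calls carry ``provisional=True``, standing in
  for the manual intensity-plot review such calls receive in practice.

Reciprocal events (the opposite class at the same locus) are qualified with
identical criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (
    ProbeMap,
    RegionDefinition,
    RegionProbeIndex,
    SampleRecord,
    SegmentCall,
)

logger = logging.getLogger(__name__)

STATUS_CARRIER = "carrier"
STATUS_RECIPROCAL = "reciprocal_carrier"
STATUS_NON_CARRIER = "non_carrier"
STATUS_UNCALLABLE = "uncallable"


@dataclass(frozen=True)
class QualificationRules:
    """Thresholds governing carrier qualification.

    ``merge_fraction`` is a strict lower bound: with 28 in-region probes,
    15 altered probes qualify (15/28 > 0.5) but 14 do not.
    """

    min_consecutive_probes: int = 3
    full_span_max_probes: int = 6
    merge_min_probes: int = 11
    merge_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.merge_fraction <= 1):
            raise ValueError("merge_fraction must be in (0, 1]")
        if self.full_span_max_probes >= self.merge_min_probes:
            raise ValueError("full_span_max_probes must be < merge_min_probes")
        if self.min_consecutive_probes < 1:
            raise ValueError("min_consecutive_probes must be >= 1")


@dataclass(frozen=True)
class CarrierStatus:
    sample_id: str
    region_id: str
    status: str
    supporting_probes: int = 0
    provisional: bool = False


def matches_class(cn_state: int, variant_class: str) -> bool:
    """True iff the copy-number state is of the given class: below 2 for a
    loss (including homozygous deletions, state 0), above 2 for a gain."""
    if variant_class == "loss":
        return cn_state < 2
    if variant_class == "gain":
        return cn_state > 2
    raise ValueError(f"unknown variant_class {variant_class!r}")


def _invert(variant_class: str) -> str:
    return "gain" if variant_class == "loss" else "loss"


def _surviving_calls(
    calls: Iterable[SegmentCall],
    region: RegionDefinition,
    probe_map: ProbeMap,
    rules: QualificationRules,
    variant_class: str,
) -> list[tuple[SegmentCall, int]]:
    """Filter to same-chromosome calls of the wanted class supported by at
    least ``min_consecutive_probes`` consecutive probes, counting probes
    within the region-plus-flank window."""
    lo, hi = region.flank_window()
    out = []
    for call in calls:
        if call.chrom != region.chrom:
            continue
        if not matches_class(call.cn_state, variant_class):
            continue
        support = probe_map.count_in(
            call.chrom, max(call.start, lo), min(call.end, hi)
        )
        if support >= rules.min_consecutive_probes:
            out.append((call, support))
    return out


def _qualify(
    calls: Sequence[SegmentCall],
    region: RegionDefinition,
    index: RegionProbeIndex,
    probe_map: ProbeMap,
    rules: QualificationRules,
    variant_class: str,
    carrier_label: str,
    sample_id: str,
) -> CarrierStatus:
    n_region = index.n_probes_region(region.region_id)
    if n_region == 0:
        return CarrierStatus(sample_id, region.region_id, STATUS_UNCALLABLE)

    surviving = _surviving_calls(calls, region, probe_map, rules, variant_class)
    if not surviving:
        return CarrierStatus(sample_id, region.region_id, STATUS_NON_CARRIER)

    if n_region < rules.merge_min_probes:
        # full-span rule: one segment must cover the whole region
        best = 0
        for call, support in surviving:
            if call.start <= region.start and call.end >= region.end:
                best = max(best, support)
        if best:
            return CarrierStatus(
                sample_id, region.region_id, carrier_label, best, False
            )
        return CarrierStatus(sample_id, region.region_id, STATUS_NON_CARRIER)

    # merge mode: union in-region probes over all surviving segments
    region_pos = index.in_region[region.region_id]
    altered = np.zeros(region_pos.size, dtype=bool)
    for call, _support in surviving:
        lo = np.searchsorted(region_pos, call.start, side="left")
        hi = np.searchsorted(region_pos, call.end, side="right")
        altered[lo:hi] = True
    n_altered = int(altered.sum())
    if n_altered > rules.merge_fraction * n_region:
        return CarrierStatus(
            sample_id, region.region_id, carrier_label, n_altered, True
        )
    return CarrierStatus(sample_id, region.region_id, STATUS_NON_CARRIER)


def qualify_sample_region(
    calls: Sequence[SegmentCall],
    region: RegionDefinition,
    index: RegionProbeIndex,
    probe_map: ProbeMap,
    rules: QualificationRules = QualificationRules(),
) -> CarrierStatus:
    """Qualify one sample at one region for the region's expected class."""
    sample_id = calls[0].sample_id if calls else ""
    return _qualify(
        calls, region, index, probe_map, rules,
        region.variant_class, STATUS_CARRIER, sample_id,
    )


def qualify_reciprocal(
    calls: Sequence[SegmentCall],
    region: RegionDefinition,
    index: RegionProbeIndex,
    probe_map: ProbeMap,
    rules: QualificationRules = QualificationRules(),
) -> CarrierStatus:
    """Qualify the opposite-class (reciprocal) event with identical rules."""
    sample_id = calls[0].sample_id if calls else ""
    return _qualify(
        calls, region, index, probe_map, rules,
        _invert(region.variant_class), STATUS_RECIPROCAL, sample_id,
    )


@dataclass
class CarrierMatrix:
    """Per-sample x per-region qualified carrier status.

    ``statuses`` has one row per sample and one column per region; cells
    hold one of the four status strings.  ``provisional`` marks merge-mode
    calls pending review.  Excluded samples stay in the matrix but never
    enter counts.
    """

    statuses: pd.DataFrame
    provisional: pd.DataFrame
    supporting_probes: pd.DataFrame
    phenotypes: pd.DataFrame

    def _counted(self) -> pd.DataFrame:
        keep = ~self.phenotypes["excluded"].astype(bool)
        return self.phenotypes.loc[keep]

    def carriers(self, region_id: str, status: str = STATUS_CARRIER) -> list[str]:
        pheno = self._counted()
        col = self.statuses.loc[pheno.index, region_id]
        return list(col.index[col == status])

    def counts_by(self, region_id: str, key: str, status: str = STATUS_CARRIER) -> pd.Series:
        """Carrier counts stratified by a phenotype column (e.g. ``group``
        or ``weight_class``)."""
        pheno = self._counted()
        col = self.statuses.loc[pheno.index, region_id]
        return (col == status).groupby(pheno[key]).sum()

    def group_sizes(self, key: str) -> pd.Series:
        return self._counted().groupby(key).size()

    def count_table(self, status: str = STATUS_CARRIER) -> pd.DataFrame:
        """Regions x (group, weight_class) carrier counts."""
        pheno = self._counted()
        strata = pheno["group"] + "/" + pheno["weight_class"].fillna("unknown")
        rows = {}
        for region_id in self.statuses.columns:
            col = self.statuses.loc[pheno.index, region_id]
            rows[region_id] = (col == status).groupby(strata).sum()
        return pd.DataFrame(rows).T.fillna(0).astype(int)


def build_carrier_matrix(
    all_calls: Sequence[SegmentCall],
    phenotypes: Sequence[SampleRecord],
    regions: Sequence[RegionDefinition],
    index: RegionProbeIndex,
    probe_map: ProbeMap,
    rules: QualificationRules = QualificationRules(),
) -> CarrierMatrix:
    """Qualify every sample at every region.

    A sample qualifying for the expected class is a ``carrier``; otherwise,
    if it qualifies for the opposite class, a ``reciprocal_carrier``.
    Output is independent of the ordering of ``all_calls``.
    """
    known = {s.sample_id for s in phenotypes}
    orphans = sorted({c.sample_id for c in all_calls} - known)
    if orphans:
        raise ValueError(f"calls reference unknown samples: {orphans[:10]}")

    calls_by_sample: dict[str, list[SegmentCall]] = {s: [] for s in known}
    for call in all_calls:
        calls_by_sample[call.sample_id].append(call)
    # canonical ordering for determinism
    for lst in calls_by_sample.values():
        lst.sort(key=lambda c: (c.chrom, c.start, c.end, c.cn_state))

    sample_ids = [s.sample_id for s in phenotypes]
    region_ids = [r.region_id for r in regions]
    status = pd.DataFrame(
        STATUS_NON_CARRIER, index=sample_ids, columns=region_ids, dtype=object
    )
    provisional = pd.DataFrame(False, index=sample_ids, columns=region_ids)
    support = pd.DataFrame(0, index=sample_ids, columns=region_ids)

    with_calls = [sid for sid in sample_ids if calls_by_sample[sid]]
    for region in regions:
        rid = region.region_id
        if index.uncallable(rid):
            status[rid] = STATUS_UNCALLABLE
            continue
        # samples with no calls anywhere are non-carriers by construction
        for sid in with_calls:
            calls = calls_by_sample[sid]
            res = qualify_sample_region(calls, region, index, probe_map, rules)
            if res.status != STATUS_CARRIER:
                rec = qualify_reciprocal(calls, region, index, probe_map, rules)
                if rec.status == STATUS_RECIPROCAL:
                    res = rec
            status.at[sid, rid] = res.status
            provisional.at[sid, rid] = res.provisional
            support.at[sid, rid] = res.supporting_probes

    pheno = pd.DataFrame(
        {
            "cohort": [s.cohort for s in phenotypes],
            "group": [s.group for s in phenotypes],
            "sex": [s.sex for s in phenotypes],
            "bmi": [np.nan if s.bmi is None else s.bmi for s in phenotypes],
            "weight_class": [s.weight_class for s in phenotypes],
            "excluded": [s.excluded for s in phenotypes],
        },
        index=sample_ids,
    )
    return CarrierMatrix(status, provisional, support, pheno)
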