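"""Synthetic cohort generation with known ground truth.

Generates the complete inputs of a rare-CNV replication study — array
probe map, per-sample copy-number segment calls, and a phenotype table —
from a single seeded specification, so that every pipeline stage can be
exercised against a known carrier assignment.

What is emulated
----------------
* cohort structure: two obesity case-control cohorts (child and adult)
  plus a general-population cohort, with configurable sizes;
* rare region-level carriers at configurable frequency, with a
  case-control effect given as an odds ratio on carrier frequency and/or
  a population effect given as a shift in log10(BMI);
* the call morphology of segment-based CNV callers: spanning calls with
  jittered breakpoints that extend into the flanks, and — for probe-dense
  regions — events fragmented into several sub-segments (fragmentation
  never drops a true carrier's in-region coverage to or below the
  merge-mode threshold, so ground truth stays well defined);
* reciprocal (opposite-class) variants;
* group-differential miscalls: false-negative carriers whose segments are
  withheld and false-positive non-carriers given spurious spanning calls.

BMI is modelled as sex-specific lognormal (base 10); case/control group
membership constrains BMI to the matching weight class by truncated
sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import datasets
from .io import (
    ProbeMap,
    RegionDefinition,
    SampleRecord,
    SegmentCall,
    build_region_probe_index,
    write_phenotypes,
    write_probe_map,
    write_regions,
    write_segment_calls,
)
from .qualify import (
    STATUS_CARRIER,
    STATUS_NON_CARRIER,
    STATUS_RECIPROCAL,
    STATUS_UNCALLABLE,
    CarrierMatrix,
    QualificationRules,
    build_carrier_matrix,
)

DEFAULT_GROUP_SIZES = {
    "control_child": 557,
    "case_obese_child": 645,
    "control_adult": 843,
    "case_obese_adult": 701,
    "population": 5213,
}

_CASE_GROUPS = ("case_obese_child", "case_obese_adult")
_CONTROL_GROUPS = ("control_child", "control_adult")

_LOG10_OBESE = math.log10(30.0)
# upper bound for controls sits just below 25 so that rounding emitted BMI
# to 2 decimals cannot push a control across the overweight threshold
_LOG10_OVERWEIGHT = math.log10(24.995)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic study.

    ``carrier_freq`` is the baseline (control / population) carrier
    frequency per region; ``odds_ratio`` scales the carrier odds in the
    obese case groups; ``bmi_shift_log10`` is added to the log10(BMI) of
    population carriers.  ``fragmentation_prob`` applies only to regions
    in merge mode (>= ``merge_min_probes`` in-region probes).
    ``jitter_probes`` is the maximum number of flank probes a breakpoint
    may wander past the region boundary.  ``seed`` is mandatory.
    """

    seed: int | None = None
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    regions: tuple[RegionDefinition, ...] | None = None
    probe_map: ProbeMap | None = None
    carrier_freq: float = 0.002
    carrier_freq_by_region: Mapping[str, float] | None = None
    odds_ratio: float = 1.0
    bmi_shift_log10: float = 0.0
    bmi_shift_by_region: Mapping[str, float] | None = None
    bmi_mu_m: float = math.log10(25.5)
    bmi_mu_f: float = math.log10(24.5)
    bmi_sigma: float = 0.07
    fragmentation_prob: float = 0.3
    jitter_probes: int = 2
    reciprocal_freq: float = 0.0
    fp_case: float = 0.0
    fp_control: float = 0.0
    fn_case: float = 0.0
    fn_control: float = 0.0
    hom_loss_prob: float = 0.05
    rules: QualificationRules = QualificationRules()

    def __post_init__(self) -> None:
        for name in ("carrier_freq", "fragmentation_prob", "reciprocal_freq",
                     "fp_case", "fp_control", "fn_case", "fn_control",
                     "hom_loss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.bmi_sigma <= 0:
            raise ValueError("bmi_sigma must be positive")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")

    def region_freq(self, region_id: str) -> float:
        if self.carrier_freq_by_region:
            return self.carrier_freq_by_region.get(region_id, self.carrier_freq)
        return self.carrier_freq

    def region_shift(self, region_id: str) -> float:
        if self.bmi_shift_by_region:
            return self.bmi_shift_by_region.get(region_id, self.bmi_shift_log10)
        return self.bmi_shift_log10


@dataclass
class SyntheticCohort:
    """A generated study: inputs plus the ground-truth carrier grid.

    ``ground_truth`` holds the *true* status per sample x region
    (``carrier`` / ``reciprocal_carrier`` / ``non_carrier`` /
    ``uncallable``); ``observed_truth`` additionally reflects injected
    miscalls, i.e. what an error-free qualifier should recover from the
    emitted segments.
    """

    spec: CohortSpec
    seed: int
    regions: list[RegionDefinition]
    probe_map: ProbeMap
    segment_calls: list[SegmentCall]
    phenotypes: list[SampleRecord]
    ground_truth: pd.DataFrame
    observed_truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "regions": outdir / "regions.tsv",
            "probes": outdir / "probes.tsv",
            "calls": outdir / "calls.tsv",
            "phenotypes": outdir / "phenotypes.tsv",
        }
        write_regions(self.regions, paths["regions"])
        write_probe_map(self.probe_map, paths["probes"])
        write_segment_calls(self.segment_calls, paths["calls"])
        write_phenotypes(self.phenotypes, paths["phenotypes"])
        return paths

    def qualify(self, rules: QualificationRules | None = None) -> CarrierMatrix:
        """Run carrier qualification on the generated inputs."""
        index = build_region_probe_index(self.regions, self.probe_map)
        return build_carrier_matrix(
            self.segment_calls, self.phenotypes, self.regions, index,
            self.probe_map, rules or self.spec.rules,
        )


def synthesize_probe_map(
    regions: Sequence[RegionDefinition],
    n_probes: Mapping[str, int],
    flank_spacing: int = 7500,
) -> ProbeMap:
    """Build a probe map placing an exact number of probes inside each
    region (evenly, endpoints included) plus regularly spaced probes
    across the flanks."""
    records: list[tuple[str, int, str]] = []
    for r in regions:
        n = int(n_probes[r.region_id])
        if n == 1:
            inside = [(r.start + r.end) // 2]
        elif n > 1:
            inside = np.unique(
                np.linspace(r.start, r.end, n).round().astype(int))
            if inside.size != n:
                raise ValueError(
                    f"region {r.region_id} too small for {n} probes")
            inside = inside.tolist()
        else:
            inside = []
        lo, hi = r.flank_window()
        left = np.arange(r.start - flank_spacing, lo - 1, -flank_spacing)[::-1]
        right = np.arange(r.end + flank_spacing, hi + 1, flank_spacing)
        for i, p in enumerate(left):
            records.append((r.chrom, int(p), f"{r.region_id}_L{i}"))
        for i, p in enumerate(inside):
            records.append((r.chrom, int(p), f"{r.region_id}_P{i}"))
        for i, p in enumerate(right):
            records.append((r.chrom, int(p), f"{r.region_id}_R{i}"))
    # drop accidental duplicates from abutting flanks
    frame = pd.DataFrame(records, columns=["chrom", "position", "probe_id"])
    frame = frame.drop_duplicates(subset=["chrom", "position"])
    return ProbeMap(frame)


def candidate_region_set(
    flank_bp: int = 500_000, flank_spacing: int = 7500
) -> tuple[list[RegionDefinition], ProbeMap]:
    """The 18 bundled candidate obesity loci together with a synthesized
    probe map whose in-region probe counts match the published coverage
    column exactly (including the zero-probe chr6 locus)."""
    regions = datasets.candidate_regions(flank_bp)
    counts = candidate_probe_counts()
    return regions, synthesize_probe_map(regions, counts, flank_spacing)


def candidate_probe_counts() -> dict[str, int]:
    df = datasets.candidate_region_counts()
    return df["probes_on_array"].astype(int).to_dict()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _truncated_log10_bmi(
    rng: np.random.Generator, mu: np.ndarray, sigma: float,
    lower: float | None, upper: float | None,
) -> np.ndarray:
    a = -np.inf if lower is None else (lower - mu) / sigma
    b = np.inf if upper is None else (upper - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, random_state=rng)


def _case_freq(base: float, odds_ratio: float) -> float:
    odds = base / (1 - base) * odds_ratio
    return odds / (1 + odds)


class _SegmentEmitter:
    """Emits caller-style segments for one region given its probe layout."""

    def __init__(self, region: RegionDefinition, probe_map: ProbeMap,
                 rules: QualificationRules):
        self.region = region
        self.rules = rules
        pos = probe_map.positions(region.chrom)
        lo, hi = region.flank_window()
        self.pos = pos
        self.f0 = int(np.searchsorted(pos, lo, side="left"))
        self.f1 = int(np.searchsorted(pos, hi, side="right")) - 1
        self.i0 = int(np.searchsorted(pos, region.start, side="left"))
        self.i1 = int(np.searchsorted(pos, region.end, side="right")) - 1
        self.n_in = self.i1 - self.i0 + 1 if self.i1 >= self.i0 else 0

    def _bounds(self, jl: int, jr: int) -> tuple[int, int, int, int]:
        """Clamp left/right extra flank probes and pad so a spanning call
        carries at least ``min_consecutive_probes`` probes."""
        el = min(jl, self.i0 - self.f0)
        er = min(jr, self.f1 - self.i1)
        need = self.rules.min_consecutive_probes
        while self.n_in + el + er < need:
            if self.i1 + er < self.f1:
                er += 1
            elif self.i0 - el > self.f0:
                el += 1
            else:
                raise ValueError(
                    f"probe map too sparse around {self.region.region_id}: "
                    f"cannot emit a >= {need}-probe spanning call"
                )
        return el, er, self.i0 - el, self.i1 + er

    def spanning(self, rng: np.random.Generator, cn_state: int,
                 sample_id: str, jitter: int) -> list[SegmentCall]:
        jl = int(rng.integers(0, jitter + 1))
        jr = int(rng.integers(0, jitter + 1))
        _el, _er, ka, kb = self._bounds(jl, jr)
        start = min(self.region.start, int(self.pos[ka])) - int(rng.integers(0, 200))
        end = max(self.region.end, int(self.pos[kb])) + int(rng.integers(0, 200))
        n = kb - ka + 1
        return [SegmentCall(sample_id, self.region.chrom, max(1, start), end,
                            cn_state, n)]

    def fragmented(self, rng: np.random.Generator, cn_state: int,
                   sample_id: str, jitter: int) -> list[SegmentCall]:
        """Two same-class sub-segments jointly covering strictly more than
        the merge fraction of in-region probes."""
        n_in = self.n_in
        # gap strictly below (1 - merge_fraction) of the in-region probes
        g_max = int(math.ceil(n_in * (1 - self.rules.merge_fraction))) - 1
        if g_max < 1:
            return self.spanning(rng, cn_state, sample_id, jitter)
        g = int(rng.integers(1, g_max + 1))
        m1 = int(rng.integers(1, n_in - g))  # left fragment in-region probes
        m2 = n_in - g - m1
        jl = int(rng.integers(0, jitter + 1))
        jr = int(rng.integers(0, jitter + 1))
        need = self.rules.min_consecutive_probes
        el = min(max(jl, need - m1), self.i0 - self.f0)
        er = min(max(jr, need - m2), self.f1 - self.i1)
        la, lb = self.i0 - el, self.i0 + m1 - 1
        ra, rb = self.i1 - m2 + 1, self.i1 + er
        calls = []
        start = min(self.region.start, int(self.pos[la])) - int(rng.integers(0, 200))
        gap_mid = (int(self.pos[lb]) + int(self.pos[lb + 1])) // 2
        calls.append(SegmentCall(sample_id, self.region.chrom, max(1, start),
                                 min(gap_mid, int(self.pos[lb]) + 100),
                                 cn_state, lb - la + 1))
        end = max(self.region.end, int(self.pos[rb])) + int(rng.integers(0, 200))
        gap_mid2 = (int(self.pos[ra - 1]) + int(self.pos[ra])) // 2
        calls.append(SegmentCall(sample_id, self.region.chrom,
                                 max(gap_mid2, int(self.pos[ra]) - 100), end,
                                 cn_state, rb - ra + 1))
        return calls


def generate(spec: CohortSpec, seed: int | None = None) -> SyntheticCohort:
    """Generate a complete synthetic study from a seeded specification.

    Two runs with the same spec and seed produce byte-identical outputs.
    """
    if seed is None:
        seed = spec.seed
    if seed is None:
        raise ValueError("a seed is required (CohortSpec.seed or argument)")
    rng = np.random.default_rng(seed)

    if spec.regions is None or spec.probe_map is None:
        regions, probe_map = candidate_region_set()
        if spec.regions is not None:
            regions = list(spec.regions)
        if spec.probe_map is not None:
            probe_map = spec.probe_map
    else:
        regions, probe_map = list(spec.regions), spec.probe_map

    # --- samples and sexes ------------------------------------------------
    sample_ids: list[str] = []
    groups: list[str] = []
    for group, size in spec.group_sizes.items():
        for i in range(size):
            sample_ids.append(f"{group}_{i:05d}")
            groups.append(group)
    n_total = len(sample_ids)
    group_arr = np.array(groups)
    sex = np.where(rng.random(n_total) < 0.5, "M", "F")
    mu = np.where(sex == "M", spec.bmi_mu_m, spec.bmi_mu_f)

    # --- true carrier assignment -----------------------------------------
    callable_regions = []
    truth = pd.DataFrame(STATUS_NON_CARRIER, index=sample_ids,
                         columns=[r.region_id for r in regions], dtype=object)
    is_case = np.isin(group_arr, _CASE_GROUPS)
    for r in regions:
        rid = r.region_id
        if probe_map.count_in(r.chrom, r.start, r.end) == 0:
            truth[rid] = STATUS_UNCALLABLE
            continue
        callable_regions.append(r)
        base = spec.region_freq(rid)
        p = np.where(is_case, _case_freq(base, spec.odds_ratio), base)
        carrier = rng.random(n_total) < p
        truth.loc[carrier, rid] = STATUS_CARRIER
        if spec.reciprocal_freq > 0:
            recip = (~carrier) & (rng.random(n_total) < spec.reciprocal_freq)
            truth.loc[recip, rid] = STATUS_RECIPROCAL

    # --- BMI and phenotype records ---------------------------------------
    shift = np.zeros(n_total)
    for r in callable_regions:
        s = spec.region_shift(r.region_id)
        if s:
            shift += np.where(truth[r.region_id] == STATUS_CARRIER, s, 0.0)

    log_bmi = np.empty(n_total)
    pop = group_arr == "population"
    log_bmi[pop] = rng.normal(mu[pop] + shift[pop], spec.bmi_sigma)
    for grp, lower, upper in (
        (_CASE_GROUPS, _LOG10_OBESE, None),
        (_CONTROL_GROUPS, None, _LOG10_OVERWEIGHT),
    ):
        mask = np.isin(group_arr, grp)
        if mask.any():
            log_bmi[mask] = _truncated_log10_bmi(
                rng, mu[mask] + shift[mask], spec.bmi_sigma, lower, upper)

    phenotypes = [
        SampleRecord(
            sample_id=sid,
            cohort="population" if grp == "population" else grp,
            group=grp,
            sex=sx,
            age=31.0 if grp == "population" else (10.0 if "child" in grp else 45.0),
            bmi=float(round(10**lb, 2)),
            excluded=False,
        )
        for sid, grp, sx, lb in zip(sample_ids, groups, sex, log_bmi)
    ]

    # --- segment emission with miscalls -----------------------------------
    observed = truth.copy()
    calls: list[SegmentCall] = []
    fp = np.where(is_case, spec.fp_case, spec.fp_control)
    fn = np.where(is_case, spec.fn_case, spec.fn_control)
    sid_arr = np.array(sample_ids)
    for r in callable_regions:
        rid = r.region_id
        emitter = _SegmentEmitter(r, probe_map, spec.rules)
        merge_mode = emitter.n_in >= spec.rules.merge_min_probes
        loss_state = lambda: 0 if rng.random() < spec.hom_loss_prob else 1
        cn_for = {"loss": loss_state, "gain": lambda: 3}
        col = truth[rid].to_numpy()

        for status, label in ((STATUS_CARRIER, r.variant_class),
                              (STATUS_RECIPROCAL,
                               "gain" if r.variant_class == "loss" else "loss")):
            idx = np.flatnonzero(col == status)
            for j in idx:
                if rng.random() < fn[j]:  # false negative: withhold segments
                    observed.iat[j, observed.columns.get_loc(rid)] = (
                        STATUS_NON_CARRIER)
                    continue
                cn = cn_for[label]()
                if merge_mode and rng.random() < spec.fragmentation_prob:
                    calls.extend(emitter.fragmented(
                        rng, cn, sid_arr[j], spec.jitter_probes))
                else:
                    calls.extend(emitter.spanning(
                        rng, cn, sid_arr[j], spec.jitter_probes))
        # false positives: spurious expected-class spanning calls
        noncar = np.flatnonzero(col == STATUS_NON_CARRIER)
        if noncar.size:
            hit = noncar[rng.random(noncar.size) < fp[noncar]]
            for j in hit:
                cn = cn_for[r.variant_class]()
                calls.extend(emitter.spanning(
                    rng, cn, sid_arr[j], spec.jitter_probes))
                observed.iat[j, observed.columns.get_loc(rid)] = STATUS_CARRIER

    calls.sort(key=lambda c: (c.sample_id, c.chrom, c.start))
    return SyntheticCohort(
        spec=spec, seed=seed, regions=regions, probe_map=probe_map,
        segment_calls=calls, phenotypes=phenotypes,
        ground_truth=truth, observed_truth=observed,
    )


def foxp2_style_spec(seed: int | None = None) -> CohortSpec:
    """Named preset for a heterogeneous-effect locus: a population cohort
    where large deletions lower BMI but small ones do not.

    The generator emits carriers for a single loss region; downstream code
    partitions them by deletion extent (segments reaching beyond the
    canonical bounds) and contrasts the subgroups.  Use together with
    :func:`generate` and :func:`rarecnv.quant.subgroup_contrast`.
    """
    region = RegionDefinition("foxp2_like", "chr7", 113_843_696, 113_859_679,
                              "loss", 500_000)
    n_probes = {"foxp2_like": 4}
    pm = synthesize_probe_map([region], n_probes)
    return CohortSpec(
        seed=seed,
        group_sizes={"population": 5000},
        regions=(region,),
        probe_map=pm,
        carrier_freq=0.002,
        bmi_shift_log10=0.0,
    )
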