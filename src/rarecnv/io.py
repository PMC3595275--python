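"""Readers, writers and validation for the tabular inputs of a rare-CNV study.

All genomic coordinates are 1-based and inclusive on both ends (genome build
hg18), the convention in which candidate-region tables are usually printed.
A flag on :func:`read_regions` converts 0-based half-open BED input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VARIANT_CLASSES = ("gain", "loss")
WEIGHT_OBESE_BMI = 30.0
WEIGHT_OVERWEIGHT_BMI = 25.0

GROUPS = (
    "case_obese_child",
    "control_child",
    "case_obese_adult",
    "control_adult",
    "population",
)


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class RegionDefinition:
    """A candidate structural-variant locus.

    ``start``/``end`` are 1-based inclusive base-pair coordinates.  The
    expected variant class is ``"loss"`` (deletion) or ``"gain"``
    (duplication).  ``flank_bp`` is the flanking context, on each side, in
    which segment calls are still examined (calls extending into the flank
    may contribute probe support).
    """

    region_id: str
    chrom: str
    start: int
    end: int
    variant_class: str
    flank_bp: int = 500_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"region {self.region_id}: start {self.start} > end {self.end}"
            )
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(
                f"region {self.region_id}: unknown variant_class "
                f"{self.variant_class!r} (expected one of {VARIANT_CLASSES})"
            )
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be non-negative")

    @property
    def span_bp(self) -> int:
        """Distance between the endpoint coordinates, ``end - start``.

        This matches the sizes printed in candidate-locus tables; the closed
        interval contains ``span_bp + 1`` bases.
        """
        return self.end - self.start

    @property
    def n_bases(self) -> int:
        return self.end - self.start + 1

    def flank_window(self) -> tuple[int, int]:
        """The closed interval covering the region plus both flanks."""
        return max(1, self.start - self.flank_bp), self.end + self.flank_bp


@dataclass(frozen=True)
class SegmentCall:
    """One contiguous copy-number segment for one sample, as emitted by an
    upstream caller.  ``cn_state`` is the integer copy number: 2 diploid
    normal, <2 loss (0 = homozygous deletion), >2 gain."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cn_state: int
    n_probes: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"segment for {self.sample_id}: start {self.start} > end {self.end}"
            )
        if self.cn_state < 0:
            raise ValueError("cn_state must be >= 0")


def weight_class_from_bmi(bmi: float | None) -> str | None:
    """Classify BMI: obese >= 30, overweight in [25, 30), normal < 25."""
    if bmi is None or (isinstance(bmi, float) and math.isnan(bmi)):
        return None
    if bmi >= WEIGHT_OBESE_BMI:
        return "obese"
    if bmi >= WEIGHT_OVERWEIGHT_BMI:
        return "overweight"
    return "normal"


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    cohort: str
    group: str
    sex: str
    age: float | None = None
    bmi: float | None = None
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"sample {self.sample_id}: unknown group {self.group!r}"
            )
        if self.sex not in ("M", "F"):
            raise ValueError(f"sample {self.sample_id}: sex must be M or F")

    @property
    def weight_class(self) -> str | None:
        return weight_class_from_bmi(self.bmi)


class ProbeMap:
    """Ordered array probe positions, per chromosome.

    Positions must be strictly increasing within each chromosome; duplicate
    positions are rejected.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"chrom", "position", "probe_id"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"probe map missing columns: {sorted(missing)}")
        frame = frame.sort_values(["chrom", "position"], kind="mergesort")
        frame = frame.reset_index(drop=True)
        for chrom, sub in frame.groupby("chrom", sort=False):
            pos = sub["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"probe map: duplicate or unsorted positions on {chrom}"
                )
        self._frame = frame
        self._positions = {
            chrom: sub["position"].to_numpy(dtype=np.int64)
            for chrom, sub in frame.groupby("chrom", sort=False)
        }

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, str]]
    ) -> "ProbeMap":
        return cls(
            pd.DataFrame(records, columns=["chrom", "position", "probe_id"])
        )

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    def chromosomes(self) -> list[str]:
        return list(self._positions)

    def positions(self, chrom: str) -> np.ndarray:
        return self._positions.get(chrom, np.empty(0, dtype=np.int64))

    def positions_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Probe positions within the closed interval [start, end]."""
        pos = self.positions(chrom)
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return pos[lo:hi]

    def count_in(self, chrom: str, start: int, end: int) -> int:
        return int(self.positions_in(chrom, start, end).size)


@dataclass
class RegionProbeIndex:
    """Per-region in-region and flank probe positions.

    ``n_probes_region`` counts probes in the closed region interval only;
    flank probes are held separately because published probe-coverage
    columns count strictly in-region probes.
    """

    regions: dict[str, RegionDefinition]
    in_region: dict[str, np.ndarray]
    in_flank_window: dict[str, np.ndarray]

    def n_probes_region(self, region_id: str) -> int:
        return int(self.in_region[region_id].size)

    def uncallable(self, region_id: str) -> bool:
        return self.n_probes_region(region_id) == 0

    def region(self, region_id: str) -> RegionDefinition:
        return self.regions[region_id]


def build_region_probe_index(
    regions: Sequence[RegionDefinition], probe_map: ProbeMap
) -> RegionProbeIndex:
    """Index probes against regions; a region with zero in-region probes is
    flagged uncallable (including regions on chromosomes absent from the
    array)."""
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region_id in region set")
    in_region: dict[str, np.ndarray] = {}
    in_flank: dict[str, np.ndarray] = {}
    for r in regions:
        in_region[r.region_id] = probe_map.positions_in(r.chrom, r.start, r.end)
        lo, hi = r.flank_window()
        in_flank[r.region_id] = probe_map.positions_in(r.chrom, lo, hi)
    return RegionProbeIndex(
        regions={r.region_id: r for r in regions},
        in_region=in_region,
        in_flank_window=in_flank,
    )


# ---------------------------------------------------------------------------
# File readers (tab-delimited dialects)
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_regions(
    path: str | Path, zero_based_half_open: bool = False
) -> list[RegionDefinition]:
    """Read a BED-like region file.

    Columns: chrom, start, end, region_id, variant_class[, flank_bp].
    Coordinates are 1-based inclusive unless ``zero_based_half_open`` is
    set, in which case they are converted (start+1, end unchanged).
    """
    regions: list[RegionDefinition] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 5:
            raise ParseError(
                f"{path}:{lineno}: expected >=5 tab-separated columns, "
                f"got {len(fields)}"
            )
        chrom, start_s, end_s, region_id, vclass = fields[:5]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad coordinate: {exc}") from exc
        if zero_based_half_open:
            start += 1
        flank = 500_000
        if len(fields) >= 6 and fields[5].strip():
            flank = int(fields[5])
        try:
            regions.append(
                RegionDefinition(region_id, chrom, start, end, vclass, flank)
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate region_id")
    return regions


def read_probe_map(path: str | Path) -> ProbeMap:
    """Read a TSV probe map with columns chrom, position, probe_id."""
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns")
        try:
            rows.append((fields[0], int(fields[1]), fields[2]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad position: {exc}") from exc
    return ProbeMap.from_records(rows)


def read_segment_calls(path: str | Path) -> list[SegmentCall]:
    """Read segment calls: TSV sample_id, chrom, start, end, cn_state,
    n_probes (the tabular dialect of common CNV callers)."""
    calls = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: expected 6 columns")
        try:
            calls.append(
                SegmentCall(
                    sample_id=fields[0],
                    chrom=fields[1],
                    start=int(fields[2]),
                    end=int(fields[3]),
                    cn_state=int(fields[4]),
                    n_probes=int(fields[5]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return calls


def read_phenotypes(path: str | Path) -> list[SampleRecord]:
    """Read phenotypes: TSV sample_id, cohort, group, sex, age, bmi,
    excluded, exclusion_reason ('.' or empty for missing values)."""
    records = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 7:
            raise ParseError(f"{path}:{lineno}: expected >=7 columns")
        def _opt_float(s: str) -> float | None:
            s = s.strip()
            return None if s in ("", ".", "NA", "nan") else float(s)
        try:
            records.append(
                SampleRecord(
                    sample_id=fields[0],
                    cohort=fields[1],
                    group=fields[2],
                    sex=fields[3],
                    age=_opt_float(fields[4]),
                    bmi=_opt_float(fields[5]),
                    excluded=fields[6].strip().lower() in ("1", "true", "yes"),
                    exclusion_reason=fields[7] if len(fields) > 7 else "",
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def check_samples_known(
    calls: Sequence[SegmentCall], phenotypes: Sequence[SampleRecord]
) -> None:
    """Raise if a segment call references a sample absent from phenotypes."""
    known = {s.sample_id for s in phenotypes}
    orphans = sorted({c.sample_id for c in calls} - known)
    if orphans:
        raise ValueError(
            f"segment calls reference unknown samples: {orphans[:10]}"
            + ("..." if len(orphans) > 10 else "")
        )


# ---------------------------------------------------------------------------
# Writers (round-trip partners of the readers above)
# ---------------------------------------------------------------------------


def write_regions(regions: Sequence[RegionDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tregion_id\tvariant_class\tflank_bp\n")
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t"
                f"{r.variant_class}\t{r.flank_bp}\n"
            )


def write_probe_map(probe_map: ProbeMap, path: str | Path) -> None:
    probe_map.frame.to_csv(path, sep="\t", header=False, index=False)


def write_segment_calls(calls: Sequence[SegmentCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.chrom}\t{c.start}\t{c.end}\t"
                f"{c.cn_state}\t{c.n_probes}\n"
            )


def write_phenotypes(records: Sequence[SampleRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in records:
            age = "." if s.age is None else f"{s.age:g}"
            bmi = "." if s.bmi is None else f"{s.bmi:.6g}"
            fh.write(
                f"{s.sample_id}\t{s.cohort}\t{s.group}\t{s.sex}\t{age}\t"
                f"{bmi}\t{int(s.excluded)}\t{s.exclusion_reason}\n"
            )


def write_association_table(
    results: pd.DataFrame, path: str | Path, json_path: str | Path | None = None
) -> None:
    """Write per-region association results as TSV, optionally with a JSON
    sidecar carrying the full records."""
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(results.to_dict(orient="records"), fh, indent=1)
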