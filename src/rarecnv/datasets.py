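"""Bundled reference count tables for the worked examples and desk checks.

Two small datasets compiled from published obesity CNV replication work:

* :func:`candidate_region_counts` — 18 candidate obesity CNV loci (hg18)
  with their expected variant class, array probe coverage, and qualified
  carrier counts in seven cohort strata (child obesity case-control,
  adult obesity case-control, and a population cohort split by weight
  class);
* :func:`deletion_220kb_cohorts` — per-cohort carrier counts for the
  220 kb deletion at chr16p11.2 (28.73-28.95 Mb, spanning SH2B1) across
  child-obesity, adult-obesity and general-population cohorts, including
  previously published counts.

These are plain input tables: every statistic quoted in the documentation
is recomputed from them at run time.
"""

from __future__ import annotations

import pandas as pd

from .association import CohortPooling
from .io import RegionDefinition

#: sample counts for the seven strata of the candidate-region table
STRATUM_SIZES = {
    "child_nonobese": 557,
    "child_obese": 645,
    "adult_nonobese": 843,
    "adult_obese": 701,
    "pop_normal": 3126,
    "pop_overweight": 1617,
    "pop_obese": 470,
}

# chrom, start, end, class, probes on array, then carrier counts per stratum
_REGION_ROWS = [
    ("chr3", 89250592, 89319536, "gain", 3, 0, 0, 0, 0, 1, 0, 1),
    ("chr6", 52875284, 52892054, "loss", 0, 0, 0, 0, 0, 0, 0, 0),
    ("chr8", 143268033, 143634461, "gain", 68, 0, 0, 1, 0, 1, 2, 0),
    ("chr10", 541873, 818440, "gain", 42, 0, 0, 0, 0, 0, 0, 0),
    ("chr11", 72013333, 72089312, "gain", 11, 0, 1, 3, 0, 1, 0, 0),
    ("chr11", 105716030, 106419349, "loss", 113, 0, 0, 0, 0, 0, 0, 0),
    ("chr15", 28700879, 30231488, "gain", 207, 0, 0, 0, 0, 0, 0, 0),
    ("chr16", 28731428, 28951376, "loss", 28, 0, 5, 0, 0, 0, 3, 1),
    ("chr17", 2224814, 2256880, "gain", 6, 0, 0, 0, 0, 0, 0, 0),
    ("chr22", 49246176, 49313898, "gain", 11, 0, 0, 0, 0, 1, 0, 0),
    ("chr3", 104059109, 104092618, "loss", 2, 3, 0, 0, 0, 1, 1, 0),
    ("chr5", 53467427, 53480255, "gain", 2, 0, 0, 0, 0, 0, 0, 0),
    ("chr5", 77039051, 77076628, "loss", 5, 1, 0, 0, 2, 1, 2, 0),
    ("chr5", 83835179, 83874339, "loss", 3, 1, 0, 0, 1, 0, 0, 0),
    ("chr7", 20708193, 20711088, "loss", 2, 1, 1, 2, 0, 16, 7, 4),
    ("chr7", 113843696, 113859679, "loss", 1, 0, 0, 0, 1, 8, 2, 0),
    ("chr17", 49444406, 49449022, "gain", 1, 0, 0, 0, 0, 3, 3, 2),
    ("chr19", 10489548, 10512171, "loss", 4, 0, 0, 0, 0, 0, 0, 0),
]


def candidate_region_counts() -> pd.DataFrame:
    """The 18 candidate loci with probe coverage and qualified carrier
    counts per cohort stratum, indexed by region id ``{chrom}_{start}``."""
    cols = ["chrom", "start", "end", "variant_class", "probes_on_array",
            *STRATUM_SIZES]
    df = pd.DataFrame(_REGION_ROWS, columns=cols)
    df.index = df["chrom"] + "_" + df["start"].astype(str)
    df.index.name = "region_id"
    return df


def candidate_regions(flank_bp: int = 500_000) -> list[RegionDefinition]:
    """The 18 candidate loci as :class:`RegionDefinition` objects."""
    df = candidate_region_counts()
    return [
        RegionDefinition(rid, row["chrom"], int(row["start"]),
                         int(row["end"]), row["variant_class"], flank_bp)
        for rid, row in df.iterrows()
    ]


def case_control_carrier_table(region_id: str) -> tuple[int, int, int, int]:
    """Pooled obese vs non-obese carriers/totals for a candidate region,
    combining case-control and population strata and excluding overweight
    samples: (carriers_obese, n_obese, carriers_nonobese, n_nonobese)."""
    df = candidate_region_counts()
    row = df.loc[region_id]
    obese = ["child_obese", "adult_obese", "pop_obese"]
    lean = ["child_nonobese", "adult_nonobese", "pop_normal"]
    return (
        int(row[obese].sum()), sum(STRATUM_SIZES[s] for s in obese),
        int(row[lean].sum()), sum(STRATUM_SIZES[s] for s in lean),
    )


_DELETION_ROWS = [
    # cohort, class, source, carriers, total
    ("child_obesity_france", "child", "this_study", 5, 645),
    ("severe_early_onset_obesity_uk", "child", "published", 3, 278),
    ("goos_uk", "child", "published", 2, 1062),
    ("adult_obesity_france", "adult", "this_study", 0, 701),
    ("bariatric_surgery_france", "adult", "this_study", 0, 139),
    ("nfbc1966_finland", "population", "this_study", 4, 5213),
    ("egcut_estonia", "population", "this_study", 0, 2665),
    ("colaus_switzerland", "population", "this_study", 1, 5612),
    ("decode_iceland", "population", "this_study", 6, 36583),
    ("ship_germany", "population", "this_study", 0, 4068),
    ("wtccc2_gain_uk_us", "population", "published", 2, 7362),
    ("isc_parc_ninds_hgdp_chop", "population", "published", 1, 7700),
]


def deletion_220kb_cohorts() -> pd.DataFrame:
    """Carrier counts for the chr16p11.2 220 kb deletion, by cohort."""
    df = pd.DataFrame(
        _DELETION_ROWS,
        columns=["cohort", "class", "source", "carriers", "total"],
    ).set_index("cohort")
    return df


_POP_THIS_STUDY = ("nfbc1966_finland", "egcut_estonia", "colaus_switzerland",
                   "decode_iceland", "ship_germany")
_POP_ALL = _POP_THIS_STUDY + ("wtccc2_gain_uk_us", "isc_parc_ninds_hgdp_chop")
_CHILD_ALL = ("child_obesity_france", "severe_early_onset_obesity_uk",
              "goos_uk")

#: the standard pooled comparisons for the 220 kb deletion
DELETION_POOLINGS = {
    "child_france_vs_population": CohortPooling(
        "child_france_vs_population",
        ("child_obesity_france",), _POP_THIS_STUDY),
    "child_total_vs_population_total": CohortPooling(
        "child_total_vs_population_total", _CHILD_ALL, _POP_ALL),
    "child_france_vs_nfbc1966": CohortPooling(
        "child_france_vs_nfbc1966",
        ("child_obesity_france",), ("nfbc1966_finland",)),
    "child_total_vs_adult_total": CohortPooling(
        "child_total_vs_adult_total", _CHILD_ALL,
        ("adult_obesity_france", "bariatric_surgery_france")),
}
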