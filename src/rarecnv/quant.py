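"""Quantitative-trait association of carrier status with BMI.

Population-cohort analyses for rare CNV carriers: two-way ANOVA on
log10(BMI) with sex fitted first (sequential sums of squares, the ``aov``
idiom), Welch t-tests of carrier means, cohort-standardized Z-score
analysis for carriers pooled across cohorts, and subgroup contrasts for
loci where overlapping variants of different extents may have different
effects.

Effect sizes are back-transformed to kg/m^2 as differences of geometric
means; the carrier-vs-rest confidence interval is the Welch interval on
the log10 scale, applied multiplicatively to the non-carrier geometric
mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


@dataclass(frozen=True)
class QuantTraitResult:
    region_id: str
    f_stat: float
    p_value: float
    n_carriers: int
    mean_bmi_change: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class MeanDiffResult:
    diff: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: float
    p_value: float
    tail: str


@dataclass(frozen=True)
class ZScoreAnalysis:
    z_scores: np.ndarray
    mean_z: float
    ci_low: float
    ci_high: float
    p_one_tailed: float
    n: int
    ci_method: str


def _welch(x: np.ndarray, y: np.ndarray, tail: str, alpha: float = 0.05):
    """Welch statistic, Welch-Satterthwaite df, CI for mean(x) - mean(y)."""
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    se = np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    diff = x.mean() - y.mean()
    t = diff / se
    if tail == "one":
        p = float(stats.t.sf(t, df))
    else:
        p = float(2 * stats.t.sf(abs(t), df))
    tcrit = stats.t.isf(alpha / 2, df)
    return diff, diff - tcrit * se, diff + tcrit * se, t, df, p


def bmi_effect_backtransform(
    log10_carrier: np.ndarray, log10_rest: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Carrier-vs-rest BMI change in kg/m^2 from log10 values.

    The point estimate is the difference of geometric means; the interval
    applies the Welch CI of the log10 difference multiplicatively to the
    non-carrier geometric mean.
    """
    diff, lo, hi, *_ = _welch(log10_carrier, log10_rest, "two", alpha)
    gm_rest = 10 ** log10_rest.mean()
    return (
        gm_rest * (10**diff - 1),
        gm_rest * (10**lo - 1),
        gm_rest * (10**hi - 1),
    )


def anova_carrier_bmi(
    data: pd.DataFrame,
    regions: Sequence[str],
    min_carriers: int = 3,
    joint: bool = False,
    ss_type: int = 1,
) -> list[QuantTraitResult]:
    """Two-way ANOVA of log10(BMI) on sex and carrier status.

    ``data`` needs columns ``log10_bmi``, ``sex``, and a 0/1 carrier
    indicator column per region.  Sex is fitted first; with sequential
    (type I) sums of squares the carrier factor is therefore tested after
    removing the sex effect.  Regions with fewer than ``min_carriers``
    carriers are skipped.  ``joint=True`` fits all carrier indicators in
    one model (for samples carrying several variants).
    """
    if data["log10_bmi"].nunique() <= 1:
        raise ValueError("zero variance in response")
    tested = [r for r in regions if int(data[r].sum()) >= min_carriers]
    results: list[QuantTraitResult] = []
    if joint:
        if not tested:
            return []
        terms = " + ".join(tested)
        model = smf.ols(f"log10_bmi ~ C(sex) + {terms}", data=data).fit()
        table = sm.stats.anova_lm(model, typ=ss_type)
        for rid in tested:
            results.append(_quant_result(data, rid, table.loc[rid]))
        return results
    for rid in tested:
        model = smf.ols(f"log10_bmi ~ C(sex) + {rid}", data=data).fit()
        table = sm.stats.anova_lm(model, typ=ss_type)
        results.append(_quant_result(data, rid, table.loc[rid]))
    return results


def _quant_result(data: pd.DataFrame, rid: str, row: pd.Series) -> QuantTraitResult:
    carrier = data[data[rid] == 1]["log10_bmi"].to_numpy()
    rest = data[data[rid] == 0]["log10_bmi"].to_numpy()
    change, lo, hi = bmi_effect_backtransform(carrier, rest)
    return QuantTraitResult(
        region_id=rid,
        f_stat=float(row["F"]),
        p_value=float(row["PR(>F)"]),
        n_carriers=int(len(carrier)),
        mean_bmi_change=change,
        ci_low=lo,
        ci_high=hi,
    )


def carrier_mean_test(
    carrier_bmis: Sequence[float],
    cohort_bmis: Sequence[float],
    tail: str = "one",
    alpha: float = 0.05,
) -> MeanDiffResult:
    """Heteroscedastic (Welch) t-test of carrier mean BMI against the rest
    of the cohort; one-tailed tests for carrier mean above the cohort."""
    x = np.asarray(carrier_bmis, dtype=float)
    y = np.asarray(cohort_bmis, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 carriers for a t-test")
    diff, lo, hi, t, df, p = _welch(x, y, tail, alpha)
    return MeanDiffResult(float(diff), float(lo), float(hi), float(t),
                          float(df), p, tail)


def zscore_test(
    carriers: pd.DataFrame,
    cohort_stats: pd.DataFrame,
    ci_method: str = "observed_sd",
    alpha: float = 0.05,
) -> ZScoreAnalysis:
    """Z-score analysis for carriers pooled across cohorts.

    Each carrier's BMI is standardized against its own cohort
    (``cohort_stats``: index cohort, columns ``mean``/``sd``).  The
    one-tailed P tests mean Z > 0 against the standard-normal null,
    P = Phi_bar(mean_z * sqrt(n)).  The CI on mean Z uses the observed
    SD of the carrier Z's by default (``ci_method="unit_null"`` uses the
    unit-variance null SE instead).
    """
    z = (
        (carriers["bmi"] - carriers["cohort"].map(cohort_stats["mean"]))
        / carriers["cohort"].map(cohort_stats["sd"])
    ).to_numpy(dtype=float)
    n = len(z)
    if n == 0:
        raise ValueError("no carriers")
    mean_z = float(z.mean())
    p = float(stats.norm.sf(mean_z * np.sqrt(n)))
    zcrit = stats.norm.isf(alpha / 2)
    if ci_method == "observed_sd" and n > 1:
        se = z.std(ddof=1) / np.sqrt(n)
    else:
        ci_method = "unit_null"
        se = 1.0 / np.sqrt(n)
    return ZScoreAnalysis(z, mean_z, mean_z - zcrit * se, mean_z + zcrit * se,
                          p, n, ci_method)


def gender_corrected_bmi(data: pd.DataFrame, method: str = "residual") -> pd.Series:
    """Sex-corrected BMI for the alternative t-test route.

    ``"residual"``: residuals of log10(BMI) on sex, re-centred on the
    overall geometric mean.  ``"stratified_z"``: within-sex Z-scores of
    log10(BMI).
    """
    log_bmi = np.log10(data["bmi"])
    if method == "residual":
        mean_by_sex = log_bmi.groupby(data["sex"]).transform("mean")
        return 10 ** (log_bmi - mean_by_sex + log_bmi.mean())
    if method == "stratified_z":
        mean_by_sex = log_bmi.groupby(data["sex"]).transform("mean")
        sd_by_sex = log_bmi.groupby(data["sex"]).transform(lambda s: s.std(ddof=1))
        return (log_bmi - mean_by_sex) / sd_by_sex
    raise ValueError("method must be 'residual' or 'stratified_z'")


@dataclass(frozen=True)
class SubgroupContrast:
    mean_change_a: float
    mean_change_b: float
    p_a_vs_population: float
    p_b_vs_population: float
    p_between: float
    n_a: int
    n_b: int


def _vs_population(sub: np.ndarray, population: np.ndarray, tail: str) -> float:
    """Subgroup vs population, one-tailed toward the subgroup lying BELOW
    the population mean; a single observation falls back to a Z test
    against the population SD."""
    if len(sub) >= 2:
        return _welch(population, sub, tail)[5]
    z = (sub[0] - population.mean()) / population.std(ddof=1)
    return float(stats.norm.cdf(z) if tail == "one" else 2 * stats.norm.sf(abs(z)))


def subgroup_contrast(
    bmis_a: Sequence[float],
    bmis_b: Sequence[float],
    population_bmis: Sequence[float],
    tail: str = "one",
) -> SubgroupContrast:
    """Contrast two carrier subgroups (e.g. large vs small deletions at one
    locus) against each other and against the population.

    Subgroup A is the one hypothesized to have REDUCED values: one-tailed
    tests point toward A below B and each subgroup below the population
    (pass reversed arguments for the opposite direction).
    """
    a = np.asarray(bmis_a, dtype=float)
    b = np.asarray(bmis_b, dtype=float)
    pop = np.asarray(population_bmis, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty subgroup")
    # tests mean(b) > mean(a); a singleton on either side degenerates the
    # Welch test and falls back to a Z against the other subgroup's spread
    if len(a) >= 2 and len(b) >= 2:
        p_between = _welch(b, a, tail)[5]
    elif len(a) >= 2:
        z = (b[0] - a.mean()) / a.std(ddof=1)
        p_between = float(stats.norm.sf(z) if tail == "one"
                          else 2 * stats.norm.sf(abs(z)))
    elif len(b) >= 2:
        z = (b.mean() - a[0]) / b.std(ddof=1)
        p_between = float(stats.norm.sf(z) if tail == "one"
                          else 2 * stats.norm.sf(abs(z)))
    else:
        p_between = float("nan")
    return SubgroupContrast(
        mean_change_a=float(a.mean() - pop.mean()),
        mean_change_b=float(b.mean() - pop.mean()),
        p_a_vs_population=_vs_population(a, pop, tail),
        p_b_vs_population=_vs_population(b, pop, tail),
        p_between=p_between,
        n_a=len(a),
        n_b=len(b),
    )
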