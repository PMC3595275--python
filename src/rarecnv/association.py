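"""Rare-carrier case-control statistics.

Exact tests on 2x2 carrier tables, odds ratios with two flavours of
confidence interval, binomial carrier-frequency estimates, pooled-cohort
comparisons, and multiple-testing adjustment.

Conventions
-----------
* The two-sided Fisher P-value follows the minimum-likelihood rule (the sum
  over all tables with fixed margins whose point probability does not
  exceed the observed table's) — the convention of R's ``fisher.test``.
* The one-sided P is the upper hypergeometric tail toward carrier
  enrichment in group 1.
* The "sample" odds ratio is the cross-product ratio ad/bc with a Woolf
  log-scale interval; the "exact" odds ratio is the conditional maximum
  likelihood estimate with an exact conditional (Cornfield-type) interval.
* Proportion intervals default to the Wald normal approximation, with
  Clopper-Pearson available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .qualify import STATUS_CARRIER, STATUS_RECIPROCAL, CarrierMatrix


@dataclass(frozen=True)
class TwoByTwo:
    """Carrier table: a/b carriers/non-carriers in group 1, c/d in group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @classmethod
    def from_group_sizes(cls, carriers1: int, n1: int, carriers2: int, n2: int) -> "TwoByTwo":
        return cls(carriers1, n1 - carriers1, carriers2, n2 - carriers2)

    @property
    def n1(self) -> int:
        return self.a + self.b

    @property
    def n2(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_p(table: TwoByTwo, tail: str = "two-sided") -> float:
    """Fisher exact P-value for a 2x2 table.

    ``tail="one-sided"`` tests enrichment of carriers in group 1 (upper
    hypergeometric tail); ``"two-sided"`` uses the minimum-likelihood rule.
    A table with an empty group carries no information; NaN is returned
    with a warning.  (A zero carrier column is fine and gives P = 1.)
    """
    if table.n1 == 0 or table.n2 == 0:
        warnings.warn("empty margin: Fisher P undefined", stacklevel=2)
        return float("nan")
    if tail == "two-sided":
        return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])
    if tail == "one-sided":
        return float(stats.fisher_exact(table.as_array(), alternative="greater")[1])
    raise ValueError("tail must be 'two-sided' or 'one-sided'")


@dataclass(frozen=True)
class OddsRatioResult:
    estimate: float
    ci_low: float
    ci_high: float
    method: str
    zero_cell: bool = False


def sample_odds_ratio(table: TwoByTwo, alpha: float = 0.05,
                      haldane: bool = False) -> OddsRatioResult:
    """Cross-product odds ratio ad/bc with Woolf log-scale CI.

    A zero cell makes the plain estimate 0 or infinite; pass
    ``haldane=True`` for the +0.5 Haldane-Anscombe correction.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    zero = min(a, b, c, d) == 0
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        zero = False
    if zero:
        if b == 0 or c == 0:
            est = float("inf") if (a > 0 or d > 0) else float("nan")
        else:
            est = 0.0
        return OddsRatioResult(est, float("nan"), float("nan"),
                               "sample", zero_cell=True)
    est = (a * d) / (b * c)
    z = stats.norm.isf(alpha / 2)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(est) - z * se), np.exp(np.log(est) + z * se)
    return OddsRatioResult(float(est), float(lo), float(hi),
                           "sample_haldane" if haldane else "sample")


def exact_odds_ratio(table: TwoByTwo, alpha: float = 0.05) -> OddsRatioResult:
    """Conditional maximum-likelihood odds ratio with the exact conditional
    (Cornfield-type) interval obtained from noncentral hypergeometric
    tails."""
    res = _scipy_odds_ratio(table.as_array(), kind="conditional")
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return OddsRatioResult(float(res.statistic), float(ci.low),
                           float(ci.high), "exact_conditional")


def odds_ratio(table: TwoByTwo, method: str = "sample",
               alpha: float = 0.05, haldane: bool = False) -> OddsRatioResult:
    if method == "sample":
        return sample_odds_ratio(table, alpha=alpha, haldane=haldane)
    if method == "exact":
        return exact_odds_ratio(table, alpha=alpha)
    raise ValueError("method must be 'sample' or 'exact'")


@dataclass(frozen=True)
class FrequencyEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    x: int
    n: int
    method: str


def carrier_frequency(x: int, n: int, alpha: float = 0.05,
                      method: str = "wald") -> FrequencyEstimate:
    """Binomial carrier-frequency estimate x/n with 95% CI.

    Default Wald interval p +- z*sqrt(p(1-p)/n), truncated to [0, 1];
    ``method="clopper-pearson"`` gives the exact interval.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("x must be in [0, n]")
    sm_method = {"wald": "normal", "clopper-pearson": "beta"}[method]
    lo, hi = proportion_confint(x, n, alpha=alpha, method=sm_method)
    return FrequencyEstimate(x / n, max(0.0, float(lo)), min(1.0, float(hi)),
                             x, n, method)


@dataclass(frozen=True)
class AssociationResult:
    table: TwoByTwo
    p_two_sided: float
    p_one_sided: float
    or_sample: OddsRatioResult
    or_exact: OddsRatioResult
    freq_group1: FrequencyEstimate
    freq_group2: FrequencyEstimate
    label: str = ""


def associate(table: TwoByTwo, label: str = "") -> AssociationResult:
    """Full association summary for a carrier table."""
    return AssociationResult(
        table=table,
        p_two_sided=fisher_p(table, "two-sided"),
        p_one_sided=fisher_p(table, "one-sided"),
        or_sample=sample_odds_ratio(table),
        or_exact=exact_odds_ratio(table),
        freq_group1=carrier_frequency(table.a, table.n1),
        freq_group2=carrier_frequency(table.c, table.n2),
        label=label,
    )


@dataclass(frozen=True)
class CohortPooling:
    """A named 2x2 comparison pooling cohorts on each side.

    ``side1``/``side2`` list cohort labels; a cohort may appear on at most
    one side.
    """

    name: str
    side1: tuple[str, ...]
    side2: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.side1) & set(self.side2)
        if overlap:
            raise ValueError(f"pooling {self.name}: cohorts on both sides: {sorted(overlap)}")


def pool_and_test(counts: pd.DataFrame, pooling: CohortPooling) -> AssociationResult:
    """Pool per-cohort carrier counts into a 2x2 comparison and test.

    ``counts`` must be indexed by cohort label with integer columns
    ``carriers`` and ``total``.
    """
    unknown = (set(pooling.side1) | set(pooling.side2)) - set(counts.index)
    if unknown:
        raise ValueError(f"pooling {pooling.name}: unknown cohorts {sorted(unknown)}")
    s1 = counts.loc[list(pooling.side1)]
    s2 = counts.loc[list(pooling.side2)]
    table = TwoByTwo.from_group_sizes(
        int(s1["carriers"].sum()), int(s1["total"].sum()),
        int(s2["carriers"].sum()), int(s2["total"].sum()),
    )
    return associate(table, label=pooling.name)


def case_control_table(matrix: CarrierMatrix, region_id: str) -> TwoByTwo:
    """Obese-vs-non-obese carrier table from a carrier matrix, excluding
    overweight samples (intermediate phenotype) from both sides."""
    pheno = matrix._counted()
    statuses = matrix.statuses.loc[pheno.index, region_id]
    obese = pheno["weight_class"] == "obese"
    lean = pheno["weight_class"] == "normal"
    return TwoByTwo.from_group_sizes(
        int(((statuses == STATUS_CARRIER) & obese).sum()), int(obese.sum()),
        int(((statuses == STATUS_CARRIER) & lean).sum()), int(lean.sum()),
    )


def reciprocal_frequency_table(matrix: CarrierMatrix) -> pd.DataFrame:
    """Per-region, per-cohort counts of expected-class carriers and
    reciprocal carriers (tabulation only; no test)."""
    pheno = matrix._counted()
    rows = []
    for region_id in matrix.statuses.columns:
        col = matrix.statuses.loc[pheno.index, region_id]
        for cohort, idx in pheno.groupby("cohort").groups.items():
            sub = col.loc[idx]
            rows.append({
                "region_id": region_id,
                "cohort": cohort,
                "n": len(sub),
                "carriers": int((sub == STATUS_CARRIER).sum()),
                "reciprocal_carriers": int((sub == STATUS_RECIPROCAL).sum()),
            })
    return pd.DataFrame(rows)


def adjust_pvalues(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: ``"bonferroni"`` or ``"bh"``
    (Benjamini-Hochberg step-up); adjusted values are capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(p, method=key)[1]
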