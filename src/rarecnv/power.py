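"""Exact unconditional power of the Fisher exact test for rare carriers.

Carrier counts in cases and controls are modelled as independent binomials
(dominant coding: one event makes a carrier).  Power at level ``alpha`` is
the joint probability, over both binomials, that the conditional Fisher
test on the realized 2x2 table rejects.  The double sum is truncated where
the binomial tail mass falls below ``truncation_eps``; the discarded mass
is reported as a rigorous bound on the absolute error of the result.

The effect size may be given as an odds ratio on the carrier odds scale,
from which the control-group frequency is derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def control_freq_from_or(p_case: float, odds_ratio: float) -> float:
    """Control carrier frequency implied by the case frequency and an odds
    ratio: odds_control = odds_case / OR."""
    if not 0 < p_case < 1:
        raise ValueError("p_case must be in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    odds = (p_case / (1 - p_case)) / odds_ratio
    return odds / (1 + odds)


@dataclass(frozen=True)
class PowerSpec:
    """Design for an exact-power computation.

    Exactly one of ``odds_ratio`` and ``p_control`` must be given.
    ``tail`` is ``"one"`` (enrichment in cases; the default, matching
    post-hoc power conventions for rare risk variants) or ``"two"``.
    """

    n_cases: int
    n_controls: int
    p_case: float
    odds_ratio: float | None = None
    p_control: float | None = None
    alpha: float = 0.05
    tail: str = "one"
    truncation_eps: float = 1e-12

    def __post_init__(self) -> None:
        if (self.odds_ratio is None) == (self.p_control is None):
            raise ValueError("give exactly one of odds_ratio / p_control")
        if not 0 < self.p_case < 1:
            raise ValueError("p_case must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.tail not in ("one", "two"):
            raise ValueError("tail must be 'one' or 'two'")
        if min(self.n_cases, self.n_controls) < 1:
            raise ValueError("group sizes must be positive")

    def resolved_p_control(self) -> float:
        if self.p_control is not None:
            return self.p_control
        return control_freq_from_or(self.p_case, self.odds_ratio)


@dataclass(frozen=True)
class PowerResult:
    power: float
    error_bound: float
    n_case_support: int
    n_control_support: int
    spec: PowerSpec


def _support(n: int, p: float, eps: float) -> tuple[np.ndarray, np.ndarray]:
    """Carrier-count support carrying all but ~eps binomial tail mass."""
    dist = stats.binom(n, p)
    lo = int(dist.ppf(eps / 2))
    hi = int(dist.isf(eps / 2))
    x = np.arange(lo, hi + 1)
    return x, dist.pmf(x)


def fisher_exact_power(spec: PowerSpec) -> PowerResult:
    """Exact unconditional power by binomial enumeration.

    For each realized pair of carrier counts the conditional Fisher P-value
    is computed from the hypergeometric distribution on the pooled carrier
    margin and compared against ``alpha``; significant outcomes are
    weighted by their joint binomial probability.
    """
    p2 = spec.resolved_p_control()
    x1, w1 = _support(spec.n_cases, spec.p_case, spec.truncation_eps)
    x2, w2 = _support(spec.n_controls, p2, spec.truncation_eps)
    n1, n2 = spec.n_cases, spec.n_controls
    total = n1 + n2
    power = 0.0
    if spec.tail == "one":
        for a, wa in zip(x1, w1):
            # one-tailed P toward case enrichment: P(X >= a | margins)
            p_vals = stats.hypergeom.sf(a - 1, total, a + x2, n1)
            power += wa * float(w2[p_vals <= spec.alpha].sum())
    else:
        for a, wa in zip(x1, w1):
            for c, wc in zip(x2, w2):
                tab = np.array([[a, n1 - a], [c, n2 - c]])
                if stats.fisher_exact(tab)[1] <= spec.alpha:
                    power += wa * wc
    bound = float(1.0 - w1.sum() * w2.sum())
    if bound > 1e-6:
        warnings.warn(
            f"truncation error bound {bound:.2e} exceeds 1e-6", stacklevel=2
        )
    return PowerResult(float(power), bound, x1.size, x2.size, spec)


def power_table(specs: Iterable[PowerSpec]) -> pd.DataFrame:
    """Exact power for a list of designs, one row per design."""
    rows = []
    for spec in specs:
        res = fisher_exact_power(spec)
        rows.append({
            "n_cases": spec.n_cases,
            "n_controls": spec.n_controls,
            "p_case": spec.p_case,
            "odds_ratio": spec.odds_ratio,
            "p_control": spec.resolved_p_control(),
            "alpha": spec.alpha,
            "tail": spec.tail,
            "power": res.power,
            "error_bound": res.error_bound,
        })
    return pd.DataFrame(rows)


def summarize(powers: Sequence[float]) -> dict[str, float]:
    """Median and minimum power across designs (order-invariant)."""
    arr = np.asarray(list(powers), dtype=float)
    if arr.size == 0:
        raise ValueError("no powers to summarize")
    return {"median": float(np.median(arr)), "min": float(arr.min())}


def sample_size_for_power(
    target_power: float,
    p_case: float,
    odds_ratio: float,
    control_ratio: float = 1.0,
    alpha: float = 0.05,
    tail: str = "one",
    n_max: int = 200_000,
) -> int:
    """Smallest case-group size reaching ``target_power`` (controls scaled
    by ``control_ratio``), found by bisection over the exact power."""

    def _power(n: int) -> float:
        spec = PowerSpec(
            n_cases=n, n_controls=max(1, int(round(n * control_ratio))),
            p_case=p_case, odds_ratio=odds_ratio, alpha=alpha, tail=tail,
        )
        return fisher_exact_power(spec).power

    lo, hi = 1, n_max
    if _power(hi) < target_power:
        raise ValueError(f"target power unreachable below n_cases={n_max}")
    while lo < hi:
        mid = (lo + hi) // 2
        if _power(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo
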