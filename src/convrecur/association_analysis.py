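"""Behaviour-engagement association statistics.

For every communication behaviour and every engagement dimension (direction x
range) a 2x2 contingency table is formed over all carer turns:

    a = engaged & behaviour present     b = not engaged & present
    c = engaged & behaviour absent      d = not engaged & absent

The association is summarised by the odds ratio OR = (a/b)/(c/d) = ad/(bc)
with a 95% Wald confidence interval

    exp( ln OR  +/-  z_{.975} * sqrt(1/a + 1/b + 1/c + 1/d) )

and the Wald p-value of ln OR.  A univariate logistic regression of the
binary outcome on behaviour presence yields the identical exponentiated
coefficient whenever all four cells are positive (the model is saturated);
the logistic route is the default for table construction and is
cross-checked against the closed form.  Behaviours occurring on fewer than a
configurable fraction of carer turns (default 1%, by ceiling) are excluded.

Turns are pooled across conversations; conversation-level clustering is
deliberately not modelled (a known limitation of the per-turn design).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engagement_labels import DIRECTIONS, RANGES, TurnRecord

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "behaviour_frequencies",
    "eligible_behaviours",
    "eligibility_threshold",
    "contingency",
    "odds_ratio",
    "logistic_association",
    "results_table",
    "significance_stars",
]

Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-tabulation of behaviour presence against engagement."""

    a: int  # engaged, behaviour present
    b: int  # not engaged, behaviour present
    c: int  # engaged, behaviour absent
    d: int  # not engaged, behaviour absent

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_present(self) -> int:
        return self.a + self.b

    def cells(self) -> tuple[int, int, int, int]:
        return self.a, self.b, self.c, self.d


@dataclass(frozen=True)
class AssociationResult:
    """One behaviour-by-dimension association summary (a results-table row)."""

    behaviour: str
    direction: str
    range: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    probability_present: float  # a / (a+b), as a percentage
    table: ContingencyTable
    method: str  # "closed_form" | "logistic"
    separation: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Footnote stars: * p<.05, ** p<.01, *** p<.005."""
    if not math.isfinite(p):
        return ""
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def behaviour_frequencies(records: Sequence[TurnRecord]) -> pd.DataFrame:
    """Count behaviour-code use across carer turns.

    Returns a frame indexed by code with ``count`` (turns carrying the code),
    ``pct_turns`` (percentage of all carer turns — the headline frequency)
    and ``pct_codes`` (share of all code occurrences), sorted by count
    descending.
    """
    counts: dict[str, int] = {}
    for r in records:
        for code in r.behaviour_codes:
            counts[code] = counts.get(code, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["count", "pct_turns", "pct_codes"])
    n_turns = len(records)
    total_occurrences = sum(counts.values())
    frame = pd.DataFrame(
        {
            "count": pd.Series(counts),
        }
    ).sort_values("count", ascending=False, kind="stable")
    frame["pct_turns"] = 100.0 * frame["count"] / n_turns
    frame["pct_codes"] = 100.0 * frame["count"] / total_occurrences
    return frame


def eligibility_threshold(n_records: int, min_fraction: float = 0.01) -> int:
    """Minimum turn count for a behaviour to enter the analysis (ceiling rule)."""
    return math.ceil(min_fraction * n_records)


def eligible_behaviours(
    records: Sequence[TurnRecord], min_fraction: float = 0.01
) -> list[str]:
    """Behaviours used on at least ``ceil(min_fraction * n_carer_turns)`` turns,
    ordered by frequency descending."""
    freq = behaviour_frequencies(records)
    threshold = eligibility_threshold(len(records), min_fraction)
    return [code for code, row in freq.iterrows() if row["count"] >= threshold]


def contingency(
    records: Sequence[TurnRecord], behaviour: str, direction: str, range_: str
) -> ContingencyTable:
    """Cross-tabulate behaviour presence against one engagement dimension."""
    if direction not in DIRECTIONS or range_ not in RANGES:
        raise ValueError(f"unknown engagement dimension {direction!r} x {range_!r}")
    observed = {code for r in records for code in r.behaviour_codes}
    if behaviour not in observed:
        raise KeyError(f"behaviour {behaviour!r} never occurs in these records")
    a = b = c = d = 0
    for r in records:
        engaged = r.labels.get(direction, range_)
        present = behaviour in r.behaviour_codes
        if present and engaged:
            a += 1
        elif present:
            b += 1
        elif engaged:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def _wald(t: ContingencyTable) -> tuple[float, float, float, float, bool]:
    """(OR, ci_low, ci_high, p, separation) by the closed form."""
    a, b, c, d = t.cells()
    if a == 0:
        # no engaged turn with the behaviour: the MLE of the OR is 0 and the
        # interval degenerates (printed as .000 (.000-.000))
        return 0.0, 0.0, 0.0, math.nan, True
    if b == 0 or c == 0:
        return math.inf, math.inf, math.inf, math.nan, True
    if d == 0:
        return 0.0, 0.0, 0.0, math.nan, True
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return (
        math.exp(log_or),
        math.exp(log_or - Z975 * se),
        math.exp(log_or + Z975 * se),
        p,
        False,
    )


def odds_ratio(
    t: ContingencyTable,
    behaviour: str = "",
    direction: str = "forward",
    range_: str = "short",
) -> AssociationResult:
    """Closed-form odds ratio with 95% Wald interval and Wald p-value."""
    or_, lo, hi, p, sep = _wald(t)
    prob = 100.0 * t.a / t.n_present if t.n_present else math.nan
    return AssociationResult(
        behaviour=behaviour,
        direction=direction,
        range=range_,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        probability_present=prob,
        table=t,
        method="closed_form",
        separation=sep,
    )


def fit_logistic_2x2(t: ContingencyTable) -> tuple[float, float, float, float]:
    """Fit outcome ~ behaviour on an aggregated 2x2 via binomial GLM.

    Returns ``(exp(coef), ci_low, ci_high, p)`` for the behaviour coefficient.
    Raises :class:`ValueError` when a zero cell makes the MLE degenerate.
    """
    import warnings

    import statsmodels.api as sm

    a, b, c, d = t.cells()
    if min(a, b, c, d) == 0:
        raise ValueError("zero cell: logistic MLE does not exist (separation)")
    endog = np.array([[a, b], [c, d]], dtype=float)
    exog = np.array([[1.0, 1.0], [1.0, 0.0]])
    with warnings.catch_warnings():
        # the aggregated 2-row model is saturated by design (df_resid = 0)
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    coef = float(fit.params[1])
    lo, hi = (float(x) for x in fit.conf_int()[1])
    return math.exp(coef), math.exp(lo), math.exp(hi), float(fit.pvalues[1])


def logistic_association(
    records: Sequence[TurnRecord], behaviour: str, direction: str, range_: str
) -> AssociationResult:
    """Univariate logistic regression of one engagement dimension on one behaviour.

    With a single binary predictor the model is saturated, so the
    exponentiated coefficient equals the closed-form odds ratio whenever all
    cells are positive.  Under separation (a zero cell) the fit is degenerate
    and the result falls back to the closed-form cells with a separation flag.
    """
    t = contingency(records, behaviour, direction, range_)
    prob = 100.0 * t.a / t.n_present if t.n_present else math.nan
    try:
        or_, lo, hi, p = fit_logistic_2x2(t)
    except (ValueError, np.linalg.LinAlgError):
        base = odds_ratio(t, behaviour, direction, range_)
        return AssociationResult(
            behaviour=behaviour,
            direction=direction,
            range=range_,
            odds_ratio=base.odds_ratio,
            ci_low=base.ci_low,
            ci_high=base.ci_high,
            p_value=base.p_value,
            probability_present=prob,
            table=t,
            method="closed_form",
            separation=True,
        )
    return AssociationResult(
        behaviour=behaviour,
        direction=direction,
        range=range_,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        probability_present=prob,
        table=t,
        method="logistic",
        separation=False,
    )


def results_table(
    records: Sequence[TurnRecord],
    direction: str,
    min_fraction: float = 0.01,
    method: str = "logistic",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Assemble the full results table for one direction.

    One row per eligible behaviour x {short, medium, long}, behaviours in
    descending frequency order.  ``method`` selects the logistic fit (default)
    or the closed form; both agree on all-positive tables.  The analyses are
    separate per behaviour with no multiplicity correction, matching the
    per-turn design; ``bh_correction`` optionally appends a
    Benjamini-Hochberg adjusted column for users who want one.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    results: list[AssociationResult] = []
    for behaviour in eligible_behaviours(records, min_fraction):
        for range_ in RANGES:
            if method == "logistic":
                res = logistic_association(records, behaviour, direction, range_)
            else:
                res = odds_ratio(
                    contingency(records, behaviour, direction, range_),
                    behaviour,
                    direction,
                    range_,
                )
            results.append(res)

    frame = pd.DataFrame(
        {
            "behaviour": [r.behaviour for r in results],
            "range": [r.range for r in results],
            "p": [r.p_value for r in results],
            "OR": [r.odds_ratio for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "prob_present": [r.probability_present for r in results],
            "odds_present": [f"{r.table.a}/{r.table.b}" for r in results],
            "odds_absent": [f"{r.table.c}/{r.table.d}" for r in results],
            "stars": [r.stars for r in results],
            "method": [r.method for r in results],
            "separation": [r.separation for r in results],
        }
    )
    if bh_correction and len(frame):
        from statsmodels.stats.multitest import multipletests

        mask = frame["p"].notna()
        adjusted = pd.Series(math.nan, index=frame.index)
        if mask.any():
            adjusted.loc[mask] = multipletests(frame.loc[mask, "p"], method="fdr_bh")[1]
        frame["p_bh"] = adjusted
    return frame
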