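"""Univariable inference: exact contingency-table tests, rank tests,
one-covariate logistic and Cox fits, and Kaplan-Meier / log-rank comparison.

Conventions match the study's reporting: the two-sided Fisher p-value is the
point-probability (sum of all equally-or-less-probable tables) method,
Pearson chi-square carries no continuity correction, rank tests use
mid-ranks with exact enumeration for small untied samples and the
tie-corrected normal approximation otherwise, Cox fits use Efron tie
handling, and intervals are Wald.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact_two_sided",
    "chi_square_test",
    "rank_tests",
    "univariable_logistic",
    "univariable_cox",
    "km_logrank",
    "printed_ddr_tables",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = group (e.g. CB / NCB) and columns = event
    (altered / not altered): ``[[a, b], [c, d]]``."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell in contingency table: {cells}")
        if sum(cells) == 0:
            raise ValueError("all-zero contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test or one-covariate fit."""

    p_value: Optional[float]
    method: str
    statistic: Optional[float] = None
    estimate: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def fisher_exact_two_sided(t: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test by the point-probability method: the sum
    of hypergeometric probabilities of every margin-preserving table no more
    probable than the observed one. Estimate is the sample odds ratio."""
    oddsratio, p = sps.fisher_exact(t.as_array(), alternative="two-sided")
    return TestResult(
        p_value=float(min(p, 1.0)),
        statistic=None,
        estimate=float(oddsratio),
        method="fisher_exact_two_sided",
    )


def chi_square_test(table: Sequence[Sequence[int]]) -> TestResult:
    """Pearson chi-square on an r x c table, (r-1)(c-1) df, no continuity
    correction."""
    arr = np.asarray(table, dtype=float)
    if arr.sum() == 0:
        raise ValueError("chi-square test on an all-zero table")
    res = sps.chi2_contingency(arr, correction=False)
    return TestResult(
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        method=f"chi_square_df{res.dof}",
    )


def rank_tests(
    values: Sequence[float],
    groups: Sequence[object],
    kind: str = "mann_whitney",
) -> TestResult:
    """Two-sided Mann-Whitney U (two groups) or Kruskal-Wallis (>= 2 groups)
    on mid-ranked data.

    Mann-Whitney uses exact enumeration when both groups have <= 8
    untied observations, otherwise the tie-corrected normal approximation
    (no continuity correction, so symmetric data give p = 1)."""
    values = np.asarray(values, dtype=float)
    labels = pd.Series(list(groups))
    split = [values[(labels == g).to_numpy()] for g in labels.unique()]
    if any(len(s) == 0 for s in split):
        raise ValueError("every group must be non-empty")
    if kind == "mann_whitney":
        if len(split) != 2:
            raise ValueError(f"Mann-Whitney requires exactly 2 groups, got {len(split)}")
        x, y = split
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=False
        )
        return TestResult(
            p_value=float(min(res.pvalue, 1.0)),
            statistic=float(res.statistic),
            method=f"mann_whitney_{method}",
        )
    if kind == "kruskal_wallis":
        res = sps.kruskal(*split)
        return TestResult(
            p_value=float(res.pvalue), statistic=float(res.statistic), method="kruskal_wallis"
        )
    raise ValueError(f"kind must be 'mann_whitney' or 'kruskal_wallis', got {kind!r}")


_SEPARATION_BETA = 30.0  # |beta| beyond this on standardized data = separation


def _wald(params: np.ndarray, bse: np.ndarray, j: int) -> tuple[float, float, float]:
    lo = params[j] - 1.959963984540054 * bse[j]
    hi = params[j] + 1.959963984540054 * bse[j]
    return float(np.exp(params[j])), float(np.exp(lo)), float(np.exp(hi))


def univariable_logistic(x: Sequence[float], y: Sequence[int]) -> TestResult:
    """One-covariate logistic fit with intercept; reports the odds ratio
    with Wald CI and p. Complete separation is detected and flagged rather
    than silently diverging."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    X = sm.add_constant(x)
    flags: tuple[str, ...] = ()
    with np.errstate(all="ignore"):
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:  # statsmodels raises on perfect separation
            return TestResult(
                p_value=None, method="logistic_wald", flags=("separation",)
            )
    scale = np.std(x) if np.std(x) > 0 else 1.0
    if not fit.mle_retvals.get("converged", True) or abs(fit.params[1]) * scale > _SEPARATION_BETA:
        flags = ("separation",)
    or_, lo, hi = _wald(fit.params, fit.bse, 1)
    return TestResult(
        p_value=float(fit.pvalues[1]),
        statistic=float(fit.tvalues[1]),
        estimate=or_,
        ci_low=lo,
        ci_high=hi,
        method="logistic_wald",
        flags=flags,
    )


def univariable_cox(
    x: Sequence[float], times: Sequence[float], events: Sequence[int]
) -> TestResult:
    """One-covariate Cox proportional-hazards fit (Efron ties); reports the
    hazard ratio with Wald CI and p."""
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("no events observed; Cox fit undefined")
    df = pd.DataFrame({"x": np.asarray(x, dtype=float), "t": times, "e": events})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="t", event_col="e")
    s = cph.summary.loc["x"]
    return TestResult(
        p_value=float(s["p"]),
        statistic=float(s["z"]),
        estimate=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        method="cox_efron_wald",
    )


def km_logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[object],
) -> tuple[dict[object, pd.DataFrame], TestResult]:
    """Kaplan-Meier curves per group plus the standard log-rank test.

    Returns a mapping group -> survival-curve DataFrame (timeline, survival
    probability, at-risk counts) and the test result. With no events
    anywhere the curves are flat at 1 and the log-rank statistic is
    undefined (flagged, p absent)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = pd.Series(list(groups))
    curves: dict[object, pd.DataFrame] = {}
    for g in labels.unique():
        mask = (labels == g).to_numpy()
        if not mask.any():
            raise ValueError(f"group {g!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        frame = kmf.survival_function_.copy()
        frame.columns = ["survival"]
        frame["at_risk"] = kmf.event_table["at_risk"].reindex(frame.index).ffill()
        curves[g] = frame
    if events.sum() == 0:
        return curves, TestResult(p_value=None, method="logrank", flags=("no_events",))
    res = multivariate_logrank_test(times, labels.to_numpy(), events)
    return curves, TestResult(
        p_value=float(min(res.p_value, 1.0)),
        statistic=float(res.test_statistic),
        method="logrank",
    )


def printed_ddr_tables() -> pd.DataFrame:
    """The five DDR/gene-level CB-vs-NCB contingency tables printed in the
    study's results (carriers among 24 CB vs 38 NCB patients), with the
    published two-sided Fisher p-values."""
    with resources.files("ucipred.data").joinpath("printed_ddr_tables.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
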