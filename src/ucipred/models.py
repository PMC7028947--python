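"""Multivariable model building and the clinical point-score predictor.

The model-building path mirrors the study design: candidate covariates are
screened by adaptive-LASSO (ALASSO) selection — an L1 penalty with
coefficient-specific weights ``1/|b_init|**gamma`` from an initial ridge
fit, which yields consistent selection — and the selected variables enter a
multivariable logistic or Cox fit pruned by backward elimination under a
Wald stay criterion (drop the least significant variable while its p-value
exceeds the stay level, default 0.10). Discrimination is summarized by the
c-statistic: the ROC area for binary benefit, Harrell's concordance for
censored survival, both with a seeded percentile-bootstrap interval.

Fitted logistic coefficients over binary indicators are turned into a
transportable point score by rounding each beta (and the intercept) to the
nearest half point, or by pinning an explicit published mapping; a score at
or above the classification threshold predicts clinical benefit.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ModelBuildConfig",
    "FittedModel",
    "PointScoreModel",
    "PrognosticIndex",
    "alasso_select",
    "fit_multivariable",
    "c_statistic",
    "roc_auc",
    "derive_point_score",
    "score_patient",
    "choose_threshold",
    "classification_metrics",
    "prognostic_index",
    "os_point_score",
    "PAPER_POINTS",
]

_Z975 = 1.959963984540054

#: The published three-factor point mapping (intercept +1, visceral
#: metastasis -2.5, NLR >= 5 -2, SNV count >= 10 +3; threshold >= -1).
PAPER_POINTS: Mapping[str, float] = {
    "intercept": 1.0,
    "visceral_mets": -2.5,
    "nlr_ge5": -2.0,
    "snv_ge10": 3.0,
}


@dataclass(frozen=True)
class ModelBuildConfig:
    family: str = "logistic"  # or "cox"
    alasso_gamma: float = 1.0
    lambda_grid: tuple[float, ...] = tuple(np.logspace(-5, 0, 31))
    tuning: str = "bic"  # or "cv"
    stay_alpha: float = 0.10
    univariable_alpha: float = 0.05
    seed: int = 0
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.family not in ("logistic", "cox"):
            raise ValueError(f"family must be 'logistic' or 'cox', got {self.family!r}")
        if not self.lambda_grid:
            raise ValueError("lambda_grid must be non-empty")
        if self.alasso_gamma <= 0:
            raise ValueError("alasso_gamma must be positive")
        for name in ("stay_alpha", "univariable_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")


@dataclass(frozen=True)
class FittedModel:
    """A fitted multivariable model. ``coefficients`` etc. are aligned with
    ``variables``; logistic models carry the intercept separately."""

    family: str
    variables: tuple[str, ...]
    coefficients: tuple[float, ...]
    standard_errors: tuple[float, ...]
    p_values: tuple[float, ...]
    effect_estimates: Mapping[str, tuple[float, float, float]]  # exp(b), lo, hi
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None
    c_statistic: Optional[float] = None
    c_statistic_ci: Optional[tuple[float, float]] = None
    flags: tuple[str, ...] = ()

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        lp = np.zeros(len(X)) if self.intercept is None else np.full(len(X), self.intercept)
        for var, b in zip(self.variables, self.coefficients):
            lp = lp + b * X[var].to_numpy(dtype=float)
        return lp


def _ridge_init_logistic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    ridge = LogisticRegression(C=10.0, l1_ratio=0.0, solver="lbfgs", max_iter=2000)
    ridge.fit(X, y)
    return ridge.coef_.ravel()


def _ridge_init_cox(X: pd.DataFrame, times: np.ndarray, events: np.ndarray) -> np.ndarray:
    df = X.copy()
    df["_t"], df["_e"] = times, events
    cph = CoxPHFitter(penalizer=0.1, l1_ratio=0.0)
    cph.fit(df, duration_col="_t", event_col="_e")
    return cph.params_.reindex(X.columns).to_numpy()


def _logistic_bic(X: np.ndarray, y: np.ndarray, support: np.ndarray) -> float:
    n = len(y)
    cols = X[:, support] if support.any() else np.empty((n, 0))
    Xd = sm.add_constant(cols, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
        llf = fit.llf
    except Exception:
        return np.inf
    k = Xd.shape[1]
    return -2 * llf + k * math.log(n)


def _cox_bic(X: pd.DataFrame, times, events, support: list[str]) -> float:
    n_events = int(np.sum(events))
    if not support:
        return 0.0  # null model: partial log-likelihood constant dropped
    df = X[support].copy()
    df["_t"], df["_e"] = times, events
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="_t", event_col="_e")
    except Exception:
        return np.inf
    return -2 * cph.log_likelihood_ + len(support) * math.log(max(n_events, 2))


def alasso_select(
    X: pd.DataFrame,
    y: Optional[Sequence[int]] = None,
    config: ModelBuildConfig = ModelBuildConfig(),
    times: Optional[Sequence[float]] = None,
    events: Optional[Sequence[int]] = None,
) -> list[str]:
    """Adaptive-LASSO variable selection.

    Computes adaptive weights ``1/|b_init|**gamma`` from a ridge fit,
    rescales each column by the inverse weight (the standard reduction of
    the weighted-L1 problem to a plain LASSO), traces the penalty path over
    ``config.lambda_grid`` and returns the variables with nonzero
    coefficients at the lambda chosen by BIC (default) or seeded
    cross-validation. Constant columns are dropped with a warning; an empty
    selection is a legal result.
    """
    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping constant covariates: {dropped}", RuntimeWarning, stacklevel=2)
    if not keep:
        return []
    Xk = X[keep]
    Xs = (Xk - Xk.mean()) / Xk.std(ddof=0)
    Xm = Xs.to_numpy(dtype=float)
    n = len(Xm)

    if config.family == "logistic":
        y = np.asarray(y, dtype=int)
        if y.min() == y.max():
            raise ValueError("outcome is constant; nothing to select")
        b_init = _ridge_init_logistic(Xm, y)
    else:
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        b_init = _ridge_init_cox(Xs, times, events)

    scale = np.abs(b_init) ** config.alasso_gamma
    scale = np.maximum(scale, 1e-10)
    Xw = Xm * scale  # lasso on Xw == weighted-L1 on Xm

    best: tuple[float, list[str]] = (np.inf, [])
    rng_folds = None
    if config.tuning == "cv":
        from sklearn.model_selection import StratifiedKFold, KFold

        if config.family == "logistic":
            rng_folds = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
        else:
            rng_folds = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)

    for lam in sorted(config.lambda_grid):
        if config.family == "logistic":
            C = 1.0 / (n * lam)
            lasso = LogisticRegression(
                C=C, l1_ratio=1.0, solver="liblinear", max_iter=2000, random_state=config.seed
            )
            lasso.fit(Xw, y)
            support = np.abs(lasso.coef_.ravel()) > 1e-10
            if config.tuning == "bic":
                crit = _logistic_bic(Xm, y, support)
            else:
                from sklearn.model_selection import cross_val_score

                crit = -float(
                    np.mean(
                        cross_val_score(
                            LogisticRegression(
                                C=C, l1_ratio=1.0, solver="liblinear", max_iter=2000,
                                random_state=config.seed,
                            ),
                            Xw, y, cv=rng_folds, scoring="neg_log_loss",
                        )
                    )
                )
            sel = [c for c, s in zip(keep, support) if s]
        else:
            df = pd.DataFrame(Xw, columns=keep)
            df["_t"], df["_e"] = times, events
            try:
                cph = CoxPHFitter(penalizer=lam, l1_ratio=1.0)
                cph.fit(df, duration_col="_t", event_col="_e")
            except Exception:
                continue
            coefs = cph.params_.reindex(keep).to_numpy()
            support_names = [c for c, b in zip(keep, coefs) if abs(b) > 1e-5]
            crit = _cox_bic(Xs, times, events, support_names)
            sel = support_names
        if crit < best[0] - 1e-12:
            best = (crit, sel)
    return best[1]


def _firth_logistic(Xd: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """Jeffreys-prior (Firth-type) penalized logistic Newton fit; finite
    estimates exist even under complete separation."""
    beta = np.zeros(Xd.shape[1])
    for _ in range(max_iter):
        p = expit(Xd @ beta)
        W = np.clip(p * (1 - p), 1e-12, None)
        XW = Xd * W[:, None]
        info = Xd.T @ XW
        info_inv = np.linalg.pinv(info)
        root_w = Xd * np.sqrt(W)[:, None]
        h = np.einsum("ij,jk,ik->i", root_w, info_inv, root_w)
        score = Xd.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    p = expit(Xd @ beta)
    W = np.clip(p * (1 - p), 1e-12, None)
    info_inv = np.linalg.pinv(Xd.T @ (Xd * W[:, None]))
    bse = np.sqrt(np.diag(info_inv))
    return beta, bse


def _fit_logistic_once(X: pd.DataFrame, y: np.ndarray):
    Xd = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    flags: tuple[str, ...] = ()
    separated = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
        params, bse = np.asarray(fit.params), np.asarray(fit.bse)
        if not fit.mle_retvals.get("converged", True) or np.any(np.abs(params) > 30):
            separated = True
    except Exception:
        separated = True
    if separated:
        params, bse = _firth_logistic(Xd, y)
        flags = ("separation", "firth_fallback")
    z = params / np.where(bse > 0, bse, np.nan)
    p = 2 * sps.norm.sf(np.abs(z))
    return params, bse, p, flags


def fit_multivariable(
    X: pd.DataFrame,
    y: Optional[Sequence[int]] = None,
    times: Optional[Sequence[float]] = None,
    events: Optional[Sequence[int]] = None,
    family: str = "logistic",
    stay_alpha: float = 0.10,
) -> FittedModel:
    """Multivariable fit with backward elimination under the stay criterion.

    Iteratively refits and drops the variable with the largest Wald p-value
    while that p-value exceeds ``stay_alpha``, stopping when every remaining
    variable meets the criterion or only one is left. Effects are reported
    as exp(beta) with 95% Wald intervals. Logistic fits that separate fall
    back to a Firth-type penalized fit (flagged).
    """
    if X.shape[1] == 0:
        raise ValueError("at least one candidate variable is required")
    current = list(X.columns)
    while True:
        if family == "logistic":
            yv = np.asarray(y, dtype=int)
            params, bse, pvals, flags = _fit_logistic_once(X[current], yv)
            var_p = pvals[1:]
        elif family == "cox":
            df = X[current].copy()
            df["_t"], df["_e"] = np.asarray(times, float), np.asarray(events, int)
            cph = CoxPHFitter()
            cph.fit(df, duration_col="_t", event_col="_e")
            params = cph.params_.reindex(current).to_numpy()
            bse = cph.standard_errors_.reindex(current).to_numpy()
            var_p = np.asarray(cph.summary.loc[current, "p"], dtype=float)
            flags = ()
        else:
            raise ValueError(f"family must be 'logistic' or 'cox', got {family!r}")
        worst = int(np.nanargmax(var_p))
        if var_p[worst] > stay_alpha and len(current) > 1:
            del current[worst]
            continue
        break

    if family == "logistic":
        effects = {
            v: (
                float(np.exp(params[j + 1])),
                float(np.exp(params[j + 1] - _Z975 * bse[j + 1])),
                float(np.exp(params[j + 1] + _Z975 * bse[j + 1])),
            )
            for j, v in enumerate(current)
        }
        c = roc_auc(
            expit(params[0] + X[current].to_numpy(dtype=float) @ params[1:]), np.asarray(y, int)
        )
        return FittedModel(
            family="logistic",
            variables=tuple(current),
            coefficients=tuple(float(b) for b in params[1:]),
            standard_errors=tuple(float(s) for s in bse[1:]),
            p_values=tuple(float(p) for p in var_p),
            effect_estimates=effects,
            intercept=float(params[0]),
            intercept_se=float(bse[0]),
            intercept_p=float(2 * sps.norm.sf(abs(params[0] / bse[0]))) if bse[0] > 0 else None,
            c_statistic=c,
            flags=flags,
        )
    effects = {
        v: (
            float(np.exp(params[j])),
            float(np.exp(params[j] - _Z975 * bse[j])),
            float(np.exp(params[j] + _Z975 * bse[j])),
        )
        for j, v in enumerate(current)
    }
    lp = X[current].to_numpy(dtype=float) @ params
    c = float(
        concordance_index(np.asarray(times, float), -lp, np.asarray(events, int))
    )
    return FittedModel(
        family="cox",
        variables=tuple(current),
        coefficients=tuple(float(b) for b in params),
        standard_errors=tuple(float(s) for s in bse),
        p_values=tuple(float(p) for p in var_p),
        effect_estimates=effects,
        c_statistic=c,
        flags=flags,
    )


def roc_auc(scores: Sequence[float], y: Sequence[int]) -> float:
    """Rank-based ROC area (probability a case outranks a non-case; ties
    count one half)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = sps.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def c_statistic(
    scores: Sequence[float],
    y: Optional[Sequence[int]] = None,
    times: Optional[Sequence[float]] = None,
    events: Optional[Sequence[int]] = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Discrimination with a seeded percentile-bootstrap 95% interval.

    Binary outcome: ROC area of ``scores`` against ``y``. Survival outcome:
    Harrell's concordance of higher-score = higher-risk over usable pairs.
    """
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=int)
        point = roc_auc(scores, y)
        stats = []
        n = len(y)
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            if y[idx].min() == y[idx].max():
                continue
            stats.append(roc_auc(scores[idx], y[idx]))
    else:
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        point = float(concordance_index(times, -scores, events))
        stats = []
        n = len(times)
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            if events[idx].sum() == 0:
                continue
            stats.append(float(concordance_index(times[idx], -scores[idx], events[idx])))
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return point, (float(lo), float(hi))


def _round_half(x: float) -> float:
    """Round to the nearest multiple of 0.5, ties away from zero."""
    r = math.copysign(math.floor(abs(x) * 2 + 0.5) / 2, x)
    return 0.0 if r == 0 else r


@dataclass(frozen=True)
class PointScoreModel:
    """A points-based predictor over binary indicators: score = intercept
    points + sum of points for the indicators that are true; scores at or
    above ``threshold`` predict clinical benefit."""

    intercept_points: float
    variable_points: Mapping[str, float]
    threshold: float = -1.0
    rounding: str = "nearest_half"
    source: Optional[FittedModel] = None

    def enumerate_scores(self) -> list[float]:
        """All achievable scores over the 2^k indicator combinations."""
        pts = list(self.variable_points.values())
        values = {
            self.intercept_points + sum(p for p, on in zip(pts, combo) if on)
            for combo in itertools.product((False, True), repeat=len(pts))
        }
        return sorted(values)

    @property
    def score_range(self) -> tuple[float, float]:
        scores = self.enumerate_scores()
        return scores[0], scores[-1]

    def __post_init__(self) -> None:
        lo, hi = self.score_range
        if not lo <= self.threshold <= hi:
            raise ValueError(
                f"threshold {self.threshold} outside achievable score range [{lo}, {hi}]"
            )


def derive_point_score(
    model: FittedModel,
    rounding: str = "nearest_half",
    threshold: float = -1.0,
    explicit_points: Optional[Mapping[str, float]] = None,
) -> PointScoreModel:
    """Convert a fitted logistic model over binary indicators to points.

    ``nearest_half`` rounds each coefficient (and the intercept) to the
    closest multiple of 0.5, ties away from zero. ``explicit`` mode pins a
    user-supplied mapping (key ``intercept`` plus one key per variable),
    which is how a published mapping is reproduced bit-exactly.
    """
    if model.family != "logistic":
        raise ValueError("point scores are derived from logistic models only")
    if rounding == "explicit":
        if explicit_points is None:
            raise ValueError("explicit rounding requires explicit_points")
        missing = ({"intercept"} | set(model.variables)) - set(explicit_points)
        if missing:
            raise ValueError(f"explicit_points missing entries for: {sorted(missing)}")
        return PointScoreModel(
            intercept_points=float(explicit_points["intercept"]),
            variable_points={v: float(explicit_points[v]) for v in model.variables},
            threshold=threshold,
            rounding="explicit",
            source=model,
        )
    if rounding != "nearest_half":
        raise ValueError(f"rounding must be 'nearest_half' or 'explicit', got {rounding!r}")
    return PointScoreModel(
        intercept_points=_round_half(model.intercept or 0.0),
        variable_points={v: _round_half(b) for v, b in zip(model.variables, model.coefficients)},
        threshold=threshold,
        rounding="nearest_half",
        source=model,
    )


def score_patient(
    psm: PointScoreModel, flags: Mapping[str, Optional[bool]]
) -> tuple[float, str]:
    """Score one patient and classify. Every indicator in the model must be
    present and non-missing; patients missing an input (e.g. no NLR drawn)
    are excluded upstream, per the listwise policy."""
    score = psm.intercept_points
    for var, pts in psm.variable_points.items():
        val = flags.get(var)
        if val is None:
            raise ValueError(
                f"indicator {var!r} is missing; exclude the patient upstream "
                "(listwise per-analysis policy) instead of scoring"
            )
        if val:
            score += pts
    return score, ("CB" if score >= psm.threshold else "NCB")


def choose_threshold(scores: Sequence[float], outcomes: Sequence[int]) -> float:
    """Pick the classification threshold maximizing Youden's J over the
    achievable score values (used when deriving a new score; a published
    threshold is pinned instead)."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):
        pred = scores >= t
        sens = (pred & (outcomes == 1)).sum() / max((outcomes == 1).sum(), 1)
        spec = (~pred & (outcomes == 0)).sum() / max((outcomes == 0).sum(), 1)
        j = sens + spec - 1
        if j > best_j:
            best_t, best_j = float(t), j
    return best_t


def classification_metrics(
    predictions: Sequence[str], outcomes: Sequence[str]
) -> dict[str, object]:
    """Sensitivity/specificity of CB predictions against CB/NCB outcomes,
    reported as exact fractions and rounded percentages."""
    if len(predictions) != len(outcomes) or len(predictions) == 0:
        raise ValueError("predictions and outcomes must be aligned and non-empty")
    pred = np.asarray([p == "CB" for p in predictions])
    obs = np.asarray([o == "CB" for o in outcomes])
    tp = int((pred & obs).sum())
    fn = int((~pred & obs).sum())
    tn = int((~pred & ~obs).sum())
    fp = int((pred & ~obs).sum())
    out: dict[str, object] = {"tp": tp, "fn": fn, "tn": tn, "fp": fp}
    out["sensitivity"] = tp / (tp + fn) if tp + fn > 0 else None
    out["specificity"] = tn / (tn + fp) if tn + fp > 0 else None
    out["sensitivity_pct"] = None if out["sensitivity"] is None else round(100 * out["sensitivity"])
    out["specificity_pct"] = None if out["specificity"] is None else round(100 * out["specificity"])
    if out["sensitivity"] is None:
        out["flags"] = ("no_positives",)
    return out


@dataclass(frozen=True)
class PrognosticIndex:
    """Linear prognostic index with ordered cutoffs defining risk groups;
    intervals are closed on the left (an index equal to a cutoff falls in
    the higher group)."""

    coefficients: Mapping[str, float]
    cutoffs: tuple[float, ...] = (-0.29, 1.54)
    group_labels: tuple[str, ...] = ("low", "intermediate", "high")

    def __post_init__(self) -> None:
        if list(self.cutoffs) != sorted(self.cutoffs) or len(set(self.cutoffs)) != len(self.cutoffs):
            raise ValueError(f"cutoffs must be strictly increasing, got {self.cutoffs}")
        if len(self.group_labels) != len(self.cutoffs) + 1:
            raise ValueError("need one more group label than cutoffs")


def prognostic_index(
    pi: PrognosticIndex, features: Mapping[str, float]
) -> tuple[float, str]:
    """Evaluate the index and assign the risk group."""
    missing = set(pi.coefficients) - set(features)
    if missing:
        raise ValueError(f"features missing for index evaluation: {sorted(missing)}")
    index = float(sum(b * float(features[v]) for v, b in pi.coefficients.items()))
    group = pi.group_labels[int(np.searchsorted(pi.cutoffs, index, side="right"))]
    return index, group


def os_point_score(
    visceral: Optional[bool], nlr_ge5: Optional[bool], ecog_ge1: Optional[bool]
) -> tuple[int, str]:
    """Overall-survival point score: visceral metastasis 2 points, NLR >= 5
    one point, ECOG >= 1 one point; groups 0-2, 3 and 4 points."""
    for name, flag in (("visceral", visceral), ("nlr_ge5", nlr_ge5), ("ecog_ge1", ecog_ge1)):
        if flag is None:
            raise ValueError(f"flag {name!r} is missing; exclude the patient upstream")
    points = 2 * int(visceral) + int(nlr_ge5) + int(ecog_ge1)
    group = "0-2" if points <= 2 else ("3" if points == 3 else "4")
    return points, group
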