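"""Survival and hypothesis-testing machinery for cohort outcome analysis.

Kaplan-Meier product-limit estimation, multivariate Cox proportional-hazards
regression (Breslow tie handling), Mann-Whitney U (exact null for small
samples), Spearman rank correlation, ROC AUC via the rank formulation, a
logistic score-combination helper, and the "at least one success" binomial
sample-size calculation used to size liquid-biopsy cohorts.

The estimators here are written out explicitly rather than delegated, so the
exact conventions (tie handling, two-sided p-values, reference levels) are
part of the package contract and testable against small-sample enumeration
oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression

__all__ = [
    "KaplanMeierCurve",
    "CoxResult",
    "ConvergenceError",
    "kaplan_meier",
    "kaplan_meier_by_group",
    "cox_ph",
    "cox_multivariate",
    "mann_whitney",
    "spearman",
    "roc_auc",
    "combine_scores_logistic",
    "min_samples_binomial",
    "confidence_at_n",
    "significance_stars",
]


class ConvergenceError(RuntimeError):
    """Raised when the Cox partial likelihood cannot be maximized reliably."""


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KaplanMeierCurve:
    """Product-limit survival curve.

    ``times`` are the distinct event times, ``survival`` the estimate just
    after each; the curve starts at S(0)=1. ``median`` is the earliest time
    at which the estimate drops to 0.5 or below, NaN if never reached.
    """

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median: float

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(time, event) -> KaplanMeierCurve:
    """Product-limit estimator for right-censored data."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("no observations")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]

    dtimes, at_risk, d = [], [], []
    n = time.size
    i = 0
    while i < n:
        t = time[i]
        j = i
        deaths = 0
        while j < n and time[j] == t:
            deaths += event[j]
            j += 1
        if deaths > 0:
            dtimes.append(t)
            at_risk.append(n - i)
            d.append(deaths)
        i = j
    if not dtimes:
        raise ValueError("at least one event is required")
    dtimes = np.array(dtimes)
    at_risk = np.array(at_risk, dtype=float)
    d = np.array(d, dtype=float)
    surv = np.cumprod(1.0 - d / at_risk)
    below = np.nonzero(surv <= 0.5)[0]
    median = float(dtimes[below[0]]) if below.size else float("nan")
    return KaplanMeierCurve(dtimes, surv, at_risk.astype(int), d.astype(int), median)


def kaplan_meier_by_group(df: pd.DataFrame, time_col: str, event_col: str,
                          group_col: str) -> dict:
    """Per-group KM curves; groups with no events are skipped (value None)."""
    out = {}
    for g, sub in df.groupby(group_col, sort=True):
        try:
            out[g] = kaplan_meier(sub[time_col], sub[event_col])
        except ValueError:
            out[g] = None
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Per-term Cox regression output; reference levels are recorded by name."""

    terms: list
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray = field(init=False)
    ci_lower: np.ndarray = field(init=False)
    ci_upper: np.ndarray = field(init=False)
    p: np.ndarray = field(init=False)
    log_likelihood: float = 0.0
    n: int = 0
    n_events: int = 0
    reference: str = ""

    def __post_init__(self):
        z = 1.959963984540054
        self.hr = np.exp(self.coef)
        self.ci_lower = np.exp(self.coef - z * self.se)
        self.ci_upper = np.exp(self.coef + z * self.se)
        with np.errstate(divide="ignore", invalid="ignore"):
            wald = np.where(self.se > 0, self.coef / self.se, np.inf)
        self.p = 2.0 * sps.norm.sf(np.abs(wald))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "hr": self.hr, "ci_lower": self.ci_lower,
             "ci_upper": self.ci_upper, "p": self.p, "se": self.se},
            index=self.terms,
        )


def _cox_loglik(beta, X, time, event):
    """Breslow partial log-likelihood with gradient and Hessian.

    Observations must be sorted by time ascending; risk sets are suffixes.
    """
    n, p = X.shape
    eta = X @ beta
    # guard against overflow in exp for diverging beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    # suffix accumulations: S0_i = sum_{j: t_j >= t_i} w_j etc.
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1],
                   axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        d = 0
        xsum = np.zeros(p)
        esum = 0.0
        while j < n and time[j] == time[i]:
            if event[j]:
                d += 1
                xsum += X[j]
                esum += eta[j]
            j += 1
        if d > 0:
            s0, s1, s2 = S0[i], S1[i], S2[i]
            ll += esum - d * math.log(s0)
            mu = s1 / s0
            grad += xsum - d * mu
            hess -= d * (s2 / s0 - np.outer(mu, mu))
        i = j
    return ll, grad, hess


def cox_ph(X, time, event, terms=None, max_iter=100, tol=1e-9,
           reference: str = "") -> CoxResult:
    """Cox proportional-hazards fit by Newton-Raphson with step halving.

    Parameters
    ----------
    X : (n, p) design matrix (already encoded; no intercept).
    time, event : durations (>0) and binary event indicators.
    terms : column names for reporting.

    Raises
    ------
    ConvergenceError on monotone likelihood (diverging coefficients) or
    failure to converge; no silent result is returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and np.asarray(time).size > 1:
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    if event.sum() < 2:
        raise ValueError("need at least two events")
    for k in range(p):
        if np.all(X[:, k] == X[0, k]):
            raise ValueError(f"term {k} is constant")
    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]

    # center covariates for numerical stability (does not change coef)
    center = Xs.mean(axis=0)
    Xc = Xs - center

    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik(beta, Xc, ts, es)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        # step halving
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, hess_new = _cox_loglik(cand, Xc, ts, es)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        else:
            raise ConvergenceError("step halving failed")
        delta = np.max(np.abs(cand - beta))
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if delta < tol or np.max(np.abs(grad)) < tol:
            converged = True
            break
    if not converged and np.max(np.abs(grad)) > 1e-4:
        raise ConvergenceError("Newton iterations did not converge")
    if np.max(np.abs(beta)) > 20:
        raise ConvergenceError(
            "monotone partial likelihood (diverging coefficient); "
            "a group may have no events")
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    if terms is None:
        terms = [f"x{k}" for k in range(p)]
    return CoxResult(list(terms), beta, se, log_likelihood=ll, n=n,
                     n_events=int(es.sum()), reference=reference)


def _encode_covariates(df: pd.DataFrame, covariates) -> tuple:
    """Encode clinical covariates the way the survival tables report them.

    age: dichotomized at 65 (1 if >65); gender: 1 for male; tnm_stage:
    ordered numeric with a separate missing-level indicator.
    """
    cols, names = [], []
    for cov in covariates:
        if cov == "age":
            cols.append((pd.to_numeric(df["age"], errors="coerce") > 65)
                        .astype(float).to_numpy())
            names.append("age_gt65")
        elif cov == "gender":
            cols.append((df["gender"].astype(str).str.lower()
                         .isin(["m", "male"])).astype(float).to_numpy())
            names.append("gender_male")
        elif cov in ("tnm", "tnm_stage"):
            stage = pd.to_numeric(df["tnm_stage"], errors="coerce")
            missing = stage.isna()
            cols.append(stage.fillna(stage.median() if not missing.all()
                                     else 0.0).to_numpy(dtype=float))
            names.append("tnm_stage")
            if missing.any():
                cols.append(missing.astype(float).to_numpy())
                names.append("tnm_missing")
        else:
            cols.append(pd.to_numeric(df[cov], errors="coerce")
                        .to_numpy(dtype=float))
            names.append(cov)
    return cols, names


def cox_multivariate(df: pd.DataFrame, time_col: str, event_col: str,
                     group_col: str, covariates=(), reference=None) -> CoxResult:
    """Multivariate Cox regression of a group term plus clinical covariates.

    The group variable is dummy-encoded against ``reference`` (default: the
    lexicographically smallest level, i.e. cluster 1 or "Large decrease").
    """
    levels = sorted(df[group_col].unique())
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present")
    cols, names = [], []
    for lev in levels:
        if lev == reference:
            continue
        cols.append((df[group_col] == lev).astype(float).to_numpy())
        names.append(f"{group_col}={lev}")
    ccols, cnames = _encode_covariates(df, covariates)
    cols += ccols
    names += cnames
    X = np.column_stack(cols)
    return cox_ph(X, df[time_col].to_numpy(), df[event_col].to_numpy(),
                  terms=names, reference=str(reference))


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def _mw_exact_cdf_counts(n1: int, n2: int) -> np.ndarray:
    """Number of arrangements giving each U value under the null.

    Classic recurrence: c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u).
    Returns an array of length n1*n2+1 summing to C(n1+n2, n1).
    """
    memo = {}

    def c(a: int, b: int, u: int) -> int:
        if u < 0 or u > a * b:
            return 0
        if a == 0 or b == 0:
            return 1 if u == 0 else 0
        key = (a, b, u)
        if key not in memo:
            memo[key] = c(a - 1, b, u - b) + c(a, b - 1, u)
        return memo[key]

    return np.array([c(n1, n2, u) for u in range(n1 * n2 + 1)], dtype=float)


def mann_whitney(a, b) -> tuple:
    """Two-sided Mann-Whitney test.

    Returns (U, p) where U counts, over all cross pairs, the wins of sample
    ``a`` (ties count one half). The null distribution is enumerated exactly
    when min(n_a, n_b) <= 8 and there are no ties; otherwise the normal
    approximation with tie correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(combined).size < combined.size

    if min(n1, n2) <= 8 and not has_ties:
        counts = _mw_exact_cdf_counts(n1, n2)
        total = counts.sum()
        u_int = int(round(u))
        lo = min(u_int, n1 * n2 - u_int)
        p = 2.0 * counts[: lo + 1].sum() / total
        return float(u), float(min(p, 1.0))

    mu = n1 * n2 / 2.0
    # tie correction on the variance
    _, tie_counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return float(u), 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    return float(u), float(min(2.0 * sps.norm.sf(z), 1.0))


def spearman(x, y) -> tuple:
    """Spearman rank correlation with average ranks; t-approximation p-value.

    Returns (rho, p); raises on constant input (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney formulation (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Logistic score combination
# ---------------------------------------------------------------------------

def combine_scores_logistic(score_a, score_b, labels, seed: int = 0) -> dict:
    """Combine two 0-1 scores with a two-feature logistic model.

    Leave-one-out probabilities are used for the cross-validated AUC so the
    combined score is never evaluated on a sample it was fitted on. A small
    ridge penalty keeps the fit defined under perfect separation, which is
    flagged in the output.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 samples for leave-one-out CV")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = np.column_stack([a, b])
    proba = np.empty(n)
    separated = False
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = LogisticRegression(C=100.0, solver="lbfgs", max_iter=2000,
                                 random_state=seed)
        clf.fit(X[mask], y[mask])
        if clf.score(X[mask], y[mask]) == 1.0:
            separated = True
        proba[i] = clf.predict_proba(X[i:i + 1])[0, 1]
    return {
        "combined_proba": proba,
        "auc_combined": roc_auc(proba, y),
        "auc_a": roc_auc(a, y),
        "auc_b": roc_auc(b, y),
        "perfect_separation": separated,
    }


# ---------------------------------------------------------------------------
# Binomial cohort sizing
# ---------------------------------------------------------------------------

def min_samples_binomial(p_subtype: float, confidence: float) -> int:
    """Smallest n such that P(at least one subtype sample) >= confidence.

    Solves 1 - (1-p)^n >= c, i.e. n = ceil(log(1-c) / log(1-p)).
    """
    if not 0.0 < p_subtype <= 1.0:
        raise ValueError("p_subtype must be in (0, 1]")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if p_subtype == 1.0:
        return 1
    n = math.ceil(math.log(1.0 - confidence) / math.log(1.0 - p_subtype))
    # guard floating-point edge cases around the boundary
    while confidence_at_n(p_subtype, n) < confidence:
        n += 1
    while n > 1 and confidence_at_n(p_subtype, n - 1) >= confidence:
        n -= 1
    return int(n)


def confidence_at_n(p_subtype: float, n: int) -> float:
    """Probability of observing at least one subtype sample among n."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 <= p_subtype <= 1.0:
        raise ValueError("p_subtype must be in [0, 1]")
    return 1.0 - (1.0 - p_subtype) ** n


def significance_stars(p: float) -> str:
    """Boxplot star convention: *, **, ***, **** at 0.05/0.01/0.001/0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "ns"
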