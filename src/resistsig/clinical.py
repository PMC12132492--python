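"""Clinical validation of expression signatures on bulk cohorts.

Samples are scored with ssGSEA; the association between score and survival
is estimated with a Cox proportional-hazards model (Newton iterations on
the Efron-tie partial likelihood), optionally adjusting for age, sex and
tumor purity.  Kaplan-Meier-style stratification splits the cohort at the
median score; binary-outcome cohorts (responder vs non-responder,
progression vs none) are compared with Wilcoxon rank-sum and Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import cohens_d, wilcoxon_rank_sum

SURVIVAL_COLUMNS = ("sample_id", "time", "event", "age", "sex", "purity")


def read_survival_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns {sorted(missing)}")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    df["event"] = df["event"].astype(bool)
    return df


@dataclass
class CoxResult:
    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.beta - 1.959963984540054 * self.se)
        hi = np.exp(self.beta + 1.959963984540054 * self.se)
        return np.column_stack([lo, hi])

    @property
    def wald_p(self) -> np.ndarray:
        z = self.beta / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "beta": self.beta,
                "hr": self.hr,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.wald_p,
            }
        )


def _efron_loglik_grad_hess(beta, X, time, event):
    """Efron-tie Cox partial log-likelihood with gradient and Hessian."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    order = np.argsort(-time, kind="mergesort")  # descending time
    Xo, to, eo, wo = X[order], time[order], event[order], w[order]
    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = to[i]
        j = i
        while j < n and to[j] == t:
            S0 += wo[j]
            xw = wo[j] * Xo[j]
            S1 += xw
            S2 += np.outer(xw, Xo[j])
            j += 1
        idx = [k for k in range(i, j) if eo[k]]
        d = len(idx)
        if d:
            T0 = sum(wo[k] for k in idx)
            T1 = np.sum([wo[k] * Xo[k] for k in idx], axis=0)
            T2 = np.sum([wo[k] * np.outer(Xo[k], Xo[k]) for k in idx], axis=0)
            for l in range(d):
                f = l / d
                D0 = S0 - f * T0
                D1 = S1 - f * T1
                D2 = S2 - f * T2
                grad -= D1 / D0
                hess -= D2 / D0 - np.outer(D1, D1) / D0**2
                loglik -= np.log(D0)
            loglik += sum(eta[order[k]] for k in idx)
            grad += np.sum([Xo[k] for k in idx], axis=0)
        i = j
    return loglik, grad, -hess  # return observed information (positive definite)


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str],
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxResult:
    """Cox proportional-hazards fit by Newton iteration, Efron tie handling.

    ``records`` needs columns time, event and the covariates; rows with
    missing covariate values are dropped listwise with a logged count.
    Raises on constant covariates and on monotone likelihood (perfect
    separation).
    """
    covariates = list(covariates)
    cols = ["time", "event"] + covariates
    df = records[cols].copy()
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        warnings.warn(f"dropped {n_before - len(df)} samples with missing covariates")
    X = df[covariates].to_numpy(dtype=float)
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=bool)
    if event.sum() < 2:
        raise ValueError("need >= 2 events")
    for j, c in enumerate(covariates):
        if np.all(X[:, j] == X[0, j]):
            raise ValueError(f"covariate {c!r} is constant")
    # standardize for numerical stability; transform estimates back
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mu) / sd
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        ll, grad, info = _efron_loglik_grad_hess(beta, Xs, time, event)
        if np.linalg.norm(grad) < tol:
            break
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.linalg.norm(beta) > 50:
            raise ValueError(
                "monotone partial likelihood (perfect separation?); fit diverged"
            )
    else:
        ll, grad, info = _efron_loglik_grad_hess(beta, Xs, time, event)
        if np.linalg.norm(grad) > 1e-4:
            raise ValueError("Cox Newton iteration did not converge")
    cov = np.linalg.inv(info)
    beta_raw = beta / sd
    se_raw = np.sqrt(np.diag(cov)) / sd
    return CoxResult(
        covariates=covariates,
        beta=beta_raw,
        se=se_raw,
        loglik=float(ll),
        n=len(df),
        n_events=int(event.sum()),
    )


def km_median_split(scores: pd.Series) -> pd.Series:
    """Median split: high = score > median; ties at the median go to low."""
    if len(scores) < 2:
        raise ValueError("need >= 2 samples")
    if scores.nunique() == 1:
        raise ValueError("all scores identical; split undefined")
    med = scores.median()
    labels = pd.Series(np.where(scores > med, "high", "low"), index=scores.index)
    labels.attrs["n_high"] = int((labels == "high").sum())
    labels.attrs["n_low"] = int((labels == "low").sum())
    return labels


def km_logrank(time: pd.Series, event: pd.Series, groups: pd.Series) -> float:
    """Log-rank p between the two median-split groups (lifelines)."""
    from lifelines.statistics import logrank_test

    hi = groups == "high"
    res = logrank_test(time[hi], time[~hi], event_observed_A=event[hi],
                       event_observed_B=event[~hi])
    return float(res.p_value)


def pooled_log_hr_test(hrs: Sequence[float], alternative: str = "greater") -> tuple[float, float]:
    """One-sample t-test of log hazard ratios against 0."""
    hrs = np.asarray(hrs, dtype=float)
    if hrs.size < 2:
        raise ValueError("need >= 2 hazard ratios")
    if np.any(hrs <= 0):
        raise ValueError("hazard ratios must be positive")
    log_hr = np.log(hrs)
    if np.allclose(log_hr.var(ddof=1), 0):
        raise ValueError("zero variance in log hazard ratios")
    alt = {"greater": "greater", "less": "less", "two_sided": "two-sided"}[alternative]
    res = stats.ttest_1samp(log_hr, 0.0, alternative=alt)
    return float(res.statistic), float(res.pvalue)


def compare_outcome_groups(
    scores: pd.Series, labels: pd.Series
) -> tuple[str, float, float]:
    """Which outcome group scores higher: (direction, rank-sum p, Cohen's d).

    ``labels`` is boolean (True = event group, e.g. progression); d > 0 means
    the True group scores higher; p is two-sided rank-sum.
    """
    lab = labels.reindex(scores.index).astype(bool)
    x = scores[lab].to_numpy()
    y = scores[~lab].to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError("both outcome groups must be non-empty")
    _, p = wilcoxon_rank_sum(x, y, "two_sided")
    d = cohens_d(x, y)
    direction = "event_higher" if d > 0 else ("event_lower" if d < 0 else "equal")
    return direction, p, d
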