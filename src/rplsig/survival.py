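"""Survival machinery: Kaplan-Meier curves, log-rank tests, Cox
proportional-hazards models and AIC backward elimination.

The Cox partial likelihood is maximized by damped Newton iteration with
Breslow tie handling by default (Efron by flag), Wald confidence intervals
and p-values, and explicit error paths for constant covariates and
monotone-likelihood separation.  Kaplan-Meier estimation and the log-rank
statistic are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


class SeparationError(RuntimeError):
    """Monotone partial likelihood: a covariate perfectly orders events."""


# ------------------------------------------------------------------ KM / logrank

def km_estimate(table: pd.DataFrame, group_col: str = "group") -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns per group a step table (time, at_risk, events, censored,
    survival) starting from S(0)=1; right-censoring handled.
    """
    out: dict[str, pd.DataFrame] = {}
    for name, sub in table.groupby(group_col, observed=True):
        if len(sub) == 0:
            raise ValueError(f"group {name!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        ev = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        out[str(name)] = pd.DataFrame(
            {
                "time": ev.index.to_numpy(dtype=float),
                "at_risk": ev["at_risk"].to_numpy(dtype=int),
                "events": ev["observed"].to_numpy(dtype=int),
                "censored": ev["censored"].to_numpy(dtype=int),
                "survival": surv.reindex(ev.index).to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    if not out:
        raise ValueError("no groups present")
    return out


def logrank_test(table: pd.DataFrame, group_col: str = "group") -> tuple[float, float]:
    """Log-rank chi-square statistic and p across two or more groups.

    Observed-minus-expected with hypergeometric variance at each distinct
    event time; tied events pooled.
    """
    groups = table[group_col]
    if groups.nunique() < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    if int(table["event"].sum()) == 0:
        raise ValueError("log-rank test needs >= 1 event")
    res = multivariate_logrank_test(table["time"], groups, table["event"])
    return float(res.test_statistic), float(res.p_value)


# ------------------------------------------------------------------ Cox model

@dataclass
class CoxResult:
    summary: pd.DataFrame  # per covariate: coefficient, hazard_ratio, ci, se, z, p_value
    log_likelihood: float  # maximized log partial likelihood
    aic: float
    n: int
    n_events: int
    ties: str
    covariates: list[str]  # original (pre-expansion) covariate names


def _design_matrix(table: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str], dict]:
    """Expand covariates to a numeric design matrix.

    Categorical columns become reference-coded indicators with the most
    frequent level as reference; column map records which design columns
    belong to each original covariate.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    col_map: dict[str, list[str]] = {}
    for cov in covariates:
        if cov not in table.columns:
            raise ValueError(f"covariate {cov!r} not in table")
        series = table[cov]
        if pd.api.types.is_numeric_dtype(series):
            arr = series.to_numpy(dtype=float)
            if np.ptp(arr) == 0:
                raise ValueError(f"covariate {cov!r} is constant")
            cols.append(arr)
            names.append(cov)
            col_map[cov] = [cov]
        else:
            levels = series.astype(str)
            ref = levels.value_counts().idxmax()
            col_map[cov] = []
            for level in sorted(set(levels) - {ref}):
                arr = (levels == level).to_numpy(dtype=float)
                if np.ptp(arr) == 0:
                    raise ValueError(f"covariate {cov!r} level {level!r} is constant")
                name = f"{cov}[{level} vs {ref}]"
                cols.append(arr)
                names.append(name)
                col_map[cov].append(name)
            if not col_map[cov]:
                raise ValueError(f"covariate {cov!r} is constant")
    return np.column_stack(cols), names, col_map


def _partial_loglik(beta, times, events, X, ties: str):
    """Log partial likelihood, gradient and information (negative Hessian)."""
    order = np.argsort(-times, kind="stable")  # descending: risk sets are prefixes
    t, d, x = times[order], events[order], X[order]
    eta = x @ beta
    # stabilize exponentials
    eta = eta - eta.max()
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = w[:, None, None] * (x[:, :, None] * x[:, None, :])
    cs_w = np.cumsum(w)
    cs_wx = np.cumsum(wx, axis=0)
    cs_wxx = np.cumsum(wxx, axis=0)

    loglik = 0.0
    grad = np.zeros_like(beta)
    info = np.zeros((beta.size, beta.size))
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        block = slice(i, j)
        ev = np.flatnonzero(d[block]) + i
        if ev.size:
            dd = ev.size
            s_x = x[ev].sum(axis=0)
            loglik += float(eta[ev].sum())
            R_w, R_wx, R_wxx = cs_w[j - 1], cs_wx[j - 1], cs_wxx[j - 1]
            if ties == "breslow":
                mu = R_wx / R_w
                loglik -= dd * np.log(R_w)
                grad += s_x - dd * mu
                info += dd * (R_wxx / R_w - np.outer(mu, mu))
            else:  # efron
                D_w = w[ev].sum()
                D_wx = wx[ev].sum(axis=0)
                D_wxx = wxx[ev].sum(axis=0)
                grad += s_x
                for l in range(dd):
                    f = l / dd
                    denom = R_w - f * D_w
                    num = R_wx - f * D_wx
                    mu = num / denom
                    loglik -= np.log(denom)
                    grad -= mu
                    info += (R_wxx - f * D_wxx) / denom - np.outer(mu, mu)
        i = j
    return loglik, grad, info


def cox_fit(
    table: pd.DataFrame,
    covariates,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton iteration.

    ``table`` needs time and event columns plus the named covariates.
    Convergence when the log partial likelihood changes by < ``tol``;
    separation (monotone likelihood) raises :class:`SeparationError`
    advising a penalized model instead of silently reporting it.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    covariates = list(covariates)
    if not covariates:
        raise ValueError("need at least one covariate")
    n_events = int(table["event"].sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events, got {n_events}")
    X, names, _ = _design_matrix(table, covariates)
    times = table["time"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)
    scale = X.std(axis=0)  # per-SD effect scale for separation detection

    beta = np.zeros(X.shape[1])
    loglik, grad, info = _partial_loglik(beta, times, events, X, ties)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix (collinear covariates or separation); "
                "consider a penalized fit"
            ) from exc
        new_beta = beta + step
        new_ll, new_grad, new_info = _partial_loglik(new_beta, times, events, X, ties)
        halvings = 0
        while new_ll < loglik and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _partial_loglik(new_beta, times, events, X, ties)
            halvings += 1
        if (np.abs(new_beta) * scale).max() > 20:
            # > 20 log hazard ratios per covariate SD is only reachable when
            # the likelihood is monotone in a coefficient
            raise SeparationError(
                "monotone partial likelihood (coefficient diverging); a covariate "
                "perfectly separates event order — use a penalized model"
            )
        converged = abs(new_ll - loglik) < tol
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if converged:
            break
    else:
        raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations")

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    crit = stats.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coefficient": beta,
            "hazard_ratio": np.exp(beta),
            "ci95_low": np.exp(beta - crit * se),
            "ci95_high": np.exp(beta + crit * se),
            "se": se,
            "z": z,
            "p_value": p,
        },
        index=pd.Index(names, name="covariate"),
    )
    k = X.shape[1]
    return CoxResult(
        summary=summary,
        log_likelihood=float(loglik),
        aic=float(2 * k - 2 * loglik),
        n=len(table),
        n_events=n_events,
        ties=ties,
        covariates=covariates,
    )


def aic_backward(
    table: pd.DataFrame, candidates, ties: str = "breslow"
) -> tuple[list[str], CoxResult]:
    """Backward elimination on AIC over Cox covariates.

    Iteratively drops the covariate whose removal most decreases the AIC;
    stops when no removal decreases it.  Ties break deterministically by
    covariate name order.  Returns the selected covariate list (possibly
    empty, with a null-model sentinel result of AIC 0-covariate) and the
    final fit.
    """
    selected = sorted(candidates)
    if not selected:
        raise ValueError("need at least one candidate covariate")
    current = cox_fit(table, selected, ties=ties)
    while len(selected) > 1:
        best_drop = None
        best_result = None
        best_aic = current.aic
        for cov in sorted(selected):
            trial = [c for c in selected if c != cov]
            try:
                res = cox_fit(table, trial, ties=ties)
            except (SeparationError, ValueError):
                continue
            if res.aic < best_aic - 1e-12:
                best_drop, best_result, best_aic = cov, res, res.aic
        if best_drop is None:
            break
        selected.remove(best_drop)
        current = best_result
    # a single remaining covariate may still be worse than the empty model:
    # null model AIC = -2 * logPL(beta=0) with k=0
    if len(selected) == 1:
        X, _, _ = _design_matrix(table, selected)
        ll0, _, _ = _partial_loglik(
            np.zeros(X.shape[1]),
            table["time"].to_numpy(dtype=float),
            table["event"].to_numpy(dtype=int),
            X,
            ties,
        )
        if -2.0 * ll0 < current.aic - 1e-12:
            return [], current
    return selected, current
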