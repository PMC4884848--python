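"""Cox proportional-hazards regression and incidence rates.

The Cox model relates covariates (crossover delay, crossover angle, limb
exponents, glycemic summaries, clinical variables) to the hazard of a
diabetes diagnosis: h(t | x) = h0(t) * exp(x . beta).  The coefficient
vector is estimated here by Newton-Raphson maximization of the Breslow
partial log-likelihood (ties share the full risk set), with covariates
standardized internally for conditioning and results reported on the
original scale.  Standard errors come from the inverse observed
information at the maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

logger = logging.getLogger(__name__)

_MAX_ITER = 50
_GRAD_TOL = 1e-9


@dataclass
class CohortRecord:
    """One patient's covariates, follow-up time (months) and outcome."""

    patient_id: object
    covariates: Mapping[str, float]
    followup_time: float
    event: bool

    def __post_init__(self) -> None:
        if not self.followup_time > 0:
            raise ValueError("followup_time must be positive")


@dataclass
class CoxFit:
    """A fitted proportional-hazards model."""

    covariate_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    n: int
    n_events: int
    n_excluded: int = 0
    diagnostic: str = ""

    def __getitem__(self, name: str) -> float:
        return float(self.beta[self.covariate_names.index(name)])

    def summary_rows(self) -> list[dict]:
        rows = []
        for i, name in enumerate(self.covariate_names):
            rows.append(
                {
                    "term": name,
                    "beta": float(self.beta[i]),
                    "se": float(self.se[i]),
                    "z": float(self.z[i]),
                    "p": float(self.p[i]),
                    "hr": float(np.exp(self.beta[i])),
                }
            )
        return rows


def breslow_loglik(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow partial log-likelihood at a given coefficient vector.

    For each distinct event time with event set D (|D| = d) and risk set R:
    sum_{i in D} x_i.beta - d * log( sum_{j in R} exp(x_j.beta) ).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ll, _, _ = _newton_terms(
        np.atleast_1d(np.asarray(beta, dtype=float)),
        X,
        np.asarray(time, dtype=float),
        np.asarray(event, dtype=bool),
        hess=False,
    )
    return ll


def cox_fit(
    records: Sequence[CohortRecord],
    covariate_names: Sequence[str],
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Records with a missing (non-finite) covariate are excluded listwise
    with a logged count.  Requires at least one event and a full-rank
    design after standardization; monotone likelihood or failure to
    converge within 50 iterations is reported via ``converged=False``.
    """
    names = list(covariate_names)
    X_rows, time, event, n_excluded = [], [], [], 0
    for rec in records:
        row = [float(rec.covariates.get(nm, np.nan)) for nm in names]
        if not np.all(np.isfinite(row)):
            n_excluded += 1
            continue
        X_rows.append(row)
        time.append(float(rec.followup_time))
        event.append(bool(rec.event))
    if n_excluded:
        logger.info("cox_fit: excluded %d records with missing covariates", n_excluded)
    X = np.asarray(X_rows, dtype=float)
    time = np.asarray(time)
    event = np.asarray(event, dtype=bool)
    n = len(time)
    if n == 0 or X.ndim != 2 or X.shape[1] != len(names):
        raise ValueError("no complete records to fit")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events: the partial likelihood is constant")

    center = X.mean(axis=0)
    scale = X.std(axis=0)
    if np.any(scale == 0):
        const = [nm for nm, s in zip(names, scale) if s == 0]
        raise ValueError(f"rank-deficient design: constant covariate(s) {const}")
    Z = (X - center) / scale
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("rank-deficient design: collinear covariates")

    beta = np.zeros(len(names))
    ll, grad, info = _newton_terms(beta, Z, time, event)
    ll_null = _partial_loglik(np.zeros(len(names)), Z, time, event)
    converged = False
    diagnostic = ""
    for _ in range(_MAX_ITER):
        if np.linalg.norm(grad, ord=np.inf) < _GRAD_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            diagnostic = "singular information matrix"
            break
        # step-halving to ensure the likelihood never decreases
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = _partial_loglik(cand, Z, time, event)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        ll, grad, info = _newton_terms(beta, Z, time, event)
        if np.linalg.norm(beta, ord=np.inf) > 1e3:
            diagnostic = "monotone likelihood (separation?)"
            break
    else:
        diagnostic = "no convergence in 50 iterations"
    if not converged and not diagnostic:
        diagnostic = "no convergence in 50 iterations"

    cov_std = np.linalg.inv(info)
    beta_orig = beta / scale
    se_orig = np.sqrt(np.diag(cov_std)) / scale
    zstat = beta_orig / se_orig
    pval = 2.0 * norm.sf(np.abs(zstat))
    return CoxFit(
        covariate_names=names,
        beta=beta_orig,
        se=se_orig,
        z=zstat,
        p=pval,
        loglik=float(ll),
        loglik_null=float(ll_null),
        converged=converged,
        n=n,
        n_events=n_events,
        n_excluded=n_excluded,
        diagnostic=diagnostic,
    )


def _partial_loglik(beta, X, time, event) -> float:
    ll, _, _ = _newton_terms(beta, X, time, event, hess=False)
    return ll


def _newton_terms(beta, X, time, event, hess=True):
    """Breslow partial log-likelihood, gradient and observed information.

    Risk sets are nested in descending time order, so the S0/S1/S2 sums of
    the Breslow terms are cumulative sums evaluated at each distinct event
    time (ties share the full risk set).
    """
    n, p = X.shape
    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    w = np.exp(eta)

    # last cumulative index of every tied-time block
    change = np.flatnonzero(ts[1:] != ts[:-1])
    ends = np.concatenate((change, [n - 1]))
    starts = np.concatenate(([0], change + 1))

    S0 = np.cumsum(w)[ends]
    S1 = np.cumsum(w[:, None] * Xs, axis=0)[ends]
    d = np.add.reduceat(es.astype(float), starts)
    has_ev = d > 0
    if not np.any(has_ev):
        return 0.0, np.zeros(p), np.zeros((p, p))

    d_ev, s0_ev, s1_ev = d[has_ev], S0[has_ev], S1[has_ev]
    ll = float(eta[es].sum() - d_ev @ np.log(s0_ev))
    xd_sums = np.add.reduceat((es[:, None] * Xs), starts, axis=0)[has_ev]
    m = s1_ev / s0_ev[:, None]
    grad = xd_sums.sum(axis=0) - d_ev @ m
    info = np.zeros((p, p))
    if hess:
        S2 = np.cumsum(np.einsum("i,ij,ik->ijk", w, Xs, Xs), axis=0)[ends]
        s2_ev = S2[has_ev]
        info = np.einsum("b,bjk->jk", d_ev, s2_ev / s0_ev[:, None, None])
        info -= np.einsum("b,bj,bk->jk", d_ev, m, m)
    return ll, grad, info


def hazard_ratio_per(fit: CoxFit, covariate: str, delta: float) -> float:
    """Hazard ratio for a ``delta``-unit increase in one covariate:
    exp(beta * delta)."""
    if covariate not in fit.covariate_names:
        raise KeyError(f"unknown covariate {covariate!r}")
    return float(np.exp(fit[covariate] * delta))


def incidence_rate(
    n_events: int, n_patients: int, mean_followup_years: float
) -> float:
    """Crude incidence, events per 1000 patient-years."""
    if n_patients <= 0 or mean_followup_years <= 0:
        raise ValueError("patient-time denominator must be positive")
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    return 1000.0 * n_events / (n_patients * mean_followup_years)
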