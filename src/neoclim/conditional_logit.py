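"""Conditional logistic regression on matched sets, and AIC model selection.

With exactly one case per matched set the exact conditional likelihood is

    l(beta) = sum_sets [ eta_case - log sum_{j in set} exp(eta_j) ],
    eta_j = x_j · beta,

i.e. a per-set softmax of the linear predictor.  It is maximised by Newton
iterations with step-halving; the covariance is the inverse observed
information at the optimum.  Since every death forms its own set there is no
within-set multi-case tie ambiguity (no Efron/Breslow choice to make).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dlnm import CrossBasisSpec, cross_basis_matrix

log = logging.getLogger(__name__)

__all__ = ["FitResult", "fit", "null_loglik", "aic_select", "SelectionResult"]


class SeparationError(RuntimeError):
    """The conditional likelihood has no finite maximiser."""


class UninformativeError(ValueError):
    """Every matched set has case covariates identical to all its controls."""


@dataclass
class FitResult:
    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    aic: float
    n_sets: int
    n_iter: int
    grad_norm: float
    converged: bool


def _prepare(X, set_ids, is_case):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    set_ids = np.asarray(set_ids)
    is_case = np.asarray(is_case).astype(bool)
    order = np.lexsort((~is_case, set_ids))  # sets contiguous, case row first
    X, set_ids, is_case = X[order], set_ids[order], is_case[order]
    starts = np.flatnonzero(np.r_[True, set_ids[1:] != set_ids[:-1]])
    sizes = np.diff(np.append(starts, len(set_ids)))
    case_rows = starts  # after the lexsort the case row leads each set
    if not is_case[case_rows].all() or is_case.sum() != len(starts):
        raise ValueError("each matched set must contain exactly one case")
    return X, starts, sizes, case_rows


def _loglik_parts(X, beta, starts, sizes, case_rows):
    eta = X @ beta
    # per-set logsumexp, numerically shifted by the set max
    set_of = np.repeat(np.arange(len(starts)), sizes)
    m = np.full(len(starts), -np.inf)
    np.maximum.at(m, set_of, eta)
    z = np.exp(eta - m[set_of])
    denom = np.zeros(len(starts))
    np.add.at(denom, set_of, z)
    lse = m + np.log(denom)
    ll = float(np.sum(eta[case_rows] - lse))
    p = z / denom[set_of]  # conditional probabilities within each set
    # score: sum over sets of (x_case - E[x])
    mu = np.zeros((len(starts), X.shape[1]))
    np.add.at(mu, set_of, p[:, None] * X)
    grad = X[case_rows].sum(axis=0) - mu.sum(axis=0)
    # observed information: sum over sets of Cov[x] under p
    A = X.T @ (p[:, None] * X)
    info = A - mu.T @ mu
    return ll, grad, info


def null_loglik(set_sizes) -> float:
    """Conditional log-likelihood at beta = 0: -sum log(set size)."""
    return float(-np.sum(np.log(np.asarray(set_sizes, dtype=float))))


def fit(X, set_ids, is_case, *, max_iter: int = 100, tol_ll: float = 1e-10,
        tol_grad: float = 1e-6, beta_cap: float = 50.0) -> FitResult:
    """Maximise the exact conditional likelihood.

    Raises
    ------
    UninformativeError
        If in every set the case covariate row equals all control rows
        (zero conditional information; the likelihood is flat).
    SeparationError
        If any coefficient runs past ``beta_cap`` while the likelihood is
        still increasing — the hallmark of complete separation, where no
        finite MLE exists.
    """
    X, starts, sizes, case_rows = _prepare(X, set_ids, is_case)
    k = X.shape[1]

    set_of = np.repeat(np.arange(len(starts)), sizes)
    spread = np.abs(X - X[case_rows][set_of]).max(axis=1)
    informative = np.zeros(len(starts))
    np.maximum.at(informative, set_of, spread)
    if (informative < 1e-12).all():
        raise UninformativeError("all matched sets are uninformative (case equals controls)")

    beta = np.zeros(k)
    ll, grad, info = _loglik_parts(X, beta, starts, sizes, case_rows)
    ev = np.linalg.eigvalsh((info + info.T) / 2.0)
    if ev.min() < 1e-10 * max(ev.max(), 1.0):
        raise np.linalg.LinAlgError("singular design: collinear cross-basis columns")
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info + 1e-8 * np.eye(k), grad, rcond=None)[0]
        scale = 1.0
        while scale > 1e-8:
            cand = beta + scale * step
            ll_new, grad_new, info_new = _loglik_parts(X, cand, starts, sizes, case_rows)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        improved = ll_new > ll
        rel = abs(ll_new - ll) / max(1.0, abs(ll_new))
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if improved and np.max(np.abs(beta)) > beta_cap:
            raise SeparationError("no finite MLE: coefficients diverging (complete separation)")
        if rel < tol_ll and np.max(np.abs(grad)) < tol_grad:
            break
    # complete separation: every case's conditional probability is ~1, the
    # likelihood supremum (0) is approached but never attained
    eta = X @ beta
    set_of = np.repeat(np.arange(len(starts)), sizes)
    m = np.full(len(starts), -np.inf)
    np.maximum.at(m, set_of, eta)
    denom = np.zeros(len(starts))
    np.add.at(denom, set_of, np.exp(eta - m[set_of]))
    p_case = np.exp(eta[case_rows] - m - np.log(denom))
    if p_case.min() > 1.0 - 1e-4:
        raise SeparationError("no finite MLE: data perfectly separated")
    grad_norm = float(np.max(np.abs(grad)))
    converged = grad_norm < tol_grad
    if not converged:
        log.warning("conditional logit did not fully converge: |grad|=%.3g after %d iter", grad_norm, n_iter)
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(info)
    vcov = (vcov + vcov.T) / 2.0
    aic = 2.0 * k - 2.0 * ll
    return FitResult(beta=beta, vcov=vcov, loglik=ll, aic=aic, n_sets=len(starts),
                     n_iter=n_iter, grad_norm=grad_norm, converged=converged)


@dataclass
class SelectionResult:
    best_spec: CrossBasisSpec
    best_fit: FitResult
    table: "object"  # pandas DataFrame: one row per candidate


def aic_select(candidates, exposures, set_ids, is_case, **fit_kwargs) -> SelectionResult:
    """Fit every candidate cross-basis spec and keep the lowest AIC.

    Candidates that fail (separation, singular design from a knot outside the
    data span, ...) are skipped with a log entry.  Exact AIC ties resolve to
    the earliest candidate in the list.
    """
    import pandas as pd

    rows = []
    best = None
    for i, spec in enumerate(candidates):
        try:
            Xc = cross_basis_matrix(exposures, spec)
            res = fit(Xc, set_ids, is_case, **fit_kwargs)
        except Exception as exc:  # noqa: BLE001 — candidate failures are not fatal
            log.warning("candidate %d (%s) skipped: %s", i, spec.label(), exc)
            rows.append({"candidate": i, "spec": spec.label(), "df": spec.ncoef,
                         "loglik": np.nan, "aic": np.nan, "status": f"skipped: {exc}"})
            continue
        rows.append({"candidate": i, "spec": spec.label(), "df": spec.ncoef,
                     "loglik": res.loglik, "aic": res.aic, "status": "ok"})
        if best is None or res.aic < best[1].aic:
            best = (spec, res)
    if best is None:
        raise RuntimeError("all candidate specs failed to fit")
    return SelectionResult(best_spec=best[0], best_fit=best[1], table=pd.DataFrame(rows))
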