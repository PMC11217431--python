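"""Distributed lag non-linear model (DLNM) cross-basis and risk prediction.

The exposure-lag-response surface is parameterised by a tensor product of two
natural cubic spline bases: one over the exposure dimension (temperature
percentile, 0–100) and one over the lag dimension (days 0..L).  For a case at
time t with lagged exposures x_{t-l0},...,x_{t-L}, the model covariate row is

    w_{ij} = sum_l  N_var(x_{t-l})_i * N_lag(l)_j ,

whose coefficients beta_{ij} (log odds-ratio scale, estimated by conditional
logistic regression) jointly encode the non-linear and delayed temperature
effect.  Cumulative relative risks on a percentile grid are obtained from the
contrast between the cross-basis row of a constant exposure p and that of the
reference percentile; the minimum-mortality temperature (MMT, x0) is the grid
argmin of that cumulative curve and becomes the reference for all reported
risks and attribution contrasts.

Natural cubic splines follow the textbook construction: a cubic B-spline basis
on the given interior/boundary knots, projected onto the subspace whose second
derivative vanishes at both boundary knots, and extended *linearly* beyond
them (first-order Taylor expansion at the boundary — the defining "natural"
behaviour).  df = #interior_knots + 1 (+1 with intercept).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import BSpline

from .exposure import LagSpec

__all__ = [
    "SplineSpec", "CrossBasisSpec", "ExposureResponseModel",
    "ns_basis", "cross_basis_row", "cross_basis_matrix",
    "cumulative_rr", "find_mmt", "lag_contributions", "default_lag_spline",
]


@dataclass(frozen=True)
class SplineSpec:
    """Natural cubic spline specification for one cross-basis dimension."""

    internal_knots: tuple
    boundary: tuple
    intercept: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        ks = tuple(float(k) for k in self.internal_knots)
        if any(not (lo < k < hi) for k in ks):
            raise ValueError(f"internal knots {ks} not strictly inside boundary {self.boundary}")
        if list(ks) != sorted(ks):
            raise ValueError("internal knots must be sorted")
        object.__setattr__(self, "internal_knots", ks)
        object.__setattr__(self, "boundary", (float(lo), float(hi)))

    @property
    def df(self) -> int:
        return len(self.internal_knots) + 1 + int(self.intercept)


def default_lag_spline(lag: LagSpec) -> SplineSpec | None:
    """Lag-dimension spline: one interior knot at the mid log-lag, intercept on.

    For the default 0–2-day window this places the knot at exp(mean(log 1,
    log 2)) = sqrt(2) ≈ 1.414, the standard log-knot construction for short
    lag windows.  A degenerate window (L == l0) gets a constant lag basis.
    """
    if lag.L == lag.l0:
        return None
    knot = math.exp((math.log(max(lag.l0, 1)) + math.log(lag.L)) / 2.0)
    return SplineSpec(internal_knots=(knot,), boundary=(float(lag.l0), float(lag.L)), intercept=True)


def ns_basis(x, spec: SplineSpec) -> np.ndarray:
    """Natural cubic spline basis matrix, one row per value of ``x``.

    Linear (not cubic) beyond the boundary knots; second derivative of every
    column is zero at both boundaries.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lo, hi = spec.boundary
    t = np.concatenate([[lo] * 4, spec.internal_knots, [hi] * 4])
    m = len(spec.internal_knots) + 4
    spl = BSpline(t, np.eye(m), 3, extrapolate=True)
    inside = np.clip(x, lo, hi)
    B = spl(inside)
    d1 = spl.derivative(1)
    below, above = x < lo, x > hi
    if below.any():
        B[below] = spl(np.array(lo)) + np.outer(x[below] - lo, d1(np.array(lo)))
    if above.any():
        B[above] = spl(np.array(hi)) + np.outer(x[above] - hi, d1(np.array(hi)))
    d2 = spl.derivative(2)
    const = np.vstack([d2(np.array(lo)), d2(np.array(hi))])  # (2, m)
    if not spec.intercept:
        B = B[:, 1:]
        const = const[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    return B @ q[:, 2:]


@dataclass(frozen=True)
class CrossBasisSpec:
    """Tensor-product cross-basis: exposure spline x lag spline.

    ``lag_spline`` defaults to the log-knot spline of :func:`default_lag_spline`;
    pass ``None`` explicitly for a single constant lag column (the cross-basis
    then collapses to the summed exposure basis over lags — the moving-average
    special case).
    """

    var_spline: SplineSpec
    lag: LagSpec = LagSpec()
    lag_spline: SplineSpec | None = field(default="auto")

    def __post_init__(self) -> None:
        if isinstance(self.lag_spline, str):
            object.__setattr__(self, "lag_spline", default_lag_spline(self.lag))

    @property
    def df_var(self) -> int:
        return self.var_spline.df

    @property
    def df_lag(self) -> int:
        return 1 if self.lag_spline is None else self.lag_spline.df

    @property
    def ncoef(self) -> int:
        return self.df_var * self.df_lag

    def lag_basis(self) -> np.ndarray:
        """(n_lags, df_lag) lag basis evaluated at the integer lags."""
        if self.lag_spline is None:
            return np.ones((self.lag.n_lags, 1))
        return ns_basis(self.lag.lags.astype(float), self.lag_spline)

    def label(self) -> str:
        ks = ",".join(f"{k:g}" for k in self.var_spline.internal_knots)
        return f"var_knots=({ks}) lag={self.lag.l0}-{self.lag.L}"


def cross_basis_matrix(exposures: np.ndarray, spec: CrossBasisSpec, center: float | None = None) -> np.ndarray:
    """Cross-basis rows for a stack of lagged exposure vectors.

    Parameters
    ----------
    exposures : (n, n_lags) array
        Row r holds (x_{t-l0}, ..., x_{t-L}) for observation r.
    center : optional percentile
        If given, the row of a constant exposure at ``center`` is subtracted,
        so a constant exposure at the center maps to the zero vector.
    """
    E = np.atleast_2d(np.asarray(exposures, dtype=float))
    if E.shape[1] != spec.lag.n_lags:
        raise ValueError(f"exposure vectors have length {E.shape[1]}, expected {spec.lag.n_lags}")
    V = ns_basis(E.ravel(), spec.var_spline).reshape(E.shape[0], E.shape[1], spec.df_var)
    R = spec.lag_basis()  # (n_lags, df_lag)
    X = np.einsum("nli,lj->nij", V, R).reshape(E.shape[0], spec.ncoef)
    if center is not None:
        X = X - cross_basis_matrix(np.full((1, spec.lag.n_lags), float(center)), spec)
    return X


def cross_basis_row(exposure_vec, spec: CrossBasisSpec, center: float | None = None) -> np.ndarray:
    """Single cross-basis covariate row for one lagged exposure vector."""
    return cross_basis_matrix(np.asarray(exposure_vec, dtype=float)[None, :], spec, center=center)[0]


def _constant_rows(grid, spec: CrossBasisSpec) -> np.ndarray:
    """Cross-basis rows C(p) for constant exposure p across all lags."""
    g = np.atleast_1d(np.asarray(grid, dtype=float))
    E = np.repeat(g[:, None], spec.lag.n_lags, axis=1)
    return cross_basis_matrix(E, spec)


@dataclass
class ExposureResponseModel:
    """Fitted cross-basis model: coefficients, covariance and reference MMT."""

    spec: CrossBasisSpec
    beta: np.ndarray
    vcov: np.ndarray
    mmt: float | None = None
    loglik: float = float("nan")
    aic: float = float("nan")
    outcome: str = "neonatal"
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.vcov = np.asarray(self.vcov, dtype=float)
        k = self.spec.ncoef
        if self.beta.size != k or self.vcov.shape != (k, k):
            raise ValueError("beta/vcov dimensions do not match the cross-basis spec")

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        d = {
            "var_spline": {"internal_knots": list(self.spec.var_spline.internal_knots),
                           "boundary": list(self.spec.var_spline.boundary),
                           "intercept": self.spec.var_spline.intercept},
            "lag_spline": None if self.spec.lag_spline is None else
                          {"internal_knots": list(self.spec.lag_spline.internal_knots),
                           "boundary": list(self.spec.lag_spline.boundary),
                           "intercept": self.spec.lag_spline.intercept},
            "lag": {"l0": self.spec.lag.l0, "L": self.spec.lag.L},
            "beta": self.beta.tolist(), "vcov": self.vcov.tolist(),
            "mmt": self.mmt, "loglik": self.loglik, "aic": self.aic,
            "outcome": self.outcome, "dataset_id": self.dataset_id,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ExposureResponseModel":
        p = Path(source)
        d = json.loads(p.read_text() if p.exists() else source)
        var = SplineSpec(tuple(d["var_spline"]["internal_knots"]), tuple(d["var_spline"]["boundary"]),
                         d["var_spline"]["intercept"])
        lagsp = d["lag_spline"]
        lag_spline = None if lagsp is None else SplineSpec(tuple(lagsp["internal_knots"]),
                                                           tuple(lagsp["boundary"]), lagsp["intercept"])
        spec = CrossBasisSpec(var, LagSpec(d["lag"]["l0"], d["lag"]["L"]), lag_spline)
        return cls(spec, np.array(d["beta"]), np.array(d["vcov"]), d["mmt"],
                   d["loglik"], d["aic"], d["outcome"], d["dataset_id"])


def cumulative_rr(model: ExposureResponseModel, grid, center: float | None = None) -> "pd.DataFrame":
    """Cumulative (over lags) relative risk on a percentile grid with 95% CI.

    log RR(p) = (C(p) - C(center)) · beta, where C(p) is the cross-basis row
    of constant exposure p; the pointwise CI uses the delta-method SE from the
    coefficient covariance through the same contrast.
    """
    import pandas as pd

    if center is None:
        center = model.mmt
    if center is None:
        raise ValueError("no center given and model has no MMT")
    g = np.atleast_1d(np.asarray(grid, dtype=float))
    contrast = _constant_rows(g, model.spec) - _constant_rows([center], model.spec)
    logrr = contrast @ model.beta
    se = np.sqrt(np.maximum(np.einsum("ni,ij,nj->n", contrast, model.vcov, contrast), 0.0))
    return pd.DataFrame({
        "percentile": g,
        "rr": np.exp(logrr),
        "lo": np.exp(logrr - 1.96 * se),
        "hi": np.exp(logrr + 1.96 * se),
        "logrr": logrr,
        "se": se,
        "centered_at": float(center),
    })


def find_mmt(model: ExposureResponseModel, step: float = 0.1, bounds: tuple = (1.0, 99.0)) -> float:
    """Locate the minimum-mortality percentile by grid search.

    The argmin of the cumulative log RR does not depend on the centering used
    during fitting (re-centering shifts the whole curve by a constant).  Ties
    resolve to the lowest percentile.  The model's ``mmt`` is updated in place
    and subsequent predictions re-center there.
    """
    lo, hi = bounds
    grid = np.arange(lo, hi + step / 2, step)
    logrr = _constant_rows(grid, model.spec) @ model.beta
    mmt = float(grid[int(np.argmin(logrr))])
    model.mmt = mmt
    return mmt


def lag_contributions(model: ExposureResponseModel, exposures: np.ndarray) -> np.ndarray:
    """Per-lag log-RR contributions relative to the model's MMT.

    Returns an (n, n_lags) array whose row sums equal the cumulative log RR of
    Eq.-style backward attribution: contribution of lag l is
    (N_var(x_{t-l}) - N_var(x0)) ⊗ N_lag(l) · beta.
    """
    if model.mmt is None:
        raise ValueError("model has no MMT; run find_mmt first")
    spec = model.spec
    E = np.atleast_2d(np.asarray(exposures, dtype=float))
    V = ns_basis(E.ravel(), spec.var_spline).reshape(E.shape[0], E.shape[1], spec.df_var)
    V0 = ns_basis(np.array([model.mmt]), spec.var_spline)[0]  # (df_var,)
    Bmat = model.beta.reshape(spec.df_var, spec.df_lag)
    W = Bmat @ spec.lag_basis().T  # (df_var, n_lags)
    return np.einsum("nli,il->nl", V - V0[None, None, :], W)


def recenter(model: ExposureResponseModel, mmt: float) -> ExposureResponseModel:
    """Copy of the model with a different reference percentile."""
    return ExposureResponseModel(
        model.spec, model.beta.copy(), model.vcov.copy(), mmt,
        model.loglik, model.aic, model.outcome, model.dataset_id)
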