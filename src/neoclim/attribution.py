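"""Backward attributable fractions and climate-change excess burdens.

For a case at time t with lagged exposures x_{t-l0},...,x_{t-L}, the
attributable fraction from the backward perspective is

    AF_{x,t} = 1 - exp( - sum_{l=l0}^{L} beta_{x_{t-l}, l} ),

where beta_{x,l} is the lag-l log odds-ratio of exposure x relative to the
minimum-mortality percentile x0.  Summing AFs over cases gives the
attributable number (AN); dividing by the number of cases gives the
population attributable fraction.  The same cases are evaluated under the
factual and the counterfactual exposure series (only the exposures change);
their difference is the burden attributable to climate change, and Eq.-style
rates follow as AR = m_neonat * AF_CC.

Heat/cold separation zeroes, inside the exponent, the lag contributions whose
exposure falls on the other side of x0 (the convention of the backward-AF
literature).  That makes heat + cold = total *exactly* when all of a case's
lagged exposures lie on one side; in mixed cases the second-order discrepancy
is reported (``side_gap``), not hidden.  The six severity ranges
(extreme/moderate/mild cold and hot, cut at the 2.5th/25th/x0/75th/97.5th
percentiles) partition each side's AF by linear allocation proportional to
each range's share of the side's retained log-RR sum, so ranges sum to their
side exactly by construction.

Uncertainty: coefficients are drawn from MVN(beta_hat, vcov) per fitted
dataset, burdens recomputed per draw, draws pooled across datasets; point
estimates are means over all draws and intervals are empirical 2.5th/97.5th
percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dlnm import ExposureResponseModel, lag_contributions

__all__ = [
    "RANGE_LABELS", "CaseAttribution", "BurdenResult", "ExcessResult",
    "case_af", "scenario_burden", "climate_excess", "attributable_rate", "monte_carlo_ui",
]

RANGE_LABELS = ("extreme_cold", "moderate_cold", "mild_cold", "mild_heat", "moderate_heat", "extreme_heat")
SIDE_OF_RANGE = {"extreme_cold": "cold", "moderate_cold": "cold", "mild_cold": "cold",
                 "mild_heat": "heat", "moderate_heat": "heat", "extreme_heat": "heat"}
RANGE_CUTS = (2.5, 25.0, 75.0, 97.5)


def _range_codes(exposures: np.ndarray, mmt: float) -> np.ndarray:
    """Severity-range index (into RANGE_LABELS) of each lagged exposure."""
    e = np.asarray(exposures, dtype=float)
    edges = np.array([RANGE_CUTS[0], RANGE_CUTS[1], mmt, RANGE_CUTS[2], RANGE_CUTS[3]])
    return np.searchsorted(edges, e, side="left")


@dataclass
class CaseAttribution:
    """Attributable fraction of one case, with its per-lag contributions."""

    af: float
    contributions: np.ndarray
    retained: np.ndarray  # boolean mask of lags kept under the restriction
    restrict: str = "all"


def case_af(model: ExposureResponseModel, exposure_vec, restrict: str = "all") -> CaseAttribution:
    """Backward AF of a single case; ``restrict`` ∈ {"all","heat","cold"} ∪ ranges."""
    x = np.asarray(exposure_vec, dtype=float)
    contrib = lag_contributions(model, x[None, :])[0]
    if restrict == "all":
        mask = np.ones_like(x, dtype=bool)
    elif restrict == "heat":
        mask = x > model.mmt
    elif restrict == "cold":
        mask = x < model.mmt
    elif restrict in RANGE_LABELS:
        mask = _range_codes(x, model.mmt) == RANGE_LABELS.index(restrict)
    else:
        raise ValueError(f"unknown restriction {restrict!r}")
    af = 1.0 - np.exp(-float(contrib[mask].sum()))
    return CaseAttribution(af=af, contributions=contrib, retained=mask, restrict=restrict)


@dataclass
class BurdenResult:
    """Attributable burden of one scenario for one fitted model."""

    scope: str
    outcome: str
    dataset_id: str
    scenario: str
    n_cases: int
    an: float
    af: float
    heat_an: float
    heat_af: float
    cold_an: float
    cold_af: float
    side_gap: float  # |heat + cold - total| summed signed discrepancy
    by_range: dict = field(default_factory=dict)

    def matches_scope(self, other: "BurdenResult") -> bool:
        return (self.scope, self.outcome, self.dataset_id) == (other.scope, other.outcome, other.dataset_id)


def _burden_sums(contrib: np.ndarray, heat_mask: np.ndarray, cold_mask: np.ndarray):
    """(AN_total, AN_heat, AN_cold) from per-lag contributions and side masks."""
    total = 1.0 - np.exp(-contrib.sum(axis=1))
    heat = 1.0 - np.exp(-np.where(heat_mask, contrib, 0.0).sum(axis=1))
    cold = 1.0 - np.exp(-np.where(cold_mask, contrib, 0.0).sum(axis=1))
    return float(total.sum()), float(heat.sum()), float(cold.sum())


def scenario_burden(model: ExposureResponseModel, exposures: np.ndarray, *, scope: str = "pooled",
                    scenario: str = "factual", with_ranges: bool = True) -> BurdenResult:
    """Sum case-level backward AFs over all cases of one scenario.

    ``exposures`` is the (n_cases, n_lags) matrix of that scenario's lagged
    percentiles for the *same* case set used under the other scenario.
    """
    E = np.atleast_2d(np.asarray(exposures, dtype=float))
    n = E.shape[0]
    contrib = lag_contributions(model, E)
    heat_mask = E > model.mmt
    cold_mask = E < model.mmt
    an, heat_an, cold_an = _burden_sums(contrib, heat_mask, cold_mask)
    gap = float(heat_an + cold_an - an)

    by_range: dict = {}
    if with_ranges:
        codes = _range_codes(E, model.mmt)
        for side, side_mask in (("heat", heat_mask), ("cold", cold_mask)):
            side_sum = np.where(side_mask, contrib, 0.0).sum(axis=1)
            side_af = 1.0 - np.exp(-side_sum)
            safe = np.where(side_sum == 0.0, 1.0, side_sum)
            for label in RANGE_LABELS:
                if SIDE_OF_RANGE[label] != side:
                    continue
                in_range = side_mask & (codes == RANGE_LABELS.index(label))
                range_sum = np.where(in_range, contrib, 0.0).sum(axis=1)
                share = np.where(side_sum == 0.0, 0.0, range_sum / safe)
                by_range[label] = float((side_af * share).sum())

    return BurdenResult(
        scope=scope, outcome=model.outcome, dataset_id=model.dataset_id, scenario=scenario,
        n_cases=n, an=an, af=an / n if n else 0.0,
        heat_an=heat_an, heat_af=heat_an / n if n else 0.0,
        cold_an=cold_an, cold_af=cold_an / n if n else 0.0,
        side_gap=gap, by_range=by_range,
    )


@dataclass
class ExcessResult:
    """Climate-change excess: factual minus counterfactual burden."""

    scope: str
    outcome: str
    dataset_id: str
    n_cases: int
    excess_an: float
    excess_af: float
    heat_excess_an: float
    heat_excess_af: float
    cold_excess_an: float
    cold_excess_af: float
    heat_share_of_factual: float   # fraction of factual heat burden due to climate change
    cold_reduction_share: float    # fraction of counterfactual cold burden averted
    by_range_excess: dict = field(default_factory=dict)


def climate_excess(factual: BurdenResult, counterfactual: BurdenResult) -> ExcessResult:
    """Difference the scenarios; proportional statements relative to Eq.-style baselines."""
    if not factual.matches_scope(counterfactual):
        raise ValueError("scope mismatch between factual and counterfactual burdens")
    if factual.n_cases != counterfactual.n_cases:
        raise ValueError("factual and counterfactual must cover the same case set")
    heat_excess = factual.heat_an - counterfactual.heat_an
    cold_excess = factual.cold_an - counterfactual.cold_an
    by_range = {k: factual.by_range[k] - counterfactual.by_range.get(k, 0.0)
                for k in factual.by_range}
    return ExcessResult(
        scope=factual.scope, outcome=factual.outcome, dataset_id=factual.dataset_id,
        n_cases=factual.n_cases,
        excess_an=factual.an - counterfactual.an,
        excess_af=factual.af - counterfactual.af,
        heat_excess_an=heat_excess,
        heat_excess_af=factual.heat_af - counterfactual.heat_af,
        cold_excess_an=cold_excess,
        cold_excess_af=factual.cold_af - counterfactual.cold_af,
        heat_share_of_factual=heat_excess / factual.heat_an if factual.heat_an else 0.0,
        cold_reduction_share=-cold_excess / counterfactual.cold_an if counterfactual.cold_an else 0.0,
        by_range_excess=by_range,
    )


def attributable_rate(af_cc: float, rates: pd.DataFrame, country: str, outcome: str = "neonatal") -> float:
    """AR per 100,000 live births: m_neonat * AF_CC (very-early uses its share of m)."""
    row = rates.loc[rates["country"] == country]
    if row.empty:
        raise KeyError(f"country {country!r} not in rate table")
    m = float(row["m_neonat"].iloc[0])
    if outcome == "very_early":
        m *= float(row["very_early_share"].iloc[0])
    elif outcome != "neonatal":
        raise ValueError(f"unknown outcome {outcome!r}")
    return m * af_cc


# ---------------------------------------------------------------------------
# Monte Carlo uncertainty
# ---------------------------------------------------------------------------

def _psd_cholesky(vcov: np.ndarray, tol: float = 1e-10):
    """Cholesky-like factor of a symmetric PSD matrix, repairing tiny negatives."""
    v = np.asarray(vcov, dtype=float)
    v = (v + v.T) / 2.0
    w, q = np.linalg.eigh(v)
    scale = max(w.max(), 1.0)
    if w.min() < -tol * scale:
        raise ValueError(f"covariance is not positive semi-definite (min eigenvalue {w.min():.3g})")
    return q * np.sqrt(np.clip(w, 0.0, None))


def _contrib_tensor(model: ExposureResponseModel, exposures: np.ndarray) -> np.ndarray:
    """(n, n_lags, k) tensor T with beta · T[n, l] = lag-l log-RR contribution."""
    from .dlnm import ns_basis

    spec = model.spec
    E = np.atleast_2d(np.asarray(exposures, dtype=float))
    V = ns_basis(E.ravel(), spec.var_spline).reshape(E.shape[0], E.shape[1], spec.df_var)
    V0 = ns_basis(np.array([model.mmt]), spec.var_spline)[0]
    R = spec.lag_basis()  # (n_lags, df_lag)
    return np.einsum("nli,lj->nlij", V - V0[None, None, :], R).reshape(E.shape[0], E.shape[1], spec.ncoef)


def _design_matrices(model, exposures):
    """G matrices (n, k) such that AN(beta) = sum(1 - exp(-G @ beta)) per restriction."""
    E = np.atleast_2d(np.asarray(exposures, dtype=float))
    T = _contrib_tensor(model, E)
    heat = (E > model.mmt)[..., None]
    cold = (E < model.mmt)[..., None]
    return {
        "total": T.sum(axis=1),
        "heat": np.where(heat, T, 0.0).sum(axis=1),
        "cold": np.where(cold, T, 0.0).sum(axis=1),
    }


MC_QUANTITIES = (
    "af_total_factual", "af_heat_factual", "af_cold_factual",
    "excess_an_total", "excess_an_heat", "excess_an_cold",
    "excess_af_total", "excess_af_heat", "excess_af_cold",
    "heat_share_of_factual", "cold_reduction_share",
)


def monte_carlo_ui(datasets, n_draws: int = 10000, seed: int = 0, block: int = 200) -> pd.DataFrame:
    """Monte Carlo uncertainty for pooled attributable burdens.

    Parameters
    ----------
    datasets : sequence of (model, factual_exposures, counterfactual_exposures)
        One entry per fitted temperature dataset; draws are pooled across them
        with equal weight.
    n_draws : int
        Coefficient draws per dataset from MVN(beta_hat, vcov).
    seed : int
        Seeds the draws; same seed gives bit-identical results.

    Returns
    -------
    DataFrame indexed by quantity with columns point, lo, hi (empirical 2.5th
    and 97.5th percentiles across all pooled draws).
    """
    rng = np.random.default_rng(seed)
    pooled = {q: [] for q in MC_QUANTITIES}
    for model, fact_exp, cf_exp in datasets:
        L = _psd_cholesky(model.vcov)
        Gf = _design_matrices(model, fact_exp)
        Gc = _design_matrices(model, cf_exp)
        n = np.atleast_2d(fact_exp).shape[0]
        draws = {q: np.empty(n_draws) for q in MC_QUANTITIES}
        done = 0
        while done < n_draws:
            b = min(block, n_draws - done)
            Z = rng.standard_normal((b, model.beta.size))
            B = model.beta[None, :] + Z @ L.T  # (b, k)
            an_f = {r: (1.0 - np.exp(-Gf[r] @ B.T)).sum(axis=0) for r in ("total", "heat", "cold")}
            an_c = {r: (1.0 - np.exp(-Gc[r] @ B.T)).sum(axis=0) for r in ("total", "heat", "cold")}
            sl = slice(done, done + b)
            draws["af_total_factual"][sl] = an_f["total"] / n
            draws["af_heat_factual"][sl] = an_f["heat"] / n
            draws["af_cold_factual"][sl] = an_f["cold"] / n
            for r in ("total", "heat", "cold"):
                draws[f"excess_an_{r}"][sl] = an_f[r] - an_c[r]
                draws[f"excess_af_{r}"][sl] = (an_f[r] - an_c[r]) / n
            with np.errstate(divide="ignore", invalid="ignore"):
                hs = np.where(an_f["heat"] != 0.0, 1.0 - an_c["heat"] / an_f["heat"], 0.0)
                cr = np.where(an_c["cold"] != 0.0, 1.0 - an_f["cold"] / an_c["cold"], 0.0)
            draws["heat_share_of_factual"][sl] = hs
            draws["cold_reduction_share"][sl] = cr
            done += b
        for q in MC_QUANTITIES:
            pooled[q].append(draws[q])

    rows = []
    for q in MC_QUANTITIES:
        allq = np.concatenate(pooled[q])
        rows.append({"quantity": q, "point": float(allq.mean()),
                     "lo": float(np.percentile(allq, 2.5)), "hi": float(np.percentile(allq, 97.5))})
    return pd.DataFrame(rows).set_index("quantity")
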