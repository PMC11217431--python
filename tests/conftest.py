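import numpy as np
import pandas as pd
import pytest

from neoclim import dlnm, pipeline
from neoclim.exposure import LagSpec
from neoclim.synthetic_world import TrueExposureResponse, WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """Compact synthetic study: 2 locations, enough births for a few hundred deaths."""
    return generate_world(WorldConfig(n_locations=2, births_per_location=6000, seed=11))


@pytest.fixture(scope="session")
def fitted_run(tmp_path_factory):
    """Moderate end-to-end pipeline run shared by attribution/pipeline tests."""
    cfg = pipeline.RunConfig(
        simulate={"n_locations": 3, "births_per_location": 20000},
        n_draws=500, seed=42,
    )
    out = tmp_path_factory.mktemp("fitted_run")
    return cfg, pipeline.run(cfg, out)


def make_model(var_knots=(20.0,), beta=None, vcov_scale=0.0, mmt=50.0, lag=LagSpec(),
               target=None, seed=0):
    """Build an ExposureResponseModel directly, without fitting.

    If ``target`` is a callable log-RR curve, beta is the least-squares
    projection of that curve onto the cumulative cross-basis space (with a
    free intercept, since cumulative curves are only identified up to the
    centering contrast).
    """
    spec = dlnm.CrossBasisSpec(dlnm.SplineSpec(tuple(var_knots), (0.0, 100.0)), lag)
    if beta is None and target is not None:
        grid = np.linspace(0.5, 99.5, 199)
        C = dlnm.cross_basis_matrix(np.repeat(grid[:, None], lag.n_lags, axis=1), spec)
        C1 = np.column_stack([np.ones(len(grid)), C])
        beta = np.linalg.lstsq(C1, np.asarray(target(grid), dtype=float), rcond=None)[0][1:]
    elif beta is None:
        beta = np.random.default_rng(seed).normal(0.0, 0.1, spec.ncoef)
    beta = np.asarray(beta, dtype=float)
    vcov = vcov_scale * np.eye(spec.ncoef)
    model = dlnm.ExposureResponseModel(spec, beta, vcov, mmt=mmt)
    return model


@pytest.fixture()
def quadratic_model():
    """Model whose cumulative curve approximates a symmetric U with minimum at 50."""
    m = make_model(var_knots=(25.0, 75.0), target=lambda p: 0.3 * ((p - 50.0) / 50.0) ** 2)
    dlnm.find_mmt(m)
    return m


@pytest.fixture(scope="session")
def true_surface():
    return TrueExposureResponse()


def random_matched_sets(n_sets=50, n_lags=3, seed=0, beta=None, spec=None):
    """Matched sets with softmax-chosen cases; exposures uniform percentiles.

    If ``beta``/``spec`` are given the case is drawn from the exact conditional
    likelihood, otherwise uniformly.
    """
    rng = np.random.default_rng(seed)
    E, sids, case = [], [], []
    for s in range(n_sets):
        m = int(rng.integers(4, 6))
        ex = rng.uniform(0.0, 100.0, (m, n_lags))
        if beta is not None:
            eta = dlnm.cross_basis_matrix(ex, spec) @ beta
            p = np.exp(eta - eta.max())
            p /= p.sum()
            c = rng.choice(m, p=p)
        else:
            c = int(rng.integers(m))
        E.append(ex)
        sids.extend([s] * m)
        case.extend(int(j == c) for j in range(m))
    return np.vstack(E), np.asarray(sids), np.asarray(case)
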