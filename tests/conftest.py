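"""Shared fixtures: small crossed designs and the brute-force REML oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from resistqg.reml import MixedREML, _build_blocks, restricted_loglik


def direct_reml_oracle(
    y: np.ndarray,
    design: pd.DataFrame,
    factors: tuple[str, ...],
    n_grid: int = 4,
) -> tuple[np.ndarray, float]:
    """Maximize the restricted likelihood by grid seeding + Nelder-Mead.

    Independent of the EM path: it only shares the likelihood function,
    which itself is pinned by closed-form tests.  Works on log-variances
    with a hard floor standing in for the boundary.
    """
    y = np.asarray(y, float)
    model = MixedREML(y, np.ones((len(y), 1)), _build_blocks(design, factors))
    K = len(factors)
    s_y = float(np.var(y, ddof=1))

    def nll(log_theta: np.ndarray) -> float:
        theta = np.exp(log_theta)
        try:
            return -model.loglik(theta)
        except ValueError:
            return np.inf

    best = None
    rng = np.random.default_rng(0)
    seeds = [np.log(np.full(K + 1, s_y / (K + 1)))]
    for _ in range(n_grid):
        frac = rng.dirichlet(np.ones(K + 1))
        seeds.append(np.log(np.maximum(frac * s_y, 1e-10)))
    for s0 in seeds:
        res = minimize(
            nll,
            s0,
            method="Nelder-Mead",
            options={"maxiter": 6000, "xatol": 1e-9, "fatol": 1e-12},
        )
        # polish the winner from its own solution
        if best is None or res.fun < best.fun:
            best = res
    res = minimize(
        nll,
        best.x,
        method="Nelder-Mead",
        options={"maxiter": 6000, "xatol": 1e-10, "fatol": 1e-13},
    )
    if res.fun < best.fun:
        best = res
    theta = np.exp(best.x)
    # the floor stands in for exact zeros
    theta[theta < 1e-9 * theta.sum()] = 0.0
    return theta, -best.fun


@pytest.fixture(scope="session")
def crossed_design_20():
    """20-row design with 2 levels per factor and a known-seed response."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(20):
        rows.append((i % 2, (i // 2) % 2, (i // 4) % 2, (i // 8) % 2))
    design = pd.DataFrame(rows, columns=["dam", "sire", "block", "plant"])
    y = (
        rng.normal(0, 0.7, 2)[design["dam"]]
        + rng.normal(0, 0.5, 2)[design["sire"]]
        + rng.normal(0, 0.3, 2)[design["block"]]
        + rng.normal(0, 0.3, 2)[design["plant"]]
        + rng.normal(0, 0.6, 20)
    )
    return y, design


@pytest.fixture(scope="session")
def oneway_sire_fixture():
    """Balanced 3 sires x 4 observations with hand-computed ANOVA values.

    Sire means 4, 7, 10 and within-sire deviations (-2, 0, 0, 2):
    MS_between = 4 * ((4-7)^2 + 0 + (10-7)^2) / 2 = 36,
    MS_within  = 24 / 9 = 8/3,
    var_sire   = (36 - 8/3) / 4 = 25/3,  var_resid = 8/3.
    """
    y = np.array([2, 4, 4, 6, 5, 7, 7, 9, 8, 10, 10, 12], float)
    design = pd.DataFrame({"sire": np.repeat(["a", "b", "c"], 4)})
    return y, design, 25.0 / 3.0, 8.0 / 3.0
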