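"""Variance-component estimation: closed forms, oracle, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resistqg.reml import (
    MixedREML,
    _build_blocks,
    fit_reml,
    restricted_loglik,
    variance_shares,
)

from conftest import direct_reml_oracle

FACTORS4 = ("dam", "sire", "block", "plant")


def test_constant_response_gives_zero_variances():
    design = pd.DataFrame(
        {"dam": [0, 0, 1, 1], "sire": [0, 1, 0, 1], "block": 0, "plant": 0}
    )
    vc = fit_reml(np.full(4, 0.25), design)
    assert vc.degenerate and vc.converged
    assert all(v == 0.0 for v in vc.component_dict().values())


def test_balanced_oneway_matches_anova_closed_form(oneway_sire_fixture):
    y, design, var_sire_anova, var_resid_anova = oneway_sire_fixture
    vc = fit_reml(y, design, factors=("sire",))
    assert vc.converged
    assert vc.var_sire == pytest.approx(var_sire_anova, abs=1e-6)
    assert vc.var_resid == pytest.approx(var_resid_anova, abs=1e-6)


def test_em_matches_direct_likelihood_maximization(crossed_design_20):
    y, design = crossed_design_20
    vc = fit_reml(y, design)
    theta_oracle, ll_oracle = direct_reml_oracle(y, design, FACTORS4)
    est = np.array(
        [vc.var_dam, vc.var_sire, vc.var_block, vc.var_plant, vc.var_resid]
    )
    assert vc.loglik_restricted >= ll_oracle - 1e-6
    np.testing.assert_allclose(est, theta_oracle, atol=1e-4)


def test_plain_em_loglik_never_decreases(crossed_design_20):
    y, design = crossed_design_20
    model = MixedREML(y, np.ones((len(y), 1)), _build_blocks(design, FACTORS4))
    s_y = float(np.var(y, ddof=1))
    theta = np.array([s_y / 8] * 4 + [s_y / 2])
    lls = []
    for _ in range(300):
        theta, ll = model.em_step_ll(theta)
        lls.append(ll)
    assert np.all(np.diff(lls) >= -1e-9)


def test_accelerated_path_loglik_never_decreases(crossed_design_20):
    y, design = crossed_design_20
    vc = fit_reml(y, design)
    assert np.all(np.diff(vc.loglik_path) >= -1e-9)


def test_dense_and_mme_routes_agree(crossed_design_20):
    y, design = crossed_design_20
    model = MixedREML(y, np.ones((len(y), 1)), _build_blocks(design, FACTORS4))
    theta = np.array([0.4, 0.2, 0.1, 0.1, 0.3])
    assert model._loglik_dense(theta) == pytest.approx(
        model._loglik_mme(theta), abs=1e-9
    )
    dense, ll_d = model._em_step_dense(theta)
    mme, ll_m = model._em_step_mme(theta)
    np.testing.assert_allclose(dense, mme, atol=1e-12)
    assert ll_d == pytest.approx(ll_m, abs=1e-9)


def test_restricted_loglik_intercept_only_closed_form():
    # V = I, intercept only: ll = -(n-1)/2 log(2 pi) - 1/2 sum((y - ybar)^2)
    y = np.array([-1.0, 0.5, 0.5, -0.2, 0.2])
    y = y - y.mean()
    design = pd.DataFrame({"dam": [0, 1, 0, 1, 0]})
    params = {"dam": 0.0, "resid": 1.0}
    expected = -(len(y) - 1) / 2 * np.log(2 * np.pi) - 0.5 * float(y @ y)
    assert restricted_loglik(params, y, design, factors=("dam",)) == pytest.approx(
        expected, abs=1e-12
    )


@pytest.mark.parametrize("c", [0.3, 2.0, 17.5])
def test_restricted_loglik_scaling_shift(crossed_design_20, c):
    # scaling y by c and all variances by c^2 shifts ll by -(n-1) log c
    y, design = crossed_design_20
    params = {"dam": 0.4, "sire": 0.2, "block": 0.1, "plant": 0.1, "resid": 0.3}
    base = restricted_loglik(params, y, design)
    scaled = {k: v * c * c for k, v in params.items()}
    shifted = restricted_loglik(scaled, c * y, design)
    assert shifted == pytest.approx(base - (len(y) - 1) * np.log(c), abs=1e-9)


def test_fit_is_local_optimum(crossed_design_20):
    y, design = crossed_design_20
    vc = fit_reml(y, design)
    params = vc.component_dict()
    base = restricted_loglik(
        {**{k: params[k] for k in FACTORS4}, "resid": params["resid"]}, y, design
    )
    rng = np.random.default_rng(3)
    for _ in range(20):
        pert = {
            k: max(v + rng.normal(0, 0.02), 1e-8)
            for k, v in params.items()
        }
        ll = restricted_loglik(
            {**{k: pert[k] for k in FACTORS4}, "resid": pert["resid"]}, y, design
        )
        assert ll <= base + 1e-7


@pytest.mark.parametrize("c", [0.1, 3.0])
def test_scale_equivariance(crossed_design_20, c):
    y, design = crossed_design_20
    vc1 = fit_reml(y, design)
    vc2 = fit_reml(c * y, design)
    for name, value in vc1.component_dict().items():
        assert vc2.component_dict()[name] == pytest.approx(
            c * c * value, rel=1e-3, abs=1e-9
        )


def test_rank_deficient_fixed_design_raises(crossed_design_20):
    y, design = crossed_design_20
    X = np.column_stack([np.ones(len(y)), np.ones(len(y))])
    with pytest.raises(ValueError, match="rank-deficient"):
        fit_reml(y, design, X=X)


def test_single_level_everywhere_raises():
    design = pd.DataFrame({"dam": [0, 0, 0], "sire": 0, "block": 0, "plant": 0})
    with pytest.raises(ValueError, match="levels"):
        fit_reml(np.array([0.1, 0.2, 0.3]), design)


def test_singular_covariance_raises(crossed_design_20):
    y, design = crossed_design_20
    params = {k: 0.0 for k in FACTORS4} | {"resid": 0.0}
    with pytest.raises(ValueError, match="singular"):
        restricted_loglik(params, y, design)


class TestVarianceShares:
    def test_equal_components(self):
        shares = variance_shares(
            {"dam": 1, "sire": 1, "block": 1, "plant": 1, "resid": 1}
        )
        assert all(v == pytest.approx(20.0) for v in shares.values())

    @pytest.mark.parametrize("c", [1.0, 0.013, 47.0])
    def test_published_share_vector_scale_invariant(self, c):
        comps = {
            "dam": 0.45 * c,
            "sire": 0.13 * c,
            "block": 0.09 * c,
            "plant": 0.06 * c,
            "resid": 0.24 * c,
        }
        shares = variance_shares(comps)
        assert shares["dam"] == pytest.approx(45.0 / 0.97, rel=1e-12)
        assert sum(shares.values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_nonzero_component(self):
        shares = variance_shares({"dam": 0.0, "sire": 2.5, "resid": 0.0})
        assert shares["sire"] == pytest.approx(100.0)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="zero"):
            variance_shares({"dam": 0.0, "resid": 0.0})


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    s_dam=st.floats(0.0, 1.0),
    s_resid=st.floats(0.05, 1.0),
)
def test_reml_estimates_always_non_negative(seed, s_dam, s_resid):
    rng = np.random.default_rng(seed)
    design = pd.DataFrame(
        {"dam": np.arange(12) % 4, "sire": np.arange(12) % 3,
         "block": np.arange(12) % 2, "plant": np.arange(12) % 2}
    )
    y = (
        rng.normal(0, np.sqrt(s_dam), 4)[design["dam"]]
        + rng.normal(0, np.sqrt(s_resid), 12)
    )
    vc = fit_reml(y, design)
    assert all(v >= 0.0 for v in vc.component_dict().values())
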