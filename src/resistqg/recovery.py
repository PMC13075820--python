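"""Simulation protocols for estimator validation.

The half-sib recovery protocol targets a known narrow-sense heritability
on the scale the estimator actually sees.  Deaths are binomial, so the
observed family proportion carries sampling variance
E[p(1-p)/n] over and above the configured residual variance; the target
phenotypic variance is therefore decomposed as

    V_P = V_A + V_e_config + b,    b = expected binomial sampling variance,

with ``b`` computed in closed form (see
:func:`resistqg.simulate.expected_binomial_noise`) and V_e_config solved
so that V_A / V_P equals the requested truth.  Dominance variance is held
at a fixed non-boundary share of V_P (the truncated-at-zero dominance
estimate is biased when the truth sits on its boundary);
common-environment variance is zero, so the dam component carries
V_A/4 + V_D/2 exactly.
"""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig
from .glmm import fit_binomial_mixed
from .heritability import h2_pipeline
from .reml import fit_reml
from .simulate import (
    expected_binomial_noise,
    generate_design,
    simulate_family_effects,
    simulate_survival,
)

__all__ = [
    "recovery_config",
    "estimate_h2_once",
    "h2_recovery",
    "null_survival_config",
    "binomial_mixed_pvalue",
]

# total observed-scale phenotypic variance of the protocol; chosen so the
# identity-link probabilities stay well inside [0, 1] at a 0.5 baseline
V_P_OBSERVED = 0.04
# dominance share of V_P: kept away from its boundary because the
# method-of-moments dominance estimate is truncated at 0, and a boundary
# truth (V_D = 0) biases the truncated mean upward and hence h2 downward
V_D_SHARE = 0.2


def recovery_config(
    true_h2: float,
    n_sires: int = 50,
    n_dams_per_sire: int = 3,
    nymphs: int = 25,
    n_replicates: int = 2,
    seed: int = 0,
) -> SimulationConfig:
    """Half-sib design whose observed-scale heritability equals ``true_h2``."""
    if not 0.0 < true_h2 < 1.0 - V_D_SHARE:
        raise ValueError(f"true_h2 must lie in (0, {1 - V_D_SHARE})")
    v_a = true_h2 * V_P_OBSERVED
    v_d = V_D_SHARE * V_P_OBSERVED
    v_e = (1.0 - true_h2 - V_D_SHARE) * V_P_OBSERVED
    # the binomial noise b depends (weakly) on the latent variance; two
    # fixed-point passes suffice at these magnitudes
    for _ in range(2):
        v_latent = 0.75 * v_a + 0.5 * v_d + v_e
        b = expected_binomial_noise(0.5, v_latent, nymphs)
        v_e = (1.0 - true_h2 - V_D_SHARE) * V_P_OBSERVED - b
    if v_e < 0:
        raise ValueError(
            "binomial sampling variance exceeds the residual budget; "
            "increase nymphs or V_P_OBSERVED"
        )
    return SimulationConfig(
        n_sires=n_sires,
        n_dams_per_sire=n_dams_per_sire,
        n_blocks=2,
        n_plants_per_block=3,
        n_replicates_per_family=n_replicates,
        nymphs_per_family_mean=nymphs,
        v_a=v_a,
        v_d=v_d,
        v_ec=0.0,
        v_e=v_e,
        baseline_survival_control=0.5,
        baseline_survival_exposed=0.5,
        link="identity",
        seed=seed,
    )


def estimate_h2_once(
    config: SimulationConfig, treatment: str = "exposed", tol: float = 1e-6
) -> float:
    """Simulate one dataset under ``config`` and return the estimated h².

    The REML tolerance is relaxed to 1e-6 for simulation batches; across
    seeds this moves h² by under 2e-3, far inside the Monte-Carlo noise.
    """
    design = generate_design(config)
    effects = simulate_family_effects(config)
    table = simulate_survival(design, effects, config).subset(treatment)
    vc = fit_reml(table.proportion_dead(), table.df, tol=tol)
    return h2_pipeline(vc).h2


def recovery_batch(
    true_h2: float, n_replicates: int, seed: int = 0, **config_kwargs
) -> dict[str, np.ndarray | float]:
    """h² and sire-variance estimates over independent simulated datasets.

    Returns arrays ``h2`` and ``var_sire`` plus the protocol truths
    ``true_h2`` and ``true_var_sire`` (= V_A / 2).
    """
    h2s = np.empty(n_replicates)
    sires = np.empty(n_replicates)
    for i in range(n_replicates):
        cfg = recovery_config(true_h2, seed=int(seed + i), **config_kwargs)
        design = generate_design(cfg)
        effects = simulate_family_effects(cfg)
        table = simulate_survival(design, effects, cfg).subset("exposed")
        vc = fit_reml(table.proportion_dead(), table.df, tol=1e-6)
        h2s[i] = h2_pipeline(vc).h2
        sires[i] = vc.var_sire
    return {
        "h2": h2s,
        "var_sire": sires,
        "true_h2": true_h2,
        "true_var_sire": cfg.v_a / 2.0,
    }


def h2_recovery(
    true_h2: float, n_replicates: int, seed: int = 0, **config_kwargs
) -> np.ndarray:
    """Estimated h² across ``n_replicates`` independent simulated datasets."""
    return recovery_batch(true_h2, n_replicates, seed, **config_kwargs)["h2"]


# variance shares reported for the parasitoid arm of the resistance
# experiment: dam 45%, sire 13%, block 9%, plant 6%, residual 24%
PUBLISHED_SHARES = {
    "dam": 45.0,
    "sire": 13.0,
    "block": 9.0,
    "plant": 6.0,
    "resid": 24.0,
}


def share_protocol_config(
    shares: dict[str, float] | None = None,
    total_variance: float = 0.04,
    n_sires: int = 50,
    n_dams_per_sire: int = 3,
    nymphs: int = 500,
    seed: int = 0,
) -> SimulationConfig:
    """Half-sib design whose true component shares match ``shares``.

    Component variances are the share vector scaled to
    ``total_variance``; large nymph counts keep binomial sampling noise
    (which would otherwise inflate the residual share) negligible.  The
    dam share must be at least a quarter of twice the sire share, since
    the dam effect carries V_A/4 plus half the dominance variance.
    """
    s = dict(PUBLISHED_SHARES if shares is None else shares)
    c = total_variance / sum(s.values())
    var_sire = s["sire"] * c
    var_dam = s["dam"] * c
    v_a = 2.0 * var_sire
    v_d = 2.0 * (var_dam - v_a / 4.0)
    if v_d < 0:
        raise ValueError("dam share too small relative to sire share")
    v_ec = (s["block"] + s["plant"]) * c
    v_e = s["resid"] * c
    v_latent = var_dam + var_sire + v_ec + v_e
    v_e = max(v_e - expected_binomial_noise(0.5, v_latent, nymphs), 0.0)
    return SimulationConfig(
        n_sires=n_sires,
        n_dams_per_sire=n_dams_per_sire,
        n_blocks=5,
        n_plants_per_block=6,
        n_replicates_per_family=2,
        nymphs_per_family_mean=nymphs,
        v_a=v_a,
        v_d=v_d,
        v_ec=v_ec,
        ec_plant_share=s["plant"] / (s["block"] + s["plant"]),
        ec_block_share=s["block"] / (s["block"] + s["plant"]),
        ec_dam_share=0.0,
        v_e=v_e,
        baseline_survival_control=0.5,
        baseline_survival_exposed=0.5,
        link="identity",
        seed=seed,
    )


def recovered_shares(
    n_replicates: int = 10, seed: int = 0, **kwargs
) -> dict[str, float]:
    """Mean estimated variance shares (%) under the share protocol."""
    from .reml import variance_shares

    sums: dict[str, float] = {}
    for i in range(n_replicates):
        cfg = share_protocol_config(seed=int(seed + i), **kwargs)
        design = generate_design(cfg)
        effects = simulate_family_effects(cfg)
        table = simulate_survival(design, effects, cfg).subset("exposed")
        vc = fit_reml(table.proportion_dead(), table.df, tol=1e-6)
        for name, val in variance_shares(vc).items():
            sums[name] = sums.get(name, 0.0) + val
    return {name: val / n_replicates for name, val in sums.items()}


def null_survival_config(seed: int = 0, **kwargs) -> SimulationConfig:
    """Paper-scale design with identical outcome distributions in both arms."""
    defaults = dict(
        n_sires=35,
        n_dams_per_sire=1,
        n_replicates_per_family=2,
        baseline_survival_control=0.7,
        baseline_survival_exposed=0.7,
        v_a=0.3,
        v_d=0.2,
        v_ec=0.1,
        v_e=0.3,
        link="logit",
        seed=seed,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def binomial_mixed_pvalue(config: SimulationConfig) -> float:
    """Simulate one survival dataset and return the treatment-test p-value."""
    design = generate_design(config)
    effects = simulate_family_effects(config)
    table = simulate_survival(design, effects, config)
    return fit_binomial_mixed(table).p_value
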