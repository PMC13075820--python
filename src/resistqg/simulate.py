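"""Synthetic data for the breeding-design and life-history experiments.

The survival generator draws family-structured mortality: latent Gaussian
effects for sire, dam, block and plant (with haplodiploid sib covariances
— sire effects carry half the additive variance, dam effects a quarter of
the additive plus half the dominance variance plus any dam share of the
common-environment variance), a residual draw per replicate, a link to a
survival probability, and binomial deaths out of a Poisson nymph count.

The life-history generator draws per-disk egg counts from a negative
binomial around treatment means with a pair-level log-normal intercept,
then beta-binomial hatching spread over the observation window.

All draws derive from ``config.seed`` through independent named streams,
so identical configs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import SimulationConfig
from .tables import FamilySurvivalTable, LifeHistoryTable

__all__ = [
    "FamilyEffects",
    "generate_design",
    "simulate_family_effects",
    "simulate_survival",
    "simulate_life_history",
    "simulate_all",
    "expected_binomial_noise",
]

# stream tags appended to the user seed so the three generators are
# independent but jointly reproducible
_STREAM_DESIGN, _STREAM_EFFECTS, _STREAM_SURVIVAL, _STREAM_LIFE = range(4)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def generate_design(config: SimulationConfig) -> FamilySurvivalTable:
    """Build the family × treatment × replicate skeleton (no outcomes).

    Families are the cross of sires and dams (``dam_id`` unique per
    family, ``sire_id`` shared across ``n_dams_per_sire`` families);
    replicates are assigned to plants round-robin so a family's
    replicates spread across plants, and blocks follow plants.  Nymph
    counts are Poisson (truncated at 1) around
    ``nymphs_per_family_mean``; ``n_dead_day10`` is zero pending
    :func:`simulate_survival`.
    """
    config.validate()
    if config.n_families == 0:
        raise ValueError("design has zero families")
    rng = _rng(config, _STREAM_DESIGN)
    rows = []
    n_plants = config.n_plants
    reps = config.n_replicates_per_family
    for fam in range(config.n_families):
        sire = fam // config.n_dams_per_sire
        for rep in range(reps):
            plant = (fam * reps + rep) % n_plants
            block = plant // config.n_plants_per_block
            n_nymphs = max(1, int(rng.poisson(config.nymphs_per_family_mean)))
            for treatment in ("control", "exposed"):
                rows.append(
                    (fam, fam, sire, block, plant, rep, treatment, n_nymphs, 0)
                )
    df = pd.DataFrame(rows, columns=list(FamilySurvivalTable.COLUMNS))
    return FamilySurvivalTable(df)


@dataclass
class FamilyEffects:
    """Latent per-level effects on the link scale."""

    sire: np.ndarray
    dam: np.ndarray
    block: np.ndarray
    plant: np.ndarray

    def row_totals(self, design: FamilySurvivalTable) -> np.ndarray:
        df = design.df
        return (
            self.sire[df["sire_id"].to_numpy()]
            + self.dam[df["dam_id"].to_numpy()]
            + self.block[df["block_id"].to_numpy()]
            + self.plant[df["plant_id"].to_numpy()]
        )


def simulate_family_effects(config: SimulationConfig) -> FamilyEffects:
    """Draw sire/dam/block/plant effects with the sib-covariance targets.

    Sire-effect variance is V_A/2 (haploid sires transmit their whole
    genome); dam-effect variance is V_A/4 + V_D/2 plus the dam share of
    V_Ec; block and plant effects carry their configured shares of V_Ec.
    Zero variances give exactly-zero effect vectors.
    """
    config.validate()
    rng = _rng(config, _STREAM_EFFECTS)
    ec_plant, ec_block, ec_dam = (s * config.v_ec for s in config.ec_shares())
    var_sire = config.v_a / 2.0
    var_dam = config.v_a / 4.0 + config.v_d / 2.0 + ec_dam

    def draw(n: int, var: float) -> np.ndarray:
        if var == 0.0:
            return np.zeros(n)
        return rng.normal(0.0, np.sqrt(var), size=n)

    return FamilyEffects(
        sire=draw(config.n_sires, var_sire),
        dam=draw(config.n_families, var_dam),
        block=draw(config.n_blocks, ec_block),
        plant=draw(config.n_plants, ec_plant),
    )


def _baseline(config: SimulationConfig, treatment: np.ndarray) -> np.ndarray:
    p = np.where(
        treatment == "exposed",
        config.baseline_survival_exposed,
        config.baseline_survival_control,
    )
    return p.astype(float)


def simulate_survival(
    design: FamilySurvivalTable,
    effects: FamilyEffects,
    config: SimulationConfig,
) -> FamilySurvivalTable:
    """Fill in binomial day-10 deaths for a design skeleton.

    The linear predictor is link(baseline survival for the row's
    treatment) + its latent effects + a residual draw with variance
    ``v_e``; deaths are binomial(n_nymphs, 1 − survival probability).
    With the identity link probabilities are clamped to [0, 1].
    """
    config.validate()
    rng = _rng(config, _STREAM_SURVIVAL)
    df = design.df.copy()
    base = _baseline(config, df["treatment"].to_numpy())
    eta = effects.row_totals(design)
    if config.v_e > 0:
        eta = eta + rng.normal(0.0, np.sqrt(config.v_e), size=len(df))
    if config.link == "logit":
        with np.errstate(divide="ignore"):
            p_survive = expit(logit(base) + eta)
    else:
        p_survive = np.clip(base + eta, 0.0, 1.0)
    df["n_dead_day10"] = rng.binomial(
        df["n_nymphs"].to_numpy(), 1.0 - p_survive
    )
    return FamilySurvivalTable(df)


def simulate_life_history(config: SimulationConfig) -> LifeHistoryTable:
    """Simulate the paired fecundity / hatch experiment.

    Per treatment arm: ``n_plants_per_arm`` plants × ``n_pairs_per_plant``
    pairs × ``n_disks`` daily leaf disks.  Egg counts per disk are
    negative binomial around the (disk-weighted) treatment mean times a
    mean-corrected pair-level log-normal intercept; hatches are
    beta-binomial with the configured hatch probability and
    overdispersion rho, and each hatching egg gets a hatch day from the
    categorical day distribution, reported as cumulative counts.
    """
    config.validate()
    lh = config.life_history
    rng = _rng(config, _STREAM_LIFE)
    weights = np.asarray(lh.disk_day_weights, float)
    weights = weights / weights.mean()
    day_probs = np.asarray(lh.hatch_day_probs, float)
    rows = []
    hcols = [f"hatched_d{d}" for d in lh.hatch_days]
    for treatment in ("control", "exposed"):
        mean_total = (
            lh.mean_total_eggs_control
            if treatment == "control"
            else lh.mean_total_eggs_exposed
        )
        p_hatch = (
            lh.hatch_p_control if treatment == "control" else lh.hatch_p_exposed
        )
        for plant in range(lh.n_plants_per_arm):
            for pair in range(lh.n_pairs_per_plant):
                if lh.pair_sd_log > 0:
                    u = rng.normal(
                        -0.5 * lh.pair_sd_log**2, lh.pair_sd_log
                    )
                else:
                    u = 0.0
                for disk in range(lh.n_disks):
                    mu = mean_total / lh.n_disks * weights[disk] * np.exp(u)
                    if lh.nb_size > 1e8:
                        eggs = int(rng.poisson(mu))
                    else:
                        eggs = int(
                            rng.negative_binomial(
                                lh.nb_size, lh.nb_size / (lh.nb_size + mu)
                            )
                        )
                    if lh.hatch_overdispersion > 0 and 0 < p_hatch < 1:
                        theta = (
                            1.0 - lh.hatch_overdispersion
                        ) / lh.hatch_overdispersion
                        p_i = rng.beta(p_hatch * theta, (1 - p_hatch) * theta)
                    else:
                        p_i = p_hatch
                    hatched = int(rng.binomial(eggs, p_i)) if eggs else 0
                    per_day = (
                        rng.multinomial(hatched, day_probs)
                        if hatched
                        else np.zeros(len(day_probs), int)
                    )
                    cumulative = np.cumsum(per_day)
                    rows.append(
                        (plant, pair, treatment, disk + 1, eggs, *cumulative)
                    )
    df = pd.DataFrame(
        rows, columns=list(LifeHistoryTable.BASE_COLUMNS) + hcols
    )
    return LifeHistoryTable(df)


def simulate_all(
    config: SimulationConfig,
) -> tuple[FamilySurvivalTable, LifeHistoryTable]:
    """Run the full generator: design → effects → survival, plus life history."""
    design = generate_design(config)
    effects = simulate_family_effects(config)
    survival = simulate_survival(design, effects, config)
    return survival, simulate_life_history(config)


def expected_binomial_noise(
    p_mean: float, v_latent: float, nymph_mean: float
) -> float:
    """Expected binomial sampling variance of an observed family proportion.

    Under the identity link the observed proportion is p̂ = X/n with
    X ~ Binomial(n, p), p ~ (p_mean, v_latent) and n Poisson(nymph_mean)
    truncated at 1.  Its variance in excess of var(p) is
    E[p(1−p)]·E[1/n] = (p_mean(1−p_mean) − v_latent)·E[1/n]; this closed
    form defines the residual variance actually seen by the Gaussian
    analysis of proportions.  ``E[1/n]`` is evaluated by series.
    """
    lam = float(nymph_mean)
    ks = np.arange(1, max(200, int(lam * 4)))
    log_pmf = ks * np.log(lam) - lam - np.array(
        [float(x) for x in np.cumsum(np.log(ks))]
    )
    pmf = np.exp(log_pmf)
    pmf /= pmf.sum()  # truncation at n >= 1
    e_inv_n = float(np.sum(pmf / ks))
    return max(p_mean * (1 - p_mean) - v_latent, 0.0) * e_inv_n
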