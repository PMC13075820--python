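"""Simulation configuration for the whitefly–parasitoid breeding-design emulator.

The survival experiment pairs virgin F1 whitefly to produce full-sib F2
families, splits each family's clutch into parasitoid-exposed and control
replicates, and scores nymph mortality at day 10.  The life-history
experiment follows mated pairs from exposed and control plants over four
daily egg-laying leaf disks and records hatching over a subsequent
observation window.  :class:`SimulationConfig` holds the ground-truth
parameters of both experiments.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = ["SimulationConfig", "LifeHistoryConfig", "load_config"]


@dataclass
class LifeHistoryConfig:
    """Parameters of the fecundity / hatch-success experiment.

    Means are totals over the four daily disks, so per-disk means are a
    quarter of these after the disk-day weighting.  ``nb_size`` is the
    negative-binomial size (Poisson limit as size → ∞) of per-disk egg
    counts; ``pair_sd_log`` is the SD of a pair-level log-normal random
    intercept (mean-corrected so group means are preserved);
    ``hatch_overdispersion`` is the beta-binomial correlation parameter
    rho = 1/(1+theta) in [0, 1), 0 being pure binomial hatching.
    """

    n_plants_per_arm: int = 15
    n_pairs_per_plant: int = 2
    n_disks: int = 4
    mean_total_eggs_control: float = 37.27
    mean_total_eggs_exposed: float = 21.47
    nb_size: float = 2.0
    pair_sd_log: float = 0.6
    disk_day_weights: tuple[float, ...] = (0.8, 1.2, 1.2, 0.8)
    hatch_p_control: float = 0.283
    hatch_p_exposed: float = 0.16
    hatch_overdispersion: float = 0.05
    hatch_days: tuple[int, ...] = (4, 5, 6, 7, 8)
    hatch_day_probs: tuple[float, ...] = (0.05, 0.10, 0.15, 0.35, 0.35)

    def validate(self) -> None:
        if min(self.n_plants_per_arm, self.n_pairs_per_plant, self.n_disks) < 1:
            raise ValueError("life-history design counts must be >= 1")
        if self.mean_total_eggs_control <= 0 or self.mean_total_eggs_exposed <= 0:
            raise ValueError("mean egg totals must be positive")
        if self.nb_size <= 0:
            raise ValueError("nb_size must be positive")
        for p in (self.hatch_p_control, self.hatch_p_exposed):
            if not 0.0 <= p <= 1.0:
                raise ValueError("hatch probabilities must lie in [0, 1]")
        if not 0.0 <= self.hatch_overdispersion < 1.0:
            raise ValueError("hatch_overdispersion must lie in [0, 1)")
        if len(self.hatch_days) != len(self.hatch_day_probs):
            raise ValueError("hatch_days and hatch_day_probs must align")
        if abs(sum(self.hatch_day_probs) - 1.0) > 1e-9:
            raise ValueError("hatch_day_probs must sum to 1")
        if len(self.disk_day_weights) != self.n_disks:
            raise ValueError("disk_day_weights must have one entry per disk")


@dataclass
class SimulationConfig:
    """Ground truth for the family survival experiment.

    Variance components live on the latent (link) scale: ``v_a`` additive,
    ``v_d`` dominance, ``v_ec`` common environment (split between plant,
    block and dam shares), ``v_e`` residual.  Under haplodiploid sib
    covariances sire effects carry V_A/2 and dam effects
    V_A/4 + V_D/2 + dam-share of V_Ec.

    ``n_dams_per_sire = 1`` reproduces the full-sib-only design of 35
    paired families; values > 1 give a half-sib design in which the sire
    variance is separately identifiable.  ``link`` is ``"logit"``
    (liability-style) or ``"identity"`` (Gaussian on the probability
    scale, clamped to [0, 1] — the scale the variance analysis fits).
    """

    n_sires: int = 35
    n_dams_per_sire: int = 1
    n_blocks: int = 4
    n_plants_per_block: int = 5
    n_replicates_per_family: int = 2
    nymphs_per_family_mean: int = 25
    v_a: float = 0.2
    v_d: float = 0.25
    v_ec: float = 0.1
    v_e: float = 0.25
    ec_plant_share: float = 0.6
    ec_block_share: float = 0.4
    ec_dam_share: float = 0.0
    baseline_survival_control: float = 0.97
    baseline_survival_exposed: float = 0.30
    link: str = "logit"
    seed: int = 0
    life_history: LifeHistoryConfig = field(default_factory=LifeHistoryConfig)

    # -- derived design quantities -------------------------------------
    @property
    def n_families(self) -> int:
        return self.n_sires * self.n_dams_per_sire

    @property
    def n_plants(self) -> int:
        return self.n_blocks * self.n_plants_per_block

    def ec_shares(self) -> tuple[float, float, float]:
        """(plant, block, dam) shares of v_ec."""
        return (self.ec_plant_share, self.ec_block_share, self.ec_dam_share)

    def validate(self) -> None:
        counts = (
            self.n_sires,
            self.n_dams_per_sire,
            self.n_blocks,
            self.n_plants_per_block,
            self.n_replicates_per_family,
            self.nymphs_per_family_mean,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all design counts must be >= 1")
        for name in ("v_a", "v_d", "v_ec", "v_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        shares = self.ec_shares()
        if any(s < 0 for s in shares):
            raise ValueError("v_ec shares must be non-negative")
        if abs(sum(shares) - 1.0) > 1e-9:
            raise ValueError("v_ec shares must sum to 1")
        for name in ("baseline_survival_control", "baseline_survival_exposed"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.link not in ("logit", "identity"):
            raise ValueError("link must be 'logit' or 'identity'")
        self.life_history.validate()

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        data = dict(data)
        lh = data.pop("life_history", None)
        known = {f.name for f in dataclasses.fields(cls)} - {"life_history"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if lh is not None:
            lh = dict(lh)
            for key in ("disk_day_weights", "hatch_days", "hatch_day_probs"):
                if key in lh:
                    lh[key] = tuple(lh[key])
            cfg.life_history = LifeHistoryConfig(**lh)
        cfg.validate()
        return cfg


def load_config(path: str | pathlib.Path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a TOML, YAML or JSON file."""
    path = pathlib.Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
    elif path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = yaml.safe_load(path.read_text())
    if not isinstance(data, Mapping):
        raise ValueError(f"config file {path} does not contain a mapping")
    return SimulationConfig.from_dict(data)
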