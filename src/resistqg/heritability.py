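"""Haplodiploid-adjusted narrow-sense heritability from sib variance components.

Under an additive–dominance model for a haplodiploid species (haploid
sires, diploid dams; dosage compensation; Hardy–Weinberg structure), the
sire variance component of a sib analysis carries half the additive
variance and the dam component a quarter of the additive plus half the
dominance variance plus the common-environment variance:

    Var_sire = V_A / 2
    Var_dam  = V_A / 4 + V_D / 2 + V_Ec

so V_A = 2 Var_sire and V_D = 2 (Var_dam - V_A/4 - V_Ec), with V_Ec taken
as the block-plus-plant variance.  Narrow-sense heritability is
h2 = V_A / V_P with V_P = V_A + V_D + V_e; an optional broad-V_P mode adds
the common-environment variance to the denominator for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .reml import VarianceComponents

__all__ = [
    "HeritabilityResult",
    "additive_variance",
    "dominance_variance",
    "narrow_sense_h2",
    "h2_pipeline",
]


@dataclass
class HeritabilityResult:
    """Genetic variances and heritability, with per-step provenance."""

    v_a: float
    v_d: float
    v_ec: float
    v_e: float
    v_p: float
    h2: float
    flags: frozenset[str] = frozenset()
    provenance: tuple[str, ...] = field(default=(), repr=False)

    def to_dict(self) -> dict[str, object]:
        return {
            "V_A": self.v_a,
            "V_D": self.v_d,
            "V_Ec": self.v_ec,
            "V_e": self.v_e,
            "V_P": self.v_p,
            "h2": self.h2,
            "flags": sorted(self.flags),
            "provenance": list(self.provenance),
        }


def additive_variance(var_sire: float) -> float:
    """V_A = 2 * Var_sire (haploid sires transmit their full genome)."""
    if var_sire < 0:
        raise ValueError("var_sire must be non-negative")
    return 2.0 * var_sire


def dominance_variance(
    var_dam: float, v_a: float, v_ec: float
) -> tuple[float, bool]:
    """V_D = 2 (Var_dam - V_A/4 - V_Ec), truncated at 0.

    Returns ``(v_d, truncated)``; sampling noise routinely drives the
    method-of-moments dominance estimate negative, in which case it is
    reported as 0 with ``truncated=True``.
    """
    if min(var_dam, v_a, v_ec) < 0:
        raise ValueError("inputs must be non-negative")
    v_d = 2.0 * (var_dam - v_a / 4.0 - v_ec)
    if v_d < 0:
        return 0.0, True
    return v_d, False


def narrow_sense_h2(v_a: float, v_d: float, v_e: float) -> float:
    """h2 = V_A / (V_A + V_D + V_e), guaranteed in [0, 1]."""
    if min(v_a, v_d, v_e) < 0:
        raise ValueError("variances must be non-negative")
    v_p = v_a + v_d + v_e
    if v_p == 0:
        raise ValueError("total phenotypic variance is zero")
    return v_a / v_p


def h2_pipeline(
    vc: VarianceComponents, broad_vp: bool = False
) -> HeritabilityResult:
    """Chain the conversions from a fitted :class:`VarianceComponents`.

    V_Ec is the sum of the block and plant components (the rearing
    environment shared within families); V_e is the residual.  With
    ``broad_vp=True`` the denominator also includes V_Ec, a sensitivity
    mode for designs where block/plant variance is non-negligible.
    """
    flags = set()
    prov = []
    if not vc.converged:
        flags.add("unconverged_components")
    if vc.degenerate:
        flags.add("degenerate_components")
    v_ec = vc.var_block + vc.var_plant
    prov.append(f"V_Ec = var_block + var_plant = {vc.var_block!r} + {vc.var_plant!r}")
    v_a = additive_variance(vc.var_sire)
    prov.append(f"V_A = 2 * var_sire = 2 * {vc.var_sire!r}")
    v_d, truncated = dominance_variance(vc.var_dam, v_a, v_ec)
    prov.append(
        f"V_D = 2 * (var_dam - V_A/4 - V_Ec) = 2 * ({vc.var_dam!r} - {v_a / 4!r} - {v_ec!r})"
        + (" [truncated at 0]" if truncated else "")
    )
    if truncated:
        flags.add("dominance_truncated")
    v_e = vc.var_resid
    v_p = v_a + v_d + v_e + (v_ec if broad_vp else 0.0)
    if broad_vp:
        flags.add("broad_vp")
        prov.append("V_P = V_A + V_D + V_e + V_Ec (broad mode)")
    else:
        prov.append("V_P = V_A + V_D + V_e")
    if v_p == 0:
        raise ValueError("total phenotypic variance is zero; h2 undefined")
    h2 = v_a / v_p
    prov.append(f"h2 = V_A / V_P = {v_a!r} / {v_p!r}")
    return HeritabilityResult(
        v_a=v_a,
        v_d=v_d,
        v_ec=v_ec,
        v_e=v_e,
        v_p=v_p,
        h2=h2,
        flags=frozenset(flags),
        provenance=tuple(prov),
    )
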