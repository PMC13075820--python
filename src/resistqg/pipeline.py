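"""Orchestration: simulate → variance components → heritability → costs.

``run_all`` runs the full analysis either on freshly simulated tables or
on CSV inputs, writes JSON results, a markdown report and a run manifest
with file digests, and returns the in-memory bundle.  Heritability for an
arm is gated: when the fitted variance collapses below a floor (as in a
control arm with almost no mortality) the stage reports "not estimable"
rather than a number.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import pathlib
from typing import Any

import numpy as np

from . import __version__
from .config import SimulationConfig
from .glmm import fit_binomial_mixed
from .heritability import h2_pipeline
from .life_history import fit_fecundity, fit_hatch, lr_test, summarize_costs
from .reml import fit_reml, variance_shares
from .simulate import simulate_all
from .tables import FamilySurvivalTable, LifeHistoryTable, read_tables, write_tables

__all__ = ["run_all", "report", "validate_bundle", "VARIATION_FLOOR"]

VARIATION_FLOOR = 1e-6


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _analyze_survival(survival: FamilySurvivalTable, floor: float) -> dict[str, Any]:
    out: dict[str, Any] = {}
    glmm = fit_binomial_mixed(survival)
    out["binomial_mixed"] = glmm.to_dict()
    out["per_treatment"] = {}
    for treatment in ("control", "exposed"):
        arm = survival.subset(treatment)
        if len(arm) == 0:
            continue
        entry: dict[str, Any] = {
            "n_rows": len(arm),
            "pooled_survival": 1.0
            - float(arm.df["n_dead_day10"].sum() / arm.df["n_nymphs"].sum()),
        }
        vc = fit_reml(arm.proportion_dead(), arm.df)
        entry["components"] = vc.to_dict()
        total = sum(vc.component_dict().values())
        if vc.degenerate or total < floor:
            entry["shares"] = None
            entry["heritability"] = {
                "status": "not estimable",
                "reason": "insufficient variation",
            }
        else:
            entry["shares"] = variance_shares(vc)
            h2 = h2_pipeline(vc)
            entry["heritability"] = {"status": "ok", **h2.to_dict()}
        out["per_treatment"][treatment] = entry
    return out


def _analyze_life_history(life: LifeHistoryTable) -> dict[str, Any]:
    df = life.df
    eggs = df["eggs_laid"].to_numpy()
    treat = df["treatment"].to_numpy()
    disk = df["disk_day"].to_numpy()
    cluster = (
        df["plant_id"].astype(str)
        + "/"
        + df["replicate_id"].astype(str)
        + "/"
        + df["treatment"].astype(str)
    ).to_numpy()

    fec_full = fit_fecundity(eggs, treat, disk, cluster, interaction=True)
    fec_no_trt = fit_fecundity(
        eggs, treat, disk, cluster, interaction=False, include_treatment=False
    )
    fec_add = fit_fecundity(eggs, treat, disk, cluster, interaction=False)
    stat, df_lr, p = lr_test(fec_add, fec_no_trt)
    wald_stat, wald_p = fec_add.treatment_wald()

    hatched = life.final_hatched()
    unhatched = eggs - hatched
    hatch_full = fit_hatch(hatched, unhatched, treat)
    hatch_null = fit_hatch(hatched, unhatched, treat, include_treatment=False)
    hstat, hdf, hp = lr_test(hatch_full, hatch_null)

    return {
        "fecundity": {
            "fit": fec_full.to_dict(),
            # Wald on the cluster-robust SE is the calibrated treatment
            # test on paired data; the marginal LR is kept for reference
            "treatment_test": {"statistic": wald_stat, "df": 1, "p_value": wald_p},
            "treatment_lr": {"statistic": stat, "df": df_lr, "p_value": p},
        },
        "hatch": {
            "fit": hatch_full.to_dict(),
            "treatment_lr": {"statistic": hstat, "df": hdf, "p_value": hp},
        },
        "costs": _jsonable(summarize_costs(life)),
    }


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_all(
    config: SimulationConfig | None = None,
    mode: str = "simulate",
    input_dir: str | pathlib.Path | None = None,
    out_dir: str | pathlib.Path = "results",
    floor: float = VARIATION_FLOOR,
) -> dict[str, Any]:
    """Run every stage and write results under ``out_dir``.

    ``mode="simulate"`` generates both tables from ``config``;
    ``mode="from-files"`` reads ``survival.csv`` / ``life_history.csv``
    from ``input_dir`` (either may be absent).  The returned bundle has a
    ``"status"`` of ``"ok"`` or ``"degenerate"`` (some stage raised a
    degenerate-fit flag).
    """
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    survival: FamilySurvivalTable | None = None
    life: LifeHistoryTable | None = None
    inputs: dict[str, pathlib.Path] = {}

    if mode == "simulate":
        if config is None:
            config = SimulationConfig()
        try:
            survival, life = simulate_all(config)
        except Exception as exc:
            raise RuntimeError(f"stage simulate failed: {exc}") from exc
        inputs = write_tables(
            {"survival": survival, "life_history": life}, out_dir
        )
    elif mode == "from-files":
        if input_dir is None:
            raise ValueError("from-files mode needs input_dir")
        tables = read_tables(input_dir)
        survival = tables.get("survival")
        life = tables.get("life_history")
        inputs = {
            name: pathlib.Path(input_dir) / f"{name}.csv"
            for name in tables
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")

    bundle: dict[str, Any] = {
        "version": __version__,
        "mode": mode,
        "config": None if config is None else dataclasses.asdict(config),
        "seed": None if config is None else config.seed,
    }
    if survival is not None:
        try:
            bundle["survival"] = _analyze_survival(survival, floor)
        except Exception as exc:
            raise RuntimeError(f"stage variance_components failed: {exc}") from exc
    if life is not None:
        try:
            bundle["life_history"] = _analyze_life_history(life)
        except Exception as exc:
            raise RuntimeError(f"stage life_history failed: {exc}") from exc

    flags: list[str] = []
    surv = bundle.get("survival")
    if surv:
        flags.extend(surv["binomial_mixed"]["flags"])
        for arm in surv["per_treatment"].values():
            if arm["components"]["degenerate"]:
                flags.append("degenerate_components")
    bundle["status"] = "degenerate" if flags else "ok"
    bundle["degenerate_flags"] = sorted(set(flags))

    results_path = out_dir / "results.json"
    results_path.write_text(json.dumps(_jsonable(bundle), indent=2))
    report_path = out_dir / "report.md"
    report_path.write_text(report(bundle))

    manifest = {
        "version": __version__,
        "seed": bundle["seed"],
        "config": bundle["config"],
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "inputs": {name: _sha256(p) for name, p in inputs.items()},
        "outputs": {
            "results.json": _sha256(results_path),
            "report.md": _sha256(report_path),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle


# ----------------------------------------------------------------------
# reporting


def report(bundle: dict[str, Any]) -> str:
    """Markdown summary: variance shares (descending), h², cost table."""
    lines = ["# Parasitism-resistance analysis report", ""]
    surv = bundle.get("survival")
    if surv:
        glmm = surv["binomial_mixed"]
        lines += [
            "## Survival",
            "",
            f"Treatment log-odds (death, exposed vs control): "
            f"{glmm['treatment_log_odds']:.3f} "
            f"(chi2 = {glmm['statistic']:.2f}, p = {glmm['p_value']:.3g})",
            "",
        ]
        for treatment, arm in surv["per_treatment"].items():
            lines.append(f"### {treatment.capitalize()} arm")
            lines.append("")
            lines.append(
                f"Pooled survival: {100 * arm['pooled_survival']:.1f}%"
            )
            lines.append("")
            if arm["shares"]:
                lines.append("| component | % of variance |")
                lines.append("| --- | --- |")
                for name, share in sorted(
                    arm["shares"].items(), key=lambda kv: -kv[1]
                ):
                    lines.append(f"| {name} | {share:.1f} |")
                lines.append("")
            h2 = arm["heritability"]
            if h2["status"] == "ok":
                flag_txt = (
                    f" (flags: {', '.join(h2['flags'])})" if h2["flags"] else ""
                )
                lines.append(f"h² = {h2['h2']:.3f}{flag_txt}")
            else:
                lines.append(f"h²: {h2['status']} ({h2['reason']})")
            lines.append("")
    life = bundle.get("life_history")
    if life:
        lines += ["## Life-history costs", ""]
        lr = life["fecundity"].get("treatment_test") or life["fecundity"]["treatment_lr"]
        lines.append(
            f"Fecundity treatment test: chi2 = {lr['statistic']:.2f}, "
            f"df = {lr['df']}, p = {lr['p_value']:.3g}"
        )
        hlr = life["hatch"]["treatment_lr"]
        lines.append(
            f"Hatch treatment LR: chi2 = {hlr['statistic']:.2f}, "
            f"df = {hlr['df']}, p = {hlr['p_value']:.3g}"
        )
        lines.append("")
        lines.append(
            "| arm | pairs | mean eggs (95% CI) | hatch % (binomial CI) |"
        )
        lines.append("| --- | --- | --- | --- |")
        for arm, c in life["costs"].items():
            lo, hi = c["eggs_ci"]
            hlo, hhi = c["hatch_ci"]
            lines.append(
                f"| {arm} | {c['n_pairs']} | "
                f"{c['mean_total_eggs']:.2f} ({lo:.2f}-{hi:.2f}) | "
                f"{100 * c['hatch_prop']:.1f} ({100 * hlo:.1f}-{100 * hhi:.1f}) |"
            )
        lines.append("")
    else:
        lines += ["## Life-history costs", "", "_section omitted: no data_", ""]
    return "\n".join(lines)


# minimal structural schema for the bundle (checked by validate_bundle)
BUNDLE_SCHEMA: dict[str, Any] = {
    "required": ["version", "mode", "status"],
    "survival_required": ["binomial_mixed", "per_treatment"],
    "arm_required": ["components", "heritability", "pooled_survival"],
    "life_required": ["fecundity", "hatch", "costs"],
}


def validate_bundle(bundle: dict[str, Any]) -> None:
    """Raise ValueError when a bundle is structurally invalid."""
    for key in BUNDLE_SCHEMA["required"]:
        if key not in bundle:
            raise ValueError(f"bundle missing key {key!r}")
    if "survival" in bundle and bundle["survival"] is not None:
        surv = bundle["survival"]
        for key in BUNDLE_SCHEMA["survival_required"]:
            if key not in surv:
                raise ValueError(f"survival section missing {key!r}")
        for arm, entry in surv["per_treatment"].items():
            for key in BUNDLE_SCHEMA["arm_required"]:
                if key not in entry:
                    raise ValueError(f"arm {arm!r} missing {key!r}")
            status = entry["heritability"].get("status")
            if status == "ok" and not (
                0.0 <= entry["heritability"]["h2"] <= 1.0
            ):
                raise ValueError("h2 outside [0, 1]")
    if "life_history" in bundle and bundle["life_history"] is not None:
        for key in BUNDLE_SCHEMA["life_required"]:
            if key not in bundle["life_history"]:
                raise ValueError(f"life_history section missing {key!r}")
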