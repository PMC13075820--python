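"""Life-history costs of surviving parasitism: fecundity and hatch success.

Fits the negative-binomial fecundity model (treatment x disk day,
cluster-robust over pairs), the beta-binomial hatch model, and the raw
cost summary with binomial confidence intervals.  Writes JSON and a
markdown cost table under results/life_history/.
"""

import json
import math
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent.parent / "src"))

import pandas as pd

from resistqg.life_history import (
    fit_fecundity,
    fit_hatch,
    lr_test,
    summarize_costs,
)
from resistqg.tables import LifeHistoryTable

ROOT = pathlib.Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data" / "life_history.csv"
OUT = ROOT / "results" / "life_history"


def main() -> None:
    life = LifeHistoryTable(pd.read_csv(DATA))
    OUT.mkdir(parents=True, exist_ok=True)
    df = life.df
    eggs = df["eggs_laid"].to_numpy()
    treat = df["treatment"].to_numpy()
    disk = df["disk_day"].to_numpy()
    cluster = (
        df["plant_id"].astype(str) + "/" + df["replicate_id"].astype(str)
        + "/" + df["treatment"]
    ).to_numpy()

    fec = fit_fecundity(eggs, treat, disk, cluster, interaction=False)
    wald_stat, wald_p = fec.treatment_wald()
    ratio = math.exp(fec.coefficients["treatment[exposed]"])
    print(
        "fecundity: exposed/control egg ratio %.3f (Wald chi2=%.2f, p=%.3g)"
        % (ratio, wald_stat, wald_p)
    )
    fec_null = fit_fecundity(
        eggs, treat, disk, cluster, interaction=False, include_treatment=False
    )
    stat, dof, p = lr_test(fec, fec_null)
    (OUT / "fecundity.json").write_text(
        json.dumps(
            {
                "fit": fec.to_dict(),
                "treatment_wald": {"statistic": wald_stat, "p_value": wald_p},
                "treatment_lr": {"statistic": stat, "df": dof, "p_value": p},
            },
            indent=2,
        )
    )

    hatched = life.final_hatched()
    hatch = fit_hatch(hatched, eggs - hatched, treat)
    h_null = fit_hatch(hatched, eggs - hatched, treat, include_treatment=False)
    hstat, hdf, hp = lr_test(hatch, h_null)
    print(
        "hatch: control %.3f vs exposed %.3f (LR chi2=%.2f, p=%.3g, rho=%.3f)"
        % (
            hatch.fitted_probability(),
            hatch.fitted_probability(**{"treatment[exposed]": True}),
            hstat,
            hp,
            hatch.overdispersion,
        )
    )
    (OUT / "hatch.json").write_text(
        json.dumps(
            {
                "fit": hatch.to_dict(),
                "treatment_lr": {"statistic": hstat, "df": hdf, "p_value": hp},
            },
            indent=2,
        )
    )

    costs = summarize_costs(life)
    lines = ["| arm | pairs | mean eggs (95% CI) | hatch % (binomial CI) |",
             "| --- | --- | --- | --- |"]
    for arm, c in costs.items():
        lo, hi = c["eggs_ci"]
        hlo, hhi = c["hatch_ci"]
        lines.append(
            f"| {arm} | {c['n_pairs']} | {c['mean_total_eggs']:.2f} "
            f"({lo:.2f}-{hi:.2f}) | {100 * c['hatch_prop']:.1f} "
            f"({100 * hlo:.1f}-{100 * hhi:.1f}) |"
        )
        print(
            f"{arm}: {c['mean_total_eggs']:.2f} eggs "
            f"(95% CI {lo:.2f}-{hi:.2f}), hatch {100 * c['hatch_prop']:.1f}%"
        )
    (OUT / "costs.md").write_text("\n".join(lines) + "\n")
    (OUT / "costs.json").write_text(
        json.dumps(costs, indent=2, default=float)
    )


if __name__ == "__main__":
    main()
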