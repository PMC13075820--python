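"""Treatment effect and variance partition for the survival experiment.

Fits the binomial mixed model (PQL) for the exposure effect on day-10
mortality, then partitions the family-proportion variance per treatment
arm by EM-REML into dam, sire, block, plant and residual components.
Writes JSON results under results/survival/.
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent.parent / "src"))

import pandas as pd

from resistqg.glmm import fit_binomial_mixed
from resistqg.reml import fit_reml, variance_shares
from resistqg.tables import FamilySurvivalTable

ROOT = pathlib.Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data" / "survival.csv"
OUT = ROOT / "results" / "survival"


def main() -> None:
    table = FamilySurvivalTable(pd.read_csv(DATA))
    OUT.mkdir(parents=True, exist_ok=True)

    glmm = fit_binomial_mixed(table)
    print(
        "treatment effect (death log-odds, exposed vs control): "
        f"{glmm.effect:.3f} (chi2={glmm.statistic:.1f}, p={glmm.p_value:.2e})"
    )
    (OUT / "binomial_mixed.json").write_text(json.dumps(glmm.to_dict(), indent=2))

    for arm in ("exposed", "control"):
        sub = table.subset(arm)
        vc = fit_reml(sub.proportion_dead(), sub.df)
        record = vc.to_dict()
        try:
            shares = variance_shares(vc)
            record["shares_pct"] = shares
            ordered = sorted(shares.items(), key=lambda kv: -kv[1])
            print(
                f"{arm}: "
                + ", ".join(f"{k} {v:.0f}%" for k, v in ordered)
            )
        except ValueError:
            record["shares_pct"] = None
            print(f"{arm}: no variance to partition")
        (OUT / f"components_{arm}.json").write_text(
            json.dumps(record, indent=2)
        )


if __name__ == "__main__":
    main()
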