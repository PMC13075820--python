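"""Haplodiploid-adjusted narrow-sense heritability of parasitism survival.

Converts the exposed-arm variance components (from 02) via
V_A = 2 Var_sire, V_D = 2 (Var_dam - V_A/4 - V_Ec), V_P = V_A + V_D + V_e,
h² = V_A / V_P, and attempts the control arm, which is gated to
"not estimable" when mortality carries no usable variation.  Also prints
the h² implied by the published variance-share vector for comparison.
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent.parent / "src"))

import dataclasses

from resistqg.heritability import h2_pipeline
from resistqg.recovery import PUBLISHED_SHARES
from resistqg.reml import VarianceComponents

ROOT = pathlib.Path(__file__).resolve().parent.parent
SURV = ROOT / "results" / "survival"
OUT = ROOT / "results" / "heritability"


def load_components(path: pathlib.Path) -> VarianceComponents:
    record = json.loads(path.read_text())
    fields = {f.name for f in dataclasses.fields(VarianceComponents)}
    return VarianceComponents(
        **{
            k: v
            for k, v in record.items()
            if k in fields and k not in ("boundary", "factors")
        }
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for arm in ("exposed", "control"):
        vc = load_components(SURV / f"components_{arm}.json")
        total = sum(vc.component_dict().values())
        if vc.degenerate or total < 1e-6:
            result = {"status": "not estimable", "reason": "insufficient variation"}
            print(f"{arm}: h2 not estimable (insufficient variation)")
        else:
            h2 = h2_pipeline(vc)
            result = {"status": "ok", **h2.to_dict()}
            print(f"{arm}: h2 = {h2.h2:.3f}  (V_A={h2.v_a:.4g}, V_P={h2.v_p:.4g})")
        (OUT / f"h2_{arm}.json").write_text(json.dumps(result, indent=2))

    published = VarianceComponents(
        var_dam=PUBLISHED_SHARES["dam"],
        var_sire=PUBLISHED_SHARES["sire"],
        var_block=PUBLISHED_SHARES["block"],
        var_plant=PUBLISHED_SHARES["plant"],
        var_resid=PUBLISHED_SHARES["resid"],
        converged=True,
    )
    h2_pub = h2_pipeline(published)
    print(
        "h2 implied by the published share vector "
        f"(45/13/9/6/24): {h2_pub.h2:.3f}"
    )
    (OUT / "h2_published_shares.json").write_text(
        json.dumps(h2_pub.to_dict(), indent=2)
    )


if __name__ == "__main__":
    main()
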