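#!/usr/bin/env python
"""Merge everything into the RP-vs-BS biosimilarity report (bevacizumab-like).

Annotates unstressed (48 h control) and stressed (48 h forced oxidation) runs
of both product roles, measures the ar time course over 24/48/72 h, attaches
the cross-mAb site attributions and writes a single JSON document with the
species tables, the species-difference lists and the ar deltas (BS - RP).
"""

import json
from pathlib import Path

from middleup.mab_model import compare_methionine_maps
from middleup.pipeline import attribute_sites, biosimilarity_report
from middleup.sequences import FD_EQUIVALENCES
from middleup.simulate import DesignRow
from middleup.workflow import measure_run_ar, prepare_mab, simulate_and_annotate

BASE_SEED = 20250925
RESULTS = Path("results")
MAB = "bevacizumab-like"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    contexts = {role: prepare_mab(MAB, role) for role in ("RP", "BS")}
    unstressed, stressed, records = {}, {}, []
    for role, ctx in contexts.items():
        con = simulate_and_annotate(
            ctx, DesignRow(MAB, role, "con", 48.0, 1), base_seed=BASE_SEED
        )
        unstressed[role] = con.annotations
        oxi = simulate_and_annotate(
            ctx, DesignRow(MAB, role, "oxi", 48.0, 1), base_seed=BASE_SEED
        )
        stressed[role] = oxi.annotations
        for duration in (24.0, 48.0, 72.0):
            for rep in (1, 2, 3):
                row = DesignRow(MAB, role, "oxi", duration, rep)
                result = simulate_and_annotate(ctx, row, base_seed=BASE_SEED)
                records.extend(measure_run_ar(result, ctx.libraries))

    inf_ctx = prepare_mab("infliximab-like", "BS")
    inf_result = simulate_and_annotate(
        inf_ctx, DesignRow("infliximab-like", "BS", "oxi", 48.0, 1),
        base_seed=BASE_SEED,
    )
    bev_result = simulate_and_annotate(
        contexts["BS"], DesignRow(MAB, "BS", "oxi", 48.0, 1), base_seed=BASE_SEED
    )
    comparison = compare_methionine_maps(
        contexts["BS"].subunits, inf_ctx.subunits, FD_EQUIVALENCES
    )
    attributions = attribute_sites(
        {k: pf.mods.n_ox for k, pf in bev_result.calls.items()},
        {k: pf.mods.n_ox for k, pf in inf_result.calls.items()},
        contexts["BS"].subunits, inf_ctx.subunits, comparison,
        names=(MAB, "infliximab-like"), equivalences=FD_EQUIVALENCES,
    )

    report = biosimilarity_report(MAB, unstressed, stressed, records, attributions)
    out = RESULTS / "biosimilarity_report.json"
    with open(out, "w") as fh:
        json.dump(report, fh, indent=1)
    print(f"wrote {out}")
    for phase in ("unstressed", "stressed"):
        diff = report["differences"].get(phase, {})
        print(f"{phase}: only in RP {diff.get('only_in_RP')}, "
              f"only in BS {diff.get('only_in_BS')}")
    print("ar deltas (BS - RP, replicate means):")
    for d in report["ar_deltas"]:
        print(f"  {d['subunit']:4s} {d['ox_level']}ox {d['duration']:>4.0f} h: "
              f"RP {d['ar_RP']:.4f}  BS {d['ar_BS']:.4f}  delta {d['delta']:+.4f}")


if __name__ == "__main__":
    main()
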