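#!/usr/bin/env python
"""Scaling diagnostics on the reference tables: proportions and span ratios.

Computes the share of each early embryonic stage in the
oviposition-to-dorsal-closure span, the ratio of post- to
pre-dorsal-closure development, the pupa:larva duration ratio, and the
closed-form thermal constants from the published coefficients.  Writes
results/reference_scaling.csv.
"""

from pathlib import Path

import pandas as pd

from thermodev import refdata
from thermodev.norms import ltt, quadratic_lower_root, thermal_constant
from thermodev.scaling import span_ratio, stage_proportions, stage_ratio

OUT = Path(__file__).resolve().parent.parent / "results"
PRE_DC = ["early_cleavages", "late_cleavages", "germ_band_extension",
          "germ_band_retraction", "dorsal_closure"]


def main() -> None:
    OUT.mkdir(exist_ok=True)
    fx = refdata.make_fixture_tables()

    props = stage_proportions(fx.durations_h, PRE_DC)
    ratio = span_ratio(fx.transitions_h, ("dorsal_closure", "boring"),
                       (None, "dorsal_closure"))
    pupa_larva = stage_ratio(fx.stage_summaries_d, "pupa", "larva")

    print("Early-stage proportions of the oviposition->dorsal-closure span:")
    print(props.loc[PRE_DC].round(2).to_string())
    print("\nPost- / pre-dorsal-closure span ratio per regime:")
    print(ratio.round(2).to_string())
    print("\nPupa : larva median-duration ratio (ratio of medians):")
    print(pupa_larva.round(2).to_string())

    coef = fx.coefficients
    print("\nClosed-form constants from the published coefficients:")
    for stage in ("larva", "pupa"):
        a, b = coef.loc[stage, ["a", "b"]]
        k = thermal_constant(b, "per_day")["degree_days"]
        print(f"  {stage:6s} LTT {ltt(a, b):.1f} C, K {k:.1f} degree-days")
    b_total = coef.loc["total_embryonic", "b"]
    k = thermal_constant(b_total, "per_hour")
    print(f"  total embryogenesis: {k['degree_hours']:.0f} degree-hours = "
          f"{k['degree_days']:.1f} degree-days")
    c2, c1, c0 = fx.quadratic["teneral"]
    print(f"  teneral quadratic lower crossing: "
          f"{quadratic_lower_root(c2, c1, c0):.1f} C")

    out = pd.concat(
        [props.loc[PRE_DC].round(4).assign(quantity="proportion_pre_dc_span"),
         ratio.round(4).to_frame().T.assign(quantity="post_pre_dc_ratio"),
         pupa_larva.round(4).to_frame().T.assign(quantity="pupa_larva_ratio")]
    )
    out.to_csv(OUT / "reference_scaling.csv")
    print(f"\nwrote {OUT / 'reference_scaling.csv'}")


if __name__ == "__main__":
    main()
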