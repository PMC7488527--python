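#!/usr/bin/env python
"""Thermal reaction norms recomputed from the packaged reference stage table.

Converts the reference median stage durations to developmental rates,
fits a linear norm per stage against the realized chamber temperatures,
and derives lower temperature thresholds and thermal constants.  Stages
failing the linearity gate (R² < 0.97) get a provisional quadratic.
Writes results/reference_reaction_norms.csv and prints the headline
thresholds.
"""

from pathlib import Path

from thermodev import refdata
from thermodev.norms import fit_linear_norm, fit_quadratic_norm, rates_from_durations
from thermodev.pipeline import norms_table
from thermodev.scaling import ltt_spread

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    durations = refdata.reference_durations()
    fits = []
    for stage in durations.index:
        temps = refdata.actual_temperatures(stage)
        rates = rates_from_durations(durations.loc[stage], out_units="per_hour")
        fit = fit_linear_norm(temps, rates.to_numpy(), stage=stage)
        fits.append(fit)
        if fit.model == "nonlinear":
            fits.append(fit_quadratic_norm(temps, rates.to_numpy(), stage=stage,
                                           rate_units="per_hour"))

    table = norms_table(fits)
    table.to_csv(OUT / "reference_reaction_norms.csv", index=False)

    print("Per-stage thermal reaction norms (rates in h^-1):")
    for f in fits:
        if f.model == "quadratic":
            print(f"  {f.stage:22s} quadratic, lower crossing "
                  f"{f.quad_lower_root_c:.1f} C")
        else:
            tag = "" if f.model == "linear" else "  [below linearity gate]"
            print(f"  {f.stage:22s} LTT {f.ltt_c:5.1f} C   "
                  f"K {f.k_degree_days:6.1f} degree-days   R2 {f.r2:.3f}{tag}")

    linear = [f for f in fits if f.model != "quadratic" and f.ltt_c is not None]
    spread = ltt_spread(linear)
    print(f"\nLTT spread: {spread['min_c']:.1f} C ({spread['min_stage']}) to "
          f"{spread['max_c']:.1f} C ({spread['max_stage']}); "
          f"range {spread['range_c']:.1f} C -> "
          f"{'compatible with' if spread['isomorphy_compatible'] else 'against'} "
          "rate isomorphy")
    print(f"\nwrote {OUT / 'reference_reaction_norms.csv'}")


if __name__ == "__main__":
    main()
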