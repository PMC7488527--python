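"""End-to-end pipeline: counts → transitions → durations → reaction norms.

Composes the full stagewise analysis: pool destructive replicates, fit a
logistic time course per transition × temperature (bias-reduced where the
data are separated), difference the median transition times into stage
durations, convert to rates, fit linear/quadratic thermal norms with lower
thresholds and thermal constants, analyze the individually resolved stages
and adult mass by heteroskedastic GLS, and derive the scaling diagnostics.
Outputs are CSV tables plus a Markdown report.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import gls as gls_mod
from . import scaling
from .io import (
    PipelineConfig,
    read_individual_records,
    read_transition_counts,
    write_individual_records,
    write_transition_counts,
)
from .logistic import fit_transition, pool_replicates
from .norms import (
    fit_linear_norm,
    fit_quadratic_norm,
    durations_from_transitions,
    rates_from_durations,
)
from .ontology import DEFAULT_ONTOLOGY
from .records import IndividualRecord, TransitionSample
from .simulate import default_config, simulate_cohort

logger = logging.getLogger(__name__)


def fit_all_transitions(
    samples: list[TransitionSample],
    method: str = "auto",
    pool: bool = True,
    separation_bound: float = 25.0,
) -> pd.DataFrame:
    """Fit every (transition, regime) group; returns a tidy fit table."""
    groups: dict[tuple[str, str], list[TransitionSample]] = defaultdict(list)
    for s in samples:
        groups[(s.transition, s.regime)].append(s)
    rows = []
    for (transition, regime), grp in sorted(groups.items()):
        if pool:
            grp = pool_replicates(grp)
        kwargs = {"separation_bound": separation_bound} if method != "penalized" else {}
        fit = fit_transition(grp, method=method, **kwargs)
        t50 = fit.t50 if fit.valid else np.nan
        if not fit.valid:
            logger.warning(
                "invalid (non-increasing) transition fit: %s at regime %s",
                transition, regime,
            )
        if fit.separation and fit.method == "ml":
            logger.warning("separation under ML: %s at regime %s", transition, regime)
        rows.append(
            {
                "transition": transition,
                "regime": regime,
                "temp_c": fit.temp_c,
                "method": fit.method,
                "beta0": fit.beta0,
                "beta1": fit.beta1,
                "se0": fit.se0,
                "se1": fit.se1,
                "t50_h": t50,
                "separation": fit.separation,
                "converged": fit.converged,
                "n_samples": fit.n_samples,
                "n_individuals": fit.n_individuals,
            }
        )
    return pd.DataFrame(rows)


def transition_table(fits: pd.DataFrame, ontology=DEFAULT_ONTOLOGY) -> pd.DataFrame:
    """Pivot a fit table into stages (ordered) × regimes of t50 hours."""
    wide = fits.pivot(index="transition", columns="regime", values="t50_h")
    order = [s for s in ontology.destructive_stages if s in wide.index]
    wide = wide.loc[order]
    # order regime columns numerically where possible
    try:
        wide = wide[sorted(wide.columns, key=float)]
    except (TypeError, ValueError):
        pass
    return wide


def fit_stage_norms(
    durations: pd.DataFrame,
    stage_temps: dict[str, tuple[float, ...]],
    r2_gate: float = 0.97,
    se_method: str = "campbell",
) -> list:
    """Linear norm per stage (per-hour rates); quadratic fallback when gated out."""
    fits = []
    for stage in durations.index:
        temps = np.asarray(stage_temps[stage], dtype=float)
        rates = rates_from_durations(durations.loc[stage], out_units="per_hour")
        fit = fit_linear_norm(
            temps, rates.to_numpy(), stage=stage, rate_units="per_hour",
            r2_gate=r2_gate, se_method=se_method,
        )
        fits.append(fit)
        if fit.model == "nonlinear":
            fits.append(
                fit_quadratic_norm(temps, rates.to_numpy(), stage=stage,
                                   rate_units="per_hour")
            )
    return fits


def norms_table(fits: list) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "stage": f.stage,
                "model": f.model,
                "rate_units": f.rate_units,
                "a": f.a,
                "b": f.b,
                "se_a": f.se_a,
                "se_b": f.se_b,
                "r2": f.r2,
                "ltt_c": f.ltt_c,
                "se_ltt_c": f.se_ltt_c,
                "k_degree_hours": f.k_degree_hours,
                "k_degree_days": f.k_degree_days,
                "quad_c2": f.quad_coef[0] if f.quad_coef else None,
                "quad_c1": f.quad_coef[1] if f.quad_coef else None,
                "quad_c0": f.quad_coef[2] if f.quad_coef else None,
                "quad_lower_root_c": f.quad_lower_root_c,
            }
        )
    return pd.DataFrame(rows)


def _markdown_table(df: pd.DataFrame, floatfmt: str = "{:.4g}") -> str:
    def cell(v):
        if isinstance(v, float):
            return "" if np.isnan(v) else floatfmt.format(v)
        return "" if v is None else str(v)

    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    sep = "|" + "|".join("---" for _ in df.columns) + "|"
    body = ["| " + " | ".join(cell(v) for v in row) + " |"
            for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *body])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; writes tables under ``config.out_dir``.

    Returns the result bundle (DataFrames keyed by name).  Any stage
    failure propagates as an exception; no partial report is left behind
    beyond what was already written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if config.simulate:
        sim = default_config()
        samples, records = simulate_cohort(sim, seed=config.seed)
        write_transition_counts(samples, out / "simulated_transition_counts.csv")
        write_individual_records(records, out / "simulated_individual_records.csv")
        logger.info("simulated %d destructive samples, %d individuals",
                    len(samples), len(records))
    else:
        samples = (
            read_transition_counts(config.transition_csv)
            if config.transition_csv
            else []
        )
        records = (
            read_individual_records(config.individual_csv)
            if config.individual_csv
            else []
        )

    report = ["# Stagewise development analysis", ""]

    if samples:
        fits = fit_all_transitions(
            samples, method=config.method, separation_bound=config.separation_bound
        )
        fits.to_csv(out / "transition_fits.csv", index=False)
        results["transition_fits"] = fits

        trans = transition_table(fits)
        durations = durations_from_transitions(trans)
        temp_by_regime = (
            fits.drop_duplicates("regime").set_index("regime")["temp_c"]
        )
        stage_temps = {
            s: tuple(temp_by_regime[r] for r in durations.columns)
            for s in durations.index
        }
        trans.round(config.duration_decimals).to_csv(out / "transition_times.csv")
        durations.round(config.duration_decimals).to_csv(out / "stage_durations.csv")
        results["transition_times"] = trans
        results["stage_durations"] = durations

        norm_fits = fit_stage_norms(
            durations, stage_temps, r2_gate=config.r2_gate,
            se_method=config.se_method,
        )
        ntab = norms_table(norm_fits)
        ntab.to_csv(out / "reaction_norms.csv", index=False)
        results["reaction_norms"] = ntab

        linear_fits = [f for f in norm_fits if f.ltt_c is not None]
        if len(linear_fits) >= 2:
            spread = scaling.ltt_spread(
                linear_fits, isomorphy_tolerance_c=config.isomorphy_tolerance_c
            )
            results["ltt_spread"] = spread
            report += [
                "## Lower temperature thresholds",
                "",
                f"LTT range {spread['min_c']:.1f} °C ({spread['min_stage']}) to "
                f"{spread['max_c']:.1f} °C ({spread['max_stage']}); "
                f"isomorphy-compatible: {spread['isomorphy_compatible']}",
                "",
            ]

        pre = [s for s in durations.index
               if s in DEFAULT_ONTOLOGY.destructive_stages[:5]]
        if len(pre) == 5:
            props = scaling.stage_proportions(durations, pre)
            props.round(2).to_csv(out / "stage_proportions.csv")
            results["stage_proportions"] = props

        report += ["## Transition times (h)", "",
                   _markdown_table(trans.round(2).reset_index()), "",
                   "## Reaction norms", "",
                   _markdown_table(ntab.round(4)), ""]

    if records:
        rates = gls_mod.individual_rates(records)
        results["individual_rates"] = rates
        for response in ("larval_rate", "pupal_rate", "teneral_rate"):
            fit = gls_mod.fit_gls_varident(rates, response)
            fit.anova.to_csv(out / f"anova_{response}.csv", index=False)
            results[f"gls_{response}"] = fit
        mass_fit, mass_summary = gls_mod.mass_analysis(records)
        mass_fit.anova.to_csv(out / "anova_mass.csv", index=False)
        mass_summary.to_csv(out / "mass_summary.csv", index=False)
        results["gls_mass"] = mass_fit
        results["mass_summary"] = mass_summary
        summ = gls_mod.summarize_stages(records,
                                        quantile_method=config.quantile_method)
        summ.to_csv(out / "stage_summaries.csv", index=False)
        results["stage_summaries"] = summ
        report += ["## Within-seed stage summaries (d)", "",
                   _markdown_table(summ.round(2)), ""]

    (out / "report.md").write_text("\n".join(report))
    logger.info("report written to %s", out / "report.md")
    return results
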