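"""Proportional-scaling and rate-isomorphy diagnostics.

Development is "rate-isomorphic" (equiproportional) when every stage
occupies a temperature-independent fraction of total development — which
holds exactly when all stages share one lower temperature threshold.
These helpers compute the descriptive quantities used to probe that
hypothesis: stage durations as proportions of a reference span, ratios of
developmental spans, ratios of stage medians, and the spread of per-stage
lower thresholds.  No formal regression test of proportions is performed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .norms import ReactionNormFit

__all__ = [
    "stage_proportions",
    "span_ratio",
    "stage_ratio",
    "ltt_spread",
]


def stage_proportions(
    durations: pd.DataFrame,
    reference_stages: list[str],
) -> pd.DataFrame:
    """Stage durations as fractions of a reference span, per temperature.

    ``durations`` is stages × regimes; the reference span is the sum of
    the named stages' durations (e.g. all five pre-dorsal-closure stages,
    making completion of dorsal closure ≡ 1).  Proportions of the stages
    that partition the span sum to 1 at every temperature by construction.
    """
    missing = [s for s in reference_stages if s not in durations.index]
    if missing:
        raise ValueError(f"reference span not covered, missing stages: {missing}")
    span = durations.loc[reference_stages].sum(axis=0)
    if (span <= 0).any():
        raise ValueError("reference span must have positive duration")
    props = durations.div(span, axis=1)
    props.attrs["reference_stages"] = list(reference_stages)
    return props


def span_ratio(
    transitions: pd.DataFrame,
    numerator: tuple[str | None, str],
    denominator: tuple[str | None, str],
) -> pd.Series:
    """Ratio of two developmental spans per temperature regime.

    Spans are pairs ``(start_stage, end_stage)`` of transition names;
    ``None`` as start means oviposition (time 0).  E.g. the
    post-dorsal-closure span (dorsal closure → boring) over the preceding
    span (oviposition → dorsal closure).
    """

    def span(pair: tuple[str | None, str]) -> pd.Series:
        start, end = pair
        t_end = transitions.loc[end]
        t_start = transitions.loc[start] if start is not None else 0.0
        return t_end - t_start

    num = span(numerator)
    den = span(denominator)
    if (np.asarray(den) == 0).any():
        raise ValueError("zero-length denominator span")
    out = num / den
    out.name = "span_ratio"
    return out


def stage_ratio(
    summaries: pd.DataFrame,
    numerator_stage: str,
    denominator_stage: str,
    value_col: str = "median_d",
) -> pd.Series:
    """Ratio of two stages' medians per temperature (e.g. pupa : larva).

    Computed from a stage-summary table (columns ``stage``, ``temp_c``,
    ``value_col``).  This is the ratio-of-medians variant; the median of
    per-individual ratios is a distinct quantity and generally differs.
    """
    wide = summaries.pivot(index="temp_c", columns="stage", values=value_col)
    out = wide[numerator_stage] / wide[denominator_stage]
    out.name = f"{numerator_stage}:{denominator_stage}"
    return out


def ltt_spread(
    norms: list[ReactionNormFit],
    isomorphy_tolerance_c: float = 1.0,
) -> dict:
    """Min/max/range of per-stage lower temperature thresholds.

    A range smaller than the tolerance is flagged as compatible with a
    single shared threshold (rate isomorphy); the comparison is
    descriptive, not a test.
    """
    fits = [f for f in norms if f.ltt_c is not None]
    if len(fits) < 2:
        raise ValueError("need >=2 fits with a defined lower threshold")
    table = pd.DataFrame(
        {"stage": [f.stage for f in fits], "ltt_c": [f.ltt_c for f in fits]}
    ).set_index("stage")
    lo = table["ltt_c"].idxmin()
    hi = table["ltt_c"].idxmax()
    rng = float(table["ltt_c"].max() - table["ltt_c"].min())
    return {
        "min_c": float(table["ltt_c"].min()),
        "min_stage": lo,
        "max_c": float(table["ltt_c"].max()),
        "max_stage": hi,
        "range_c": rng,
        "isomorphy_compatible": rng < isomorphy_tolerance_c,
        "table": table,
    }
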