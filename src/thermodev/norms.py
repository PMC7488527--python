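"""Thermal reaction norms: stage durations, rates, thresholds, degree-days.

Median stage durations D are differences of consecutive median transition
times; developmental rates are reciprocals R = 1/D.  Within the permissive
temperature range the rate–temperature relationship is treated as linear,
R = a + b·T, whenever the ordinary-least-squares R² clears a linearity
gate (default 0.97).  A linear norm yields the lower temperature threshold
LTT = −a/b (°C, where the extrapolated rate reaches zero) and the thermal
constant K = 1/b (accumulated degree-hours or degree-days above the LTT).
Markedly nonlinear stages are provisionally described by a quadratic
R = c2·T² + c1·T + c0, whose smaller real root plays the role of a
provisional lower threshold.

Rates carry explicit unit tags (``per_hour`` or ``per_day``): the LTT is
invariant to the choice, while K converts as degree-days = degree-hours/24.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

HOURS_PER_DAY = 24.0

__all__ = [
    "ReactionNormFit",
    "durations_from_transitions",
    "rates_from_durations",
    "fit_linear_norm",
    "fit_quadratic_norm",
    "ltt",
    "thermal_constant",
    "ltt_se",
]


@dataclass
class ReactionNormFit:
    """One stage's fitted thermal response of developmental rate."""

    stage: str
    model: str  # "linear" | "nonlinear" | "quadratic"
    rate_units: str  # "per_hour" | "per_day"
    n: int
    r2: float
    # linear path
    a: float | None = None
    b: float | None = None
    se_a: float | None = None
    se_b: float | None = None
    cov_ab: float | None = None
    s2: float | None = None  # residual mean square
    ltt_c: float | None = None
    se_ltt_c: float | None = None
    k_degree_hours: float | None = None
    k_degree_days: float | None = None
    # quadratic path
    quad_coef: tuple[float, float, float] | None = None  # (c2, c1, c0)
    quad_lower_root_c: float | None = None
    temps: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    rates: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)


def durations_from_transitions(transitions: pd.DataFrame) -> pd.DataFrame:
    """Difference consecutive median transition times into stage durations.

    ``transitions`` is stages (ordered, rows) × temperature regimes
    (columns), in hours from oviposition.  The first stage's duration is
    its own transition time; durations must be strictly positive, and the
    per-column sums of durations equal the last transition time exactly.
    """
    tr = transitions.astype(float)
    dur = tr.diff()
    dur.iloc[0] = tr.iloc[0]
    bad = dur <= 0
    if bad.to_numpy().any():
        stage_idx, col_idx = np.argwhere(bad.to_numpy())[0]
        stage = dur.index[stage_idx]
        prev = dur.index[stage_idx - 1] if stage_idx else "oviposition"
        raise ValueError(
            f"non-monotone transitions: {prev!r} -> {stage!r} at regime "
            f"{dur.columns[col_idx]!r} gives non-positive duration"
        )
    return dur


def rates_from_durations(
    durations: pd.DataFrame | pd.Series,
    out_units: str = "per_hour",
    in_units: str = "hours",
):
    """Convert durations to developmental rates R = 1/D with explicit units."""
    d = durations.astype(float)
    if (np.asarray(d) <= 0).any():
        raise ValueError("durations must be strictly positive")
    hours = d if in_units == "hours" else d * HOURS_PER_DAY
    if in_units not in ("hours", "days"):
        raise ValueError(f"unknown in_units {in_units!r}")
    if out_units == "per_hour":
        return 1.0 / hours
    if out_units == "per_day":
        return HOURS_PER_DAY / hours
    raise ValueError(f"unknown out_units {out_units!r}")


def ltt(a: float, b: float) -> float:
    """Lower temperature threshold −a/b (°C) from a linear rate norm."""
    if b <= 0:
        raise ValueError(f"slope must be positive to define a threshold, got b={b}")
    return -a / b


def thermal_constant(b: float, rate_units: str) -> dict[str, float]:
    """Thermal constant K = 1/b in degree-hours and degree-days."""
    if b <= 0:
        raise ValueError(f"slope must be positive, got b={b}")
    k = 1.0 / b
    if rate_units == "per_hour":
        return {"degree_hours": k, "degree_days": k / HOURS_PER_DAY}
    if rate_units == "per_day":
        return {"degree_hours": k * HOURS_PER_DAY, "degree_days": k}
    raise ValueError(f"unknown rate_units {rate_units!r}")


def fit_linear_norm(
    temps,
    rates,
    stage: str = "",
    rate_units: str = "per_hour",
    r2_gate: float = 0.97,
    se_method: str = "campbell",
) -> ReactionNormFit:
    """OLS fit of R = a + b·T; threshold and thermal constant if linear.

    ``model`` is set to ``"linear"`` only when R² clears the gate;
    otherwise the fit is flagged ``"nonlinear"`` (coefficients still
    reported) and the quadratic path is the recommended description.
    Replicated rate values per temperature are allowed.
    """
    T = np.asarray(temps, dtype=float)
    R = np.asarray(rates, dtype=float)
    if T.shape != R.shape:
        raise ValueError("temps and rates must have equal length")
    if len(np.unique(T)) < 3:
        raise ValueError("need rates at >=3 distinct temperatures")

    X = sm.add_constant(T)
    res = sm.OLS(R, X).fit()
    a, b = float(res.params[0]), float(res.params[1])
    se_a, se_b = (float(v) for v in res.bse)
    cov_ab = float(res.cov_params()[0, 1])
    n = len(R)
    r2 = float(res.rsquared)
    s2 = float(res.mse_resid) if n > 2 else 0.0

    fit = ReactionNormFit(
        stage=stage,
        model="linear" if r2 >= r2_gate else "nonlinear",
        rate_units=rate_units,
        n=n,
        r2=r2,
        a=a,
        b=b,
        se_a=se_a,
        se_b=se_b,
        cov_ab=cov_ab,
        s2=s2,
        temps=T,
        rates=R,
    )
    if b > 0:
        fit.ltt_c = ltt(a, b)
        k = thermal_constant(b, rate_units)
        fit.k_degree_hours = k["degree_hours"]
        fit.k_degree_days = k["degree_days"]
        fit.se_ltt_c = ltt_se(fit, method=se_method)
    return fit


def ltt_se(
    fit: ReactionNormFit,
    method: str = "campbell",
    n_boot: int = 10_000,
    seed: int = 0,
) -> float:
    """Approximate standard error of the lower temperature threshold.

    ``campbell``
        The classic approximation SE = (ȳ/b)·√( s²/(N·ȳ²) + (SE_b/b)² )
        with ȳ the mean observed rate.
    ``delta``
        First-order variance of −a/b using the full OLS covariance of
        (a, b) including their covariance.
    ``bootstrap``
        Parametric residual bootstrap: Gaussian residuals with variance s²
        around the fitted line, refit, SD of the resampled thresholds.
    """
    if fit.b is None or fit.b <= 0:
        raise ValueError("threshold SE requires a fitted positive slope")
    if fit.n < 3:
        raise ValueError("need at least 3 points")
    a, b, s2 = fit.a, fit.b, fit.s2
    if method == "campbell":
        ybar = float(np.mean(fit.rates))
        return abs(ybar / b) * np.sqrt(
            s2 / (fit.n * ybar**2) + (fit.se_b / b) ** 2
        )
    if method == "delta":
        var = (
            fit.se_a**2 / b**2
            + a**2 * fit.se_b**2 / b**4
            - 2 * a * fit.cov_ab / b**3
        )
        return float(np.sqrt(max(var, 0.0)))
    if method == "bootstrap":
        if s2 == 0:
            return 0.0
        rng = np.random.default_rng(seed)
        T = fit.temps
        X = sm.add_constant(T)
        fitted = a + b * T
        vals = []
        for _ in range(n_boot):
            Rb = fitted + rng.normal(0.0, np.sqrt(s2), size=len(T))
            coef, *_ = np.linalg.lstsq(X, Rb, rcond=None)
            if coef[1] > 0:
                vals.append(-coef[0] / coef[1])
        return float(np.std(vals, ddof=1))
    raise ValueError(f"unknown SE method {method!r}")


def fit_quadratic_norm(temps, rates, stage: str = "",
                       rate_units: str = "per_day") -> ReactionNormFit:
    """Least-squares quadratic R = c2·T² + c1·T + c0 with its lower crossing.

    The provisional lower threshold is the smaller real root of the
    fitted parabola (the crossing below the vertex); absent when the
    discriminant is negative.  A vanishing c2 degrades gracefully to the
    linear root −c0/c1.
    """
    T = np.asarray(temps, dtype=float)
    R = np.asarray(rates, dtype=float)
    if len(np.unique(T)) < 3:
        raise ValueError("need rates at >=3 distinct temperatures")
    coef = np.polyfit(T, R, 2)  # highest power first
    c2, c1, c0 = (float(c) for c in coef)
    pred = np.polyval(coef, T)
    sst = float(np.sum((R - R.mean()) ** 2))
    r2 = 1.0 - float(np.sum((R - pred) ** 2)) / sst if sst > 0 else 1.0
    fit = ReactionNormFit(
        stage=stage, model="quadratic", rate_units=rate_units,
        n=len(R), r2=r2, quad_coef=(c2, c1, c0), temps=T, rates=R,
    )
    fit.quad_lower_root_c = quadratic_lower_root(c2, c1, c0)
    return fit


def quadratic_lower_root(c2: float, c1: float, c0: float) -> float | None:
    """Smaller real root of c2·T² + c1·T + c0 (None if no real crossing)."""
    if c2 == 0:
        if c1 == 0:
            raise ValueError("degenerate polynomial")
        return -c0 / c1
    disc = c1**2 - 4 * c2 * c0
    if disc < 0:
        return None
    roots = np.sort(np.roots([c2, c1, c0]).real)
    return float(roots[0])
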