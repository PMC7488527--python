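"""Heteroskedastic GLS for individually resolved stages and adult mass.

The within-seed stages (larva, pupa, teneral adult) and adult body mass
are observed per individual.  Rates (1/duration, per day) or masses are
modelled with fixed effects

    y = β0 + β_T·(T − T̄) + β_S·sex + β_TS·(T − T̄)·sex + ε,

with temperature continuous, sex a ±½ contrast (female +½, male −½), and
a distinct residual variance per temperature×sex stratum, estimated under
restricted maximum likelihood.  Inference uses sequential (type I)
F-tests in the order temperature, sex, temperature×sex, computed from
nested weighted residual sums of squares with the estimated variance
weights held fixed.

REML estimation profiles the fixed effects: given stratum variances,
coefficients come from weighted least squares; stratum variances are then
updated from stratum residual sums of squares divided by (n_s − Σ
leverages), the leverage sum being the REML degrees-of-freedom
adjustment.  The fixed point of this iteration solves the REML score
equations for the variance-per-stratum model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .records import IndividualRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GLSFit",
    "individual_rates",
    "fit_gls_varident",
    "summarize_stages",
    "mass_analysis",
]

TERMS = ("temperature", "sex", "temperature:sex")

#: sex contrast used in the design matrix (documented, not configurable)
SEX_CONTRAST = {"female": 0.5, "male": -0.5}


@dataclass
class GLSFit:
    """Heteroskedastic GLS fit with sequential ANOVA."""

    response: str
    coefficients: pd.Series
    se: pd.Series
    variance_multipliers: pd.Series  # residual-variance ratio per stratum; reference = 1
    sigma2: float  # residual variance of the reference stratum
    reml_loglik: float
    anova: pd.DataFrame  # term, F, df1, df2, p
    nobs: int
    df_resid: int
    converged: bool
    temp_center: float
    strata: pd.Series = field(repr=False, default=None)


def individual_rates(records: list[IndividualRecord]) -> pd.DataFrame:
    """Per-individual development rates (day⁻¹) for larva, pupa, teneral.

    Records carrying exclusion flags or missing/zero durations are dropped;
    the number of exclusions is logged and kept in ``df.attrs``.
    """
    rows, excluded = [], 0
    for r in records:
        if r.flags:
            excluded += 1
            continue
        if None in (r.larval_d, r.pupal_d, r.teneral_d):
            excluded += 1
            continue
        rows.append(
            {
                "id": r.id,
                "temp_c": r.temp_c,
                "sex": r.sex,
                "larval_rate": 1.0 / r.larval_d,
                "pupal_rate": 1.0 / r.pupal_d,
                "teneral_rate": 1.0 / r.teneral_d,
                "mass_mg": r.mass_mg,
            }
        )
    if excluded:
        logger.warning("excluded %d flagged/incomplete individual records", excluded)
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = excluded
    return df


def _design(df: pd.DataFrame, temp_center: float) -> np.ndarray:
    tc = df["temp_c"].to_numpy(dtype=float) - temp_center
    sx = df["sex"].map(SEX_CONTRAST).to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), tc, sx, tc * sx])


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = y - X @ coef
    XtWX = Xw.T @ Xw
    return coef, resid, XtWX, Xw


def _reml_loglik(X, y, sigma2_by_obs):
    w = 1.0 / sigma2_by_obs
    coef, resid, XtWX, _ = _wls(X, y, w)
    n, p = X.shape
    sign, logdet = np.linalg.slogdet(XtWX)
    return -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + np.sum(np.log(sigma2_by_obs))
        + logdet
        + np.sum(resid**2 * w)
    )


def fit_gls_varident(
    df: pd.DataFrame,
    response: str,
    max_iter: int = 200,
    tol: float = 1e-8,
    homoskedastic: bool = False,
) -> GLSFit:
    """Fit the temperature×sex fixed-effect model with per-stratum variances.

    ``df`` needs columns ``temp_c``, ``sex`` and the response.  With
    ``homoskedastic=True`` the variance multipliers are pinned to 1, in
    which case the coefficients equal OLS exactly.
    """
    data = df.dropna(subset=[response]).reset_index(drop=True)
    y = data[response].to_numpy(dtype=float)
    temp_center = float(data["temp_c"].mean())
    X = _design(data, temp_center)
    n, p = X.shape
    if n <= p:
        raise ValueError("not enough observations for the 4-coefficient model")

    strata = (
        data["temp_c"].astype(float).round(6).astype(str) + ":" + data["sex"]
    )
    labels = sorted(strata.unique())
    idx = strata.map({lab: k for k, lab in enumerate(labels)}).to_numpy()
    counts = np.bincount(idx, minlength=len(labels))
    if not homoskedastic:
        if len(labels) < 2:
            raise ValueError("need >=2 temperature×sex strata")
        if counts.min() < 2:
            empty = [labels[k] for k in np.where(counts < 2)[0]]
            raise ValueError(f"strata with <2 observations: {empty}")

    sigma2 = np.full(len(labels), np.var(y) if np.var(y) > 0 else 1.0)
    converged = homoskedastic
    for _ in range(max_iter):
        if homoskedastic:
            sigma2 = np.ones(len(labels)) * max(np.var(y), 1e-300)
            break
        w = 1.0 / sigma2[idx]
        w = w / w.mean()  # common weight scale is irrelevant; avoids overflow
        coef, resid, XtWX, Xw = _wls(X, y, w)
        Hdiag = np.einsum(
            "ij,jk,ik->i", Xw, np.linalg.pinv(XtWX), Xw
        )  # leverages of the weighted regression (pinv: tolerate collinear designs)
        new = np.empty_like(sigma2)
        for k in range(len(labels)):
            mask = idx == k
            denom = counts[k] - Hdiag[mask].sum()
            denom = max(denom, 0.5)  # guard tiny strata
            new[k] = np.sum(resid[mask] ** 2) / denom
        # relative floor: a stratum variance below ~machine noise of the
        # response scale means an exact fit; equalize rather than amplify it
        new = np.maximum(new, 1e-20 * max(np.var(y), 1e-300))
        rel = np.max(np.abs(new - sigma2) / np.maximum(sigma2, 1e-300))
        sigma2 = new
        if rel < tol:
            converged = True
            break
    if not converged and not homoskedastic:
        logger.warning("varIdent REML iteration did not converge in %d steps", max_iter)

    w = 1.0 / sigma2[idx]
    wscale = w.mean()
    w = w / wscale
    coef, resid, XtWX, _ = _wls(X, y, w)
    cov = np.linalg.pinv(XtWX) / wscale  # undo the weight normalization
    se = np.sqrt(np.diag(cov))
    names = ["(Intercept)", "temperature", "sex", "temperature:sex"]

    # sequential (type I) F-tests with the final weights held fixed
    full_rss = float(np.sum(resid**2 * w))
    df_resid = n - p
    rss_seq = []
    for k in range(1, p + 1):
        _, r, _, _ = _wls(X[:, :k], y, w)
        rss_seq.append(float(np.sum(r**2 * w)))
    mse = full_rss / df_resid
    rows = []
    for j, term in enumerate(TERMS):
        num = (rss_seq[j] - rss_seq[j + 1]) / 1.0
        F = num / mse
        rows.append(
            {
                "term": term,
                "F": F,
                "df1": 1,
                "df2": df_resid,
                "p": float(stats.f.sf(F, 1, df_resid)),
            }
        )
    anova = pd.DataFrame(rows)

    ref = labels[0]
    mult = pd.Series(sigma2 / sigma2[0], index=labels, name="variance_multiplier")
    return GLSFit(
        response=response,
        coefficients=pd.Series(coef, index=names),
        se=pd.Series(se, index=names),
        variance_multipliers=mult,
        sigma2=float(sigma2[0]),
        reml_loglik=float(_reml_loglik(X, y, sigma2[idx])),
        anova=anova,
        nobs=n,
        df_resid=df_resid,
        converged=bool(converged),
        temp_center=temp_center,
        strata=pd.Series(strata.to_numpy(), name="stratum"),
    )


def summarize_stages(
    records: list[IndividualRecord],
    quantile_method: str = "linear",
) -> pd.DataFrame:
    """Median and quartiles of stage durations per stage × temperature.

    Quantiles use linear interpolation by default (the numpy/R type-7
    convention); the method is configurable.
    """
    df = pd.DataFrame(
        [
            {
                "temp_c": r.temp_c,
                "larva": r.larval_d,
                "pupa": r.pupal_d,
                "teneral": r.teneral_d,
            }
            for r in records
            if not r.flags
        ]
    )
    rows = []
    for stage in ("larva", "pupa", "teneral"):
        for temp, grp in df.groupby("temp_c"):
            vals = grp[stage].dropna().to_numpy()
            if len(vals) == 0:
                rows.append({"stage": stage, "temp_c": temp, "n": 0,
                             "median_d": np.nan, "q1_d": np.nan, "q3_d": np.nan})
                continue
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75],
                                      method=quantile_method)
            rows.append({"stage": stage, "temp_c": temp, "n": len(vals),
                         "median_d": med, "q1_d": q1, "q3_d": q3})
    return pd.DataFrame(rows)


def mass_analysis(
    records: list[IndividualRecord],
) -> tuple[GLSFit, pd.DataFrame]:
    """GLS temperature×sex analysis of adult mass plus mean±SD summary."""
    df = pd.DataFrame(
        [
            {"temp_c": r.temp_c, "sex": r.sex, "mass_mg": r.mass_mg}
            for r in records
            if not r.flags and r.mass_mg is not None
        ]
    )
    if df.empty:
        raise ValueError("no mass observations")
    fit = fit_gls_varident(df, "mass_mg")
    summary = (
        df.groupby(["temp_c", "sex"])["mass_mg"]
        .agg(n="count", mean_mg="mean", sd_mg=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return fit, summary
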