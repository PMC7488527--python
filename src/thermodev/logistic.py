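"""Logistic estimation of stage-transition times from destructive samples.

Each destructive sample contributes a binomial observation: of ``n_total``
individuals sacrificed at age ``t`` (hours since oviposition), ``n_past``
have passed the stage boundary.  The proportion past the boundary is
modelled as ``logit(P) = β0 + β1·t`` and the median transition time is the
age at which the fitted curve crosses P = 0.5, i.e. t50 = −β0/β1.

Synchronous transitions sampled on a coarse grid routinely produce
complete or quasi-complete separation (only 0/n and n/n counts), under
which the maximum-likelihood estimates diverge.  For those cases the
module provides Firth-type bias-reduced estimation — the Jeffreys-prior
penalty ½·log det I(β) added to the binomial log-likelihood — which always
yields finite estimates.  Both estimators run the same iteratively
reweighted least squares on internally standardized ages.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .records import TransitionSample

__all__ = [
    "LogisticTransitionFit",
    "pool_replicates",
    "fit_logistic_ml",
    "fit_logistic_penalized",
    "median_transition_time",
    "detect_separation",
]


@dataclass
class LogisticTransitionFit:
    """Fitted logistic time course of one stage transition at one temperature."""

    transition: str
    temp_c: float
    method: str  # "ml" | "penalized"
    beta0: float
    beta1: float
    se0: float
    se1: float
    converged: bool
    separation: bool
    n_samples: int
    n_individuals: int

    @property
    def t50(self) -> float:
        """Median transition time in hours (age where fitted P = 0.5)."""
        return median_transition_time(self)

    @property
    def valid(self) -> bool:
        """A developmental transition must have increasing proportion past."""
        return self.beta1 > 0

    def predict(self, age_h) -> np.ndarray:
        return expit(self.beta0 + self.beta1 * np.asarray(age_h, dtype=float))


def pool_replicates(samples: list[TransitionSample]) -> list[TransitionSample]:
    """Pool replicate samples whose ages agree after rounding to the hour.

    Counts are summed within each rounded-hour bin and the age replaced by
    the rounded hour.  All samples must share one transition and regime.
    """
    if not samples:
        return []
    keys = {(s.transition, s.regime) for s in samples}
    if len(keys) > 1:
        raise ValueError(f"cannot pool across transitions/regimes: {sorted(keys)}")
    bins: dict[int, list[TransitionSample]] = defaultdict(list)
    for s in samples:
        bins[int(round(s.age_h))].append(s)
    pooled = []
    for hour in sorted(bins):
        group = bins[hour]
        pooled.append(
            TransitionSample(
                regime=group[0].regime,
                temp_c=group[0].temp_c,
                age_h=float(hour),
                transition=group[0].transition,
                n_total=sum(s.n_total for s in group),
                n_past=sum(s.n_past for s in group),
            )
        )
    return pooled


def detect_separation(samples: list[TransitionSample]) -> bool:
    """Data-level check for complete/quasi-complete separation by age.

    True when no sample shows an intermediate count and every all-zero
    sample is younger than (or tied with) every all-past sample — i.e. a
    step function fits the data perfectly and the ML slope diverges.
    """
    ages0, ages1 = [], []
    for s in samples:
        if 0 < s.n_past < s.n_total:
            return False
        (ages1 if s.n_past == s.n_total and s.n_total > 0 else ages0).append(s.age_h)
    if not ages0 or not ages1:
        return False
    return max(ages0) <= min(ages1)


def _prepare(samples: list[TransitionSample]):
    t = np.array([s.age_h for s in samples], dtype=float)
    y = np.array([s.n_past for s in samples], dtype=float)
    n = np.array([s.n_total for s in samples], dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("need samples at >=2 distinct ages")
    return t, y, n


def _loglik(X, beta, y, n):
    eta = X @ beta
    # binomial log-likelihood up to the constant combinatorial term
    return float(np.sum(y * eta - n * np.logaddexp(0.0, eta)))


def _information(X, beta, n):
    pi = expit(X @ beta)
    w = n * pi * (1.0 - pi)
    return X.T @ (w[:, None] * X), w, pi


def _irls(
    t: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    firth: bool,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_bound: float = 25.0,
):
    """IRLS on standardized ages; returns (beta_std, cov_std, converged, diverged, scaler)."""
    mu, sd = t.mean(), t.std()
    if sd == 0:
        raise ValueError("ages are constant")
    z = (t - mu) / sd
    X = np.column_stack([np.ones_like(z), z])

    p0 = np.clip(y.sum() / n.sum(), 1e-3, 1 - 1e-3)
    beta = np.array([logit(p0), 0.0])

    def objective(b):
        ll = _loglik(X, b, y, n)
        if firth:
            info, _, _ = _information(X, b, n)
            sign, logdet = np.linalg.slogdet(info)
            ll += 0.5 * logdet if sign > 0 else -np.inf
        return ll

    converged = False
    diverged = False
    obj = objective(beta)
    for _ in range(max_iter):
        info, w, pi = _information(X, beta, n)
        score = X.T @ (y - n * pi)
        if firth:
            try:
                info_inv = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                info = info + 1e-10 * np.eye(2)
                info_inv = np.linalg.inv(info)
            sqw = np.sqrt(np.maximum(w, 0.0))
            WX = sqw[:, None] * X
            h = np.einsum("ij,jk,ik->i", WX, info_inv, WX)
            score = X.T @ (y - n * pi + h * (0.5 - pi))
        if np.linalg.norm(score) < tol:
            converged = True
            break
        if not firth and np.max(np.abs(beta)) > separation_bound:
            diverged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(info + 1e-10 * np.eye(2), score)
        # step halving: never let the (penalized) log-likelihood decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                break
            factor *= 0.5
        beta = beta + factor * step
        obj = objective(beta)

    info, _, _ = _information(X, beta, n)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return beta, cov, converged, diverged, (mu, sd)


def _destandardize(beta_z, cov_z, mu, sd):
    # beta_orig = A @ beta_z with A mapping standardized to hour scale
    A = np.array([[1.0, -mu / sd], [0.0, 1.0 / sd]])
    beta = A @ beta_z
    cov = A @ cov_z @ A.T
    return beta, cov


def _fit(
    samples: list[TransitionSample],
    firth: bool,
    tol: float,
    max_iter: int,
    separation_bound: float,
) -> LogisticTransitionFit:
    t, y, n = _prepare(samples)
    data_separated = detect_separation(samples)
    if not firth:
        if np.all(y == 0) or np.all(y == n):
            raise ValueError("no transition observed (all-zero or all-past counts)")
    beta_z, cov_z, converged, diverged, (mu, sd) = _irls(
        t, y, n, firth=firth, tol=tol, max_iter=max_iter,
        separation_bound=separation_bound,
    )
    separated = data_separated or diverged
    if not firth and separated:
        warnings.warn(
            "complete/quasi-complete separation: ML estimates are unbounded; "
            "consider the penalized (bias-reduced) fit",
            stacklevel=3,
        )
    beta, cov = _destandardize(beta_z, cov_z, mu, sd)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    s0 = samples[0]
    return LogisticTransitionFit(
        transition=s0.transition,
        temp_c=s0.temp_c,
        method="penalized" if firth else "ml",
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        se0=float(se[0]),
        se1=float(se[1]),
        converged=bool(converged and not diverged),
        separation=bool(separated),
        n_samples=len(samples),
        n_individuals=int(n.sum()),
    )


def fit_logistic_ml(
    samples: list[TransitionSample],
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_bound: float = 25.0,
) -> LogisticTransitionFit:
    """Maximum-likelihood logistic fit of proportion-past-transition vs age.

    Each sample enters as a binomial observation with its own ``n_total``.
    Under separation the estimates diverge; the fit is returned with the
    ``separation`` flag set and a warning issued.
    """
    return _fit(samples, firth=False, tol=tol, max_iter=max_iter,
                separation_bound=separation_bound)


def fit_logistic_penalized(
    samples: list[TransitionSample],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticTransitionFit:
    """Firth-type bias-reduced logistic fit (Jeffreys-prior penalty).

    Maximizes ℓ(β) + ½·log det I(β) via IRLS with hat-value–adjusted
    working counts; estimates remain finite under complete separation.
    """
    return _fit(samples, firth=True, tol=tol, max_iter=max_iter,
                separation_bound=np.inf)


def fit_transition(
    samples: list[TransitionSample],
    method: str = "auto",
    **kwargs,
) -> LogisticTransitionFit:
    """Fit one transition with explicit or automatic estimator choice.

    ``auto`` uses the bias-reduced fit when the data are separated (the
    typical situation for the fast, synchronous embryonic transitions)
    and plain maximum likelihood otherwise.
    """
    if method not in ("auto", "ml", "penalized"):
        raise ValueError(f"unknown method {method!r}")
    pen_kwargs = {k: v for k, v in kwargs.items() if k != "separation_bound"}
    if method == "ml":
        return fit_logistic_ml(samples, **kwargs)
    if method == "penalized":
        return fit_logistic_penalized(samples, **pen_kwargs)
    if detect_separation(samples):
        return fit_logistic_penalized(samples, **pen_kwargs)
    fit = fit_logistic_ml(samples, **kwargs)
    if fit.separation or not fit.converged:
        return fit_logistic_penalized(samples, **pen_kwargs)
    return fit


def median_transition_time(fit: LogisticTransitionFit) -> float:
    """Age (h) at which the fitted logistic crosses P = 0.5: −β0/β1."""
    if fit.beta1 <= 0:
        raise ValueError(
            f"non-monotone transition ({fit.transition}: beta1={fit.beta1:.4g} <= 0)"
        )
    return -fit.beta0 / fit.beta1
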