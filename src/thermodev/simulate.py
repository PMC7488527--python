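"""Cohort simulator with known ground-truth thermal parameters.

Generates the two data streams the analysis consumes:

* destructive samples — cohorts of eggs laid within a short collection
  window, incubated at constant temperature and scored at scheduled ages
  against every embryonic/early-larval stage boundary, yielding binomial
  counts of individuals past each transition; and
* individually resolved records — per-beetle larval/pupal/teneral
  durations and adult mass with sex-specific temperature responses.

Each stage's median duration follows its thermal law, D_s(T) = 1/R_s(T)
with R_s linear (a_s + b_s·T) or quadratic in temperature.  An
individual's realized stage duration is D_s(T)·exp(ε)·exp(η) with
stage-specific lognormal noise ε (parametrized by a coefficient of
variation) and an optional individual-level lognormal factor η shared
across all stages, modelling persistently slow or fast developers.
Oviposition is jittered uniformly across the collection window around the
recorded (midpoint) age.  Default parameters reproduce the fitted thermal
laws and realized chamber temperatures of the reference dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ontology import DEFAULT_ONTOLOGY, StageOntology
from .records import IndividualRecord, TransitionSample
from . import refdata

__all__ = ["ThermalLaw", "SimConfig", "simulate_cohort", "default_config"]


@dataclass(frozen=True)
class ThermalLaw:
    """Thermal law for one stage's median developmental rate.

    ``kind='linear'``: R(T) = a + b·T; ``kind='quadratic'``:
    R(T) = c2·T² + c1·T + c0.  ``rate_units`` fixes the duration scale
    (per_hour → hours, per_day → days).
    """

    kind: str
    coef: tuple[float, ...]
    rate_units: str = "per_hour"

    def rate(self, temp_c: float) -> float:
        if self.kind == "linear":
            a, b = self.coef
            return a + b * temp_c
        if self.kind == "quadratic":
            c2, c1, c0 = self.coef
            return c2 * temp_c**2 + c1 * temp_c + c0
        raise ValueError(f"unknown law kind {self.kind!r}")

    def median_duration(self, temp_c: float) -> float:
        r = self.rate(temp_c)
        if r <= 0:
            raise ValueError(
                f"non-positive implied rate at {temp_c} °C for law {self}"
            )
        return 1.0 / r


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a simulated rearing experiment."""

    ontology: StageOntology = DEFAULT_ONTOLOGY
    laws: dict[str, ThermalLaw] = field(default_factory=dict)
    temperatures: tuple[float, ...] = ()
    regime_labels: tuple[str, ...] = ()
    #: lognormal coefficient of variation of individual stage durations
    cv: float | dict[str, float] = 0.08
    #: SD of the per-individual lognormal factor shared across stages
    shared_factor_sd: float = 0.0
    collection_window_min: float = 20.0
    #: destructive schedule: (regime_label, temp_c, age_h, n) tuples
    schedule: tuple[tuple[str, float, float, int], ...] = ()
    #: individuals reared per temperature for the within-seed stages
    n_individuals_per_temp: int = 115
    sex_ratio: float = 0.5  # probability of female
    #: additive shift of the female rate intercept per within-seed stage
    sex_rate_offset: dict[str, float] = field(default_factory=dict)
    #: mass model: sex -> (m0, m1, m2) for mass = m0 + m1·Tc + m2·Tc², Tc = T − 26
    mass_model: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "female": (6.95, -0.12, 0.0),
            "male": (5.07, -0.02, 0.015),
        }
    )
    mass_sd_mg: float = 0.8
    #: optional Poisson-distributed sample sizes (mean = scheduled n)
    poisson_n: bool = False

    def stage_cv(self, stage: str) -> float:
        if isinstance(self.cv, dict):
            return float(self.cv.get(stage, 0.0))
        return float(self.cv)

    def validate(self) -> None:
        if self.shared_factor_sd < 0:
            raise ValueError("shared_factor_sd must be >= 0")
        if self.collection_window_min < 0:
            raise ValueError("collection window must be >= 0")
        if not (0 <= self.sex_ratio <= 1):
            raise ValueError("sex_ratio must be in [0, 1]")
        for s in self.ontology.stages:
            if self.stage_cv(s) < 0:
                raise ValueError(f"negative CV for stage {s!r}")
            if s not in self.laws:
                raise ValueError(f"no thermal law for stage {s!r}")
        for _, temp, age, n in self.schedule:
            if n < 1:
                raise ValueError("scheduled n must be >= 1")
            if age < 0:
                raise ValueError("scheduled age must be >= 0")
        temps = set(self.temperatures) | {t for _, t, _, _ in self.schedule}
        for s in self.ontology.stages:
            law = self.laws[s]
            for T in temps:
                if law.rate(T) <= 0:
                    raise ValueError(
                        f"thermal law for stage {s!r} implies non-positive "
                        f"duration at {T} °C"
                    )


def _sigma_from_cv(cv: float) -> float:
    # lognormal with multiplicative median 1 and coefficient of variation cv
    return float(np.sqrt(np.log1p(cv**2)))


def _stage_durations(
    config: SimConfig,
    stages: tuple[str, ...],
    temp_c: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n, len(stages)) matrix of realized stage durations at one temperature."""
    eta = (
        rng.normal(0.0, config.shared_factor_sd, size=n)
        if config.shared_factor_sd > 0
        else np.zeros(n)
    )
    out = np.empty((n, len(stages)))
    for j, s in enumerate(stages):
        med = config.laws[s].median_duration(temp_c)
        sigma = _sigma_from_cv(config.stage_cv(s))
        eps = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
        out[:, j] = med * np.exp(eps + eta)
    return out


def simulate_cohort(
    config: SimConfig, seed: int
) -> tuple[list[TransitionSample], list[IndividualRecord]]:
    """Run one simulated experiment; identical config+seed gives identical output.

    For each scheduled destructive sample, ``n`` fresh individuals are
    drawn (destructive sampling sacrifices the cohort, so samples are
    independent), their cumulative transition times computed as running
    sums of stage durations, and the count past each transition recorded.
    Recorded ages are collection-window midpoints; the true developmental
    age of an individual is the recorded age plus a uniform jitter of up
    to half the window either way.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    dest = config.ontology.destructive_stages
    indiv = config.ontology.individual_stages
    half_window_h = config.collection_window_min / 60.0 / 2.0

    samples: list[TransitionSample] = []
    for regime, temp, age, n_sched in config.schedule:
        n = int(rng.poisson(n_sched)) if config.poisson_n else int(n_sched)
        if n < 1:
            n = 1
        durs = _stage_durations(config, dest, temp, n, rng)  # hours
        cum = np.cumsum(durs, axis=1)
        jitter = (
            rng.uniform(-half_window_h, half_window_h, size=n)
            if half_window_h > 0
            else np.zeros(n)
        )
        true_age = age + jitter
        for j, stage in enumerate(dest):
            samples.append(
                TransitionSample(
                    regime=regime,
                    temp_c=temp,
                    age_h=age,
                    transition=stage,
                    n_total=n,
                    n_past=int(np.sum(cum[:, j] <= true_age)),
                )
            )

    records: list[IndividualRecord] = []
    for temp in config.temperatures:
        n = config.n_individuals_per_temp
        # stratified assignment: the expected sex ratio holds exactly per
        # temperature, so sex contrasts stay orthogonal to any temperature
        # response (including the quadratic teneral law the linear ANOVA
        # model does not capture)
        n_female = int(round(n * config.sex_ratio))
        female = np.zeros(n, dtype=bool)
        female[:n_female] = True
        female = rng.permutation(female)
        eta = (
            rng.normal(0.0, config.shared_factor_sd, size=n)
            if config.shared_factor_sd > 0
            else np.zeros(n)
        )
        durs = {}
        for s in indiv:
            law = config.laws[s]
            base_rate = law.rate(temp)
            offs = config.sex_rate_offset.get(s, 0.0)
            rate = np.where(female, base_rate + offs, base_rate)
            if np.any(rate <= 0):
                raise ValueError(
                    f"sex-adjusted rate non-positive for stage {s!r} at {temp} °C"
                )
            sigma = _sigma_from_cv(config.stage_cv(s))
            eps = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
            durs[s] = (1.0 / rate) * np.exp(eps + eta)  # days
        tc = temp - 26.0
        mass = np.empty(n)
        for sex, is_sex in (("female", female), ("male", ~female)):
            m0, m1, m2 = config.mass_model[sex]
            mass[is_sex] = m0 + m1 * tc + m2 * tc**2
        if config.mass_sd_mg > 0:
            mass = mass + rng.normal(0.0, config.mass_sd_mg, size=n)
        mass = np.maximum(mass, 0.01)
        for i in range(n):
            records.append(
                IndividualRecord(
                    id=f"T{temp:g}-{i:04d}",
                    temp_c=temp,
                    sex="female" if female[i] else "male",
                    larval_d=float(durs["larva"][i]) if "larva" in durs else None,
                    pupal_d=float(durs["pupa"][i]) if "pupa" in durs else None,
                    teneral_d=float(durs["teneral"][i]) if "teneral" in durs else None,
                    mass_mg=float(mass[i]),
                )
            )
    return samples, records


def default_schedule(
    config: SimConfig,
    rel_ages: tuple[float, ...] = (0.8, 0.875, 0.95, 1.0, 1.05, 1.125, 1.2),
    n_per_sample: int = 30,
) -> tuple[tuple[str, float, float, int], ...]:
    """Destructive schedule bracketing each transition's true median time.

    For every temperature, sampling ages are placed at fixed multiples of
    each transition's true cumulative median (the union over transitions,
    rounded to 0.1 h), emulating the pilot-then-refine scheduling of a
    real destructive experiment.
    """
    dest = config.ontology.destructive_stages
    entries = []
    for regime, temp in zip(config.regime_labels, config.temperatures):
        medians = np.cumsum(
            [config.laws[s].median_duration(temp) for s in dest]
        )
        ages = sorted({round(m * f, 1) for m in medians for f in rel_ages})
        for age in ages:
            entries.append((regime, temp, float(age), n_per_sample))
    return tuple(entries)


#: individual-stage duration CVs implied by the reference quartile spreads
#: (the teneral stage is by far the most variable within-seed period)
INDIVIDUAL_STAGE_CV = {"larva": 0.15, "pupa": 0.12, "teneral": 0.40}


def default_config(
    cv: float | dict[str, float] = 0.08,
    shared_factor_sd: float = 0.0,
    n_per_sample: int = 30,
    n_individuals_per_temp: int = 115,
) -> SimConfig:
    """Study-condition defaults: reference thermal laws and realized temperatures.

    Destructive-stage laws are the per-hour linear coefficients fitted to
    the reference durations (the two markedly nonlinear stages get their
    OLS linear description as simulation truth, which is adequate over the
    permissive range); within-seed stages use the per-day reference
    coefficients, with the teneral stage quadratic.  The five realized
    pre-dorsal-closure chamber temperatures serve as the simulated
    temperatures.

    A scalar ``cv`` applies to the destructive stages; the within-seed
    stages then use the quartile-calibrated ``INDIVIDUAL_STAGE_CV``.  Pass
    a dict to control every stage explicitly.
    """
    coefs = refdata.reference_coefficients()
    laws: dict[str, ThermalLaw] = {}
    for stage in DEFAULT_ONTOLOGY.destructive_stages:
        if stage in coefs.index:
            a, b = coefs.loc[stage, ["a", "b"]]
        else:
            # nonlinear stages: linear OLS description of the reference durations
            durs = refdata.reference_durations().loc[stage].to_numpy()
            temps = np.asarray(refdata.actual_temperatures(stage))
            b, a = np.polyfit(temps, 1.0 / durs, 1)
        laws[stage] = ThermalLaw("linear", (float(a), float(b)), "per_hour")
    for stage in ("larva", "pupa"):
        a, b = coefs.loc[stage, ["a", "b"]]
        laws[stage] = ThermalLaw("linear", (float(a), float(b)), "per_day")
    laws["teneral"] = ThermalLaw(
        "quadratic", refdata.QUADRATIC_COEFFICIENTS["teneral"], "per_day"
    )

    if not isinstance(cv, dict):
        cv = {
            **{s: float(cv) for s in DEFAULT_ONTOLOGY.destructive_stages},
            **INDIVIDUAL_STAGE_CV,
        }

    temps = refdata.ACTUAL_TEMPS["pre_dorsal_closure"]
    labels = tuple(str(sp) for sp in refdata.SET_POINTS)
    cfg = SimConfig(
        laws=laws,
        temperatures=temps,
        regime_labels=labels,
        cv=cv,
        shared_factor_sd=shared_factor_sd,
        n_individuals_per_temp=n_individuals_per_temp,
    )
    return replace(cfg, schedule=default_schedule(cfg, n_per_sample=n_per_sample))
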