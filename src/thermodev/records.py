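"""Core record types shared by the simulator, estimators, and I/O layer."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TransitionSample:
    """One destructive sample scored against one stage boundary.

    A cohort of eggs laid within a short collection window is incubated at
    a constant temperature and sacrificed at ``age_h`` hours after
    oviposition (midpoint of the window); ``n_past`` of the ``n_total``
    individuals have reached or passed the later stage of the transition.
    """

    regime: str
    temp_c: float
    age_h: float
    transition: str
    n_total: int
    n_past: int

    def __post_init__(self) -> None:
        if self.n_total < 0 or self.n_past < 0:
            raise ValueError("counts must be non-negative")
        if self.n_past > self.n_total:
            raise ValueError(
                f"n_past ({self.n_past}) exceeds n_total ({self.n_total})"
            )
        if self.age_h < 0:
            raise ValueError("sample age must be non-negative")

    @property
    def proportion(self) -> float:
        return self.n_past / self.n_total if self.n_total else float("nan")


@dataclass(frozen=True)
class IndividualRecord:
    """One individually followed beetle: stage durations in days and adult mass.

    ``larval_d`` covers feeding and pupation preparation (boring into the
    seed is excluded), ``pupal_d`` the pupa, ``teneral_d`` the eclosed adult
    hardening inside the seed before emergence.  ``flags`` marks records to
    exclude (e.g. overlooked or discarded individuals).
    """

    id: str
    temp_c: float
    sex: str
    larval_d: float | None = None
    pupal_d: float | None = None
    teneral_d: float | None = None
    mass_mg: float | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("larval_d", "pupal_d", "teneral_d", "mass_mg"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
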