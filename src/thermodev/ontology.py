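"""Ordered developmental-stage ontology for *Callosobruchus maculatus*.

The life cycle from oviposition to adult emergence is divided into twelve
stages.  The first nine (embryonic and early larval) are observed by
destructive sampling of egg cohorts — each sample yields counts of
individuals at or past each stage boundary.  The last three (larva inside
the seed, pupa, teneral adult) are followed individually through an
incision in the seed coat, yielding one duration per individual per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DESTRUCTIVE = "destructive"
INDIVIDUAL = "individual"

#: Canonical stage ids in developmental order, with display labels.
DEFAULT_STAGES: tuple[tuple[str, str, str], ...] = (
    ("early_cleavages", "Early cleavages up to 256 nuclei", DESTRUCTIVE),
    ("late_cleavages", "Late cleavages and germ band formation", DESTRUCTIVE),
    ("germ_band_extension", "Germ band extension", DESTRUCTIVE),
    ("germ_band_retraction", "Germ band retraction", DESTRUCTIVE),
    ("dorsal_closure", "Dorsal closure", DESTRUCTIVE),
    ("final_morphogenesis", "Final morphogenesis", DESTRUCTIVE),
    ("sclerotization", "Sclerotization", DESTRUCTIVE),
    ("hatching", "Hatching", DESTRUCTIVE),
    ("boring", "Boring into the seed", DESTRUCTIVE),
    ("larva", "Larva (feeding and pupation)", INDIVIDUAL),
    ("pupa", "Pupa", INDIVIDUAL),
    ("teneral", "Teneral adult", INDIVIDUAL),
)


@dataclass(frozen=True)
class StageOntology:
    """Strictly ordered stage list with an observation mode per stage.

    Transition ``k`` separates stage ``k`` from stage ``k+1``; destructive
    stages must precede individually observed stages (the experimental
    design stages egg cohorts destructively and then follows late larvae
    one by one).
    """

    stages: tuple[str, ...] = tuple(s for s, _, _ in DEFAULT_STAGES)
    labels: dict[str, str] = field(
        default_factory=lambda: {s: lab for s, lab, _ in DEFAULT_STAGES}
    )
    observation_mode: dict[str, str] = field(
        default_factory=lambda: {s: m for s, _, m in DEFAULT_STAGES}
    )

    def __post_init__(self) -> None:
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage names must be unique")
        modes = [self.observation_mode[s] for s in self.stages]
        for m in modes:
            if m not in (DESTRUCTIVE, INDIVIDUAL):
                raise ValueError(f"unknown observation mode {m!r}")
        # destructive block must come first, with no interleaving
        seen_individual = False
        for m in modes:
            if m == INDIVIDUAL:
                seen_individual = True
            elif seen_individual:
                raise ValueError(
                    "destructive stages must precede individually observed stages"
                )

    @property
    def destructive_stages(self) -> tuple[str, ...]:
        return tuple(
            s for s in self.stages if self.observation_mode[s] == DESTRUCTIVE
        )

    @property
    def individual_stages(self) -> tuple[str, ...]:
        return tuple(
            s for s in self.stages if self.observation_mode[s] == INDIVIDUAL
        )

    def index(self, stage: str) -> int:
        return self.stages.index(stage)

    def label(self, stage: str) -> str:
        return self.labels.get(stage, stage)


DEFAULT_ONTOLOGY = StageOntology()
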