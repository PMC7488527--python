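"""CSV readers/writers and pipeline configuration.

Data interchange is plain CSV with fixed, documented headers:

* transition counts — ``regime,temp_c,age_h,transition,n_total,n_past``
* individual records — ``id,temp_c,sex,larval_d,pupal_d,teneral_d,mass_mg[,flags]``

Malformed rows are reported with their line numbers and reading fails
hard: silent data loss is worse than a traceback in a destructive
experiment that cannot be rerun.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .records import IndividualRecord, TransitionSample

logger = logging.getLogger(__name__)

TRANSITION_COLUMNS = ["regime", "temp_c", "age_h", "transition", "n_total", "n_past"]
INDIVIDUAL_COLUMNS = ["id", "temp_c", "sex", "larval_d", "pupal_d", "teneral_d",
                      "mass_mg"]


def _check_header(header: list[str], required: list[str], path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_transition_counts(path) -> list[TransitionSample]:
    """Read destructive-sample counts, validating every row."""
    path = Path(path)
    out: list[TransitionSample] = []
    errors: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty file", stacklevel=2)
            return []
        _check_header(reader.fieldnames, TRANSITION_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    TransitionSample(
                        regime=row["regime"],
                        temp_c=float(row["temp_c"]),
                        age_h=float(row["age_h"]),
                        transition=row["transition"],
                        n_total=int(row["n_total"]),
                        n_past=int(row["n_past"]),
                    )
                )
            except (ValueError, KeyError, TypeError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors))
    if not out:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
    return out


def write_transition_counts(samples: list[TransitionSample], path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRANSITION_COLUMNS)
        for s in samples:
            writer.writerow(
                [s.regime, repr(s.temp_c), repr(s.age_h), s.transition,
                 s.n_total, s.n_past]
            )


def read_individual_records(path) -> list[IndividualRecord]:
    """Read individually resolved records, validating every row."""
    path = Path(path)
    out: list[IndividualRecord] = []
    errors: list[str] = []

    def opt(v):
        return None if v in (None, "", "NA") else float(v)

    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty file", stacklevel=2)
            return []
        _check_header(reader.fieldnames, INDIVIDUAL_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            try:
                flags = frozenset(
                    f for f in (row.get("flags") or "").split("|") if f
                )
                out.append(
                    IndividualRecord(
                        id=row["id"],
                        temp_c=float(row["temp_c"]),
                        sex=row["sex"],
                        larval_d=opt(row["larval_d"]),
                        pupal_d=opt(row["pupal_d"]),
                        teneral_d=opt(row["teneral_d"]),
                        mass_mg=opt(row["mass_mg"]),
                        flags=flags,
                    )
                )
            except (ValueError, KeyError, TypeError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors))
    if not out:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
    return out


def write_individual_records(records: list[IndividualRecord], path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(INDIVIDUAL_COLUMNS + ["flags"])
        for r in records:
            writer.writerow(
                [
                    r.id,
                    repr(r.temp_c),
                    r.sex,
                    "" if r.larval_d is None else repr(r.larval_d),
                    "" if r.pupal_d is None else repr(r.pupal_d),
                    "" if r.teneral_d is None else repr(r.teneral_d),
                    "" if r.mass_mg is None else repr(r.mass_mg),
                    "|".join(sorted(r.flags)),
                ]
            )


@dataclass
class PipelineConfig:
    """End-to-end pipeline options; defaults mirror the study's choices."""

    transition_csv: str | None = None
    individual_csv: str | None = None
    simulate: bool = False  # generate inputs with the default simulator
    seed: int = 0
    method: str = "auto"  # logistic estimator: auto | ml | penalized
    separation_bound: float = 25.0
    r2_gate: float = 0.97
    se_method: str = "campbell"  # campbell | delta | bootstrap
    quantile_method: str = "linear"
    isomorphy_tolerance_c: float = 1.0
    duration_decimals: int = 2
    ltt_decimals: int = 1
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))
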