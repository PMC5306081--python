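"""Domain types and file I/O for Draize eye test studies.

A *study* is the unit of classification: one chemical instilled into the eyes
of 1-6 albino rabbits, each graded for corneal opacity (CO, 0-4), iritis
(IR, 0-2), conjunctival redness (CR, 0-3) and conjunctival chemosis (CC, 0-4)
at a series of observation times.  Time is stored as integer hours on a single
axis: the 1 h reading is ``1`` and day *d* is ``24*d``; the standard grid is
1 h and days 1, 2, 3, 7, 14 and 21, but ad-hoc days (e.g. day 15) are legal.

Unrecorded grades are ``None`` (MISSING) and are never treated as zero: they
do not enter severity means, persistence calls or CO = 4 detection.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "TISSUES",
    "MAX_GRADE",
    "HOUR1",
    "DAY7_H",
    "DAY14_H",
    "DAY21_H",
    "STANDARD_TIMES",
    "SEVERITY_TIMES",
    "PhysicalForm",
    "PhysicalGroup",
    "Observation",
    "AnimalRecord",
    "Study",
    "TissueMean",
    "SeverityMeans",
    "ValidationError",
    "severity_means",
    "read_studies",
    "write_studies",
]

TISSUES: tuple[str, ...] = ("CO", "IR", "CR", "CC")

#: maximum grade per tissue endpoint on the Draize scale
MAX_GRADE: dict[str, int] = {"CO": 4, "IR": 2, "CR": 3, "CC": 4}

HOUR1 = 1
DAY7_H = 168
DAY14_H = 336
DAY21_H = 504
STANDARD_TIMES: tuple[int, ...] = (1, 24, 48, 72, 168, 336, 504)
#: readings that enter the per-animal "severity" means (days 1-3)
SEVERITY_TIMES: tuple[int, ...] = (24, 48, 72)


class ValidationError(ValueError):
    """Raised when a study, animal or observation violates the dialect."""


class PhysicalForm(str, enum.Enum):
    """Physical form of the chemical as tested."""

    L = "L"
    L_SOLVENT_NEAT_UNKNOWN = "L_SOLVENT_NEAT_UNKNOWN"
    L_SOLVENT_AVAILABLE_S = "L_SOLVENT_AVAILABLE_S"
    S_WAXY = "S_WAXY"
    S = "S"
    UNKNOWN = "UNKNOWN"


class PhysicalGroup(str, enum.Enum):
    """Reporting granularity for physical form: liquids* / solids / unknown.

    ``LIQUIDS_STAR`` includes liquids and anything tested in solvent.
    """

    LIQUIDS_STAR = "LIQUIDS_STAR"
    SOLIDS = "SOLIDS"
    UNKNOWN = "UNKNOWN"


_FORM_TO_GROUP = {
    PhysicalForm.L: PhysicalGroup.LIQUIDS_STAR,
    PhysicalForm.L_SOLVENT_NEAT_UNKNOWN: PhysicalGroup.LIQUIDS_STAR,
    PhysicalForm.L_SOLVENT_AVAILABLE_S: PhysicalGroup.LIQUIDS_STAR,
    PhysicalForm.S_WAXY: PhysicalGroup.SOLIDS,
    PhysicalForm.S: PhysicalGroup.SOLIDS,
    PhysicalForm.UNKNOWN: PhysicalGroup.UNKNOWN,
}


@dataclass(frozen=True)
class Observation:
    """Grades of the four tissue endpoints at one observation time.

    ``grades`` maps tissue code to an integer grade, or ``None`` for MISSING.
    """

    time_hours: int
    grades: Mapping[str, Optional[int]]

    def __post_init__(self) -> None:
        if not isinstance(self.time_hours, int) or self.time_hours <= 0:
            raise ValidationError(
                f"time_hours must be a positive integer, got {self.time_hours!r}"
            )
        clean: dict[str, Optional[int]] = {}
        for tissue in TISSUES:
            g = self.grades.get(tissue)
            if g is None:
                clean[tissue] = None
                continue
            if isinstance(g, bool) or not isinstance(g, int):
                raise ValidationError(
                    f"{tissue} grade at {self.time_hours} h must be an integer, got {g!r}"
                )
            if not 0 <= g <= MAX_GRADE[tissue]:
                raise ValidationError(
                    f"{tissue} grade {g} at {self.time_hours} h outside "
                    f"[0, {MAX_GRADE[tissue]}]"
                )
            clean[tissue] = g
        unknown = set(self.grades) - set(TISSUES)
        if unknown:
            raise ValidationError(f"unknown tissue code(s): {sorted(unknown)}")
        object.__setattr__(self, "grades", clean)

    def grade(self, tissue: str) -> Optional[int]:
        return self.grades[tissue]


@dataclass
class AnimalRecord:
    """Time series of ocular grades for a single animal."""

    animal_id: str
    observations: Sequence[Observation]
    terminated_early: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValidationError(f"animal {self.animal_id!r} has no observations")
        self.observations = tuple(
            sorted(self.observations, key=lambda o: o.time_hours)
        )
        times = [o.time_hours for o in self.observations]
        for a, b in zip(times, times[1:]):
            if a == b:
                raise ValidationError(
                    f"animal {self.animal_id!r}: duplicate observation at {a} h"
                )
        if self.terminated_early is None:
            self.terminated_early = self.last_observation_hours < DAY21_H
        elif self.terminated_early and self.last_observation_hours >= DAY21_H:
            raise ValidationError(
                f"animal {self.animal_id!r}: terminated_early set but a day-21 "
                "observation is present"
            )

    @property
    def last_observation_hours(self) -> int:
        return self.observations[-1].time_hours

    def at(self, time_hours: int) -> Optional[Observation]:
        for obs in self.observations:
            if obs.time_hours == time_hours:
                return obs
        return None

    def grade_at(self, tissue: str, time_hours: int) -> Optional[int]:
        obs = self.at(time_hours)
        return None if obs is None else obs.grade(tissue)

    def last_recorded(self, tissue: str) -> tuple[Optional[int], Optional[int]]:
        """Latest non-missing grade for ``tissue`` as ``(grade, time_hours)``."""
        for obs in reversed(self.observations):
            g = obs.grade(tissue)
            if g is not None:
                return g, obs.time_hours
        return None, None


@dataclass
class Study:
    """One Draize eye test study: metadata plus 1-6 animal records."""

    study_id: str
    chemical_name: str
    animals: Sequence[AnimalRecord]
    cas_rn: Optional[str] = None
    physical_form: PhysicalForm = PhysicalForm.UNKNOWN
    severe_other_effects: bool = False
    other_effects_note: str = ""
    data_source: str = ""
    purity: Optional[str] = None
    comments: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.physical_form, str) and not isinstance(
            self.physical_form, PhysicalForm
        ):
            self.physical_form = PhysicalForm(self.physical_form)
        if not 1 <= len(self.animals) <= 6:
            raise ValidationError(
                f"study {self.study_id!r}: must have 1-6 animals, "
                f"got {len(self.animals)}"
            )
        self.animals = tuple(self.animals)
        ids = [a.animal_id for a in self.animals]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"study {self.study_id!r}: duplicate animal ids")

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def physical_group(self) -> PhysicalGroup:
        return _FORM_TO_GROUP[self.physical_form]


@dataclass(frozen=True)
class TissueMean:
    """Per-animal day 1-3 mean for one tissue (exact rational)."""

    mean: Optional[Fraction]
    n_readings: int

    @property
    def defined(self) -> bool:
        return self.mean is not None


@dataclass
class SeverityMeans:
    """Per-animal, per-tissue means of the 24/48/72 h gradings.

    Means are exact :class:`fractions.Fraction` values over the *available*
    readings among 24/48/72 h; an animal/tissue with no reading in that window
    is flagged undefined rather than silently zero.
    """

    per_animal: dict[str, dict[str, TissueMean]]
    warnings: list[str] = field(default_factory=list)

    def mean(self, animal_id: str, tissue: str) -> Optional[Fraction]:
        return self.per_animal[animal_id][tissue].mean

    def n_readings(self, animal_id: str, tissue: str) -> int:
        return self.per_animal[animal_id][tissue].n_readings


def severity_means(study: Study) -> SeverityMeans:
    """Compute the UN GHS "severity scores": day 1-3 means per animal/tissue.

    Only the 24, 48 and 72 h gradings enter the mean; the 1 h reading and any
    reading from day 7 onwards are excluded.  MISSING gradings are excluded
    from numerator and denominator alike.
    """
    per_animal: dict[str, dict[str, TissueMean]] = {}
    warnings: list[str] = []
    for animal in study.animals:
        row: dict[str, TissueMean] = {}
        for tissue in TISSUES:
            grades = [
                g
                for t in SEVERITY_TIMES
                if (g := animal.grade_at(tissue, t)) is not None
            ]
            if grades:
                row[tissue] = TissueMean(Fraction(sum(grades), len(grades)), len(grades))
            else:
                row[tissue] = TissueMean(None, 0)
        per_animal[animal.animal_id] = row
        n_avail = max(tm.n_readings for tm in row.values())
        if n_avail < len(SEVERITY_TIMES):
            warnings.append(
                f"study {study.study_id} animal {animal.animal_id}: only "
                f"{n_avail}/3 day 1-3 readings available"
            )
    return SeverityMeans(per_animal=per_animal, warnings=warnings)


# ---------------------------------------------------------------------------
# File dialect
#
# CSV is a two-file dialect sharing a path prefix:
#   <prefix>.studies.csv  -- one row per study (metadata)
#   <prefix>.scores.csv   -- long format, one row per (study, animal, time)
# JSON is a single file with one object per study.
# ---------------------------------------------------------------------------

_STUDY_COLS = [
    "study_id",
    "chemical_name",
    "cas_rn",
    "physical_form",
    "data_source",
    "purity",
    "severe_other_effects",
    "other_effects_note",
    "comments",
]
_SCORE_COLS = ["study_id", "animal_id", "time_hours", "CO", "IR", "CR", "CC"]


def _csv_paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    if p.name.endswith(".scores.csv"):
        stem = p.name[: -len(".scores.csv")]
        return p.with_name(f"{stem}.studies.csv"), p
    if p.name.endswith(".studies.csv"):
        stem = p.name[: -len(".studies.csv")]
        return p, p.with_name(f"{stem}.scores.csv")
    return p.with_name(p.name + ".studies.csv"), p.with_name(p.name + ".scores.csv")


def _parse_bool(value: str) -> bool:
    return str(value).strip().lower() in {"true", "1", "yes", "x"}


def _study_from_dict(payload: dict) -> Study:
    animals = []
    for arec in payload["animals"]:
        obs = [
            Observation(
                time_hours=int(o["time_hours"]),
                grades={t: o.get(t) for t in TISSUES},
            )
            for o in arec["observations"]
        ]
        animals.append(AnimalRecord(animal_id=str(arec["animal_id"]), observations=obs))
    return Study(
        study_id=str(payload["study_id"]),
        chemical_name=payload.get("chemical_name", ""),
        cas_rn=payload.get("cas_rn") or None,
        physical_form=PhysicalForm(payload.get("physical_form", "UNKNOWN")),
        animals=animals,
        severe_other_effects=bool(payload.get("severe_other_effects", False)),
        other_effects_note=payload.get("other_effects_note", ""),
        data_source=payload.get("data_source", ""),
        purity=payload.get("purity") or None,
        comments=payload.get("comments", ""),
    )


def _study_to_dict(study: Study) -> dict:
    return {
        "study_id": study.study_id,
        "chemical_name": study.chemical_name,
        "cas_rn": study.cas_rn,
        "physical_form": study.physical_form.value,
        "data_source": study.data_source,
        "purity": study.purity,
        "severe_other_effects": study.severe_other_effects,
        "other_effects_note": study.other_effects_note,
        "comments": study.comments,
        "animals": [
            {
                "animal_id": a.animal_id,
                "observations": [
                    {"time_hours": o.time_hours, **{t: o.grade(t) for t in TISSUES}}
                    for o in a.observations
                ],
            }
            for a in sorted(study.animals, key=lambda a: a.animal_id)
        ],
    }


def read_studies(path: str | Path, format: str = "csv") -> list[Study]:
    """Read fully validated studies from the CSV or JSON dialect.

    For ``format="csv"``, ``path`` is a prefix (or either of the two files):
    ``<prefix>.studies.csv`` holds metadata and ``<prefix>.scores.csv`` the
    long-format grade rows.  Blank grade cells are MISSING, not zero.
    """
    if format == "json":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return [_study_from_dict(p) for p in payload]
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    studies_path, scores_path = _csv_paths(path)
    meta = pd.read_csv(studies_path, dtype=str, keep_default_na=False)
    scores = pd.read_csv(scores_path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in _SCORE_COLS if c not in scores.columns]
    if missing_cols:
        raise ValidationError(f"scores file lacks column(s) {missing_cols}")

    grades_by_study: dict[str, dict[str, list[Observation]]] = {}
    seen: set[tuple[str, str, int]] = set()
    for row in scores.itertuples(index=False):
        sid, aid = str(row.study_id), str(row.animal_id)
        try:
            t = int(row.time_hours)
        except ValueError as exc:
            raise ValidationError(
                f"study {sid} animal {aid}: bad time_hours {row.time_hours!r}"
            ) from exc
        key = (sid, aid, t)
        if key in seen:
            raise ValidationError(
                f"study {sid} animal {aid}: duplicate observation at {t} h"
            )
        seen.add(key)
        grades: dict[str, Optional[int]] = {}
        for tissue in TISSUES:
            cell = str(getattr(row, tissue)).strip()
            if cell == "":
                grades[tissue] = None
                continue
            try:
                grades[tissue] = int(cell)
            except ValueError as exc:
                raise ValidationError(
                    f"study {sid} animal {aid} at {t} h: non-integer "
                    f"{tissue} grade {cell!r}"
                ) from exc
        try:
            obs = Observation(time_hours=t, grades=grades)
        except ValidationError as exc:
            raise ValidationError(f"study {sid} animal {aid}: {exc}") from exc
        grades_by_study.setdefault(sid, {}).setdefault(aid, []).append(obs)

    studies: list[Study] = []
    for row in meta.itertuples(index=False):
        sid = str(row.study_id)
        per_animal = grades_by_study.pop(sid, None)
        if not per_animal:
            raise ValidationError(f"study {sid}: no score rows")
        animals = [
            AnimalRecord(animal_id=aid, observations=obs_list)
            for aid, obs_list in sorted(per_animal.items())
        ]
        extra = {
            c: getattr(row, c)
            for c in meta.columns
            if c not in _STUDY_COLS and str(getattr(row, c)).strip()
        }
        comments = str(getattr(row, "comments", "") or "")
        if extra:  # unknown columns are preserved, not dropped
            extra_txt = "; ".join(f"{k}={v}" for k, v in sorted(extra.items()))
            comments = f"{comments} [{extra_txt}]" if comments else f"[{extra_txt}]"
        studies.append(
            Study(
                study_id=sid,
                chemical_name=str(getattr(row, "chemical_name", "") or ""),
                cas_rn=str(getattr(row, "cas_rn", "") or "") or None,
                physical_form=PhysicalForm(
                    str(getattr(row, "physical_form", "") or "UNKNOWN")
                ),
                animals=animals,
                severe_other_effects=_parse_bool(
                    getattr(row, "severe_other_effects", "")
                ),
                other_effects_note=str(getattr(row, "other_effects_note", "") or ""),
                data_source=str(getattr(row, "data_source", "") or ""),
                purity=str(getattr(row, "purity", "") or "") or None,
                comments=comments,
            )
        )
    if grades_by_study:
        raise ValidationError(
            f"score rows without metadata for study ids {sorted(grades_by_study)}"
        )
    return studies


def write_studies(
    studies: Iterable[Study], path: str | Path, format: str = "csv"
) -> None:
    """Write studies in canonical order (study_id, animal_id, time_hours)."""
    studies = sorted(studies, key=lambda s: s.study_id)
    if format == "json":
        Path(path).write_text(
            json.dumps([_study_to_dict(s) for s in studies], indent=1) + "\n",
            encoding="utf-8",
        )
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    studies_path, scores_path = _csv_paths(path)
    meta_rows = []
    score_rows = []
    for s in studies:
        meta_rows.append(
            {
                "study_id": s.study_id,
                "chemical_name": s.chemical_name,
                "cas_rn": s.cas_rn or "",
                "physical_form": s.physical_form.value,
                "data_source": s.data_source,
                "purity": s.purity or "",
                "severe_other_effects": "true" if s.severe_other_effects else "false",
                "other_effects_note": s.other_effects_note,
                "comments": s.comments,
            }
        )
        for a in sorted(s.animals, key=lambda a: a.animal_id):
            for o in a.observations:
                score_rows.append(
                    {
                        "study_id": s.study_id,
                        "animal_id": a.animal_id,
                        "time_hours": o.time_hours,
                        **{
                            t: ("" if o.grade(t) is None else o.grade(t))
                            for t in TISSUES
                        },
                    }
                )
    pd.DataFrame(meta_rows, columns=_STUDY_COLS).to_csv(studies_path, index=False)
    pd.DataFrame(score_rows, columns=_SCORE_COLS).to_csv(scores_path, index=False)
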