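"""Seeded generator of Draize studies with controlled classification targets.

Each :class:`SyntheticProfile` names a cell of the classification landscape —
a target category, optionally a target main driver, a persistence pattern
(none / minority / majority of animals at day 21), delayed CO = 4, early
termination, presence of the day-7 reading — and the generator emits studies
guaranteed (generate-then-verify, bounded retries) to classify to that target
under the standard rules.

Grade trajectories follow a peak-and-decay template: onset at 24 h, optional
delayed spike, roughly linear decay.  That is adequate for exercising the
classification logic; no biological kinetics are claimed, and the optional
grade jitter (``noise_level``) never alters the target classification because
off-target draws are rejected and retried.

The module also ships hand-crafted fixtures reproducing, at the pattern
level, study designs that exercise every corner of the rules (borderline
No Cat, persistence-only Cat 1, delayed CO = 4, undifferentiated Cat 2,
early-terminated SCNM); each carries its expected classification as
executable documentation.
"""

from __future__ import annotations

import enum
import zlib
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .engine import (
    Category,
    ClassificationResult,
    DriverCode,
    DriverGroup,
    NoCatSubgroup,
    classify,
)
from .records import (
    DAY7_H,
    DAY14_H,
    DAY21_H,
    MAX_GRADE,
    STANDARD_TIMES,
    TISSUES,
    AnimalRecord,
    Observation,
    PhysicalForm,
    Study,
)

__all__ = [
    "PersistencePattern",
    "SyntheticProfile",
    "PROFILES",
    "GenerationError",
    "generate_study",
    "generate_cohort",
    "WorkedExample",
    "worked_example_fixtures",
]

MAX_RETRIES = 50


class GenerationError(RuntimeError):
    """Profile is inconsistent or no on-target study found within the retry bound."""


class PersistencePattern(str, enum.Enum):
    NONE = "none"
    MINORITY = "minority"
    MAJORITY = "majority"


@dataclass(frozen=True)
class SyntheticProfile:
    name: str
    target_category: Category
    target_main_driver: Optional[DriverCode] = None
    target_subgroup: Optional[NoCatSubgroup] = None
    n_animals: int = 3
    persistence_pattern: PersistencePattern = PersistencePattern.NONE
    delayed_co4: bool = False
    early_termination: Optional[int] = None
    day7_reading_present: bool = True
    noise_level: float = 0.0
    seed: int = 0


def _check_consistent(p: SyntheticProfile) -> None:
    if not 1 <= p.n_animals <= 6:
        raise GenerationError(f"{p.name}: n_animals must be 1..6")
    if p.target_category in (Category.CAT2B, Category.NOCAT) and (
        p.persistence_pattern is not PersistencePattern.NONE
    ):
        raise GenerationError(
            f"{p.name}: {p.target_category.value} is incompatible with day-21 persistence"
        )
    severity_targets = {
        DriverCode.CO_MEAN_GE_3,
        DriverCode.IR_MEAN_GT_1_5,
        DriverCode.CO_MEAN_GE_1,
        DriverCode.CONJ_MEAN_GE_2,
        DriverCode.IR_MEAN_GE_1,
    }
    if p.target_main_driver in severity_targets and p.n_animals < 3:
        raise GenerationError(
            f"{p.name}: severity drivers need at least three animals"
        )
    if p.target_category in (
        Category.CAT2A,
        Category.CAT2B,
        Category.CAT2_UNDIFF,
        Category.NOCAT,
    ) and p.n_animals < 3:
        raise GenerationError(
            f"{p.name}: {p.target_category.value} requires >= 3 animals "
            "(fewer animals yield SCNM)"
        )


# -- trajectory templates ----------------------------------------------------


def _grid(p: SyntheticProfile) -> tuple[int, ...]:
    times = [t for t in STANDARD_TIMES if p.day7_reading_present or t != DAY7_H]
    if p.early_termination is not None:
        times = [t for t in times if t <= p.early_termination]
    return tuple(times)


def _series(times, onset_peak=0, decay=(0, 0, 0), hour1=0):
    """Map the grid to grades: 1 h value, 24-72 h peak, then day 7/14/21 tail."""
    tail = {DAY7_H: decay[0], DAY14_H: decay[1], DAY21_H: decay[2]}
    out = {}
    for t in times:
        if t == 1:
            out[t] = hour1
        elif t <= 72:
            out[t] = onset_peak
        else:
            out[t] = tail.get(t, decay[0])
    return out


def _animal(aid: str, times, co=None, ir=None, cr=None, cc=None) -> AnimalRecord:
    series = {"CO": co or {}, "IR": ir or {}, "CR": cr or {}, "CC": cc or {}}
    obs = [
        Observation(t, {k: series[k].get(t, 0) for k in TISSUES}) for t in times
    ]
    return AnimalRecord(animal_id=aid, observations=obs)


def _n_affected(p: SyntheticProfile) -> int:
    """How many animals carry the day-21 persistent effect."""
    from .engine import majority_threshold

    thr = majority_threshold(p.n_animals)
    if p.persistence_pattern is PersistencePattern.MAJORITY:
        return thr
    if p.persistence_pattern is PersistencePattern.MINORITY:
        return 1  # always < threshold for n >= 2
    return 0


def _build_base(p: SyntheticProfile) -> tuple[list[AnimalRecord], bool]:
    """Deterministic on-target study skeleton for a profile; (animals, other_fx)."""
    times = _grid(p)
    n = p.n_animals
    cat = p.target_category
    drv = p.target_main_driver
    animals: list[AnimalRecord] = []
    other_effects = False

    def mild(aid):  # low, fully reversing background response
        return _animal(
            aid,
            times,
            co={},
            cr=_series(times, onset_peak=1),
            cc={},
        )

    if cat is Category.NOCAT:
        sub = p.target_subgroup or NoCatSubgroup.CO_EQ0
        for i in range(n):
            co = cr = cc = None
            if sub in (NoCatSubgroup.CO_GT0, NoCatSubgroup.CO_GT0_STAR):
                co = {1: 2}  # CO > 0 at the 1 h reading only
            if i == 0 and sub in (
                NoCatSubgroup.CO_EQ0_STAR,
                NoCatSubgroup.CO_GT0_STAR,
            ):
                cr = _series(times, onset_peak=2, decay=(1, 0, 0))
                cc = _series(times, onset_peak=1)
            else:
                cr = _series(times, onset_peak=1)
            animals.append(_animal(f"a{i + 1}", times, co=co, cr=cr, cc=cc))

    elif cat in (Category.CAT2A, Category.CAT2B, Category.CAT2_UNDIFF):
        drv = drv or DriverCode.CO_MEAN_GE_1
        persist_d7 = cat is Category.CAT2A
        for i in range(n):
            affected = i < max(2, n - 1)  # a clear majority
            if drv is DriverCode.CONJ_MEAN_GE_2:
                cr = _series(
                    times, onset_peak=2 if affected else 1,
                    decay=(1 if persist_d7 and affected else 0, 0, 0),
                )
                animals.append(_animal(f"a{i + 1}", times, cr=cr))
            elif drv is DriverCode.IR_MEAN_GE_1:
                ir = _series(times, onset_peak=1 if affected else 0,
                             decay=(1 if persist_d7 and affected else 0, 0, 0))
                cr = _series(times, onset_peak=1)
                animals.append(_animal(f"a{i + 1}", times, ir=ir, cr=cr))
            else:
                co = _series(
                    times, onset_peak=2 if affected else 1,
                    decay=(1 if persist_d7 and affected else 0, 0, 0),
                )
                cr = _series(times, onset_peak=1)
                animals.append(_animal(f"a{i + 1}", times, co=co, cr=cr))

    elif cat is Category.CAT1:
        k = _n_affected(p)
        if drv is DriverCode.CO_MEAN_GE_3:
            for i in range(n):
                peak = 3 if i < max(2, n - 1) else 2
                co = _series(times, onset_peak=peak, decay=(2, 1, 0))
                animals.append(_animal(f"a{i + 1}", times, co=co,
                                       cr=_series(times, onset_peak=1)))
        elif drv is DriverCode.IR_MEAN_GT_1_5:
            for i in range(n):
                peak = 2 if i < max(2, n - 1) else 1
                ir = _series(times, onset_peak=peak, decay=(1, 0, 0))
                co = _series(times, onset_peak=1)
                animals.append(_animal(f"a{i + 1}", times, ir=ir, co=co,
                                       cr=_series(times, onset_peak=1)))
        elif drv in (DriverCode.CO_PERS_D21, DriverCode.CONJ_PERS_D21,
                     DriverCode.IR_PERS_D21):
            k = k or 1
            for i in range(n):
                affected = i < k
                co = ir = cr = cc = None
                if drv is DriverCode.CO_PERS_D21:
                    if affected and p.delayed_co4:
                        co = _series(times, onset_peak=1, decay=(2, 4, 2))
                    elif affected:
                        co = _series(times, onset_peak=2, decay=(2, 1, 1))
                    else:
                        co = _series(times, onset_peak=1)
                    cr = _series(times, onset_peak=1)
                elif drv is DriverCode.CONJ_PERS_D21:
                    cr = _series(times, onset_peak=2,
                                 decay=(2, 1, 2 if affected else 0))
                else:  # IR persistence
                    ir = _series(times, onset_peak=1,
                                 decay=(1, 1, 1 if affected else 0))
                    cr = _series(times, onset_peak=1)
                animals.append(_animal(f"a{i + 1}", times, co=co, ir=ir,
                                       cr=cr, cc=cc))
        elif drv is DriverCode.CO_EQ_4:
            k = k or 1
            for i in range(n):
                if i < k:
                    co = _series(times, onset_peak=2, decay=(2, 1, 0))
                    co[48] = 4  # spike; day 1-3 mean (2+4+2)/3 < 3
                else:
                    co = _series(times, onset_peak=1)
                animals.append(_animal(f"a{i + 1}", times, co=co,
                                       cr=_series(times, onset_peak=1)))
        elif drv is DriverCode.OTHER_EFFECTS:
            other_effects = True
            for i in range(n):
                animals.append(mild(f"a{i + 1}"))
        else:
            raise GenerationError(f"{p.name}: no Cat 1 construction for {drv}")

    elif cat is Category.SCNM:
        if p.early_termination is not None:
            for i in range(n):
                co = _series(times, onset_peak=2 if i == 0 else 1,
                             decay=(2, 2, 0))
                cr = _series(times, onset_peak=1)
                animals.append(_animal(f"a{i + 1}", times, co=co, cr=cr))
        else:
            for i in range(n):
                animals.append(mild(f"a{i + 1}") if n > 1 else _animal(
                    f"a{i + 1}", times,
                    co=_series(times, onset_peak=2, decay=(1, 0, 0)),
                    cr=_series(times, onset_peak=2, decay=(1, 0, 0)),
                ))
    else:
        raise GenerationError(f"{p.name}: unsupported target {cat}")

    return animals, other_effects


def _apply_noise(
    animals: Sequence[AnimalRecord], rng: np.random.Generator, level: float
) -> list[AnimalRecord]:
    out = []
    for a in animals:
        obs = []
        for o in a.observations:
            grades = {}
            for t in TISSUES:
                g = o.grade(t)
                if g is not None and rng.random() < level:
                    g = int(np.clip(g + rng.choice((-1, 1)), 0, MAX_GRADE[t]))
                grades[t] = g
            obs.append(Observation(o.time_hours, grades))
        out.append(AnimalRecord(animal_id=a.animal_id, observations=obs))
    return out


def _on_target(p: SyntheticProfile, result: ClassificationResult) -> bool:
    if result.category is not p.target_category:
        return False
    if p.target_main_driver is not None and result.main_driver is not p.target_main_driver:
        return False
    if p.target_subgroup is not None and result.nocat_subgroup is not p.target_subgroup:
        return False
    return True


def generate_study(
    profile: SyntheticProfile, seed: Optional[int] = None
) -> Study:
    """Emit one study that classifies exactly to the profile's target.

    Deterministic for a fixed ``(profile, seed)``.  Noise draws that knock the
    study off target are rejected; after ``MAX_RETRIES`` rejected draws a
    :class:`GenerationError` is raised rather than returning an off-target
    study.
    """
    _check_consistent(profile)
    seed = profile.seed if seed is None else seed
    name_tag = zlib.crc32(profile.name.encode()) & 0x7FFFFFFF  # stable across runs
    rng = np.random.default_rng(np.random.SeedSequence((seed, name_tag)))
    base, other_effects = _build_base(profile)
    for attempt in range(MAX_RETRIES + 1):
        animals = (
            _apply_noise(base, rng, profile.noise_level)
            if profile.noise_level > 0
            else base
        )
        study = Study(
            study_id=f"{profile.name}-s{seed}",
            chemical_name=f"synthetic {profile.name}",
            animals=animals,
            physical_form=PhysicalForm.L,
            severe_other_effects=other_effects,
            other_effects_note="synthetic severe observation" if other_effects else "",
            data_source="synthetic",
        )
        if _on_target(profile, classify(study)):
            return study
        if profile.noise_level == 0:
            break
    raise GenerationError(
        f"profile {profile.name!r}, seed {seed}: no on-target study within "
        f"{MAX_RETRIES} retries"
    )


def generate_cohort(
    spec: Mapping[SyntheticProfile | str, int], seed: int = 0
) -> list[Study]:
    """Reproducible cohort with exact per-profile counts."""
    studies: list[Study] = []
    ss = np.random.SeedSequence(seed)
    for profile, count in spec.items():
        if isinstance(profile, str):
            profile = PROFILES[profile]
        child_seeds = ss.spawn(1)[0].generate_state(count) >> 1  # < 2**31
        for i in range(count):
            s = generate_study(profile, seed=int(child_seeds[i]))
            s.study_id = f"{profile.name}-{seed}-{i}"
            studies.append(s)
    return studies


def _p(name, cat, drv=None, **kw) -> SyntheticProfile:
    return SyntheticProfile(name=name, target_category=cat, target_main_driver=drv, **kw)


#: registry of supported profiles; each verified by the round-trip tests
PROFILES: dict[str, SyntheticProfile] = {
    p.name: p
    for p in [
        _p("nocat_co0", Category.NOCAT, target_subgroup=NoCatSubgroup.CO_EQ0),
        _p("nocat_co0_star", Category.NOCAT, target_subgroup=NoCatSubgroup.CO_EQ0_STAR),
        _p("nocat_cogt0", Category.NOCAT, target_subgroup=NoCatSubgroup.CO_GT0),
        _p("nocat_cogt0_star", Category.NOCAT, target_subgroup=NoCatSubgroup.CO_GT0_STAR),
        _p("cat2b_co", Category.CAT2B, DriverCode.CO_MEAN_GE_1),
        _p("cat2b_conj", Category.CAT2B, DriverCode.CONJ_MEAN_GE_2),
        _p("cat2a_co", Category.CAT2A, DriverCode.CO_MEAN_GE_1),
        _p("cat2a_conj", Category.CAT2A, DriverCode.CONJ_MEAN_GE_2),
        _p("cat2_undiff", Category.CAT2_UNDIFF, DriverCode.CO_MEAN_GE_1,
           day7_reading_present=False),
        _p("cat1_sev_co", Category.CAT1, DriverCode.CO_MEAN_GE_3),
        _p("cat1_sev_ir", Category.CAT1, DriverCode.IR_MEAN_GT_1_5),
        _p("cat1_pers_co_minority", Category.CAT1, DriverCode.CO_PERS_D21,
           n_animals=6, persistence_pattern=PersistencePattern.MINORITY),
        _p("cat1_pers_co_majority", Category.CAT1, DriverCode.CO_PERS_D21,
           n_animals=3, persistence_pattern=PersistencePattern.MAJORITY),
        _p("cat1_pers_conj", Category.CAT1, DriverCode.CONJ_PERS_D21,
           n_animals=6, persistence_pattern=PersistencePattern.MINORITY),
        _p("cat1_pers_ir", Category.CAT1, DriverCode.IR_PERS_D21,
           n_animals=3, persistence_pattern=PersistencePattern.MINORITY),
        _p("cat1_co4", Category.CAT1, DriverCode.CO_EQ_4),
        _p("cat1_co4_delayed", Category.CAT1, DriverCode.CO_PERS_D21,
           n_animals=6, persistence_pattern=PersistencePattern.MINORITY,
           delayed_co4=True),
        _p("cat1_other", Category.CAT1, DriverCode.OTHER_EFFECTS),
        _p("scnm_early_term", Category.SCNM, early_termination=DAY14_H),
        _p("scnm_two_animals", Category.SCNM, n_animals=2),
        _p("scnm_single_animal", Category.SCNM, n_animals=1),
    ]
}


# ---------------------------------------------------------------------------
# Worked-example fixtures (synthetic "pattern" studies)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorkedExample:
    """A hand-built pattern study plus its expected classification."""

    study: Study
    category: Category
    main_driver: Optional[DriverCode] = None
    main_driver_group: Optional[DriverGroup] = None
    nocat_subgroup: Optional[NoCatSubgroup] = None
    scnm_probable: Optional[str] = None
    #: category expected under the full revised rules, when it differs
    revised_category: Optional[Category] = None
    revised_reason: tuple[str, ...] = ()


def _study(sid, animals, chem="synthetic pattern", other=False) -> Study:
    return Study(
        study_id=sid,
        chemical_name=chem,
        animals=animals,
        physical_form=PhysicalForm.L,
        severe_other_effects=other,
        data_source="synthetic",
    )


def worked_example_fixtures() -> dict[str, WorkedExample]:
    """Named pattern studies for the rule corners, with expected outcomes.

    These are synthetic reconstructions satisfying the textual constraints of
    well-known reference-study patterns (borderline No Cat, persistence-only
    Cat 1, delayed CO = 4, missing day-7 reading, early termination); they are
    not transcripts of any database rows.
    """
    T = STANDARD_TIMES
    ex: dict[str, WorkedExample] = {}

    # -- borderline No Cat: CO = 0 everywhere, one animal CR mean >= 2 ------
    a1 = _animal("a1", T, cr={24: 2, 48: 2, 72: 2, 168: 1}, cc={24: 1, 48: 1})
    a2 = _animal("a2", T, cr={24: 1, 48: 1})
    a3 = _animal("a3", T, cr={24: 1})
    ex["no324"] = WorkedExample(
        study=_study("no324-pattern", [a1, a2, a3]),
        category=Category.NOCAT,
        nocat_subgroup=NoCatSubgroup.CO_EQ0_STAR,
    )

    # -- No Cat with early transient CO but no borderline means -------------
    a1 = _animal("a1", T, co={1: 2, 24: 1}, cr={24: 1})
    a2 = _animal("a2", T, co={1: 2, 24: 1}, cr={24: 1})
    a3 = _animal("a3", T, co={1: 2}, cr={24: 1})
    ex["no275"] = WorkedExample(
        study=_study("no275-pattern", [a1, a2, a3]),
        category=Category.NOCAT,
        nocat_subgroup=NoCatSubgroup.CO_GT0,
    )

    # -- Cat 1 only via day-21 conjunctival grades of 1 ---------------------
    a1 = _animal("a1", T, cr={24: 2, 48: 2, 72: 2, 168: 2, 336: 1, 504: 1})
    a2 = _animal("a2", T, cr={24: 2, 48: 2, 72: 2, 168: 1, 336: 1, 504: 1})
    a3 = _animal("a3", T, cr={24: 2, 48: 2, 72: 1, 168: 1, 336: 1},
                 cc={24: 2, 48: 1, 72: 1, 168: 1, 336: 1, 504: 1})
    ex["no110"] = WorkedExample(
        study=_study("no110-pattern", [a1, a2, a3]),
        category=Category.CAT1,
        main_driver=DriverCode.CONJ_PERS_D21,
        main_driver_group=DriverGroup.PERSISTENCE,
        revised_category=Category.CAT2A,
        revised_reason=("rec1",),
    )

    # -- CR = 2 with CC = 1 and IR = 1 on day 21 in one animal --------------
    # other animals fully reversed by day 15 (ad-hoc 360 h reading)
    t15 = (1, 24, 48, 72, 168, 336, 360, 504)
    a1 = _animal("a1", t15, cr={24: 2, 48: 2, 72: 2, 168: 2, 336: 2, 360: 2, 504: 2},
                 cc={24: 2, 48: 1, 168: 1, 336: 1, 360: 1, 504: 1},
                 ir={24: 1, 48: 1, 168: 1, 336: 1, 360: 1, 504: 1})
    a2 = _animal("a2", t15, cr={24: 2, 48: 2, 72: 1, 168: 1, 336: 1})
    a3 = _animal("a3", t15, cr={24: 2, 48: 1, 168: 1})
    ex["no114"] = WorkedExample(
        study=_study("no114-pattern", [a1, a2, a3]),
        category=Category.CAT1,
        main_driver=DriverCode.CONJ_PERS_D21,
        main_driver_group=DriverGroup.PERSISTENCE,
    )

    # -- CR = 3 on day 21 in 2/6 animals, no corneal involvement ------------
    animals = []
    for i in range(6):
        persist = i < 2
        animals.append(
            _animal(
                f"a{i + 1}", T,
                cr={24: 3, 48: 3, 72: 2, 168: 3 if persist else 1,
                    336: 3 if persist else 0, 504: 3 if persist else 0},
            )
        )
    ex["no117"] = WorkedExample(
        study=_study("no117-pattern", animals),
        category=Category.CAT1,
        main_driver=DriverCode.CONJ_PERS_D21,
        main_driver_group=DriverGroup.PERSISTENCE,
        revised_category=Category.CAT2A,
        revised_reason=("rec2",),
    )

    # -- CO persistence in 1/6, day 1-3 means between Cat 2 and Cat 1 -------
    animals = [
        _animal("a1", T, co={24: 2, 48: 2, 72: 2, 168: 2, 336: 1, 504: 1},
                cr={24: 1, 48: 1}),
    ]
    for i in range(1, 6):
        animals.append(
            _animal(f"a{i + 1}", T, co={24: 2, 48: 2, 72: 1, 168: 1},
                    cr={24: 1, 48: 1})
        )
    ex["no57"] = WorkedExample(
        study=_study("no57-pattern", animals),
        category=Category.CAT1,
        main_driver=DriverCode.CO_PERS_D21,
        main_driver_group=DriverGroup.PERSISTENCE,
        revised_category=Category.CAT2A,
        revised_reason=("rec2",),
    )

    # -- delayed CO = 4 on day 14 in 1/6, persisting ------------------------
    animals = [
        _animal("a1", T, co={24: 1, 48: 1, 72: 1, 168: 2, 336: 4, 504: 2},
                cr={24: 1, 48: 1}),
    ]
    for i in range(1, 6):
        animals.append(
            _animal(f"a{i + 1}", T, co={24: 1, 48: 1, 72: 1, 168: 1},
                    cr={24: 2, 48: 2, 72: 2, 168: 1})
        )
    ex["no80"] = WorkedExample(
        study=_study("no80-pattern", animals),
        category=Category.CAT1,
        main_driver=DriverCode.CO_PERS_D21,
        main_driver_group=DriverGroup.PERSISTENCE,
        revised_category=Category.CAT2A,
        revised_reason=("rec2",),
    )

    # -- CO = 4 in 1/3, terminated on day 14, persistence unknown -----------
    t14 = (1, 24, 48, 72, 168, 336)
    a1 = _animal("a1", t14, co={24: 2, 48: 4, 72: 2, 168: 3, 336: 3},
                 cr={24: 2, 48: 2, 72: 1, 168: 1, 336: 1})
    a2 = _animal("a2", (1, 24, 48, 72, 168, 336, 504),
                 co={24: 2, 48: 2, 72: 1, 168: 1}, cr={24: 1, 48: 1})
    a3 = _animal("a3", (1, 24, 48, 72, 168, 336, 504),
                 co={24: 1, 48: 1}, cr={24: 1})
    ex["no128"] = WorkedExample(
        study=_study("no128-pattern", [a1, a2, a3]),
        category=Category.CAT1,
        main_driver=DriverCode.CO_EQ_4,
        main_driver_group=DriverGroup.CO4,
    )

    # -- terminated day 14 with CO = 3 in 1/3: SCNM, Cat 1 assumed ----------
    t14 = (1, 24, 48, 72, 168, 336)
    a1 = _animal("a1", t14, co={24: 2, 48: 2, 72: 2, 168: 3, 336: 3},
                 cr={24: 1, 48: 1, 168: 1, 336: 1})
    a2 = _animal("a2", t14, co={1: 1}, cr={24: 1})
    a3 = _animal("a3", t14, co={24: 2, 48: 1, 72: 1}, cr={24: 1})
    ex["no589"] = WorkedExample(
        study=_study("no589-pattern", [a1, a2, a3]),
        category=Category.SCNM,
        scnm_probable="Cat 1",
    )

    # -- Cat 2 with no day-7 grading: subcategory cannot be resolved --------
    t_no7 = (1, 24, 48, 72, 336, 504)
    a1 = _animal("a1", t_no7, co={24: 1, 48: 1, 72: 1},
                 cr={24: 2, 48: 2, 72: 2}, cc={24: 2, 48: 1})
    a2 = _animal("a2", t_no7, co={24: 1, 48: 1, 72: 1}, cr={24: 2, 48: 2, 72: 2})
    a3 = _animal("a3", t_no7, cr={24: 2, 48: 2, 72: 2})
    ex["no217"] = WorkedExample(
        study=_study("no217-pattern", [a1, a2, a3]),
        category=Category.CAT2_UNDIFF,
        main_driver=DriverCode.CONJ_MEAN_GE_2,
        main_driver_group=DriverGroup.SEVERITY,
    )

    # -- single animal, severe AND persistent: Cat 1 via CO persistence -----
    a1 = _animal(
        "a1", T,
        co={24: 4, 48: 4, 72: 4, 168: 3, 336: 2, 504: 2},
        ir={24: 2, 48: 2, 72: 2, 168: 1, 336: 1, 504: 1},
        cr={24: 3, 48: 3, 72: 2, 168: 2, 336: 1, 504: 1},
    )
    ex["single_severe_persistent"] = WorkedExample(
        study=_study("single-severe-persistent-pattern", [a1]),
        category=Category.CAT1,
        main_driver=DriverCode.CO_PERS_D21,
        main_driver_group=DriverGroup.PERSISTENCE,
    )

    # -- CO = 4 in 1/3 that fully reversed by day 21 ------------------------
    a1 = _animal("a1", T, co={24: 2, 48: 4, 72: 2, 168: 2, 336: 1, 504: 0},
                 cr={24: 2, 48: 2, 72: 2, 168: 1})
    a2 = _animal("a2", T, co={24: 2, 48: 2, 72: 1, 168: 1}, cr={24: 2, 48: 2, 72: 2, 168: 1})
    a3 = _animal("a3", T, co={24: 1, 48: 1, 72: 1}, cr={24: 2, 48: 2, 72: 1})
    ex["co4_reversible"] = WorkedExample(
        study=_study("co4-reversible-pattern", [a1, a2, a3]),
        category=Category.CAT1,
        main_driver=DriverCode.CO_EQ_4,
        main_driver_group=DriverGroup.CO4,
        revised_category=Category.CAT2A,
        revised_reason=("rec2", "rec3"),
    )

    return ex
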