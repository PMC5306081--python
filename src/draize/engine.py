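"""UN GHS/EU CLP classification engine for Draize eye test studies.

Implements the 11 classification criteria (reported as 9 merged drivers, with
conjunctival redness and chemosis assessed independently but reported together
as "Conj"), the day-21 persistence/reversibility assessment, Cat 2A/2B
subcategorisation and the Study-Criteria-Not-Met (SCNM) logic.

Driver semantics
----------------
Cat 1:
  * ``CO_MEAN_GE_3``  - CO day 1-3 mean >= 3 in >=60 % of animals (n >= 3)
  * ``IR_MEAN_GT_1_5``- IR day 1-3 mean > 1.5 in >=60 % of animals (n >= 3)
  * ``CO_PERS_D21``   - CO > 0 at the day-21 reading in >= 1 animal
  * ``CONJ_PERS_D21`` - CR and/or CC > 0 at the day-21 reading in >= 1 animal
  * ``IR_PERS_D21``   - IR > 0 at the day-21 reading in >= 1 animal
  * ``CO_EQ_4``       - CO = 4 at any recorded time (incl. 1 h) in any animal
  * ``OTHER_EFFECTS`` - other severe reactions (e.g. pannus, discoloration)
Cat 2 (all require n >= 3 and the >=60 % majority):
  * ``CO_MEAN_GE_1``, ``CONJ_MEAN_GE_2`` (CR mean >= 2 and/or CC mean >= 2),
    ``IR_MEAN_GE_1``

Severity (mean-score) criteria are disabled for studies with fewer than three
animals: a >=60 % majority is not a meaningful classification basis there.
Persistence, CO = 4 and other-effects criteria apply at any group size.

All mean comparisons use exact rational arithmetic (grades are integers, day
1-3 means are multiples of 1/3), so cut-offs are never missed to float error.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

from .records import (
    DAY7_H,
    DAY14_H,
    DAY21_H,
    TISSUES,
    AnimalRecord,
    SeverityMeans,
    Study,
    severity_means,
)

__all__ = [
    "Category",
    "DriverCode",
    "DriverGroup",
    "NoCatSubgroup",
    "Driver",
    "TissueStatus",
    "ReversibilityStatus",
    "ClassificationResult",
    "CAT1_DRIVERS",
    "CAT2_DRIVERS",
    "PERSISTENCE_DRIVERS",
    "SEVERITY_CAT1_DRIVERS",
    "majority_threshold",
    "evaluate_criteria",
    "reversibility",
    "classify",
    "scnm_probable",
    "category_rank",
]


class Category(str, enum.Enum):
    CAT1 = "Cat 1"
    CAT2A = "Cat 2A"
    CAT2B = "Cat 2B"
    CAT2_UNDIFF = "Cat 2"
    NOCAT = "No Cat"
    SCNM = "SCNM"


class DriverCode(str, enum.Enum):
    CO_MEAN_GE_3 = "CO mean >= 3"
    IR_MEAN_GT_1_5 = "IR mean > 1.5"
    CO_PERS_D21 = "CO pers D21"
    CONJ_PERS_D21 = "Conj pers D21"
    IR_PERS_D21 = "IR pers D21"
    CO_EQ_4 = "CO = 4"
    CO_MEAN_GE_1 = "CO mean >= 1"
    CONJ_MEAN_GE_2 = "Conj mean >= 2"
    IR_MEAN_GE_1 = "IR mean >= 1"
    OTHER_EFFECTS = "Other effects"


class DriverGroup(str, enum.Enum):
    SEVERITY = "severity"
    PERSISTENCE = "persistence"
    CO4 = "CO = 4"
    OTHER = "other"


class NoCatSubgroup(str, enum.Enum):
    CO_GT0_STAR = "CO > 0**"
    CO_GT0 = "CO > 0"
    CO_EQ0_STAR = "CO = 0**"
    CO_EQ0 = "CO = 0"


SEVERITY_CAT1_DRIVERS = frozenset({DriverCode.CO_MEAN_GE_3, DriverCode.IR_MEAN_GT_1_5})
PERSISTENCE_DRIVERS = frozenset(
    {DriverCode.CO_PERS_D21, DriverCode.CONJ_PERS_D21, DriverCode.IR_PERS_D21}
)
CAT1_DRIVERS = (
    SEVERITY_CAT1_DRIVERS
    | PERSISTENCE_DRIVERS
    | {DriverCode.CO_EQ_4, DriverCode.OTHER_EFFECTS}
)
CAT2_DRIVERS = frozenset(
    {DriverCode.CO_MEAN_GE_1, DriverCode.CONJ_MEAN_GE_2, DriverCode.IR_MEAN_GE_1}
)


@dataclass(frozen=True)
class Driver:
    """A triggered classification criterion with its animal count.

    For the merged conjunctival drivers, ``n_animals_meeting`` is the size of
    the union of animals meeting the CR or the CC criterion, and
    ``component_detail`` keeps the per-endpoint counts.
    """

    code: DriverCode
    n_animals_meeting: int
    animal_ids: frozenset[str] = frozenset()
    component_detail: Optional[dict[str, int]] = None


class TissueStatus(str, enum.Enum):
    REVERSED = "reversed"
    PERSISTENT = "persistent"
    UNKNOWN = "unknown"


@dataclass
class ReversibilityStatus:
    """Per animal/tissue day-21 status plus study-level reversibility flags.

    ``UNKNOWN`` means there is no (non-missing) day-21 reading for that
    animal/tissue, e.g. after early humane termination — it is *not* evidence
    of recovery.  ``fully_reversed_by_21d`` is true iff every animal's last
    recorded grade of every observed tissue is 0 (whether the final reading is
    day 21 or earlier).
    """

    per_animal: dict[str, dict[str, TissueStatus]]
    fully_reversed_by_21d: bool
    any_unknown: bool

    def status(self, animal_id: str, tissue: str) -> TissueStatus:
        return self.per_animal[animal_id][tissue]


@dataclass
class ClassificationResult:
    category: Category
    drivers: tuple[Driver, ...]
    scnm_probable: Optional[str] = None
    main_driver: Optional[DriverCode] = None
    main_driver_group: Optional[DriverGroup] = None
    nocat_subgroup: Optional[NoCatSubgroup] = None
    borderline: bool = False
    fully_reversed_by_21d: bool = False
    any_unknown: bool = False
    warnings: list[str] = field(default_factory=list)

    def driver(self, code: DriverCode) -> Optional[Driver]:
        for d in self.drivers:
            if d.code == code:
                return d
        return None

    @property
    def driver_codes(self) -> frozenset[DriverCode]:
        return frozenset(d.code for d in self.drivers)


#: order used by the monotonicity/ordering properties (SCNM is incomparable)
_CATEGORY_RANK = {
    Category.NOCAT: 0,
    Category.CAT2B: 1,
    Category.CAT2_UNDIFF: 2,
    Category.CAT2A: 3,
    Category.CAT1: 4,
}


def category_rank(category: Category) -> Optional[int]:
    """Severity rank NOCAT < CAT2B < CAT2_UNDIFF < CAT2A < CAT1; None for SCNM."""
    return _CATEGORY_RANK.get(category)


def majority_threshold(n_animals: int) -> int:
    """Smallest k with k/n >= 0.6: 2/3, 3/4, 3/5 and 4/6 for the usual sizes."""
    if not 1 <= n_animals <= 6:
        raise ValueError(f"n_animals must be in 1..6, got {n_animals}")
    return -(-3 * n_animals // 5)  # ceil(3n/5), exact integer arithmetic


def _persists_at_d21(animal: AnimalRecord, tissue: str, low_conj_ok: bool) -> bool:
    """Grade > 0 at an explicit day-21 reading (>= 2 for CR/CC when rec1)."""
    g = animal.grade_at(tissue, DAY21_H)
    if g is None:
        return False
    floor = 2 if (low_conj_ok and tissue in ("CR", "CC")) else 1
    return g >= floor


def evaluate_criteria(
    study: Study,
    *,
    rec1: bool = False,
    rec2: bool = False,
    rec3: bool = False,
    means: Optional[SeverityMeans] = None,
) -> tuple[Driver, ...]:
    """Evaluate every classification criterion and return the triggered drivers.

    The ``rec*`` switches apply the proposed rule revisions (see
    :mod:`draize.revised`); all default to the standard UN GHS/EU CLP reading.
    """
    means = means if means is not None else severity_means(study)
    n = study.n_animals
    thr = majority_threshold(n)
    drivers: list[Driver] = []

    def meeting(tissue: str, cutoff, strict: bool = False) -> frozenset[str]:
        out = set()
        for a in study.animals:
            m = means.mean(a.animal_id, tissue)
            if m is None:
                continue
            if (m > cutoff) if strict else (m >= cutoff):
                out.add(a.animal_id)
        return frozenset(out)

    # severity criteria: only evaluable with >= 3 animals
    if n >= 3:
        for code, ids in (
            (DriverCode.CO_MEAN_GE_3, meeting("CO", 3)),
            (DriverCode.IR_MEAN_GT_1_5, meeting("IR", Fraction(3, 2), strict=True)),
        ):
            if len(ids) >= thr:
                drivers.append(Driver(code, len(ids), ids))
        for code, tissue, cutoff in (
            (DriverCode.CO_MEAN_GE_1, "CO", 1),
            (DriverCode.IR_MEAN_GE_1, "IR", 1),
        ):
            ids = meeting(tissue, cutoff)
            if len(ids) >= thr:
                drivers.append(Driver(code, len(ids), ids))
        cr_ids = meeting("CR", 2)
        cc_ids = meeting("CC", 2)
        if len(cr_ids) >= thr or len(cc_ids) >= thr:
            union = cr_ids | cc_ids
            drivers.append(
                Driver(
                    DriverCode.CONJ_MEAN_GE_2,
                    len(union),
                    union,
                    component_detail={"CR": len(cr_ids), "CC": len(cc_ids)},
                )
            )

    # persistence on day 21 (explicit 504 h reading with grade > 0);
    # rec2 requires the >=60 % majority and >= 3 animals instead of 1 animal
    def pers_ok(count: int) -> bool:
        return count >= thr and n >= 3 if rec2 else count >= 1

    pers_ids = {
        t: frozenset(
            a.animal_id for a in study.animals if _persists_at_d21(a, t, rec1)
        )
        for t in TISSUES
    }
    if pers_ok(len(pers_ids["CO"])):
        drivers.append(Driver(DriverCode.CO_PERS_D21, len(pers_ids["CO"]), pers_ids["CO"]))
    if pers_ok(len(pers_ids["CR"])) or pers_ok(len(pers_ids["CC"])):
        union = pers_ids["CR"] | pers_ids["CC"]
        drivers.append(
            Driver(
                DriverCode.CONJ_PERS_D21,
                len(union),
                union,
                component_detail={"CR": len(pers_ids["CR"]), "CC": len(pers_ids["CC"])},
            )
        )
    if pers_ok(len(pers_ids["IR"])):
        drivers.append(Driver(DriverCode.IR_PERS_D21, len(pers_ids["IR"]), pers_ids["IR"]))

    # CO = 4 at any recorded time point (including the 1 h reading)
    co4_ids = frozenset(
        a.animal_id
        for a in study.animals
        if any(o.grade("CO") == 4 for o in a.observations)
    )
    co4_present = pers_ok(len(co4_ids))
    if co4_present and rec3:
        # suppressed when every CO = 4 animal shows an explicit CO = 0 on day 21
        if all(
            next(a for a in study.animals if a.animal_id == aid).grade_at("CO", DAY21_H) == 0
            for aid in co4_ids
        ):
            co4_present = False
    if co4_present:
        drivers.append(Driver(DriverCode.CO_EQ_4, len(co4_ids), co4_ids))

    if study.severe_other_effects:
        drivers.append(Driver(DriverCode.OTHER_EFFECTS, 0))

    return tuple(drivers)


def _animal_reversed(
    animal: AnimalRecord,
    *,
    forgive: Optional[dict[str, frozenset[str]]] = None,
) -> bool:
    """True iff the animal's last recorded grade of every observed tissue is 0.

    ``forgive`` maps tissue -> animal ids whose day-21 residue is disregarded
    (used by the revised criteria, e.g. CR/CC = 1 on day 21 under rec1).
    """
    any_recorded = False
    for tissue in TISSUES:
        g, t = animal.last_recorded(tissue)
        if g is None:
            continue
        any_recorded = True
        if g == 0:
            continue
        if (
            forgive is not None
            and t == DAY21_H
            and animal.animal_id in forgive.get(tissue, frozenset())
        ):
            continue
        return False
    return any_recorded


def reversibility(study: Study) -> ReversibilityStatus:
    """Day-21 persistence status per animal/tissue plus study-level flags."""
    per_animal: dict[str, dict[str, TissueStatus]] = {}
    any_unknown = False
    for a in study.animals:
        row = {}
        for tissue in TISSUES:
            g = a.grade_at(tissue, DAY21_H)
            if g is None:
                row[tissue] = TissueStatus.UNKNOWN
                any_unknown = True
            elif g == 0:
                row[tissue] = TissueStatus.REVERSED
            else:
                row[tissue] = TissueStatus.PERSISTENT
        per_animal[a.animal_id] = row
    fully = all(_animal_reversed(a) for a in study.animals)
    return ReversibilityStatus(
        per_animal=per_animal, fully_reversed_by_21d=fully, any_unknown=any_unknown
    )


def _forgiven_residues(
    study: Study, rec1: bool, rec2: bool
) -> dict[str, frozenset[str]]:
    """Day-21 residues disregarded by the revised reversibility reading.

    rec1 forgives CR/CC = 1 on day 21 (recognised as fully reversed); rec2
    forgives any day-21 residue held by fewer than the majority threshold of
    animals (such minority findings are deemed unrelated to the chemical).
    """
    forgive: dict[str, set[str]] = {t: set() for t in TISSUES}
    n = study.n_animals
    thr = majority_threshold(n)
    for tissue in TISSUES:
        holders = [
            a.animal_id
            for a in study.animals
            if (g := a.grade_at(tissue, DAY21_H)) is not None and g > 0
        ]
        for a in study.animals:
            g = a.grade_at(tissue, DAY21_H)
            if g is None or g == 0:
                continue
            if rec1 and tissue in ("CR", "CC") and g == 1:
                forgive[tissue].add(a.animal_id)
            elif rec2 and n >= 3 and len(holders) < thr:
                forgive[tissue].add(a.animal_id)
    return {t: frozenset(ids) for t, ids in forgive.items()}


def classify(
    study: Study,
    *,
    rec1: bool = False,
    rec2: bool = False,
    rec3: bool = False,
) -> ClassificationResult:
    """Assign the UN GHS/EU CLP category of a study.

    Decision order:

    1. any Cat 1 driver -> ``CAT1``;
    2. SCNM if (a) any animal was terminated before day 21 without full
       reversal of its effects, (b) only two animals were used, or (c) a
       single animal was used (reaching here it showed neither CO = 4 nor
       persistence);
    3. any Cat 2 severity driver and full reversal by day 21 -> ``CAT2A`` /
       ``CAT2B`` / undifferentiated ``CAT2`` by the day-7 rule;
    4. otherwise ``NOCAT``.
    """
    from . import drivers as _drv  # late import: module boundary, no cycle at load

    means = severity_means(study)
    warnings = list(means.warnings)
    driver_set = evaluate_criteria(study, rec1=rec1, rec2=rec2, rec3=rec3, means=means)
    rev = reversibility(study)
    n = study.n_animals

    cat1 = [d for d in driver_set if d.code in CAT1_DRIVERS]
    if cat1:
        co4 = next((d for d in driver_set if d.code == DriverCode.CO_EQ_4), None)
        if co4 is not None and not any(
            o.grade("CO") == 4
            for a in study.animals
            for o in a.observations
            if o.time_hours > 1
        ):
            warnings.append("CO = 4 observed only at the 1 h reading drives Cat 1")
        result = ClassificationResult(
            category=Category.CAT1,
            drivers=driver_set,
            fully_reversed_by_21d=rev.fully_reversed_by_21d,
            any_unknown=rev.any_unknown,
            warnings=warnings,
        )
        assignment = _drv.assign_main_driver(result, study)
        result.main_driver = assignment.driver
        result.main_driver_group = assignment.group
        return result

    forgive = _forgiven_residues(study, rec1, rec2) if (rec1 or rec2) else None
    reversed_all = all(_animal_reversed(a, forgive=forgive) for a in study.animals)

    if rec2 and n < 3:
        had_suppressed_cat1 = any(
            (a.grade_at(t, DAY21_H) or 0) > 0
            for a in study.animals
            for t in TISSUES
        ) or any(o.grade("CO") == 4 for a in study.animals for o in a.observations)
        if had_suppressed_cat1:
            warnings.append(
                "revised majority rule: n < 3 studies cannot be classified Cat 1 "
                "via persistence or CO = 4 and are reported SCNM"
            )

    if not reversed_all:
        # rule 1: terminated (or unread) before day 21 without full reversal
        result = ClassificationResult(
            category=Category.SCNM,
            drivers=driver_set,
            fully_reversed_by_21d=False,
            any_unknown=rev.any_unknown,
            warnings=warnings,
        )
        result.scnm_probable = scnm_probable(study, result, means=means)
        return result
    if n <= 2:
        # rules 2 and 3: too few animals without any Cat 1 finding
        result = ClassificationResult(
            category=Category.SCNM,
            drivers=driver_set,
            fully_reversed_by_21d=True,
            any_unknown=rev.any_unknown,
            warnings=warnings,
        )
        result.scnm_probable = scnm_probable(study, result, means=means)
        return result

    cat2 = [d for d in driver_set if d.code in CAT2_DRIVERS]
    if cat2:
        subcat = _cat2_subcategory(study)
        result = ClassificationResult(
            category=subcat,
            drivers=driver_set,
            fully_reversed_by_21d=True,
            any_unknown=rev.any_unknown,
            warnings=warnings,
        )
        assignment = _drv.assign_main_driver(result, study)
        result.main_driver = assignment.driver
        result.main_driver_group = assignment.group
        return result

    result = ClassificationResult(
        category=Category.NOCAT,
        drivers=driver_set,
        fully_reversed_by_21d=True,
        any_unknown=rev.any_unknown,
        warnings=warnings,
    )
    result.nocat_subgroup = _drv.nocat_subgroup(study, result)
    result.borderline = result.nocat_subgroup in (
        NoCatSubgroup.CO_GT0_STAR,
        NoCatSubgroup.CO_EQ0_STAR,
    )
    return result


def _cat2_subcategory(study: Study) -> Category:
    """2A if any grade > 0 in [day 7, day 21); 2B needs an explicit all-zero
    day-7 reading; undifferentiated Cat 2 when day 7 was never graded."""
    any_d7_reading = False
    for a in study.animals:
        for o in a.observations:
            if DAY7_H <= o.time_hours < DAY21_H:
                if any((g or 0) > 0 for g in o.grades.values()):
                    return Category.CAT2A
            if o.time_hours == DAY7_H:
                any_d7_reading = True
    return Category.CAT2B if any_d7_reading else Category.CAT2_UNDIFF


def scnm_probable(
    study: Study,
    result: ClassificationResult,
    *,
    means: Optional[SeverityMeans] = None,
) -> str:
    """Most probable classification of an SCNM study, from the available data.

    Heuristics mirror the annotation practice for incomplete studies: a final
    reading on day 14 or later with CO >= 3 is assumed to persist ("Cat 1");
    Cat 2-level severity with unknown reversibility gives a lower bound; a
    complete benign pattern in an undersized study maps to the category the
    pattern itself determines.
    """
    if result.category is not Category.SCNM:
        raise ValueError("scnm_probable is only defined for SCNM results")
    means = means if means is not None else severity_means(study)
    n = study.n_animals

    for a in study.animals:
        if a.last_observation_hours < DAY21_H and a.last_observation_hours >= DAY14_H:
            g = a.grade_at("CO", a.last_observation_hours)
            if g is not None and g >= 3:
                return "Cat 1"

    # Cat 2-level severity pattern, using the majority rule at any group size
    thr = majority_threshold(n)

    def count(tissue: str, cutoff) -> int:
        return sum(
            1
            for a in study.animals
            if (m := means.mean(a.animal_id, tissue)) is not None and m >= cutoff
        )

    cat2_pattern = (
        count("CO", 1) >= thr
        or count("IR", 1) >= thr
        or count("CR", 2) >= thr
        or count("CC", 2) >= thr
    )
    all_means_defined = all(
        means.mean(a.animal_id, t) is not None
        for a in study.animals
        for t in TISSUES
    )
    reversed_all = all(_animal_reversed(a) for a in study.animals)

    if cat2_pattern:
        if not reversed_all:
            persists_d7 = any(
                (o.grade(t) or 0) > 0
                for a in study.animals
                for o in a.observations
                if o.time_hours >= DAY7_H
                for t in TISSUES
            )
            return "Cat 2A or higher" if persists_d7 else "at least Cat 2"
        subcat = _cat2_subcategory(study)
        return {
            Category.CAT2A: "Cat 2A",
            Category.CAT2B: "Cat 2B",
            Category.CAT2_UNDIFF: "Cat 2",
        }[subcat]

    if reversed_all and all_means_defined:
        return "No Cat"
    return "undetermined"
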