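"""Main driver of classification, No Cat subgroups and persistence grouping.

The *main driver* is the single prioritised criterion reported for every
classified study.  For Cat 1 the group order is severity (day 1-3 means) >
persistence on day 21 in the absence of severity > CO = 4 in the absence of
both (or when persistence is unknown) > other severe observations.  Within the
severity and persistence groups the endpoint with the largest number of
animals fulfilling the criterion wins; ties break CO > Conj > IR.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .engine import (
    CAT2_DRIVERS,
    PERSISTENCE_DRIVERS,
    SEVERITY_CAT1_DRIVERS,
    Category,
    ClassificationResult,
    DriverCode,
    DriverGroup,
    NoCatSubgroup,
    majority_threshold,
)
from .records import DAY21_H, TISSUES, Study, severity_means

__all__ = [
    "MainDriverAssignment",
    "PersistenceGroup",
    "assign_main_driver",
    "nocat_subgroup",
    "persistence_group",
]

# tie-break priority: CO first, then conjunctival effects, then iritis
_PRIORITY = {
    DriverCode.CO_MEAN_GE_3: 0,
    DriverCode.IR_MEAN_GT_1_5: 2,
    DriverCode.CO_PERS_D21: 0,
    DriverCode.CONJ_PERS_D21: 1,
    DriverCode.IR_PERS_D21: 2,
    DriverCode.CO_MEAN_GE_1: 0,
    DriverCode.CONJ_MEAN_GE_2: 1,
    DriverCode.IR_MEAN_GE_1: 2,
}

_CLASSIFIED = {Category.CAT1, Category.CAT2A, Category.CAT2B, Category.CAT2_UNDIFF}


@dataclass(frozen=True)
class MainDriverAssignment:
    group: DriverGroup
    driver: Optional[DriverCode]
    n_animals: int
    tie_broken: bool


class PersistenceGroup(str, enum.Enum):
    MAJORITY = "majority"
    MINORITY = "minority"
    NONE = "none"


def _pick(drivers) -> tuple[DriverCode, int, bool]:
    best = max(drivers, key=lambda d: (d.n_animals_meeting, -_PRIORITY[d.code]))
    tie = sum(1 for d in drivers if d.n_animals_meeting == best.n_animals_meeting) > 1
    return best.code, best.n_animals_meeting, tie


def assign_main_driver(
    result: ClassificationResult, study: Study
) -> MainDriverAssignment:
    """Select the single main driver of a classified study."""
    if result.category not in _CLASSIFIED:
        raise ValueError(
            f"main driver undefined for category {result.category.value}"
        )
    drivers = result.drivers

    if result.category is not Category.CAT1:
        cat2 = [d for d in drivers if d.code in CAT2_DRIVERS]
        if not cat2:
            raise ValueError("Cat 2 study without Cat 2 driver")
        code, n, tie = _pick(cat2)
        return MainDriverAssignment(DriverGroup.SEVERITY, code, n, tie)

    sev = [d for d in drivers if d.code in SEVERITY_CAT1_DRIVERS]
    if sev:
        code, n, tie = _pick(sev)
        return MainDriverAssignment(DriverGroup.SEVERITY, code, n, tie)
    pers = [d for d in drivers if d.code in PERSISTENCE_DRIVERS]
    if pers:
        code, n, tie = _pick(pers)
        return MainDriverAssignment(DriverGroup.PERSISTENCE, code, n, tie)
    co4 = next((d for d in drivers if d.code is DriverCode.CO_EQ_4), None)
    if co4 is not None:
        return MainDriverAssignment(
            DriverGroup.CO4, DriverCode.CO_EQ_4, co4.n_animals_meeting, False
        )
    other = next((d for d in drivers if d.code is DriverCode.OTHER_EFFECTS), None)
    if other is not None:
        return MainDriverAssignment(
            DriverGroup.OTHER, DriverCode.OTHER_EFFECTS, other.n_animals_meeting, False
        )
    raise ValueError("Cat 1 study without any eligible driver")


def nocat_subgroup(study: Study, result: ClassificationResult) -> NoCatSubgroup:
    """Four-way No Cat subgrouping on the CO axis with the borderline ** flag.

    CO > 0 means any CO grade above zero at any recorded time (including the
    1 h reading) in any animal.  ** marks borderline studies: at least one
    animal with a day 1-3 mean at or above a Cat 2 cut-off (CO >= 1, IR >= 1,
    CR >= 2 or CC >= 2), but in too few animals to classify.
    """
    if result.category is not Category.NOCAT:
        raise ValueError("nocat_subgroup is only defined for No Cat results")
    co_gt0 = any(
        (o.grade("CO") or 0) > 0 for a in study.animals for o in a.observations
    )
    means = severity_means(study)
    cutoffs = {"CO": 1, "IR": 1, "CR": 2, "CC": 2}
    star = any(
        (m := means.mean(a.animal_id, t)) is not None and m >= cutoffs[t]
        for a in study.animals
        for t in TISSUES
    )
    if co_gt0:
        return NoCatSubgroup.CO_GT0_STAR if star else NoCatSubgroup.CO_GT0
    return NoCatSubgroup.CO_EQ0_STAR if star else NoCatSubgroup.CO_EQ0


def persistence_group(study: Study, tissue: str) -> PersistenceGroup:
    """Majority/minority/none persistence of one tissue on day 21.

    Majority means persistence in >=60 % of the animals (the same threshold
    as the severity criteria); single-animal studies are excluded from this
    analysis.  ``tissue`` is one of CO/IR/CR/CC or ``"Conj"`` (CR and/or CC).
    """
    if study.n_animals < 2:
        raise ValueError("persistence grouping excludes single-animal studies")
    if tissue == "Conj":
        tissues = ("CR", "CC")
    elif tissue in TISSUES:
        tissues = (tissue,)
    else:
        raise ValueError(f"unknown tissue {tissue!r}")
    count = sum(
        1
        for a in study.animals
        if any((a.grade_at(t, DAY21_H) or 0) > 0 for t in tissues)
    )
    if count == 0:
        return PersistenceGroup.NONE
    if count >= majority_threshold(study.n_animals):
        return PersistenceGroup.MAJORITY
    return PersistenceGroup.MINORITY
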