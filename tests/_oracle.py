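"""Independent brute-force reading of the classification rules.

Deliberately written in a different style from the package engine (float
means, flat loops over the eleven criteria taken literally) and kept free of
any import from ``draize.engine``'s decision logic — it only consumes the
``Study`` container.  Valid for *complete* studies: >= 3 animals, every
animal graded for all four tissues at 1, 24, 48, 72, 168, 336 and 504 h.
"""

from __future__ import annotations

import math

import numpy as np

from draize.records import Observation, AnimalRecord, Study

FULL_GRID = (1, 24, 48, 72, 168, 336, 504)
MAXG = {"CO": 4, "IR": 2, "CR": 3, "CC": 4}


def _mean(animal, tissue):
    vals = [animal.grade_at(tissue, t) for t in (24, 48, 72)]
    return sum(vals) / 3.0


def _majority(n):
    return math.ceil(0.6 * n)


def oracle_drivers(study: Study) -> set[str]:
    """Literal check of each of the 11 criteria, merged to the 9 drivers."""
    n = len(study.animals)
    need = _majority(n)
    out = set()

    if sum(1 for a in study.animals if _mean(a, "CO") >= 3) >= need:
        out.add("CO_MEAN_GE_3")
    if sum(1 for a in study.animals if _mean(a, "IR") > 1.5) >= need:
        out.add("IR_MEAN_GT_1_5")
    if sum(1 for a in study.animals if _mean(a, "CO") >= 1) >= need:
        out.add("CO_MEAN_GE_1")
    if sum(1 for a in study.animals if _mean(a, "IR") >= 1) >= need:
        out.add("IR_MEAN_GE_1")
    cr = sum(1 for a in study.animals if _mean(a, "CR") >= 2)
    cc = sum(1 for a in study.animals if _mean(a, "CC") >= 2)
    if cr >= need or cc >= need:
        out.add("CONJ_MEAN_GE_2")

    if any(a.grade_at("CO", 504) > 0 for a in study.animals):
        out.add("CO_PERS_D21")
    if any(
        a.grade_at("CR", 504) > 0 or a.grade_at("CC", 504) > 0
        for a in study.animals
    ):
        out.add("CONJ_PERS_D21")
    if any(a.grade_at("IR", 504) > 0 for a in study.animals):
        out.add("IR_PERS_D21")
    if any(
        a.grade_at("CO", t) == 4 for a in study.animals for t in FULL_GRID
    ):
        out.add("CO_EQ_4")
    if study.severe_other_effects:
        out.add("OTHER_EFFECTS")
    return out


CAT1_SET = {
    "CO_MEAN_GE_3",
    "IR_MEAN_GT_1_5",
    "CO_PERS_D21",
    "CONJ_PERS_D21",
    "IR_PERS_D21",
    "CO_EQ_4",
    "OTHER_EFFECTS",
}
CAT2_SET = {"CO_MEAN_GE_1", "CONJ_MEAN_GE_2", "IR_MEAN_GE_1"}


def oracle_category(study: Study) -> str:
    drivers = oracle_drivers(study)
    if drivers & CAT1_SET:
        return "Cat 1"
    if drivers & CAT2_SET:
        # complete studies reaching here have all grades 0 on day 21
        late = any(
            a.grade_at(t2, t) > 0
            for a in study.animals
            for t in (168, 336)
            for t2 in MAXG
        )
        return "Cat 2A" if late else "Cat 2B"
    return "No Cat"


def random_complete_study(rng: np.random.Generator, study_id: str = "r") -> Study:
    """Random complete >=3-animal study covering all rule boundaries.

    Grades are drawn from a skewed distribution; a fraction of studies is
    forced to reverse from day 7 or day 14 onwards so that the Cat 2 / No Cat
    branches are exercised, not just persistence-driven Cat 1.
    """
    n = int(rng.integers(3, 7))
    reverse_from = rng.choice([168, 336, 999], p=[0.45, 0.25, 0.30])
    animals = []
    for i in range(n):
        obs = []
        for t in FULL_GRID:
            grades = {}
            for tissue, mx in MAXG.items():
                g = int(
                    rng.choice(
                        range(5), p=[0.52, 0.20, 0.13, 0.09, 0.06]
                    )
                )
                g = min(g, mx)
                if t >= reverse_from:
                    g = 0
                grades[tissue] = g
            obs.append(Observation(t, grades))
        animals.append(AnimalRecord(animal_id=f"a{i + 1}", observations=obs))
    return Study(
        study_id=study_id,
        chemical_name="random",
        animals=animals,
        severe_other_effects=bool(rng.random() < 0.02),
    )
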