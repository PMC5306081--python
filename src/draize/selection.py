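"""Reference-chemical selection rules for alternative-method validation.

A chemical whose in vivo classification is uncertain, driven by minority or
delayed effects, or not reproducible is a poor reference for developing or
validating alternative (non-animal) test methods.  This module codes those
exclusion criteria as rules R1-R10 and emits a recommended / conditional /
excluded verdict per chemical, separately for prospective studies and
retrospective evaluations.

R1  Cat 1 based only on CO = 4 and/or persistence in a minority (<60 %) of
    the animals                                      -> excluded (both)
R2  Cat 1 from a single-animal study                 -> excluded prospective,
    conditional retrospective; severe-and-persistent single-animal patterns
    are conditional in both
R3  Cat 1 based only on day-21 conjunctival scores of 1  -> excluded (both)
R4  Cat 1 via CO = 4 that reversed to 0 by day 21    -> excluded (both)
R5  SCNM                                             -> excluded prospective;
    annotations implying "requires classification" remain usable (conditional)
    for retrospective No Cat-vs-classified evaluations
R6  Cat 1 by other observations only (e.g. colourants)   -> conditional
R7  Discordant repeat studies                        -> excluded (both);
    2A/2B-only discordance -> conditional (usable under unified Cat 2)
R8  No Cat repeats spanning CO > 0** and CO = 0      -> excluded (both)
R9  Higher class at a lower tested concentration     -> conditional
R10 Purity < 95 % or unknown commercial source       -> conditional
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .engine import (
    PERSISTENCE_DRIVERS,
    SEVERITY_CAT1_DRIVERS,
    Category,
    ClassificationResult,
    DriverCode,
    DriverGroup,
    NoCatSubgroup,
    majority_threshold,
)
from .records import DAY21_H, Study
from .repro import ChemicalGroup, ConcordanceLevel, StudyOutcome, concordance

__all__ = [
    "Verdict",
    "Scope",
    "SelectionFlag",
    "SelectionRecord",
    "selection_record",
    "flag_chemical",
    "flag_cohort",
    "cohort_flag_summary",
]


class Verdict(str, enum.Enum):
    RECOMMENDED = "recommended"
    CONDITIONAL = "conditional"
    EXCLUDED = "excluded"


_SEVERITY_ORDER = {Verdict.RECOMMENDED: 0, Verdict.CONDITIONAL: 1, Verdict.EXCLUDED: 2}


class Scope(str, enum.Enum):
    PROSPECTIVE = "prospective"
    RETROSPECTIVE = "retrospective"
    BOTH = "both"


@dataclass(frozen=True)
class Reason:
    rule: str
    text: str


@dataclass
class SelectionFlag:
    """Per-chemical verdict with rule-coded reasons."""

    chemical: str
    verdict: Verdict
    verdict_retrospective: Verdict
    reasons: list[Reason]

    @property
    def scope(self) -> Scope:
        worst = max(self.verdict, self.verdict_retrospective, key=_SEVERITY_ORDER.get)
        if worst is Verdict.RECOMMENDED:
            return Scope.BOTH
        if self.verdict is self.verdict_retrospective:
            return Scope.BOTH
        return (
            Scope.PROSPECTIVE
            if _SEVERITY_ORDER[self.verdict] > _SEVERITY_ORDER[self.verdict_retrospective]
            else Scope.RETROSPECTIVE
        )


# SCNM annotations that still allow a "requires classification" conclusion
_SCNM_REQUIRES_CLASSIFICATION = {
    "Cat 1",
    "Cat 2A or higher",
    "Cat 2 or Cat 1",
    "Cat 2A",
    "Cat 2",
    "Cat 2B",
    "at least Cat 2",
}


@dataclass
class SelectionRecord:
    """Per-study facts the selection rules consume.

    Built from raw data via :func:`selection_record`, or filled by hand when
    only outcome-level information is available (rules needing missing raw
    detail simply do not fire).
    """

    outcome: StudyOutcome
    minority_cat1_basis: Optional[bool] = None
    single_animal_severe_persistent: Optional[bool] = None
    conj_pers_only_low: Optional[bool] = None
    co4_only_reversed: Optional[bool] = None
    other_effects_only: Optional[bool] = None
    purity_pct: Optional[float] = None
    source_known: bool = True


def selection_record(
    study: Study,
    result: ClassificationResult,
    *,
    purity_pct: Optional[float] = None,
    source_known: bool = True,
) -> SelectionRecord:
    """Derive the rule inputs for one classified study from its raw grades."""
    from .repro import outcome_from_result

    outcome = outcome_from_result(study, result)
    n = study.n_animals
    thr = majority_threshold(n)
    codes = result.driver_codes

    cat1_basis = codes & (PERSISTENCE_DRIVERS | {DriverCode.CO_EQ_4})
    has_severity = bool(codes & SEVERITY_CAT1_DRIVERS)
    minority = None
    if result.category is Category.CAT1:
        minority = (
            not has_severity
            and n >= 2
            and bool(cat1_basis)
            and all(
                d.n_animals_meeting < thr
                for d in result.drivers
                if d.code in cat1_basis
            )
            and DriverCode.OTHER_EFFECTS not in codes
        )

    severe_persistent = None
    if n == 1 and result.category is Category.CAT1:
        from .records import severity_means

        means = severity_means(study)
        a = study.animals[0]
        co = means.mean(a.animal_id, "CO")
        ir = means.mean(a.animal_id, "IR")
        severe = (co is not None and co >= 3) or (ir is not None and ir > 1.5)
        persistent = bool(codes & PERSISTENCE_DRIVERS)
        severe_persistent = severe and persistent

    conj_low = None
    if result.category is Category.CAT1:
        cat1_codes = codes - CAT2_CODES_IGNORED
        only_conj = cat1_codes & _CAT1_CODES == {DriverCode.CONJ_PERS_D21}
        if only_conj:
            d21 = [
                g
                for a in study.animals
                for t in ("CR", "CC")
                if (g := a.grade_at(t, DAY21_H)) is not None and g > 0
            ]
            conj_low = bool(d21) and max(d21) == 1
        else:
            conj_low = False

    co4_rev = None
    if result.category is Category.CAT1:
        cat1_codes = codes & _CAT1_CODES
        if cat1_codes == {DriverCode.CO_EQ_4}:
            co4_driver = result.driver(DriverCode.CO_EQ_4)
            co4_rev = all(
                a.grade_at("CO", DAY21_H) == 0
                for a in study.animals
                if a.animal_id in co4_driver.animal_ids
            )
        else:
            co4_rev = False

    other_only = (
        result.category is Category.CAT1
        and result.main_driver_group is DriverGroup.OTHER
    )

    return SelectionRecord(
        outcome=outcome,
        minority_cat1_basis=minority,
        single_animal_severe_persistent=severe_persistent,
        conj_pers_only_low=conj_low,
        co4_only_reversed=co4_rev,
        other_effects_only=other_only,
        purity_pct=purity_pct,
        source_known=source_known,
    )


_CAT1_CODES = PERSISTENCE_DRIVERS | SEVERITY_CAT1_DRIVERS | {
    DriverCode.CO_EQ_4,
    DriverCode.OTHER_EFFECTS,
}
CAT2_CODES_IGNORED = frozenset(
    {DriverCode.CO_MEAN_GE_1, DriverCode.CONJ_MEAN_GE_2, DriverCode.IR_MEAN_GE_1}
)


def flag_chemical(
    records: Sequence[SelectionRecord],
    *,
    related_lower_conc_higher_class: bool = False,
) -> SelectionFlag:
    """Apply rules R1-R10 to all studies of one chemical.

    ``records`` are the studies of a single chemical key (same tested
    concentration); ``related_lower_conc_higher_class`` feeds R9 from a
    cross-concentration comparison done by the caller.
    """
    if not records:
        raise ValueError("flag_chemical needs at least one study record")
    chemical = records[0].outcome.chemical
    reasons: list[tuple[Reason, Verdict, Verdict]] = []  # (reason, prosp, retro)

    def fire(rule, text, prospective, retrospective=None):
        reasons.append(
            (Reason(rule, text), prospective, retrospective or prospective)
        )

    for rec in records:
        o = rec.outcome
        if o.category is Category.CAT1:
            if o.n_animals == 1 or (o.n_animals is None and rec.single_animal_severe_persistent is not None):
                if rec.single_animal_severe_persistent:
                    fire("R2", f"study {o.study_id}: single-animal Cat 1 with severe, "
                               "persistent effects", Verdict.CONDITIONAL)
                else:
                    fire("R2", f"study {o.study_id}: Cat 1 from a single-animal study",
                         Verdict.EXCLUDED, Verdict.CONDITIONAL)
            elif rec.minority_cat1_basis:
                fire("R1", f"study {o.study_id}: Cat 1 only via CO = 4/persistence "
                           "in a minority of the animals", Verdict.EXCLUDED)
            if rec.conj_pers_only_low:
                fire("R3", f"study {o.study_id}: Cat 1 based only on day-21 "
                           "conjunctival scores of 1", Verdict.EXCLUDED)
            if rec.co4_only_reversed:
                fire("R4", f"study {o.study_id}: Cat 1 via CO = 4 that reversed "
                           "to 0 by day 21", Verdict.EXCLUDED)
            if rec.other_effects_only:
                fire("R6", f"study {o.study_id}: Cat 1 by other observations only",
                     Verdict.CONDITIONAL)
        elif o.category is Category.SCNM:
            retro = (
                Verdict.CONDITIONAL
                if (o.scnm_assumed or "") in _SCNM_REQUIRES_CLASSIFICATION
                else Verdict.EXCLUDED
            )
            fire("R5", f"study {o.study_id}: study criteria not met "
                       f"({o.scnm_assumed or 'no assumed class'})",
                 Verdict.EXCLUDED, retro)

    if len(records) >= 2:
        group = ChemicalGroup(chemical=chemical, outcomes=[r.outcome for r in records])
        split = concordance(group, unified_cat2=False)
        unified = concordance(group, unified_cat2=True)
        if split.level is ConcordanceLevel.DISCORDANT:
            if unified.concordant:
                fire("R7", "repeat studies discordant only in the Cat 2A/2B "
                           "subcategory", Verdict.CONDITIONAL)
            else:
                fire("R7", "repeat studies with discordant classifications",
                     Verdict.EXCLUDED)
        subgroups = {
            r.outcome.nocat_subgroup
            for r in records
            if r.outcome.nocat_subgroup is not None
        }
        all_nocatish = all(
            r.outcome.category is Category.NOCAT
            or r.outcome.nocat_subgroup is not None
            for r in records
        )
        if (
            all_nocatish
            and NoCatSubgroup.CO_GT0_STAR in subgroups
            and NoCatSubgroup.CO_EQ0 in subgroups
        ):
            fire("R8", "No Cat repeats spanning CO > 0** and CO = 0",
                 Verdict.EXCLUDED)

    if related_lower_conc_higher_class:
        fire("R9", "higher classification obtained at a lower tested "
                   "concentration", Verdict.CONDITIONAL)
    for rec in records:
        if rec.purity_pct is not None and rec.purity_pct < 95:
            fire("R10", f"study {rec.outcome.study_id}: purity below 95 %",
                 Verdict.CONDITIONAL)
            break
        if not rec.source_known:
            fire("R10", f"study {rec.outcome.study_id}: unknown commercial source",
                 Verdict.CONDITIONAL)
            break

    def worst(idx: int) -> Verdict:
        if not reasons:
            return Verdict.RECOMMENDED
        return max((r[idx] for r in reasons), key=_SEVERITY_ORDER.get)

    return SelectionFlag(
        chemical=chemical,
        verdict=worst(1),
        verdict_retrospective=worst(2),
        reasons=[r[0] for r in reasons],
    )


def flag_cohort(
    records: Iterable[SelectionRecord],
) -> list[SelectionFlag]:
    """Group records by chemical, apply R9 across concentrations, flag each.

    Concentrations are parsed from a trailing ``(x %)`` qualifier in the
    chemical name; the base name links the concentration series.
    """
    by_chem: dict[str, list[SelectionRecord]] = {}
    for r in records:
        by_chem.setdefault(r.outcome.chemical, []).append(r)

    conc_re = re.compile(r"^(?P<base>.*?)\s*\((?P<conc>[0-9.]+)\s*%.*\)\s*$")
    series: dict[str, list[tuple[float, str]]] = {}
    max_cat: dict[str, int] = {}
    rank = {
        Category.NOCAT: 0,
        Category.CAT2B: 1,
        Category.CAT2_UNDIFF: 1,
        Category.CAT2A: 1,
        Category.CAT1: 2,
    }
    for chem, recs in by_chem.items():
        m = conc_re.match(chem)
        if m:
            series.setdefault(m.group("base"), []).append(
                (float(m.group("conc")), chem)
            )
        cats = [rank.get(r.outcome.category) for r in recs]
        max_cat[chem] = max((c for c in cats if c is not None), default=-1)

    r9_chems: set[str] = set()
    for base, members in series.items():
        for conc_a, chem_a in members:
            for conc_b, chem_b in members:
                if conc_a < conc_b and max_cat[chem_a] > max_cat[chem_b] >= 0:
                    r9_chems.add(chem_a)
                    r9_chems.add(chem_b)

    return [
        flag_chemical(recs, related_lower_conc_higher_class=chem in r9_chems)
        for chem, recs in sorted(by_chem.items())
    ]


def cohort_flag_summary(flags: Iterable[SelectionFlag]) -> dict[str, dict[str, float]]:
    """Counts and fractions of verdicts over a flagged cohort (prospective)."""
    flags = list(flags)
    total = len(flags)
    out: dict[str, dict[str, float]] = {}
    for verdict in Verdict:
        n = sum(1 for f in flags if f.verdict is verdict)
        out[verdict.value] = {
            "n": n,
            "fraction": n / total if total else float("nan"),
        }
    out["total"] = {"n": total, "fraction": 1.0 if total else float("nan")}
    return out
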