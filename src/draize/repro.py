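"""Concordance of repeat Draize eye test studies of the same chemical.

Chemicals tested more than once in independent studies let the between-study
reproducibility of the test be quantified: do repeat studies agree on the
UN GHS category, on the main driver of classification, and (for chemicals
never requiring classification) on the No Cat subgroup?

Chemical identity includes the tested concentration — a 5 % and a 100 %
solution of the same surfactant are different test items and are never
merged.  SCNM studies can take part through their annotated most-probable
class ("assumed" class); annotations that only give a lower bound (e.g.
"at least Cat 2") take part in any comparison they decide (such as
classified-versus-No Cat) and render the group UNCERTAIN otherwise.

The module also packages, at the outcome level, the repeat-study groups of
the reference database: 24 chemical groups with at least one classified
study and 18 groups that are No Cat throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .engine import Category, ClassificationResult, DriverCode, NoCatSubgroup
from .records import Study

__all__ = [
    "StudyOutcome",
    "ChemicalGroup",
    "ConcordanceLevel",
    "ConcordanceVerdict",
    "Metric",
    "outcome_from_result",
    "group_repeats",
    "concordance",
    "summarize_concordance",
    "table4_fixture",
    "table5_fixture",
]


class ConcordanceLevel(str, enum.Enum):
    SAME_CLASS_SAME_DRIVER = "same class, same main driver"
    SAME_CLASS_DIFF_DRIVER = "same class, different main driver"
    SAME_SUBGROUP = "No Cat, same subgroup"
    DIFF_SUBGROUP = "No Cat, different subgroup"
    DISCORDANT = "different classification"
    UNCERTAIN = "uncertain"


_CONCORDANT = {
    ConcordanceLevel.SAME_CLASS_SAME_DRIVER,
    ConcordanceLevel.SAME_CLASS_DIFF_DRIVER,
    ConcordanceLevel.SAME_SUBGROUP,
}


@dataclass(frozen=True)
class StudyOutcome:
    """Classification outcome of a single study, as used for concordance."""

    study_id: str
    chemical: str
    category: Category
    main_driver: Optional[DriverCode] = None
    nocat_subgroup: Optional[NoCatSubgroup] = None
    #: SCNM annotation, e.g. "Cat 1", "Cat 2A", "No Cat", "at least Cat 2"
    scnm_assumed: Optional[str] = None
    n_animals: Optional[int] = None


@dataclass
class ChemicalGroup:
    chemical: str
    outcomes: list[StudyOutcome]

    @property
    def n(self) -> int:
        return len(self.outcomes)


@dataclass(frozen=True)
class ConcordanceVerdict:
    chemical: str
    level: ConcordanceLevel
    unified_cat2: bool
    use_assumed_scnm: bool

    @property
    def concordant(self) -> bool:
        return self.level in _CONCORDANT


def outcome_from_result(study: Study, result: ClassificationResult) -> StudyOutcome:
    """Build a concordance outcome from a classified study."""
    return StudyOutcome(
        study_id=study.study_id,
        chemical=study.chemical_name,
        category=result.category,
        main_driver=result.main_driver,
        nocat_subgroup=result.nocat_subgroup,
        scnm_assumed=result.scnm_probable,
        n_animals=study.n_animals,
    )


def group_repeats(outcomes: Iterable[StudyOutcome]) -> list[ChemicalGroup]:
    """Group outcomes by exact chemical key; only repeats (>= 2) are returned.

    Concentration-qualified names ("Triton X-100 (5 %)" vs "(100 %)") are
    distinct keys by construction.
    """
    by_key: dict[str, list[StudyOutcome]] = {}
    for o in outcomes:
        by_key.setdefault(o.chemical, []).append(o)
    return [
        ChemicalGroup(chemical=k, outcomes=sorted(v, key=lambda o: o.study_id))
        for k, v in sorted(by_key.items())
        if len(v) >= 2
    ]


# possible-category sets -----------------------------------------------------

_SPLIT_CAT2 = frozenset({Category.CAT2A, Category.CAT2B})
_ASSUMED_EXACT = {
    "Cat 1": frozenset({Category.CAT1}),
    "Cat 2A": frozenset({Category.CAT2A}),
    "Cat 2B": frozenset({Category.CAT2B}),
    "Cat 2": _SPLIT_CAT2,
    "No Cat": frozenset({Category.NOCAT}),
}
_ASSUMED_BOUNDS = {
    "at least Cat 2": _SPLIT_CAT2 | {Category.CAT1},
    "Cat 2A or higher": frozenset({Category.CAT2A, Category.CAT1}),
    "Cat 2 or Cat 1": _SPLIT_CAT2 | {Category.CAT1},
}


def _possible(
    outcome: StudyOutcome, unified_cat2: bool, use_assumed_scnm: bool
) -> Optional[frozenset[Category]]:
    """Set of categories the study could represent; ``None`` when unusable."""
    if outcome.category is Category.SCNM:
        if not use_assumed_scnm or not outcome.scnm_assumed:
            return None
        possible = _ASSUMED_EXACT.get(outcome.scnm_assumed) or _ASSUMED_BOUNDS.get(
            outcome.scnm_assumed
        )
        if possible is None:
            return None
    elif outcome.category is Category.CAT2_UNDIFF:
        possible = _SPLIT_CAT2
    else:
        possible = frozenset({outcome.category})
    if unified_cat2:
        possible = frozenset(
            Category.CAT2_UNDIFF if c in _SPLIT_CAT2 else c for c in possible
        )
    return possible


def concordance(
    group: ChemicalGroup,
    unified_cat2: bool = True,
    use_assumed_scnm: bool = True,
) -> ConcordanceVerdict:
    """Agreement verdict for one chemical's repeat studies.

    With ``unified_cat2`` the optional 2A/2B subcategories count as one class
    (the EU CLP reading).  With ``use_assumed_scnm`` SCNM members adopt their
    annotated most-probable class.
    """
    if group.n < 2:
        raise ValueError("concordance requires at least two studies")
    possible = [_possible(o, unified_cat2, use_assumed_scnm) for o in group.outcomes]
    level = _decide(group, possible)
    return ConcordanceVerdict(
        chemical=group.chemical,
        level=level,
        unified_cat2=unified_cat2,
        use_assumed_scnm=use_assumed_scnm,
    )


def _decide(group, possible) -> ConcordanceLevel:
    if any(p is None for p in possible):
        return ConcordanceLevel.UNCERTAIN
    for i, pi in enumerate(possible):
        for pj in possible[i + 1 :]:
            if not (pi & pj):
                return ConcordanceLevel.DISCORDANT
    if not all(len(p) == 1 for p in possible):
        return ConcordanceLevel.UNCERTAIN
    (cat,) = {next(iter(p)) for p in possible}
    if cat is Category.NOCAT:
        subgroups = {o.nocat_subgroup for o in group.outcomes}
        return (
            ConcordanceLevel.SAME_SUBGROUP
            if len(subgroups) == 1 and None not in subgroups
            else ConcordanceLevel.DIFF_SUBGROUP
        )
    drivers = {o.main_driver for o in group.outcomes}
    return (
        ConcordanceLevel.SAME_CLASS_SAME_DRIVER
        if len(drivers) == 1 and None not in drivers
        else ConcordanceLevel.SAME_CLASS_DIFF_DRIVER
    )


@dataclass(frozen=True)
class Metric:
    """A concordance fraction with its exact integer counts."""

    numerator: int
    denominator: int

    @property
    def pct(self) -> float:
        return 100.0 * self.numerator / self.denominator if self.denominator else float("nan")

    def __str__(self) -> str:
        return f"{self.pct:.1f} % ({self.numerator}/{self.denominator})"


def summarize_concordance(
    groups: Iterable[ChemicalGroup], use_assumed_scnm: bool = True
) -> dict[str, Metric]:
    """Cohort-level concordance fractions, on exact integer arithmetic.

    Groups are stratified by the highest definite class among their members:
    Cat 1 groups, groups whose maximum class is Cat 2, and all-No Cat groups.
    UNCERTAIN groups (no usable assumed class) are excluded from every
    denominator.  Both the unified-Cat 2 and the split-subcategory readings
    are reported for the classified strata.
    """
    groups = list(groups)
    verdict_u = {g.chemical: concordance(g, True, use_assumed_scnm) for g in groups}
    verdict_s = {g.chemical: concordance(g, False, use_assumed_scnm) for g in groups}

    cat1_groups, cat2_groups, nocat_groups = [], [], []
    for g in groups:
        if verdict_u[g.chemical].level is ConcordanceLevel.UNCERTAIN:
            continue
        poss = [_possible(o, False, use_assumed_scnm) for o in g.outcomes]
        if any(p == {Category.CAT1} for p in poss):
            cat1_groups.append(g)
        elif all(p == {Category.NOCAT} for p in poss):
            nocat_groups.append(g)
        else:
            cat2_groups.append(g)

    def frac(groups_, pred) -> Metric:
        return Metric(sum(1 for g in groups_ if pred(g)), len(groups_))

    def conc(vmap):
        return lambda g: vmap[g.chemical].concordant

    def same_driver(g) -> bool:
        return (
            verdict_u[g.chemical].level is ConcordanceLevel.SAME_CLASS_SAME_DRIVER
        )

    classified = cat1_groups + cat2_groups
    return {
        "cat1_concordant": frac(cat1_groups, conc(verdict_u)),
        "cat1_same_driver": frac(cat1_groups, same_driver),
        "cat2max_concordant_unified": frac(cat2_groups, conc(verdict_u)),
        "cat2max_concordant_split": frac(cat2_groups, conc(verdict_s)),
        "cat2max_with_nocat_study": frac(
            cat2_groups,
            lambda g: any(o.category is Category.NOCAT for o in g.outcomes),
        ),
        "nocat_same_subgroup": frac(nocat_groups, conc(verdict_u)),
        "classified_concordant_unified": frac(classified, conc(verdict_u)),
        "classified_concordant_split": frac(classified, conc(verdict_s)),
        "classified_same_driver": frac(classified, same_driver),
    }


# ---------------------------------------------------------------------------
# Packaged repeat-study groups, encoded at the outcome level
# ---------------------------------------------------------------------------

_C = Category
_D = DriverCode
_S = NoCatSubgroup


def _o(sid, chem, cat, driver=None, subgroup=None, assumed=None) -> StudyOutcome:
    return StudyOutcome(
        study_id=str(sid),
        chemical=chem,
        category=cat,
        main_driver=driver,
        nocat_subgroup=subgroup,
        scnm_assumed=assumed,
    )


def table4_fixture() -> list[ChemicalGroup]:
    """The 24 repeat-study chemical groups with at least one classified study.

    Outcome-level encoding (category, main driver, SCNM assumed class) of the
    replicate-study groups; raw per-animal grades for these studies exist only
    in the reference database itself.
    """
    rows: list[tuple[str, list[StudyOutcome]]] = []

    def grp(chem, *outs):
        rows.append((chem, list(outs)))

    grp(
        "Pyridine",
        _o(13, "Pyridine", _C.CAT1, _D.CO_MEAN_GE_3),
        _o(184, "Pyridine", _C.CAT2A, _D.CO_MEAN_GE_1),
    )
    grp(
        "2-Benzyl-4-chlorophenol",
        _o(19, "2-Benzyl-4-chlorophenol", _C.CAT1, _D.CO_MEAN_GE_3),
        _o(84, "2-Benzyl-4-chlorophenol", _C.CAT1, _D.CO_PERS_D21),
    )
    grp(
        "Dibenzoyl-L-tartaric acid",
        _o(26, "Dibenzoyl-L-tartaric acid", _C.CAT1, _D.CO_MEAN_GE_3),
        _o(27, "Dibenzoyl-L-tartaric acid", _C.CAT1, _D.CO_MEAN_GE_3),
    )
    grp(
        "Imidazole",
        _o(30, "Imidazole", _C.CAT1, _D.CO_MEAN_GE_3),
        _o(89, "Imidazole", _C.CAT1, _D.CO_PERS_D21),
    )
    grp(
        "Promethazine HCL",
        _o(31, "Promethazine HCL", _C.CAT1, _D.CO_MEAN_GE_3),
        _o(32, "Promethazine HCL", _C.CAT1, _D.CO_MEAN_GE_3),
    )
    grp(
        "Triton X-100 (100 %)",
        _o(36, "Triton X-100 (100 %)", _C.CAT1, _D.CO_MEAN_GE_3),
        _o(37, "Triton X-100 (100 %)", _C.CAT1, _D.CO_MEAN_GE_3),
        _o(590, "Triton X-100 (100 %)", _C.SCNM, assumed="Cat 1"),
    )
    grp(
        "Quinacrine",
        _o(44, "Quinacrine", _C.CAT1, _D.CO_MEAN_GE_3),
        _o(96, "Quinacrine", _C.CAT1, _D.CO_PERS_D21),
    )
    grp(
        "Butoxyethanol",
        _o(51, "Butoxyethanol", _C.CAT1, _D.CO_PERS_D21),
        _o(110, "Butoxyethanol", _C.CAT1, _D.CONJ_PERS_D21),
        _o(217, "Butoxyethanol", _C.CAT2_UNDIFF, _D.CONJ_MEAN_GE_2),
    )
    grp(
        "Ethanol (100 %)",
        _o(57, "Ethanol (100 %)", _C.CAT1, _D.CO_PERS_D21),
        _o(171, "Ethanol (100 %)", _C.CAT2A, _D.CO_MEAN_GE_1),
        _o(201, "Ethanol (100 %)", _C.CAT2A, _D.CO_MEAN_GE_1),
        _o(602, "Ethanol (100 %)", _C.SCNM, assumed="at least Cat 2"),
    )
    grp(
        "Benzalkonium chloride (1 %)",
        _o(66, "Benzalkonium chloride (1 %)", _C.CAT1, _D.CO_PERS_D21),
        _o(67, "Benzalkonium chloride (1 %)", _C.CAT1, _D.CO_PERS_D21),
    )
    grp(
        "Cetyltrimethyl ammonium bromide (10 %)",
        _o(69, "Cetyltrimethyl ammonium bromide (10 %)", _C.CAT1, _D.CO_PERS_D21),
        _o(70, "Cetyltrimethyl ammonium bromide (10 %)", _C.CAT1, _D.CO_PERS_D21),
    )
    grp(
        "Sodium lauryl sulphate (10 %)",
        _o(74, "Sodium lauryl sulphate (10 %)", _C.CAT1, _D.CO_PERS_D21),
        _o(75, "Sodium lauryl sulphate (10 %)", _C.CAT1, _D.CO_PERS_D21),
        _o(189, "Sodium lauryl sulphate (10 %)", _C.CAT2A, _D.CO_MEAN_GE_1),
    )
    grp(
        "Sodium oxalate",
        _o(98, "Sodium oxalate", _C.CAT1, _D.CO_PERS_D21),
        _o(99, "Sodium oxalate", _C.CAT1, _D.CO_PERS_D21),
    )
    grp(
        "(3-Aminopropyl)triethoxy silane",
        _o(123, "(3-Aminopropyl)triethoxy silane", _C.CAT1, _D.CO_EQ_4),
        _o(124, "(3-Aminopropyl)triethoxy silane", _C.CAT1, _D.CO_EQ_4),
    )
    grp(
        "n-Butanol (100 %)",
        _o(128, "n-Butanol (100 %)", _C.CAT1, _D.CO_EQ_4),
        _o(179, "n-Butanol (100 %)", _C.CAT2A, _D.CO_MEAN_GE_1),
    )
    grp(
        "Iso-Butanol",
        _o(175, "Iso-Butanol", _C.CAT2A, _D.CO_MEAN_GE_1),
        _o(589, "Iso-Butanol", _C.SCNM, assumed="Cat 1"),
    )
    grp(
        "Gamma-Butyrolactone",
        _o(173, "Gamma-Butyrolactone", _C.CAT2A, _D.CO_MEAN_GE_1),
        _o(174, "Gamma-Butyrolactone", _C.CAT2A, _D.CO_MEAN_GE_1),
    )
    grp(
        "Methyl acetate",
        _o(176, "Methyl acetate", _C.CAT2A, _D.CO_MEAN_GE_1),
        _o(225, "Methyl acetate", _C.CAT2B, _D.CO_MEAN_GE_1),
    )
    grp(
        "Methyl N,N,N-trimethyl-anilinium sulphate (30 %, aqueous)",
        _o(178, "Methyl N,N,N-trimethyl-anilinium sulphate (30 %, aqueous)", _C.CAT2A, _D.CO_MEAN_GE_1),
        _o(205, "Methyl N,N,N-trimethyl-anilinium sulphate (30 %, aqueous)", _C.CAT2A, _D.CONJ_MEAN_GE_2),
    )
    grp(
        "n-Octanol",
        _o(181, "n-Octanol", _C.CAT2A, _D.CO_MEAN_GE_1),
        _o(228, "n-Octanol", _C.CAT2B, _D.CO_MEAN_GE_1),
    )
    grp(
        "Tetra aminopyrimidine sulphate",
        _o(198, "Tetra aminopyrimidine sulphate", _C.CAT2A, _D.CO_MEAN_GE_1),
        _o(317, "Tetra aminopyrimidine sulphate", _C.NOCAT, subgroup=_S.CO_EQ0),
    )
    grp(
        "Triton X-100 (5 %)",
        _o(207, "Triton X-100 (5 %)", _C.CAT2A, _D.CO_MEAN_GE_1),
        _o(647, "Triton X-100 (5 %)", _C.SCNM, assumed="Cat 2A"),
    )
    grp(
        "Toluene",
        _o(321, "Toluene", _C.NOCAT, subgroup=_S.CO_GT0_STAR),
        _o(627, "Toluene", _C.SCNM, assumed="at least Cat 2"),
    )
    grp(
        "o-Phenylenediamine",
        _o(614, "o-Phenylenediamine", _C.SCNM, assumed="Cat 2A or higher"),
        _o(615, "o-Phenylenediamine", _C.SCNM, assumed="Cat 2A or higher"),
    )
    return [ChemicalGroup(chemical=c, outcomes=outs) for c, outs in rows]


def table5_fixture() -> list[ChemicalGroup]:
    """The 18 repeat-study chemical groups that are No Cat throughout."""
    data: list[tuple[str, list[tuple[int, _S | None, str | None]]]] = [
        ("Methyl amyl ketone", [(257, _S.CO_GT0_STAR, None), (284, _S.CO_GT0, None)]),
        ("Phosphoric acid, tributyl ester", [(260, _S.CO_GT0_STAR, None), (446, _S.CO_EQ0, None)]),
        ("1,2,3-Trichloropropane", [(275, _S.CO_GT0, None), (327, _S.CO_EQ0, None)]),
        ("Methyl iso-butyl ketone", [(285, _S.CO_GT0, None), (286, _S.CO_GT0, None)]),
        ("Triethanolamine (100 %)", [(292, _S.CO_GT0, None), (468, _S.CO_EQ0, None)]),
        ("Sodium lauryl sulphate (1 %)", [(296, _S.CO_GT0, None), (297, _S.CO_GT0, None)]),
        ("Xylene", [(322, _S.CO_EQ0_STAR, None), (483, _S.CO_EQ0, None)]),
        ("3-Phenoxy benzaldehyde (100 %)", [(358, _S.CO_EQ0, None), (359, _S.CO_EQ0, None)]),
        ("Gamma-Glycidyloxypropyltrimethoxy silane", [(391, _S.CO_EQ0, None), (392, _S.CO_EQ0, None)]),
        ("Gamma-Mercaptopropyl trimethoxy silane (100 %)", [(393, _S.CO_EQ0, None), (394, _S.CO_EQ0, None)]),
        ("Glycerol (100 %)", [(400, _S.CO_EQ0, None), (401, _S.CO_EQ0, None)]),
        ("Kronitex TXP", [(425, _S.CO_EQ0, None), (426, _S.CO_EQ0, None)]),
        ("Perfluoro-n-hexane", [(443, _S.CO_EQ0, None), (444, _S.CO_EQ0, None)]),
        ("Polyethylene glycol 400 (100 %)", [(448, _S.CO_EQ0, None), (449, _S.CO_EQ0, None)]),
        ("Tricresyl phosphate", [(465, _S.CO_EQ0, None), (466, _S.CO_EQ0, None)]),
        ("Tween 20", [(476, _S.CO_EQ0, None), (477, _S.CO_EQ0, None)]),
        ("PEG-40 hydrogenated castor oil", [(501, _S.CO_EQ0, None), (502, _S.CO_EQ0, None)]),
        ("Tetrabromobisphenol A", [(574, _S.CO_EQ0, None), (677, _S.CO_EQ0, "No Cat")]),
    ]
    groups = []
    for chem, members in data:
        outs = []
        for sid, sub, assumed in members:
            cat = _C.SCNM if assumed is not None else _C.NOCAT
            outs.append(_o(sid, chem, cat, subgroup=sub, assumed=assumed))
        groups.append(ChemicalGroup(chemical=chem, outcomes=outs))
    return groups
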