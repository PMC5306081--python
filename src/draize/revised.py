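"""Proposed revisions of the Cat 1 classification criteria.

Three independently switchable recommendations:

* **rec1** — conjunctival redness/chemosis scores below 2 on day 21 are
  recognised as fully reversed: they neither create the "Conj pers D21"
  driver nor block Cat 2 eligibility (mirrors the US EPA "fully cleared"
  reading of low conjunctival grades).
* **rec2** — persistence on day 21 and CO = 4 must, like the severity
  criteria, appear in >=60 % of the animals (2/3, 3/4, 3/5, 4/6) to trigger
  Cat 1; minority day-21 residues are disregarded as chemically unrelated,
  and studies with fewer than three animals can no longer be classified
  Cat 1 on these grounds (they are reported SCNM).
* **rec3** — a CO = 4 that fully reverses (explicit CO = 0 on day 21 for
  every affected animal) no longer triggers Cat 1 on its own.

Revisions only remove Cat 1 triggers, so the revised category can never
exceed the standard one.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable

from .engine import Category, ClassificationResult, classify

__all__ = ["RevisionConfig", "STANDARD", "REVISED", "classify_with_config", "compare"]


@dataclass(frozen=True)
class RevisionConfig:
    """Which of the three proposed rule revisions to apply."""

    rec1_conj_low_reversed: bool = False
    rec2_majority_for_persistence_and_co4: bool = False
    rec3_reversible_co4_not_cat1: bool = False

    @property
    def enabled(self) -> tuple[str, ...]:
        return tuple(
            f.name[:4] for f in fields(self) if getattr(self, f.name)
        )


STANDARD = RevisionConfig()
REVISED = RevisionConfig(True, True, True)


def classify_with_config(study, config: RevisionConfig) -> ClassificationResult:
    """Classify under a given revision configuration.

    With all flags off this is identical to :func:`draize.engine.classify`.
    """
    return classify(
        study,
        rec1=config.rec1_conj_low_reversed,
        rec2=config.rec2_majority_for_persistence_and_co4,
        rec3=config.rec3_reversible_co4_not_cat1,
    )


@dataclass(frozen=True)
class Comparison:
    study_id: str
    standard: Category
    revised: Category
    changed: bool
    changed_reason: tuple[str, ...]


def compare(study, config: RevisionConfig = REVISED) -> Comparison:
    """Standard vs revised classification, with the responsible rule codes.

    ``changed_reason`` lists each enabled recommendation that, applied alone,
    already changes the standard category; if only the combination changes it,
    all enabled recommendations are listed.
    """
    std = classify(study)
    rev = classify_with_config(study, config)
    changed = rev.category is not std.category
    reasons: tuple[str, ...] = ()
    if changed:
        single = []
        for name, single_cfg in (
            ("rec1", RevisionConfig(rec1_conj_low_reversed=True)),
            ("rec2", RevisionConfig(rec2_majority_for_persistence_and_co4=True)),
            ("rec3", RevisionConfig(rec3_reversible_co4_not_cat1=True)),
        ):
            if name in config.enabled and (
                classify_with_config(study, single_cfg).category is not std.category
            ):
                single.append(name)
        reasons = tuple(single) if single else config.enabled
    return Comparison(
        study_id=study.study_id,
        standard=std.category,
        revised=rev.category,
        changed=changed,
        changed_reason=reasons,
    )


def compare_cohort(studies: Iterable, config: RevisionConfig = REVISED):
    """Comparison records for every study in a cohort."""
    return [compare(s, config) for s in studies]
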