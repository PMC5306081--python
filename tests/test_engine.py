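"""Classification engine: thresholds, criteria, reversibility, SCNM."""

import math

import numpy as np
import pytest

from draize.engine import (
    Category,
    DriverCode,
    DriverGroup,
    NoCatSubgroup,
    TissueStatus,
    category_rank,
    classify,
    evaluate_criteria,
    majority_threshold,
    reversibility,
    scnm_probable,
)
from draize.records import AnimalRecord, Observation, Study

from _oracle import FULL_GRID, random_complete_study


def _animal(aid, grades_by_time):
    obs = [
        Observation(t, {"CO": co, "IR": ir, "CR": cr, "CC": cc})
        for t, (co, ir, cr, cc) in sorted(grades_by_time.items())
    ]
    return AnimalRecord(aid, obs)


def _zeros(times=FULL_GRID):
    return {t: (0, 0, 0, 0) for t in times}


class TestMajorityThreshold:
    @pytest.mark.parametrize("n,expected", [(3, 2), (4, 3), (5, 3), (6, 4)])
    def test_published_thresholds(self, n, expected):
        assert majority_threshold(n) == expected

    @pytest.mark.parametrize("n", range(1, 7))
    def test_equals_smallest_k_at_least_60pct(self, n):
        brute = next(k for k in range(1, n + 1) if k / n >= 0.6)
        assert majority_threshold(n) == brute
        assert majority_threshold(n) == math.ceil(0.6 * n)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            majority_threshold(7)


class TestEvaluateCriteria:
    def test_single_borderline_animal_triggers_nothing(self):
        # one of three animals with CR mean 2: below the 2/3 majority
        g = _zeros()
        a1 = dict(g)
        a1.update({24: (0, 0, 2, 0), 48: (0, 0, 2, 0), 72: (0, 0, 2, 0)})
        study = Study(
            study_id="s", chemical_name="x",
            animals=[_animal("a1", a1), _animal("a2", g), _animal("a3", g)],
        )
        assert evaluate_criteria(study) == ()

    def test_severity_disabled_below_three_animals(self):
        a1 = dict(_zeros())
        a1.update({24: (4, 2, 3, 4), 48: (4, 2, 3, 4), 72: (4, 2, 3, 4)})
        study = Study(study_id="s", chemical_name="x", animals=[_animal("a1", a1)])
        codes = {d.code for d in evaluate_criteria(study)}
        assert codes == {DriverCode.CO_EQ_4}

    def test_all_zero_study_has_no_drivers(self):
        study = Study(
            study_id="s", chemical_name="x",
            animals=[_animal(f"a{i}", _zeros()) for i in range(3)],
        )
        assert evaluate_criteria(study) == ()

    def test_co4_detected_at_one_hour_reading_with_warning(self):
        g = _zeros()
        a1 = dict(g)
        a1[1] = (4, 0, 0, 0)
        study = Study(
            study_id="s", chemical_name="x",
            animals=[_animal("a1", a1), _animal("a2", g), _animal("a3", g)],
        )
        result = classify(study)
        assert result.category is Category.CAT1
        assert DriverCode.CO_EQ_4 in result.driver_codes
        assert any("1 h" in w for w in result.warnings)

    def test_conjunctival_criteria_assessed_per_endpoint(self):
        # CR meets the cut-off in one animal, CC in another: union is 2 but
        # neither endpoint reaches the 2/3 majority on its own
        g = _zeros()
        a1 = dict(g)
        a1.update({24: (0, 0, 2, 0), 48: (0, 0, 2, 0), 72: (0, 0, 2, 0)})
        a2 = dict(g)
        a2.update({24: (0, 0, 0, 2), 48: (0, 0, 0, 2), 72: (0, 0, 0, 2)})
        study = Study(
            study_id="s", chemical_name="x",
            animals=[_animal("a1", a1), _animal("a2", a2), _animal("a3", g)],
        )
        assert not {d.code for d in evaluate_criteria(study)}

    def test_conjunctival_driver_counts_union_of_cr_and_cc_animals(self):
        g = _zeros()
        a1 = dict(g)
        a1.update({24: (0, 0, 2, 0), 48: (0, 0, 2, 0), 72: (0, 0, 2, 0)})
        a2 = dict(g)
        a2.update({24: (0, 0, 3, 0), 48: (0, 0, 2, 0), 72: (0, 0, 2, 0)})
        a3 = dict(g)
        a3.update({24: (0, 0, 0, 2), 48: (0, 0, 0, 2), 72: (0, 0, 0, 2)})
        study = Study(
            study_id="s", chemical_name="x",
            animals=[_animal("a1", a1), _animal("a2", a2), _animal("a3", a3)],
        )
        (conj,) = evaluate_criteria(study)
        assert conj.code is DriverCode.CONJ_MEAN_GE_2
        assert conj.n_animals_meeting == 3  # union; CR alone has 2
        assert conj.component_detail == {"CR": 2, "CC": 1}


class TestReversibility:
    def test_persistent_reversed_unknown_triad(self):
        g = dict(_zeros())
        g[504] = (1, 0, 0, 0)
        a1 = _animal("a1", g)  # CO persistent
        a2 = _animal("a2", _zeros())  # reversed
        a3 = _animal("a3", _zeros(times=(1, 24, 48, 72, 168, 336)))  # no day 21
        study = Study(study_id="s", chemical_name="x", animals=[a1, a2, a3])
        rev = reversibility(study)
        assert rev.status("a1", "CO") is TissueStatus.PERSISTENT
        assert rev.status("a2", "CO") is TissueStatus.REVERSED
        assert rev.status("a3", "CO") is TissueStatus.UNKNOWN
        assert rev.any_unknown
        assert not rev.fully_reversed_by_21d  # a1 persists

    def test_early_terminated_but_reversed_counts_as_reversed(self):
        a = _animal("a1", {1: (2, 0, 0, 0), 24: (1, 0, 0, 0), 48: (0, 0, 0, 0)})
        study = Study(study_id="s", chemical_name="x", animals=[a])
        assert reversibility(study).fully_reversed_by_21d


class TestClassify:
    def test_worked_examples(self, worked_examples):
        for name, we in worked_examples.items():
            r = classify(we.study)
            assert r.category is we.category, name
            if we.main_driver is not None:
                assert r.main_driver is we.main_driver, name
                assert r.main_driver_group is we.main_driver_group, name
            if we.nocat_subgroup is not None:
                assert r.nocat_subgroup is we.nocat_subgroup, name
            if we.scnm_probable is not None:
                assert r.scnm_probable == we.scnm_probable, name

    def test_two_animal_benign_study_is_scnm(self):
        study = Study(
            study_id="s", chemical_name="x",
            animals=[_animal("a1", _zeros()), _animal("a2", _zeros())],
        )
        r = classify(study)
        assert r.category is Category.SCNM
        assert r.scnm_probable == "No Cat"

    def test_single_animal_with_persistence_is_cat1(self):
        g = dict(_zeros())
        g[504] = (1, 0, 0, 0)
        study = Study(study_id="s", chemical_name="x", animals=[_animal("a1", g)])
        assert classify(study).category is Category.CAT1

    def test_cat2b_requires_all_zero_from_day7(self):
        g = _zeros()
        hot = {1: (0, 0, 0, 0), 24: (2, 0, 1, 0), 48: (2, 0, 1, 0),
               72: (1, 0, 0, 0), 168: (0, 0, 0, 0), 336: (0, 0, 0, 0),
               504: (0, 0, 0, 0)}
        study = Study(
            study_id="s", chemical_name="x",
            animals=[_animal("a1", hot), _animal("a2", hot), _animal("a3", g)],
        )
        r = classify(study)
        assert r.category is Category.CAT2B
        for a in study.animals:
            for o in a.observations:
                if o.time_hours >= 168:
                    assert all(v == 0 for v in o.grades.values())

    def test_missing_day7_reading_gives_undifferentiated_cat2(self, worked_examples):
        r = classify(worked_examples["no217"].study)
        assert r.category is Category.CAT2_UNDIFF

    def test_classify_invariant_to_animal_order(self, rng):
        for i in range(25):
            s = random_complete_study(rng, f"p{i}")
            r1 = classify(s)
            shuffled = Study(
                study_id=s.study_id, chemical_name=s.chemical_name,
                animals=list(reversed(s.animals)),
                severe_other_effects=s.severe_other_effects,
            )
            r2 = classify(shuffled)
            assert r1.category is r2.category
            assert r1.main_driver is r2.main_driver
            assert {d.code for d in r1.drivers} == {d.code for d in r2.drivers}

    def test_monotone_in_single_grade_increase(self, rng):
        # raising any one recorded grade never lowers the category
        for i in range(150):
            s = random_complete_study(rng, f"m{i}")
            base_rank = category_rank(classify(s).category)
            ai = int(rng.integers(0, len(s.animals)))
            oi = int(rng.integers(0, len(FULL_GRID)))
            tissue = ["CO", "IR", "CR", "CC"][int(rng.integers(0, 4))]
            animal = s.animals[ai]
            obs = animal.observations[oi]
            from draize.records import MAX_GRADE

            g = obs.grade(tissue)
            if g >= MAX_GRADE[tissue]:
                continue
            new_grades = dict(obs.grades)
            new_grades[tissue] = g + 1
            new_obs = list(animal.observations)
            new_obs[oi] = Observation(obs.time_hours, new_grades)
            bumped_animals = list(s.animals)
            bumped_animals[ai] = AnimalRecord(animal.animal_id, new_obs)
            bumped = Study(
                study_id=s.study_id, chemical_name=s.chemical_name,
                animals=bumped_animals,
                severe_other_effects=s.severe_other_effects,
            )
            assert category_rank(classify(bumped).category) >= base_rank

    def test_cat1_implies_nonempty_drivers(self, rng):
        for i in range(50):
            s = random_complete_study(rng, f"d{i}")
            r = classify(s)
            if r.category is Category.CAT1:
                assert r.drivers


class TestScnmProbable:
    def test_error_on_non_scnm(self):
        study = Study(
            study_id="s", chemical_name="x",
            animals=[_animal(f"a{i}", _zeros()) for i in range(3)],
        )
        r = classify(study)
        with pytest.raises(ValueError):
            scnm_probable(study, r)

    def test_terminated_day3_mild_is_undetermined(self):
        times = (1, 24, 48, 72)
        g = {t: (1, 0, 0, 0) if t == 24 else (0, 0, 1, 0) for t in times}
        study = Study(
            study_id="s", chemical_name="x",
            animals=[_animal(f"a{i}", g) for i in range(3)],
        )
        r = classify(study)
        assert r.category is Category.SCNM
        assert r.scnm_probable == "undetermined"

    def test_high_co_at_day14_termination_assumed_cat1(self, worked_examples):
        r = classify(worked_examples["no589"].study)
        assert r.category is Category.SCNM
        assert r.scnm_probable == "Cat 1"
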