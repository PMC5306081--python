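"""Domain model, severity means and file dialect round trips."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from draize.records import (
    AnimalRecord,
    Observation,
    Study,
    ValidationError,
    read_studies,
    severity_means,
    write_studies,
)


def _study(co_by_time, **kwargs):
    obs = [Observation(t, {"CO": g, "IR": 0, "CR": 0, "CC": 0}) for t, g in co_by_time]
    return Study(
        study_id="s1",
        chemical_name="x",
        animals=[AnimalRecord("a1", obs)],
        **kwargs,
    )


class TestValidation:
    def test_grade_above_tissue_maximum_rejected(self):
        with pytest.raises(ValidationError, match=r"CO grade 5.*\[0, 4\]"):
            Observation(24, {"CO": 5, "IR": 0, "CR": 0, "CC": 0})

    @pytest.mark.parametrize("tissue,mx", [("IR", 2), ("CR", 3), ("CC", 4)])
    def test_each_tissue_has_its_own_bound(self, tissue, mx):
        Observation(24, {tissue: mx})  # at the bound: fine
        with pytest.raises(ValidationError):
            Observation(24, {tissue: mx + 1})

    def test_duplicate_observation_time_rejected(self):
        obs = [Observation(24, {"CO": 1}), Observation(24, {"CO": 2})]
        with pytest.raises(ValidationError, match="duplicate"):
            AnimalRecord("a1", obs)

    def test_animal_count_bounds(self):
        obs = [Observation(24, {"CO": 0})]
        animals = [AnimalRecord(f"a{i}", obs) for i in range(7)]
        with pytest.raises(ValidationError, match="1-6 animals"):
            Study(study_id="s", chemical_name="x", animals=animals)

    def test_terminated_early_derived_from_last_observation(self):
        a = AnimalRecord("a1", [Observation(336, {"CO": 0})])
        assert a.terminated_early
        b = AnimalRecord("a1", [Observation(504, {"CO": 0})])
        assert not b.terminated_early


class TestSeverityMeans:
    @pytest.mark.parametrize(
        "grades,expected",
        [
            ([(24, 0), (48, 0), (72, 0)], Fraction(0)),
            ([(1, 2), (24, 0), (48, 0), (72, 0)], Fraction(0)),  # 1 h excluded
            ([(24, 2), (48, 3), (72, 4)], Fraction(3)),
            ([(24, 2), (48, 3)], Fraction(5, 2)),  # partial window
        ],
    )
    def test_day13_mean(self, grades, expected):
        s = _study(grades)
        assert severity_means(s).mean("a1", "CO") == expected

    def test_missing_grades_excluded_not_zeroed(self):
        obs = [
            Observation(24, {"CO": 3, "IR": None, "CR": 0, "CC": 0}),
            Observation(48, {"CO": None, "IR": 1, "CR": 0, "CC": 0}),
            Observation(72, {"CO": 3, "IR": 1, "CR": 0, "CC": 0}),
        ]
        s = Study(study_id="s", chemical_name="x",
                  animals=[AnimalRecord("a1", obs)])
        sm = severity_means(s)
        assert sm.mean("a1", "CO") == Fraction(3)
        assert sm.n_readings("a1", "CO") == 2
        assert sm.mean("a1", "IR") == Fraction(1)

    def test_no_reading_in_window_is_undefined_not_zero(self):
        s = _study([(1, 2), (168, 1)])
        sm = severity_means(s)
        assert sm.mean("a1", "CO") is None
        assert sm.n_readings("a1", "CO") == 0
        assert sm.warnings  # data-quality warning attached

    def test_late_observations_never_change_the_mean(self):
        base = _study([(24, 2), (48, 2), (72, 2)])
        late = _study([(24, 2), (48, 2), (72, 2), (168, 4), (504, 4)])
        assert severity_means(base).mean("a1", "CO") == severity_means(late).mean(
            "a1", "CO"
        )


# -- hypothesis: order invariance of the means -------------------------------

grades_st = st.lists(
    st.tuples(
        st.sampled_from([1, 24, 48, 72, 168, 336, 504]),
        st.integers(min_value=0, max_value=4),
    ),
    min_size=1,
    max_size=7,
    unique_by=lambda x: x[0],
)


@settings(max_examples=50, deadline=None)
@given(grades=grades_st, perm_seed=st.integers(0, 1000))
def test_severity_means_permutation_invariant(grades, perm_seed):
    import random

    shuffled = grades.copy()
    random.Random(perm_seed).shuffle(shuffled)
    assert severity_means(_study(grades)).per_animal == severity_means(
        _study(shuffled)
    ).per_animal


# -- round trips -------------------------------------------------------------


@pytest.mark.parametrize("fmt", ["csv", "json"])
def test_round_trip_identity(tmp_path, small_cohort, fmt):
    path = tmp_path / ("cohort.json" if fmt == "json" else "cohort")
    write_studies(small_cohort, path, format=fmt)
    back = read_studies(path, format=fmt)
    assert len(back) == len(small_cohort)
    by_id = {s.study_id: s for s in small_cohort}
    for s in back:
        orig = by_id[s.study_id]
        assert s.chemical_name == orig.chemical_name
        assert s.physical_form == orig.physical_form
        assert len(s.animals) == len(orig.animals)
        for a, b in zip(
            sorted(s.animals, key=lambda a: a.animal_id),
            sorted(orig.animals, key=lambda a: a.animal_id),
        ):
            assert [(o.time_hours, dict(o.grades)) for o in a.observations] == [
                (o.time_hours, dict(o.grades)) for o in b.observations
            ]


def test_write_is_byte_stable(tmp_path, small_cohort):
    p1, p2 = tmp_path / "one", tmp_path / "two"
    write_studies(small_cohort, p1, format="csv")
    write_studies(list(reversed(small_cohort)), p2, format="csv")
    for suffix in (".studies.csv", ".scores.csv"):
        a = (tmp_path / ("one" + suffix)).read_bytes()
        b = (tmp_path / ("two" + suffix)).read_bytes()
        assert a == b  # canonical ordering makes output order-independent


def test_blank_cell_reads_back_as_missing(tmp_path):
    (tmp_path / "c.studies.csv").write_text(
        "study_id,chemical_name,cas_rn,physical_form,data_source,purity,"
        "severe_other_effects,other_effects_note,comments\n"
        "s1,foo,,L,src,,false,,\n"
    )
    (tmp_path / "c.scores.csv").write_text(
        "study_id,animal_id,time_hours,CO,IR,CR,CC\n"
        "s1,a1,24,1,,0,0\n"
    )
    (study,) = read_studies(tmp_path / "c", format="csv")
    assert study.animals[0].grade_at("IR", 24) is None
    assert study.animals[0].grade_at("CO", 24) == 1


def test_out_of_range_grade_in_file_names_the_offender(tmp_path):
    (tmp_path / "c.studies.csv").write_text(
        "study_id,chemical_name,cas_rn,physical_form,data_source,purity,"
        "severe_other_effects,other_effects_note,comments\ns1,foo,,L,,,false,,\n"
    )
    (tmp_path / "c.scores.csv").write_text(
        "study_id,animal_id,time_hours,CO,IR,CR,CC\ns1,a1,24,5,0,0,0\n"
    )
    with pytest.raises(ValidationError, match="s1.*a1"):
        read_studies(tmp_path / "c", format="csv")


def test_empty_cohort_writes_header_only(tmp_path):
    write_studies([], tmp_path / "empty", format="csv")
    lines = (tmp_path / "empty.scores.csv").read_text().strip().splitlines()
    assert lines == ["study_id,animal_id,time_hours,CO,IR,CR,CC"]
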