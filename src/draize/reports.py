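"""Cohort-level summary tables: driver distributions, driver frequencies and
day-wise grade distributions.

All tables are plain :class:`pandas.DataFrame` objects built from per-study
indicator counts, so they are invariant to cohort order and fully
reconstructible from the classification results.  Percentages are reported to
one decimal; the underlying counts are kept alongside.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .drivers import PersistenceGroup, persistence_group
from .engine import (
    CAT1_DRIVERS,
    CAT2_DRIVERS,
    Category,
    ClassificationResult,
    DriverCode,
    DriverGroup,
)
from .records import Study

__all__ = [
    "driver_distribution",
    "driver_frequency",
    "grade_time_distribution",
    "select_studies",
]

_DAY_GRID = (1, 2, 3, 7, 14, 21)


def _pg(study: Study) -> str:
    return study.physical_group.value


def driver_distribution(
    studies: Sequence[Study], results: Sequence[ClassificationResult]
) -> pd.DataFrame:
    """Counts and percentages of studies by main driver (or No Cat subgroup).

    One row per (category, row_label, physical_group) plus ``ALL`` totals.
    ``pct_within_category`` percentages sum to 100 within each category block
    (the framed-group rule); ``pct_within_row`` distributes each driver row
    over the physical groups.
    """
    rows = []
    for study, result in zip(studies, results):
        if result.category is Category.SCNM:
            label = "SCNM"
        elif result.category is Category.NOCAT:
            label = result.nocat_subgroup.value
        elif result.main_driver_group is DriverGroup.OTHER:
            label = "other observations"
        else:
            label = result.main_driver.value
        rows.append(
            {
                "category": result.category.value,
                "row_label": label,
                "physical_group": _pg(study),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "category",
                "row_label",
                "physical_group",
                "n",
                "pct_within_category",
                "pct_within_row",
            ]
        )
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["category", "row_label", "physical_group"])
        .size()
        .rename("n")
        .reset_index()
    )
    all_rows = (
        df.groupby(["category", "row_label"])
        .size()
        .rename("n")
        .reset_index()
        .assign(physical_group="ALL")
    )
    out = pd.concat([counts, all_rows], ignore_index=True)
    cat_tot = df.groupby("category").size()
    row_tot = df.groupby(["category", "row_label"]).size()
    out["pct_within_category"] = [
        round(100.0 * r.n / cat_tot[r.category], 1) for r in out.itertuples()
    ]
    out.loc[out.physical_group != "ALL", "pct_within_category"] = np.nan
    out["pct_within_row"] = [
        round(100.0 * r.n / row_tot[(r.category, r.row_label)], 1)
        for r in out.itertuples()
    ]
    out.loc[out.physical_group == "ALL", "pct_within_row"] = 100.0
    return out.sort_values(
        ["category", "row_label", "physical_group"]
    ).reset_index(drop=True)


def driver_frequency(
    studies: Sequence[Study], results: Sequence[ClassificationResult]
) -> pd.DataFrame:
    """Total frequency of each driver, split single vs multiple occurrence.

    A driver occurs *single* in a study when it is the only driver of that
    study's own category class (Cat 1 drivers for Cat 1 studies, Cat 2
    drivers for Cat 2 studies), *multiple* otherwise.  Severity drivers never
    appear for studies with fewer than three animals (the engine does not
    evaluate them there).
    """
    rows = []
    for study, result in zip(studies, results):
        if result.category is Category.CAT1:
            relevant = CAT1_DRIVERS
        elif result.category in (
            Category.CAT2A,
            Category.CAT2B,
            Category.CAT2_UNDIFF,
        ):
            relevant = CAT2_DRIVERS
        else:
            continue
        codes = [d.code for d in result.drivers if d.code in relevant]
        mode = "single" if len(codes) == 1 else "multiple"
        for code in codes:
            rows.append(
                {
                    "driver": code.value,
                    "occurrence": mode,
                    "physical_group": _pg(study),
                }
            )
    if not rows:
        return pd.DataFrame(columns=["driver", "occurrence", "physical_group", "n"])
    return (
        pd.DataFrame(rows)
        .groupby(["driver", "occurrence", "physical_group"])
        .size()
        .rename("n")
        .reset_index()
    )


def select_studies(
    studies: Sequence[Study],
    results: Sequence[ClassificationResult],
    *,
    category: Optional[Category] = None,
    tissue: Optional[str] = None,
    pers_group: Optional[PersistenceGroup] = None,
) -> list[Study]:
    """Filter a classified cohort by category and day-21 persistence bucket.

    Single-animal studies are excluded whenever a persistence bucket is
    requested, matching the persistence-grouping convention.
    """
    out = []
    for study, result in zip(studies, results):
        if category is not None and result.category is not category:
            continue
        if pers_group is not None:
            if study.n_animals < 2:
                continue
            if persistence_group(study, tissue or "CO") is not pers_group:
                continue
        out.append(study)
    return out


def grade_time_distribution(
    studies: Iterable[Study], tissue: str, days: Sequence[int] = _DAY_GRID
) -> pd.DataFrame:
    """Per-day distribution of one tissue's individual-animal grades.

    For each observation day: number of animals with a recorded grade,
    median/quartiles/min/max, and the percentage of animals at grade >= 2 and
    at grade 0.  ``n`` shrinks over days as animals are terminated early.
    """
    studies = list(studies)
    rows = []
    for day in days:
        t = 1 if day == 0 else 24 * day
        grades = [
            g
            for s in studies
            for a in s.animals
            if (g := a.grade_at(tissue, t)) is not None
        ]
        if grades:
            arr = np.asarray(grades)
            rows.append(
                {
                    "day": day,
                    "n": len(arr),
                    "median": float(np.median(arr)),
                    "q1": float(np.percentile(arr, 25)),
                    "q3": float(np.percentile(arr, 75)),
                    "min": int(arr.min()),
                    "max": int(arr.max()),
                    "pct_ge_2": round(100.0 * float((arr >= 2).mean()), 1),
                    "pct_zero": round(100.0 * float((arr == 0).mean()), 1),
                }
            )
        else:
            rows.append(
                {
                    "day": day,
                    "n": 0,
                    "median": np.nan,
                    "q1": np.nan,
                    "q3": np.nan,
                    "min": np.nan,
                    "max": np.nan,
                    "pct_ge_2": np.nan,
                    "pct_zero": np.nan,
                }
            )
    return pd.DataFrame(rows)
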