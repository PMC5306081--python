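# draize

Drivers-of-classification analysis for the in vivo Draize rabbit eye test
(OECD TG 405) under the UN GHS / EU CLP serious eye damage / eye irritation
classification system.

## The problem

Validating non-animal alternatives to the Draize eye test requires knowing
*why* each reference chemical got its in vivo classification. A study grades
four ocular tissues per animal over up to 21 days — corneal opacity (CO, 0–4),
iritis (IR, 0–2), conjunctival redness (CR, 0–3) and conjunctival chemosis
(CC, 0–4) — and eleven independent criteria can each trigger a category:

* **Cat 1** (serious eye damage): CO mean ≥ 3 or IR mean > 1.5 over days 1–3
  in ≥ 60 % of the animals (2/3, 3/4, 3/5, 4/6); CO, IR, CR or CC > 0 on
  day 21 in ≥ 1 animal ("persistence"); CO = 4 at any time in any animal;
  or other severe reactions (pannus, corneal discoloration, …).
* **Cat 2** (reversible irritation): CO mean ≥ 1, IR mean ≥ 1, CR mean ≥ 2 or
  CC mean ≥ 2 in ≥ 60 % of the animals, with all effects fully reversible by
  day 21 (optional 2A/2B split by day-7 reversibility).
* **No Cat** otherwise; **SCNM** (study criteria not met) when the data do not
  allow an unambiguous call (early termination without full reversal, or one
  or two animals without Cat 1 findings).

CR and CC are assessed independently but reported merged ("Conj"), giving
nine drivers. The package classifies per-animal score time series under these
rules, identifies every driver and the single prioritised *main* driver
(severity > persistence > CO = 4, endpoints tie-broken CO > Conj > IR),
subgroups No Cat studies on the CO axis with a borderline (`**`) flag,
annotates SCNM studies with their most probable class, evaluates three
proposed revisions of the Cat 1 criteria, measures concordance between
repeat studies of the same chemical, applies reference-chemical selection
rules (R1–R10), and builds cohort-level summary tables. A seeded synthetic
generator produces studies with controlled classification targets so all of
this is testable without the original proprietary database.

It is intended for regulatory and predictive toxicologists assembling or
auditing reference-chemical sets for alternative-method development and
validation.

## Worked example

Classify a six-animal study in which one animal shows low-level corneal
opacity that never reverses while the other five recover (the classic
"persistence in the minority" pattern):

```python
from draize import worked_example_fixtures, classify
from draize.revised import REVISED, compare

study = worked_example_fixtures()["no57"].study
r = classify(study)
print("category:   ", r.category.value)
print("drivers:    ", ", ".join(f"{d.code.value} ({d.n_animals_meeting})"
                                for d in r.drivers))
print("main driver:", r.main_driver.value, f"[{r.main_driver_group.value}]")
c = compare(study)
print("revised:    ", c.revised.value, "via", "+".join(c.changed_reason))
```

prints

```
category:    Cat 1
drivers:     CO mean >= 1 (6), CO pers D21 (1)
main driver: CO pers D21 [persistence]
revised:     Cat 2A via rec2
```

i.e. the study is Cat 1 solely because one of six animals has CO > 0 on
day 21 (driver `CO pers D21`, the main driver since no severity criterion is
met); its day 1–3 means only reach the Cat 2 level (`CO mean >= 1` in all six
animals). Under the proposed revision that subjects persistence to the same
≥ 60 % majority rule as severity (`rec2`), the same data yield Cat 2A.

The same machinery is available from the shell:

```sh
draize simulate --profile cat1_pers_co_minority --n 5 --seed 1 --out cohort
draize classify --in cohort --out classified.csv
draize classify --in cohort --compare        # standard vs revised
draize repro --fixtures table4               # repeat-study concordance
draize flags --in cohort                     # selection verdicts R1-R10
draize stats --in cohort                     # driver distribution table
```

## Layout

| module | contents |
|---|---|
| `draize.records` | domain types, validation, severity means, CSV/JSON dialect |
| `draize.engine` | the 11 criteria, reversibility, SCNM logic, categories |
| `draize.drivers` | main-driver prioritisation, No Cat subgroups, persistence groups |
| `draize.revised` | the three proposed Cat 1 revisions and the comparator |
| `draize.repro` | repeat-study grouping, concordance verdicts, fixtures |
| `draize.selection` | reference-chemical selection rules R1–R10 |
| `draize.reports` | driver distribution / frequency / grade-by-day tables |
| `draize.simulate` | synthetic study generator and worked-example fixtures |
| `draize.cli` | `draize classify\|repro\|flags\|stats\|simulate` |

See `docs/methods.md` for the full description of the rules as implemented,
the numerical conventions and the known limitations.
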