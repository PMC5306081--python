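# Methods

This note documents the classification rules as implemented, the conventions
chosen where the regulatory text is silent, the synthetic-data model, and the
limits of what the test suite shows.

## Data model

A *study* is 1–6 rabbits, each a time series of integer grades for corneal
opacity (CO, 0–4), iritis (IR, 0–2), conjunctival redness (CR, 0–3) and
conjunctival chemosis (CC, 0–4). Time is integer hours on a single axis: the
1 h reading is `1`, day *d* is `24·d`; the standard grid is
{1, 24, 48, 72, 168, 336, 504} h but ad-hoc days (e.g. a day-15 reading) are
legal. An unrecorded grade is MISSING, never zero: it does not enter severity
means, persistence calls, CO = 4 detection or the reversibility check. This
matters because studies terminated early for humane reasons have *unknown*,
not *recovered*, late status.

**Severity means.** The per-animal "severity score" of a tissue is the
arithmetic mean of its 24/48/72 h grades. The 1 h reading and anything from
day 7 on are excluded. The mean is taken over the *available* readings in the
window (a data-quality warning is attached when fewer than three exist);
with no reading in the window it is undefined and can trigger nothing.
Means are exact `Fraction`s — grades are integers, so day 1–3 means are
multiples of 1/3 — and every cut-off comparison (≥ 3, > 1.5, ≥ 2, ≥ 1) is
exact rational arithmetic. No float ever touches a classification boundary.

## Classification engine

The eleven criteria, evaluated per study:

| driver | rule | scope |
|---|---|---|
| `CO mean >= 3` | CO severity mean ≥ 3 | ≥ 60 % of animals, n ≥ 3 |
| `IR mean > 1.5` | IR severity mean strictly > 1.5 | ≥ 60 %, n ≥ 3 |
| `CO pers D21` | CO > 0 at the 504 h reading | ≥ 1 animal |
| `Conj pers D21` | CR > 0 and/or CC > 0 at 504 h | ≥ 1 animal |
| `IR pers D21` | IR > 0 at 504 h | ≥ 1 animal |
| `CO = 4` | CO = 4 at any recorded time (incl. 1 h) | ≥ 1 animal |
| `Other effects` | severe other reactions flag | study level |
| `CO mean >= 1`, `Conj mean >= 2`, `IR mean >= 1` | Cat 2 severity | ≥ 60 %, n ≥ 3 |

Conventions:

* The ≥ 60 % majority threshold is the smallest k with k/n ≥ 0.6
  (2/3, 3/4, 3/5, 4/6), computed as `ceil(3n/5)` in integers.
* Mean-score criteria are disabled below three animals: a majority is not a
  meaningful classification basis there. Persistence, CO = 4 and
  other-effects criteria apply at any group size.
* The conjunctival criteria are assessed per endpoint (CR majority *or* CC
  majority) and reported as one merged driver whose animal count is the
  union of animals meeting either endpoint, with per-endpoint counts kept in
  `component_detail`. Union rather than max was chosen as the most natural
  merged count; both are available.
* Persistence requires an explicit day-21 observation with grade > 0. A
  nonzero grade at an earlier final reading is *unknown*, not persistent,
  and routes to SCNM.
* CO = 4 is scanned at every recorded time. Whether a CO = 4 seen only at
  the 1 h reading should count is genuinely open in the regulatory text
  ("at any time point"); the engine counts it and attaches a warning.

**Category assignment.** Any Cat 1 driver ⇒ Cat 1. Otherwise SCNM when
(1) any animal ends before day 21 without full reversal (last recorded grade
of any observed tissue nonzero), (2) exactly two animals, or (3) one animal
(neither CO = 4 nor persistence — guaranteed at this point). Otherwise any
Cat 2 driver with full reversal by day 21 ⇒ Cat 2, subcategorised: any grade
> 0 in [day 7, day 21) ⇒ 2A; else an explicit day-7 reading ⇒ 2B; else
undifferentiated Cat 2 (no day-7 grading, the split cannot be resolved).
Otherwise No Cat. "Full reversal" is judged on the last recorded grade per
tissue per animal, so an animal released early with all-zero grades counts
as reversed while a missing day-21 reading after nonzero grades does not.

**SCNM probable class.** Annotated heuristically from the available data: a
final reading on day ≥ 14 with CO ≥ 3 is assumed persistent ("Cat 1", the
high score is very unlikely to clear within a week); a Cat 2-level severity
pattern (majority rule applied at any n) with unknown reversibility gives
"at least Cat 2" / "Cat 2A or higher"; a complete benign pattern in an
undersized study maps to the category the pattern itself determines
("Cat 2A", "Cat 2B", "No Cat"); otherwise "undetermined".

## Main driver, subgroups, persistence buckets

Cat 1 groups are prioritised severity > persistence (in the absence of
severity) > CO = 4 (in the absence of both, or when persistence is unknown)
> other observations. Within severity and persistence groups the endpoint
with the largest animal count wins; ties break CO > Conj > IR, reflecting
the clinical weight of corneal damage. Cat 2 studies pick among the three
Cat 2 drivers the same way. Single-animal Cat 1 studies can never have a
severity group (means are disabled); they route to persistence when
persistence was observed, else to CO = 4.

No Cat studies are subgrouped on the CO axis: `CO > 0` iff any CO grade > 0
at any recorded time (the 1 h reading included), with `**` marking
borderline studies — at least one animal whose day 1–3 mean meets a Cat 2
cut-off (inclusive ≥, e.g. CR mean exactly 2 qualifies), but too few
animals to classify.

Persistence buckets (majority / minority / none per tissue, single-animal
studies excluded) use the same ≥ 60 % threshold and feed the day-wise grade
distribution tables.

## Revised criteria

Three independently switchable revisions, all of which only *remove* Cat 1
triggers (the revised category provably never exceeds the standard one):

* **rec1** — CR/CC = 1 on day 21 is recognised as fully reversed: it neither
  creates `Conj pers D21` nor blocks Cat 2 eligibility. Mirrors the US EPA
  "fully cleared" treatment of low conjunctival grades.
* **rec2** — persistence and CO = 4 must meet the same ≥ 60 % majority as
  severity. Day-21 residues held by fewer than the threshold of animals are
  also disregarded in the reversibility check — they are deemed unrelated to
  the chemical (secondary infection, grooming, behaviour), so a
  minority-persistence study with Cat 2 severity becomes Cat 2A rather than
  unclassifiable. Under rec2 studies with fewer than three animals cannot be
  Cat 1 via these routes at all and are reported SCNM with a prominent
  warning; Cat 2 was considered but rejected since such findings are exactly
  the single-animal observations the revision distrusts.
* **rec3** — a CO = 4 that fully reverses (explicit CO = 0 on day 21 for
  *every* affected animal) no longer triggers Cat 1. Unknown status leaves
  Cat 1 intact: only observed reversal is forgiven.

The comparator reports, per study, both categories and which enabled
revision(s), applied alone, already change the standard category (all
enabled ones when only the combination does).

## Repeat-study concordance

Chemical identity includes the tested concentration ("X (5 %)" ≠
"X (100 %)"). Each group member contributes a *set* of possible categories:
a singleton for a definite outcome, the annotated assumed class for SCNM
members (when `use_assumed_scnm`), an interval for lower-bound annotations
("at least Cat 2" → {2B, 2A, 1}), {2A, 2B} for undifferentiated Cat 2 under
the split reading. Two members with disjoint sets make the group
DISCORDANT; all-singleton, all-equal groups are concordant (same vs
different main driver; for all-No Cat groups, same vs different subgroup);
anything else is UNCERTAIN and excluded from every denominator. With
`unified_cat2` the 2A/2B/undifferentiated distinctions collapse first, so
unified concordance is never below split concordance.

Summary fractions are exact integer counts over three strata: groups with a
definite Cat 1 member, groups whose maximum class is Cat 2, and all-No Cat
groups. The packaged fixtures encode the known repeat-study groups at the
outcome level (category, main driver, SCNM assumed class, No Cat subgroup)
— the concordance arithmetic is fully determined by outcomes, and raw
grades for those studies are not redistributable.

## Selection rules

R1–R10 (see `draize.selection` docstring for the table) are pure functions
of the classified outcomes plus optional raw-data-derived facts (minority
basis, day-21 conjunctival residue level, CO = 4 reversal, purity, source).
Verdicts are computed separately for prospective studies and retrospective
evaluations; adding a triggered rule can only keep or worsen a verdict.
Concentration series for R9 are linked by parsing a trailing "(x %)"
qualifier from the chemical name. R9 and R10 are advisory (conditional),
never hard exclusions.

## Synthetic data

Profiles name cells of the classification landscape (target category, target
main driver, No Cat subgroup, persistence pattern, delayed CO = 4, early
termination, day-7 reading present, animal count). Trajectories use a
peak-and-decay template: onset at 24 h, plateau through day 3, roughly
linear decay, with an optional delayed CO = 4 spike on day 14 and an
optional persistent day-21 residue in a chosen number of animals. Defaults:
three animals (six where a minority pattern needs room), full standard grid,
no noise. Optional noise jitters each recorded grade ±1 with the given
probability; generation is verify-then-accept with at most 50 retries, so
the delivered study always classifies to its target — an exhausted retry
budget raises rather than returning an off-target study. Generation is
deterministic for a fixed (profile, seed).

What the generator does *not* emulate: empirical grade distributions of real
studies, inter-animal correlation beyond the affected/background roles,
biological recovery kinetics, scorer subjectivity. Passing tests therefore
demonstrate the correctness of the rule logic on structurally realistic
inputs, not predictive performance on any historical database.

The worked-example fixtures are hand-built pattern studies (borderline
No Cat with and without `**`, Cat 1 via day-21 conjunctival 1s, CR = 2/CR = 3
persistence without corneal involvement, minority CO persistence, delayed
CO = 4, CO = 4 with and without reversal, undifferentiated Cat 2, day-14
termination with high CO, a severe-and-persistent single-animal study). They
satisfy the textual constraints of well-known study patterns and carry their
expected outcomes as executable documentation; they are not transcripts of
any database rows.

## Verification

* An independent brute-force oracle (`tests/_oracle.py`) re-reads the eleven
  criteria literally in a different style (float means, flat loops) and is
  compared with the engine on 10,000 random complete ≥ 3-animal studies —
  categories and full driver sets must agree exactly. The random generator
  forces a fraction of studies to reverse from day 7 or day 14 so the
  Cat 2/No Cat branches are exercised, not just persistence-driven Cat 1.
* Property tests: order invariance over animals and observations;
  monotonicity (raising any single recorded grade never lowers the
  category); revised ≤ standard everywhere; round-trip identity of the file
  dialects; byte-stable canonical writes.
* Problem sizes in the default suite (10,000 oracle studies, 100 seeds per
  generator profile, a few hundred studies per property) keep the whole run
  around half a minute while crossing every rule boundary many times.

## Known limitations

* SCNM probable-class annotation is heuristic; real regulatory calls on
  incomplete studies involve expert judgement the package does not model.
* The undifferentiated-Cat 2 handling assumes a missing day-7 grading is the
  only reason the 2A/2B split can fail.
* Lower-bound SCNM annotations make some groups UNCERTAIN rather than
  forcing a verdict; denominators shrink accordingly.
* Dose/volume normalisation, species other than rabbit, and the historical
  weighted sum score (MMAS) are out of scope.
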