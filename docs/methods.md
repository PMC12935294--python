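# Methods

## Scope and data model

The package analyzes spontaneous adverse-event reports in the FAERS
quarterly ASCII layout: six '$'-delimited tables joined on PRIMARYID. A
report carries demographics, outcome codes, an ordered drug list with role
codes (primary suspect, secondary suspect, concomitant, interacting),
MedDRA preferred-term (PT) reaction and indication sets, and therapy start
dates. FAERS dates come at year, month or day precision
(`YYYY[MM[DD]]`); the `PartialDate` type preserves that precision instead
of guessing. Where an order on dates is needed (version selection),
missing components are padded with 1 — the earliest interpretation — and
remaining ties fall to the PRIMARYID rule, which keeps selection
deterministic and conservative. The '$' dialect is unquoted; an embedded
'$' in free text is not supported (documented limitation of the format).

Age units convert to years as DEC×10, YR×1, MON÷12, WK÷52.18, DY÷365.25,
HR÷8766; an unrecognized unit drops the age rather than guessing. Country
strings map to uppercase ISO-3166 alpha-2 codes where recognizable and are
otherwise kept verbatim.

## Deduplication

Stage 1 (case versions): among reports sharing a CASEID, keep the one with
the latest FDA date; on ties, the higher PRIMARYID. Stage 2 (independent
copies): among reports identical on the six-field key (sex, age, reporting
country, event date, reaction set, harmonized ingredient set), keep the
lowest PRIMARYID. Two deliberate choices: field comparison uses harmonized
ingredient sets, not verbatim drug strings, since name harmonization
precedes analysis; and a missing value never matches another missing value
— merging on shared absence would delete unrelated incomplete reports.
This is stricter than some published pipelines and is surfaced here rather
than hidden. Both stages are idempotent and order-invariant, and a
survivor rule exists for every group, so deduplication is a total
function.

## Cohort extraction

Indication matching is exact-string (case-insensitive,
whitespace-normalized) against an editable catalog of thymoma, thymic
carcinoma and thymic neuroendocrine terms; substring matching is avoided
so short terms cannot fire inside unrelated PTs. When a report lists terms
from several disease classes the more specific/malignant wins (carcinoma >
neuroendocrine > thymoma > unspecified). Drug names harmonize through an
editable generic+brand dictionary covering the thirteen ICI ingredients
(eight anti-PD-1, three anti-PD-L1, two anti-CTLA-4) plus common
chemotherapy and targeted agents. A case enters the cohort when at least
one *primary-suspect* drug harmonizes to an ICI. The regimen is the single
ICI class of the suspect drugs, or combination ICI when two or more
classes co-occur (including the anti-PD-1 + anti-PD-L1 pattern, which
published strata never show but the rule must cover); a separate flag
records chemotherapy/targeted co-medication in any role.

## Disproportionality

For each PT observed in a stratum's exposed set, a report-level 2×2 table
(a report contributes once however often it lists the PT) yields

    ROR = ad/bc,   95% CI = exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)),  z = 1.96.

Any zero cell leaves ROR and CI undefined (rendered NA) — no continuity
correction, matching the convention that such cells are reported as
incalculable rather than smoothed. The signal rule is a ≥ 3 and CI lower
bound > 1. The ROR measures reporting disproportion, not incidence or
risk; no multiple-testing correction is applied (none is conventional for
this screening rule) and the number of PTs tested accompanies the output.
The default comparator for a stratum is every deduplicated report outside
that stratum, keeping a–d a partition of the corpus; a
`comparator="whole_database"` switch reuses the full non-case pool
instead, since published analyses are often ambiguous on this point — the
difference is negligible when the cohort is tiny relative to the database.
PRR and Bayesian shrinkage statistics are deliberately out of scope (hooks
exist in the result type).

## Time to onset

Onset is the day count from the earliest day-precision ICI therapy start
to the event date. Month- or year-precision dates cannot produce a day
count and are excluded, as are non-positive intervals; the source material
is silent on how partial dates were treated, so exclusion is the explicit
choice here. Raw day counts feed descriptive medians (published medians
range beyond a year), while the Weibull fit is restricted to 365 days
after therapy start: right truncation of spontaneous reports is handled by
exclusion, not by a truncated likelihood (an explicit non-goal).

The WSP test fits a two-parameter Weibull by maximum likelihood (no
censoring) via `lifelines.WeibullFitter`; 95% CIs are normal
approximations on the log-parameters back-transformed to the natural
scale, so they are always positive. Classification: shape CI entirely
below 1 → early failure (decreasing hazard), CI containing 1 → random
failure, CI entirely above 1 → wear-out; the three rules are exhaustive
and mutually exclusive, with CI endpoints equal to 1 counting as
"contains". The fit refuses fewer than 10 records (configurable) and
degenerate samples. Parameter recovery is verified against an independent
coarse-grid profile-likelihood oracle and, over 20 seeds at n = 2,000,
shape estimates stay within 10% of truth with ≥ 90% CI coverage for
shapes 0.5, 1 and 2. The scale estimate is noticeably noisier at small
shapes (its MLE can sit ±15% off at n = 2,000, verified by grid search),
so only its average is constrained in the test suite.

Subgroup onset comparisons use the two-sided Mann–Whitney U test — the
published analysis names no test; Mann–Whitney is the standard choice for
skewed onset data — with exact enumeration when both groups have n ≤ 8 and
the tie-corrected normal approximation otherwise; Kruskal–Wallis covers
more than two groups. ECDF curves are right-continuous steps reaching 1 at
the maximum observed day.

## Descriptive comparison

Fatal cases are those whose outcome codes include death. Percentages use
the column totals (fatal n, nonfatal n, overall N) *including* missing
levels, rendered half-up to one decimal — the convention needed to
reproduce published cohort tables; top-PT tables use two decimals.
Fatal-vs-nonfatal tests default to Pearson chi-square without continuity
correction and switch to the Fisher exact test when any expected cell is
below 5 (2×2 via scipy; r×c via a hand-written conditional enumeration
over tables with the observed margins, cross-checked against R's
`fisher.test`). Missing values are excluded from tests by default and can
be included as a level via a flag; the published P values for the
reference cohort cannot be back-derived unambiguously from the printed
counts under either convention, so the package surfaces its own computed
values rather than forcing agreement. Regression modelling of fatality
predictors is out of scope.

## Synthetic corpus

The generator produces a FAERS-shaped corpus with known ground truth.
Background reports draw each catalog PT independently (a report may carry
several; one lacking any draw receives a filler PT so reaction sets are
never empty), with demographics, outcome and reporter mixes, and partial
missingness. Defaults describe the conditions the pipeline must survive:
100,000 background reports, ~2% same-CASEID re-versions and ~2%
distinct-CASEID field-identical copies, 60% missing event dates (the
published cohort had usable onset data in roughly a third of cases), 26%
missing age, 10% background death rate. Spiked drug–event pairs set the
exposed-group PT probability on the odds scale, odds(p1) = ROR·odds(p0),
so the expected 2×2 table reproduces the target; exposed reports carry a
TET indication and a primary-suspect ICI so they traverse the real cohort
filters, with onset times drawn from a configurable Weibull. The manifest
records exact p0/p1, realized a/b/c/d over originals, and every injected
duplicate, giving downstream stages an exact oracle: across 20 seeds the
screened CI covers a spiked ROR of 10 in ≥ 90% of corpora, the log-ROR is
unbiased within Monte-Carlo error, and with the exposed group at
background rates at most 7.5% of PTs are flagged.

Idealizations, hence limits of what passing tests show about real data:
PTs are independent within a report (no syndrome co-occurrence), drug
co-prescription structure and country-specific reporting rates are not
modelled, and non-injected reports are forced pairwise-distinct on the
stage-2 key (a deterministic one-day event-date nudge resolves accidental
clashes) so that duplicate ground truth is exactly identifiable — real
data contain coincidental field-identical reports that no rule-based
deduplication can distinguish from true duplicates.

## Published-cohort fixtures

Four deterministic fixtures reconstruct the published TET cohort so the
descriptive stages can be checked against printed values: the 152-case
cohort table (all sex/age/weight/disease/country/regimen/reporter/
fatality marginals, and the printed group medians — age 53/61/58.5), the
56-record onset subset (median 21.0 days, 41/56 within 60 days, range
2–1250, fatal subset median 18.0 in 8–266), the 29-patient cardiac series
(39 events, 20 myocarditis, 3 cardiac failure, 7 multi-event patients),
and the top-20 PT table over the 476-event denominator. Printed tables fix
only marginals; the joint structure is completed deterministically, and
where the source states a further property the completion honors it — in
particular the onset multiset is chosen so the windowed WSP test
classifies as early failure (shape 0.69, CI 0.57–0.85), the published
overall profile. Each fixture re-verifies its marginals at build time and
raises on any mismatch. Two printed inconsistencies are left as printed
rather than resolved: the weight-band totals (37 printed vs 8+32 cell sum)
and the onset-missing row (the fixture follows the per-cell counts and the
n = 56 onset subset).

## Numerical and reporting conventions

RORs and CI bounds render to two decimals and percentages to one (half-up,
matching print conventions); screening output sorts by descending case
count, then ROR, then PT name, so runs are byte-reproducible. Quarters are
parsed independently and concatenated *before* deduplication because case
versions span quarters. All generator and pipeline randomness flows from a
single integer seed; identical spec + seed yields byte-identical corpus
files. Problem sizes in the validation suite (100k-report corpora, 20
seeds, n = 2,000 Weibull samples) were chosen as the smallest sizes at
which the Monte-Carlo properties above are sharp.
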