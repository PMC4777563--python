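# Methods

## The episode model

`pcekit` operates on day-granular encounter records. All intervals are
closed `[admit, discharge]`; a missing discharge means the stay was
ongoing at study end and is treated as discharged at `study_end`. The
*effective discharge* used everywhere is
`min(discharge or study_end, study_end, death_date)`.

An episode is built by a single chronological scan of one person's
institutional encounters, sorted by `(admit_date, discharge_date,
sector priority, encounter_id)` with acute-start sectors first on
ties. The first unconsumed acute-start encounter anchors an episode;
while the next institutional encounter (any institutional sector except
`inpatient_nonacute`) is admitted on or before the running window end,
it is absorbed and the window end becomes
`max(window_end, effective_discharge + window_days)`. Otherwise the
episode closes with
`end_date = min(final_discharge + window_days, death_date, study_end)`.
Institutional encounters unreachable from an acute anchor are
*unallocated*. The boundary is closed: a discharge-to-admission gap of
exactly `window_days` chains, one more day does not; the same
convention is used by the synthetic generator, so a single boundary
rule governs the whole package. Same-day transfers (admit equal to the
prior discharge) chain, and overlapping stays chain and extend the
window through the max rule. The test suite checks the scan against an
independently written fixed-point grouper (transitive closure of the
gap relation intersected with acute-anchor reachability).

Community encounters are point-in-time; one dated within the closed
span `[start_date, end_date]` of an episode of the same person is
attached to it (episode spans of one person are disjoint, so attachment
is unique). This includes visits during an intermediate within-episode
gap between two stays, and the tail through `window_days` after the
final discharge.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window_days` | 30 | stabilisation window, days; also the community tail |
| `study_start`/`study_end` | 2010-04-01 / 2011-03-31 | fiscal study year; costs and episodes censored at the end |
| `ed_starts_episode` | true | whether an emergency-department visit may anchor an episode |
| `percentile` | 95 | person-cost percentile defining the high-cost cohort |
| `quantile_method` | linear interpolation | threshold convention (`lower_value` available); selection is strictly greater-than, so ties at the threshold are excluded |

The 30-day window is the conventional threshold used for readmission
quality measures and payment bundles. `ed_starts_episode` is exposed
because reported sector-allocation patterns can be reproduced under
either convention; with it disabled, ED visits can still extend an
episode but a lone ED visit is unallocated.

## Classification

The 12-category hierarchy is resolved by first-match in rank order on
the anchor encounter only. Two categories are flag-driven rather than
MRD-driven: Post-Admission Events fires on any diagnosis flagged
`post_admission` (but is not assessed when the Pregnancy or
Perinatal/LBW rules have already fired), and Trauma scans all diagnosis
codes on the record, not only the MRD. Admissions at inpatient
mental-health facilities classify as Mental Illness & Addictions
regardless of an unmapped MRD. A missing MRD falls through to the
admission-type × service-type rules and finally to Other Causes; such
anchors are logged. The classifier is total and order-independent in
the diagnosis list.

Outpatient-oncology costs attached to an episode are tallied under
their own sector in the ledger and reports; attachment never re-labels
an episode's grouping.

## Cost accounting

Costs are parsed to integer cents and summed exactly; report tables
render dollars and percents with half-up rounding to one decimal.
Per-diem stays (`long_term_care`, `complex_continuing_care`) carry one
row per stay with the whole-stay cost; when such a member stay runs
past its episode's end date (possible only under death or fiscal-year
censoring), the episode receives `cost × days_inside / stay_days`
(inclusive day counts, rounded to the cent) and the remainder stays
outside. The ledger therefore satisfies
`allocated + remaining = grand total` to the cent on every input, which
the suite asserts on every synthetic run.

## Cohort characteristics

Annual person-level cost is the sum over all sectors of that person's
encounter costs. Characteristic binning follows the conventions of the
modelled cohort table: age {0–17, 18–44, 45–64, 65–84, 85+}; rurality
score ≥ 40 rural, 0–39 urban, else missing; morbidity burden
{no contact (missing), 0, 1–7, ≥ 8 aggregated diagnosis groups};
prior-year distinct-drug counts {0, 1–5, 6–9, 10–19, 20+} with
percentages over drug-benefit-eligible persons. The UPC index is
undefined below three attributed ambulatory visits; visits without a
provider id are excluded from numerator and denominator and logged.
Persons with some system contact but fewer than three attributed
visits are displayed in the low-continuity bin (the raw `insufficient`
category is retained internally); persons with no contact at all form
their own bin.

The cohort-threshold step computes the percentile over all persons and
filters to community-dwelling, alive-at-index persons afterwards,
matching the order in which the selection is described; morbidity and
rurality arrive as input fields (only the ≥ 40 cut is applied), and
per-encounter costs arrive precomputed — estimating them from resource
intensity weights is out of scope.

## The synthetic generator

The generator emulates an *already-selected* high-cost community
cohort, which is why the end-to-end pipeline and the acceptance script
run it with `select_high_cost=False`; the percentile-selection step is
demonstrated and tested on the person-cost distribution separately.
Episodes are planted first — anchor attributes drawn to land in an
intended clinical grouping, follow-up stays with inter-stay gaps
uniform on [1, 45] days so that chains deliberately straddle the
30-day boundary — and encounters are serialized from the plants. A gap
beyond the window either starts a new planted episode (when the
sampled stay can anchor) or leaves the stay unallocated, decided at
generation time under the same closed-boundary rule the builder uses,
so ground truth is exact by construction rather than post-hoc
labelling.

Default rates are the study conditions of the modelled cohort: 17% of
persons with no episode and ≈ 1.2 planted chains per person (giving
≈ 83% with at least one episode), 9% annual mortality, 52.1%
drug-benefit eligibility, 11.7% palliative care, and a grouping mix
equal to the reported episode distribution (35% planned surgical, 21%
unplanned medical, 10.8% post-admission events, …). Demographics are
sampled from the reported marginal distributions. Per-sector costs are
log-normal with scale parameters chosen to put median stay and visit
costs at realistic magnitudes for each sector (≈ $8k inpatient acute,
≈ $400 ED visit, ≈ $110 physician visit); community contacts arrive at
0.25/day inside episode spans and 0.03/day outside, so roughly
three-quarters to four-fifths of total cost falls inside episodes.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: realistic ICD-10-CA coding (toy prefixes
such as `TRM`/`CAN` stand in for the real code lists), inter-facility
transfer records needing reconciliation, correlation between
demographics and clinical grouping (a planted pregnancy episode may
belong to an implausible person), seasonality, and deaths occurring
mid-stay — the generator places death dates after a person's last
discharge so that planted ground truth stays exact, and death-censoring
inside stays is exercised by crafted fixtures instead. Marginal rates
are matched; joint structure is not.

## Numerical choices

- Quantiles and medians/IQRs use linear interpolation (numpy default);
  the sample SD uses `ddof=1`. The high-cost threshold additionally
  supports a `lower_value` convention.
- Percent cells round half-up to one decimal, matching report style.
  Summed rounded percent columns are allowed drift of ±0.05 per bin.
- Grouping-summary rows are ordered by descending total cost; empty
  groupings keep their row with n = 0 and blank statistics.
- Degenerate inputs: an empty encounter file is a warning, not an
  error; an empty cohort yields an empty-but-valid report bundle; every
  invalid input row produces a diagnostic naming the row and aborts the
  read (no silent drops).
- Unknown sector names are a hard error: the allocation accounting must
  be exhaustive over the fixed 15-sector vocabulary.

## Known limitations

- Community care between and after stays is attributed purely by date
  within the episode span; there is no clinical linkage of a visit to
  the episode's condition.
- The per-diem proration is linear in days, ignoring within-stay cost
  profiles.
- The bundled code map is synthetic; real deployments must supply
  jurisdiction-specific prefix lists (JSON/YAML, keyed by category).
- UPC is computed from whatever ambulatory visits are supplied; a
  two-year look-back requires providing two years of visits.
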