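# Methods

`pollenhq` analyses season-long series of daily bee-pollen residue
measurements. This note records the model choices, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical conventions.

## The hazard quotient model

The pollen hazard quotient of one detection is

    PHQ = concentration [ng/g pollen] / LD50 [μg/bee, acute oral]

with no unit conversion — a screening index by convention, not a dose.
Derived scores:

* **PHQmax** — PHQ at an analyte's maximum detected concentration over
  the season; the worst single-day threat an analyte posed.
* **mean PHQ** — PHQ at the mean concentration over the analyte's
  detection days. Means are taken over *detected* days only; including
  not-detected days as zeros would make the score depend on season
  length rather than on contamination episodes.
* **tPHQday** — the sum of all defined PHQs in one daily sample. A day
  is *relevant* for bee health when tPHQday strictly exceeds the
  relevance threshold (default 50). The strict `>` is deliberate; an
  inclusive `>=` reading is available as a config flag
  (`inclusive_threshold`).
* **LD50 fraction** — with a nurse bee consuming `m` mg bee bread per
  day and concentration = PHQ·LD50 (ppb), the ingested dose is
  PHQ·LD50·m·10⁻⁶ μg, i.e. a fraction PHQ·m·10⁻⁶ of the LD50. At the
  default m = 9.5 mg/day a PHQ of 100 corresponds to 0.095 ≈ 0.1% of
  the LD50 per day, or ≈1% over a 10-day nursing period.

Analytes without an LD50 value (e.g. non-agricultural repellents) have
*undefined* PHQs. They are excluded from tPHQday and reported in a
separate listing — scoring them as zero would silently understate a
day's load; removing such an analyte from a series never changes
tPHQday.

Tunable parameters (`HazardConfig`): relevance threshold 50
(dimensionless), consumption 9.5 mg/day, nursing period 10 days,
reporting precision 2 significant figures. Internal computation is
always full precision; rounding (decimal half-away-from-zero, the
convention of printed report tables) is applied only to exported tables.

## Quality control

Two decisions precede scoring:

* **Recovery screening.** Spike recoveries inside [30, 160]% pass;
  below 30% an analyte is flagged but retained; below 10% it is
  *excluded* — quantification at a few percent recovery is meaningless.
  The 10% cut cleanly separates a catastrophic recovery (4%) from
  merely poor ones (29%, 53%) in the reference panel. An analyte with
  no recovery value is flagged, never excluded. Masking removes an
  excluded analyte's concentrations (they become NaN detections) but
  keeps its detection days, so persistence analysis still sees them.
* **LOQ censoring.** Concentrations below the analyte's limit of
  quantification become not-detected; a value exactly at the LOQ counts
  as detected. Censoring is idempotent and never creates detections.
  Concentrations are *not* recovery-corrected by default (reported
  values stay raw, as in screening practice); a 100/recovery correction
  exists for sensitivity analyses.

## Temporal analysis

A **detection run** is a maximal stretch of detection days where
interruptions of at most `gap_tolerance` consecutive *sampled*
not-detected days are bridged (default 1 — monitoring narratives
routinely report periods "with one exception"). Days without a sample
(rain days) are observationally neutral: no foraging means no
observation, so they neither extend nor break a run and do not consume
gap budget. Within a run, the peak is the maximum quantified
concentration (earliest day wins ties), `days_to_peak` = peak − start + 1,
`days_to_clearance` = end − peak. The invariant
`Σ(length − internal_gaps) = detection frequency` ties runs to d_f.

**Co-application scoring** replaces exploratory clustering with a
pairwise statistic: over days where both analytes are quantified, the
linear correlation of log-concentrations (noise is multiplicative, so
log scale; configurable) and the coefficient of variation of the
concentration ratio. A pair sharing one formulation at a fixed ratio
shows correlation near 1 and ratio CV near the measurement noise
(√2·CV_noise for two independent noise streams); fewer than 3 shared
days yields an undefined score.

## Pooling and dilution

Pooling assumes equal daily pollen mass: the pooled concentration over a
window is the arithmetic mean of daily concentrations with not-detected
days contributing 0 (an LOQ/2 substitution is available for
sensitivity). Windows are non-overlapping k-day blocks anchored at D1,
or calendar months over sample dates. The **dilution factor** of an
analyte is its season maximum daily concentration divided by the pooled
mean of the window containing that maximum; it is 1 for a constant
series, k for a single-day pulse in a k-day window, and non-decreasing
in window length for a fixed single pulse. Limitation: real daily trap
masses vary (roughly 20–55 g/day in the reference setting) and are not
modelled; factors are therefore equal-weight idealizations.

## The synthetic generator

The generator stands in for raw daily matrices, which monitoring
studies rarely publish. It emulates:

* **spray-event pulses**: geometric (log-linear) rise from ~2×LOQ on
  the onset day to the peak over `rise_days`, then log-linear decay to
  below the LOQ within `decay_days`. Both flanks are multiplicative
  because observed pulses jump into their maxima by large factors
  (hundreds of ng/g to thousands within one day) and fall the same way;
  a linear rise leaves the pre-peak day at (r−1)/r of the peak, which
  is both unlike the observed time courses and too flat for the peak
  day to be identifiable under noise. Typical footprints are ~10 days;
  decay defaults (5–9 days) are presets read from narrative spans, not
  estimates.
* **co-application**: partner analytes receive the primary's profile
  scaled by a fixed formulation ratio; censoring then applies each
  partner's own LOQ.
* **noise**: mean-one lognormal with coefficient of variation
  `noise_cv` (default 0.1) — concentrations are positive and span three
  orders of magnitude.
* **background traces**: per-day Bernoulli detections uniform in
  [LOQ, 3·LOQ] (default rate 0.02), mimicking long low-level tails.
* **rain days**: calendar dates without samples; day indices number
  only sampled days.

Randomness is split per (seed, analyte, purpose) via hashed spawn keys,
so adding an analyte never perturbs the others and the ground truth
(event windows, peaks, expected detection days at zero noise) is
seed-independent. Parameter-recovery holds at the study conditions: for
pulses ≥10×LOQ at noise CV ≤ 0.2, run boundaries land within ±1 day of
truth and the peak day is exact in ≥95% of 100 seeded replicates.

The 102-day season preset (`paper_like_spec`) is a hand-written
storyboard at the reference study's conditions: 29 analytes, event days
and peak sizes following the published per-analyte narratives (peaks
6–4530 ng/g), nine rain days, 1–13 residues on active days. The large
April fungicide episode is modelled as three stacked co-applied events
(main peak, a two-high-day shoulder, a mid-run secondary maximum),
matching the published per-day values of that run; a single clean pulse
would be narrower than the observed episode and overstates monthly
dilution (factor ~11.5 instead of the observed four- to tenfold).

What the generator does **not** emulate: landscape and foraging
dynamics, pollen-mass variation, weather beyond rain-day masking,
correlated noise across analytes (beyond shared events), or seasonal
drift in background rates. Passing tests therefore demonstrate the
correctness and statistical behaviour of the analysis operations under
a plausible data-generating process — not conclusions about any real
landscape.

## Reference-table transcriptions

The bundled per-analyte panel and the per-day PHQ-contribution table
are transcriptions of printed summary tables. Two caveats are encoded
in tests rather than patched in the data: the methiocarb PHQmax cannot
be reproduced from its printed (rounded) inputs — 14/0.08 = 175 against
a reported 170, a <5% artefact of input rounding — and one small
PHQmax (kresoxim-methyl) is printed at two decimals rather than two
significant figures. A handful of tiny per-day contributions could not
be attributed to a unique analyte during transcription; their PHQ
values and all row sums are unambiguous, and only those sums feed the
relevant-day count.

## Numerical conventions and degenerate inputs

ND is encoded on disk as an empty cell or `ND`; a literal `0` is
treated as ND with a warning (true zeros are indistinguishable from
censoring at the instrument). Masked detections round-trip as `MASKED`.
Dates are ISO-8601; `day_index` is authoritative for ordering and run
arithmetic, dates for calendar-month pooling. The residue writer keeps
9 significant digits, making read∘write an identity within float
formatting. Empty series: residues-per-day summaries return zeros; peak
timing of no runs is an empty summary; pooling an empty series is an
error, and a window longer than the series collapses to a single window
with a warning.
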