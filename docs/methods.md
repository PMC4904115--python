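# Methods

## Scope and model of the problem

`uhrconvert` operationalizes the two semi-structured interviews used to
diagnose the ultra-high-risk (UHR) state for psychosis — the CAARMS
12/2006 and the SIPS 5.0 — as deterministic rule engines over a shared
clinical fact base, and provides the psychometric machinery needed to
compare them: individual-case conversion, categorical agreement
statistics and equipercentile score linking.

A subject is represented by subscale-level positive-symptom ratings
(severity and frequency), clinical-course facts (onset, duration at
psychotic intensity, spontaneous resolution, danger/disorganization,
prior episodes, substance and comorbidity flags), trait risk
(schizotypal personality disorder, first-degree relative with
psychosis) and functioning history (SOFAS for the CAARMS, GAF for the
SIPS). Item-level interview content, negative/cognitive/general
subscales and follow-up trajectories are out of scope.

## The rule engines

Both engines return exactly one primary outcome — `UHR_NEG`, `UHR_POS`
or `PSYCHOSIS` — plus the set of UHR subgroups met (GRD, APS,
BLIPS/BIPS) and an ordered rule trace of every criterion evaluated.
Precedence is psychosis threshold, then BLIPS/BIPS, APS, GRD; when
several subgroups are met conjointly, all are reported and the primary
label follows BLIPS > APS > GRD.

Key operationalization choices:

* **Severity/frequency pairing.** A qualifying frequency must be met on
  the *same* subscale as the qualifying severity. The printed inclusion
  criteria list the frequency band over "P1, P2, P3 and/or P4" without
  explicit pairing; within-symptom pairing is the clinically coherent
  reading and is how the CAARMS subthreshold-frequency path is defined.
* **30% functional drop.** `current <= 0.70 * reference`, inclusive, on
  the raw 0–100 scale. A zero/undefined reference evaluates false (a
  30% drop from 0 is meaningless).
* **SIPS frequency floor.** The SIPS prints frequency anchors 1–3 only;
  a value 0 ("below the lowest anchor") is representable so that a
  severity-6 symptom too infrequent to qualify is expressible. The
  printed APS "frequency 2" and BIPS "frequency 1" are read as minimum
  qualifying frequencies, with the POPS frequency 3 taking precedence;
  a literal equality reading would leave severity-6/frequency-2 cases
  unclassifiable.
* **Urgency.** Any severity-6 symptom that is seriously disorganizing
  or dangerous is over the SIPS psychosis threshold regardless of
  duration or frequency. Urgency is modelled as requiring psychotic
  severity (the printed psychosis-threshold table pairs it with the
  severity-6 row); whether sub-psychotic severities can ever be urgent
  is not decidable from the sources and is deliberately not modelled.
* **Unknown flags.** Missing clinical-course booleans are tri-state
  `None`. An unknown exclusion-type flag is treated as "not triggered"
  (rule in only on positive evidence) and the assumption is recorded in
  the rule trace. For BLIPS the exclusion is "symptoms do *not* resolve
  spontaneously", so unknown resolution is treated as resolved.
* **CAARMS psychosis vs BLIPS.** A psychotic-intensity episode with
  BLIPS-band frequency that lasted at most 7 days but did not resolve
  spontaneously is classified psychotic: spontaneous resolution is a
  BLIPS requirement and no other category can hold the case. A
  psychotic-intensity symptom at frequency exactly 3 is APS
  (subthreshold-frequency path) even at long durations, per the printed
  bands.
* **Exclusion scope.** The comorbidity exclusion applies to SIPS APS
  and BIPS only (never POPS or GRD). The SIPS substance-intertwined
  flag is per-subscale: a flagged subscale cannot qualify but others
  can. The CAARMS substance exclusion is the subject-level
  peak-intoxication flag; the per-subscale 0–2 substance code and the
  0–100 distress ratings are informational and never change an outcome
  (enforced by metamorphic tests).
* **Duration caps.** "3 months" for SIPS BIPS is operationalized as 91
  days; any episode in the (7 d, 3 mo] band lands in the documented
  cross-instrument discordance region regardless of the exact cap.

## Conversion (CONVERT)

Conversion crosswalks the ratings onto the target instrument's scales,
carries the shared clinical facts, and applies the target engine.
Subscale map: CAARMS P1→SIPS P1, P2→P2, P3→P4, P4→P5; backwards, CAARMS
P2 receives the highest of SIPS P2/P3 (the SIPS grandiosity subscale
has no CAARMS counterpart and is left unrated going forward).
Severities cross unchanged — the diagnostic thresholds are defined on
raw anchors, and equipercentile adjustment is a separate score-level
facility, never part of diagnostic conversion.

Frequencies map between the anchor sets: CAARMS 0–6 → SIPS 0–3 as
{0→0, 1→0, 2→1, 3→2, 4→2, 5→3, 6→3}, ambiguity resolved downward
(prefer under-calling frequency to over-calling diagnosis). Backwards,
SIPS 0–3 → CAARMS {0→1, 1→2, 2→3, 3→5} for sub-psychotic subscales;
for a subscale at SIPS psychotic intensity the anchors (all "per day"
phenomena) map into the CAARMS daily band, {1→4, 2→4, 3→5} — the
conservative map would strand an established psychotic episode below
the CAARMS 4–6 psychotic-frequency band and deny it any category.

Functioning proxies: converting toward the SIPS without GAF scores, the
GAF one-month drop is proxied by the SOFAS drop (and vice versa toward
the CAARMS, with the GAF's one-month window standing in for the
sustained-drop flag); every proxy is recorded as an assumption note.

The five engineered discordances are regression-tested end to end:
dangerous brief episodes (CAARMS BLIPS → SIPS psychosis), the 7-day vs
3-month caps (SIPS BIPS → CAARMS psychosis), perceptual abnormalities
at severity 5 (CAARMS psychotic, SIPS attenuated), the CAARMS-only
functioning gate, and the SIPS-only comorbidity gate.

## Agreement statistics

For a k×k paired-outcome table: observed agreement `Po`, chance
agreement `Pe` from the marginals, `kappa = (Po−Pe)/(1−Pe)`, PABAK
`(k·Po−1)/(k−1)`, the McNemar-Bowker symmetry statistic
`Σ_{i<j}(n_ij−n_ji)²/(n_ij+n_ji)` with zero-total pairs dropped from
statistic and df, independence expected counts and Haberman adjusted
residuals (|r| > 3.29 ≈ p < 0.001).

The kappa Z statistic and 95% CI use the null-hypothesis standard
error (`kappa ± 1.96·SE0`); the large-sample non-null SE of Fleiss,
Cohen & Everitt (1969) is also exposed on the result. The Bowker p is
asymptotic chi-square; an exact binomial McNemar variant is available
for 2×2 tables. Weighted kappa takes either a full weight matrix or
per-category scores expanded to absolute-difference linear weights
`w_ij = 1 − |s_i − s_j|/range(s)`; with functioning-based scores
(UHR− = 1, UHR+ = 0.84, Psychosis = 0) the off-diagonal UHR−/UHR+
weight is 0.84 and UHR−/Psychosis is 0.

Diagnostic accuracy of conversion binarizes labels against a positive
class: sensitivity, specificity, and the single-threshold trapezoid ROC
area `(sens+spec)/2`, which equals the rank concordance probability of
a binary predictor; kappa/PABAK/percent agreement are computed on the
full multi-class table. Undefined rates (empty denominator) are
reported as missing, never as 0.

## Equipercentile linking

Unsmoothed observed-score equipercentile linking with the standard
uniform-kernel continuization (each integer score spread over ±0.5):
`e(x) = Q_target(P_source(x))`, `Q` the piecewise-linear inverse
(leftmost solution on flat runs), clamped to `[min−0.5, max+0.5]` on
the bounded scales. No presmoothing is applied; log-linear presmoothing
is out of scope. For frequency linkings the SIPS frequency is first
recoded onto the analytic bands of the published linking table
(1 = ≥1 h/day ≥4 d/wk, 2 = ≥several min/day ≥1×/mo, 3 = ≥1×/wk,
0 = none) — verbatim, including its unusual ordering; the recode exists
only for the linking pathway and is never used for diagnosis. The
cohort report produces all published domain linkings, including the
max(P2, P3) SIPS collapse onto CAARMS P2, for severity and frequency in
both directions.

## Synthetic cohorts

The generator draws each subject from a latent state — none,
trait_risk, attenuated, brief_psychotic, frank_psychotic — and
constructs ratings on both instruments so that, with every discordance
mechanism off, both engines recover the state's canonical outcome
exactly (verified at 100% on n = 1000). Severities are uniform within
the qualifying band (no score distributions are published;
uniform-within-band is the least-assumption choice and is irrelevant to
outcome-level behaviour). One global seed drives per-subject
substreams, so cohorts are byte-identical across runs and stable under
changes of n.

`CohortSpec.table3_like()` encodes the study-like conditions: latent
mixture 0.24/0.06/0.34/0.12/0.24 (anchored to the observed 24%/52%/24%
outcome marginals), danger prevalence 0.56 among brief episodes,
long-duration prevalence 0.16, perceptual band-shift 0.12 among frank
psychosis, comorbidity 0.045 among attenuated cases — each taken from
the documented discordance counts. Under these conditions the 3×3
cross-instrument kappa falls in the substantial range (roughly
0.75–0.90 across seeds).

What the generator does *not* emulate: rating noise between interviewers,
item-level symptom structure, partially missing ratings, temporal
symptom trajectories, or correlated measurement error between the two
instruments (a single rater scored both in the source study, which
inflates agreement). Passing tests therefore demonstrate the
correctness of the rules, conversion and statistics — not the field
accuracy of either interview.

## Numerical conventions

Proportions are kept at full precision internally; printed-precision
rounding (2 dp percentages, 3 dp kappa) happens only at presentation.
Degenerate inputs are explicit errors: `Pe = 1` (kappa undefined), zero
marginals (residuals), empty score distributions, non-square tables.
Bowker on a table with no discordant pairs returns (0, 0 df, p = 1).
The equipercentile inverse picks the leftmost solution on flat CDF
runs; ties in the SIPS P2/P3 collapse keep the larger frequency.

## Problem sizes

The test suite sweeps full 7×7 (CAARMS) and 7×4 (SIPS) single-subscale
grids under six course configurations plus 400 random points of the
full multi-subscale grid per engine, and uses synthetic cohorts of
100–1000 subjects; the acceptance script uses cohorts of 212–400
subjects and 25-replicate linking checks. These sizes give exact
(enumerative) coverage of the rule logic and tight Monte-Carlo
envelopes for the stochastic checks while keeping the whole suite in
the order of seconds.

## Known limitations

* The engines encode the printed criteria tables; manual nuances not
  printed there (e.g. interviewer judgement in rating severity, exact
  handling of unknown danger status in the original tool) are resolved
  by the documented conventions above.
* The weighted-kappa construction from functioning scores in the source
  material is underdetermined; the default linear weighting is one
  defensible choice and the weight matrix is fully user-specifiable.
* The published decimal linking tables cannot be reproduced without the
  raw score distributions, which were not deposited; the linking module
  is validated by its mathematical invariants instead.
* The SOFAS↔GAF cross-instrument functioning linkage is published
  elsewhere and is handled here only as the documented proxy rule in
  conversion.
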