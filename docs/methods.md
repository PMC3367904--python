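# Methods notes

## Design generation

The experiment is three sessions of 18 blocks; each block is 24 mini-blocks
of 4 trials (96 trials), with blocks 6, 12 and 18 of every session serving
as transfer blocks. Training blocks hold 8 mini-blocks of each of two fixed
sequences and 4 of each of two random four-location sets; transfer blocks
hold 8 ordinal-only, 8 order-only and 8 random-transfer mini-blocks.
Per session this yields 120 mini-blocks per fixed sequence and 60 per
random set in training, and 5184 trials per participant overall.

Generation choices that the published constraints leave open:

* **Adjacency.** "Neighboring locations" is read as the 8-neighborhood
  (orthogonal + diagonal): the strictest reading, preventing all visually
  contiguous transitions. No consecutive pair within a mini-block may be
  adjacent; the constraint is not applied across mini-block boundaries
  (a fixation cross intervenes).
* **Counterbalancing.** A cohort seed fixes a partition of the 32 cells into
  eight quadruples (re-drawn until every quadruple admits at least one
  non-adjacent ordering); the participant number rotates quadruples through
  the eight slots (two fixed, two random, four reserved), so over an
  8-participant cycle every location serves every role equally often.
* **Interleaving.** Mini-block orders are drawn by rejection sampling with a
  10,000-retry cap on the run-length constraint (no more than three
  consecutive mini-blocks of the same condition, at the fixed-vs-random /
  transfer-condition level).
* **Ordinal-only mini-blocks.** The test item occupies its learned serial
  position (all four positions are used; each of the eight fixed items
  serves exactly once per transfer block) among three never-trained
  locations, so its learned predecessor can never precede it.
* **Order-only mini-blocks.** Beyond the single published layout, each
  mini-block preserves exactly one learned transition X→Y with Y at a wrong
  serial position, one further same-sequence item at a wrong position, and
  one other-sequence item at its correct (non-initial) position. Layouts are
  enumerated exhaustively and one is chosen by seed; transitions alternate
  between the two sequences and rotate across mini-blocks to spread item
  usage. The correct-position item is barred from slot 1 because an
  opening item at its learned position would constitute a position-item
  probe. Control trials (trained item, wrong position, trained
  non-predecessor before it) arise as a by-product and are tagged at
  generation; `classify_transfer_trials` re-derives every tag from first
  principles and raises on any disagreement.
* **Response sides.** 48 left / 48 right per block, seed-shuffled, with no
  within-mini-block balance constraint.

All generation is deterministic given (seed, participant): regenerating
yields a bit-identical table.

## Generative RT model

Baseline search RT is shifted lognormal — right-skewed, strictly positive,
standard for visual search:

| parameter | default | meaning |
|---|---|---|
| `baseline_shift` | 300 ms | irreducible motor/encoding time |
| `baseline_mu` | 6.2 | log-location; exp(6.2) ≈ 493 ms scale |
| `baseline_sigma` | 0.35 | log-dispersion (baseline median ≈ 793 ms) |
| `s_pos_asym`, `s_pos_rate` | 90 ms, 0.03/exposure | position–item curve |
| `s_item_asym`, `s_item_rate` | 70 ms, 0.004/exposure | item–item curve |
| `race_channel_sigma` | 30 ms | per-channel retrieval noise (race) |
| `coactivation_bonus` | 80 ms | over-additive gain when both cues pool |
| `error_rate` | 0.03 | i.i.d. error probability |
| `between_subject_sd` | 0.2 | lognormal SD of per-participant asymptote multipliers |
| `n_participants` | 21 | cohort size |

Learning follows exponential practice curves `asym·(1 − e^(−rate·n))`, with
`n` counting completed mini-blocks of the relevant fixed sequence. The
default asymptotes echo the magnitudes of the two single-source advantages
the analysis is built to detect (tens of milliseconds), and the rates place
the position curve at ~97% of asymptote after one session (120 exposures)
while the item curve is still at ~38% — the early/late dissociation the
transfer analysis should recover. Cue availability follows the derived-list
logic: fixed trials expose both cues, ordinal-only test trials the position
cue, order-only test trials the item cue, and control/new-location/random
trials none.

Expression architectures:

* **race** — each available cue contributes `max(0, s_cue + noise)` and the
  largest draw wins; the combined RT is the minimum of coupled single-cue
  RTs, so the race model inequality holds by construction at any parameter
  setting (verified by Monte Carlo in the tests).
* **coactivation** — available facilitations add, plus `coactivation_bonus`
  when both cues are present, producing fast-tail violations of the bound.

Facilitation acts subtractively on the baseline draw, with RTs floored at
100 ms; retrieval is modeled at the facilitation level rather than as full
evidence accumulation — sufficient to realize both architectures'
distributional signatures without fitting sequential-sampling models.
Errors are drawn i.i.d.; error-trial RTs come from the baseline alone
(a failed search applies no learned facilitation). Post-error slowing is
not modeled, but errors exist, so the post-error exclusion rule is
exercised. The simulator does not emulate spatial effects (eccentricity,
salience — the reason the real design counterbalances locations), RT
autocorrelation, fatigue or block-boundary effects; passing pipeline tests
therefore validates the analysis logic, not robustness to those phenomena.

## Preprocessing

Error trials and the immediately following trial (within a session, across
mini-block boundaries) are excluded; the operation is idempotent. All
analyses use participant-wise cell medians (even-sized cells: midpoint of
the two central order statistics). Difference scores:

* `*_vs_new` = new-location median − test median (positive = facilitation);
  the new-location reference is taken from ordinal-only mini-blocks of the
  same transfer block.
* `*_vs_fixed` = test median − fixed median (positive = cost), the fixed
  reference being the immediately preceding training block (blocks 5, 11,
  17), the closest uncontaminated estimate of intact-sequence performance.
* `fixed_vs_random` = random − fixed per training block.

## Race model inequality test

Per participant, condition CDFs are estimated at the ten decile midpoints
(5%…95%) by linear interpolation of order statistics at plotting positions
(i − ½)/n, clamped to the sample range (RTs pooled across sessions; order
and ordinal trials are too few per session for stable tail quantiles). The
bound F_order + F_ordinal is inverted exactly: the mixture
G = (F_order + F_ordinal)/2 weighs each condition ½ regardless of sample
size, each CDF being the same piecewise-linear estimate completed by jumps
to 0 and 1 at the sample extremes; the bound's quantile at level p is the
generalized inverse of G at p/2. This construction guarantees, exactly and
for any input, that the bound never exceeds either single-condition
quantile function — a property a simpler pooled-sample quantile does not
have when samples are tied or disjoint.

Group inference: per level, a paired one-tailed t-test of fixed < bound;
p-values are Bonferroni-multiplied by the number of restricted-range
comparisons (default levels 5% and 15%, i.e. the 5–20% range where
violations can occur, factor 2) and a violation is declared iff any
restricted-range adjusted p < α (default 0.05). Zero-variance difference
columns are resolved by the sign of the mean difference. Both the level
grid and the restricted set are configurable.

Calibration and power (validation studies, also run by the acceptance
suite): over 500 simulated 21-participant race cohorts the violation rate
is ~0 (the coupled-baseline race leaves slack in the bound, so the test is
conservative); over 500 coactivation cohorts with the default bonus the
rate is ~1.0.

## Explicit-knowledge scoring

Ordered reports are scored by exact position matches; the guessing null for
hits in an ordered 4-of-32 draw is available in closed form
(inclusion–exclusion over forced matches; verified against exhaustive
enumeration on small alphabets) and by Monte Carlo. Report scores are
**upper-tail** probabilities P(hits ≥ observed) — a point density would
judge a 3-hit report "less explicit" than some worse reports — and the two
fixed-sequence scores are averaged; participants with an averaged score
below 5% are flagged for exclusion. Unordered (random-set, rare-location)
reports are scored with the hypergeometric upper tail; the rare-location
score is computed but never used for exclusion. Lost reports are flagged,
not excluded.

Because hit counts are discrete (P(≥2 hits) ≈ 0.0066, P(≥1) ≈ 0.119) and
two reports are averaged, the 5% rule is strictly conservative: under pure
guessing the realized exclusion rate is ≈ 4×10⁻⁵, not 5%. The nominal level
would be attained only by a continuous score.

## Statistics

* Two-way repeated-measures ANOVA by the classical within-subjects SS
  decomposition, each effect tested against its subject-by-effect
  interaction, with uncorrected degrees of freedom (no sphericity
  correction). On 2-level factors F equals the square of the corresponding
  paired t.
* Session regressions report the standardized slope (z-scored variables)
  with n − 2 df over all participant × transfer-block observations.
* Correlation p-values use the t transformation r·√((n−2)/(1−r²)), matching
  R's `cor.test`.
* Within-subject error bars: SE = √(MS_subject×condition / n), identical
  across conditions by construction.

## Validation-study sizes and known limitations

The cohort studies share a single design table across participants and
cohorts: location counterbalancing exists to cancel spatial confounds that
the RT model does not represent, so regenerating designs would add cost
without information. Study sizes — 500 cohorts for the RMI rates, 100 for
the time-course sign tests, 200 participants for curve recovery — give
Monte-Carlo standard errors of ~1%, ~5% and a few ms respectively.

The slow item–item curve reaches only ~76% of its asymptote within three
sessions, so its asymptote and rate trade off in least squares; recovery is
asserted loosely for the asymptote (±50%) while the fitted curve's values
must track the generating curve to < 8 ms RMSE over the observed exposure
range. The position curve's asymptote is recovered within ±20%.

Out of scope by design: stimulus rendering and timing hardware, sequential
sampling (LBA/DDM) fits, kernel-smoothed or bootstrap RMI variants,
capacity coefficients, graded (similarity-based) item–item cueing, and
modeling the emergence of explicit knowledge from RT learning.
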