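# Methods

This note documents the models, conventions, and numerical choices behind
`tapslip`, and what the synthetic-data tests do and do not establish.

## Segmentation

The parse rule is **greedy left-to-right tiling**: at cursor `c`, if the
next `k` keys equal the target sequence a correct trial is emitted and the
cursor advances by `k`; otherwise the key joins the running non-trial
segment. Maximal non-trial runs *between* correct trials become single
errors; leading/trailing runs become labeled residuals (never dropped), so
trial spans always partition the block — an invariant the suite checks on
random streams. Greedy tiling with a fixed-length pattern is maximal
(earliest-end interval scheduling), and the suite verifies it against an
independent dynamic-programming tiling oracle.

Two consequences matter:

* an error can never contain a full sequence match (the scan would have
  claimed it), so `annotate_error` rejects that input;
* a "missing one key" error (a clean 4-correct-key prefix directly followed
  by a correct trial) is unreachable for the default sequence: since
  4–1–3–2–4 begins with the key it ends' neighbor needs, the next trial's
  leading 4 completes the prefix across the boundary and the greedy scan
  absorbs it into a correct trial. The annotator still implements the type
  (it is reachable for other sequences or direct calls); the generator's
  default error mix therefore uses wrong-key errors (first wrong key at
  ordinal 1–5) and incomplete sequences (1–3 correct prefix keys) only.

**First wrong key**: the longest leading run of error keys equal to a
sequence prefix counts as correct; the next key is the first wrong one. A
4-correct-prefix followed by a wrong fifth key is typed `wrong_key` with
ordinal 5 (a key was pressed and was wrong); `missing_one_key` is reserved
for prefix-only errors.

**Error duration** is `t_next − t_prev`: from the last key of the preceding
correct trial to the first key of the following one, spanning the onset and
offset transitions. A strict intra-key definition would give every
single-key error zero duration and make the 0.5-s minimum-duration filter
vacuous for them; the transition-inclusive definition keeps that filter
meaningful. (The strict alternative can be obtained by passing explicit
timestamps to `annotate_error`.)

**Restart attempts** count occurrences of the sequence's first transition
(4→1) among consecutive error keys; the bridge pair into the following
correct trial is checked against the same transition (for the default
sequence it can never fire, because correct trials begin with 4).

## Selection and matching

Defaults: ≥ 3 correct trials before and after (2 after when the trailing
correct run closes the block), duration strictly > 500 ms, length ≤ 20 keys
*inclusive* (the retain-≤ 20 reading; the threshold is configurable).
Positions come from `ROUND((i−1)/k)+1` with half-away-from-zero rounding
(halves cannot arise for odd k). Exhaustively enumerating all 60-key
single-error blocks through the real parser and rules yields eligible
positions exactly 4–10.

Control candidates are every 7-trial window inside a run of consecutive
correct trials, plus one 6-trial window when a run closes its block
(mirroring the 6-trial error periods at block end). Matching draws, per
error, one same-position control uniformly over lexicographically ordered
candidates, **without reuse of a control's center trial** within a set;
candidate windows may overlap (the position is defined by the 4th trial,
not the whole window). A second set re-runs matching with set 1's centers
forbidden; errors without a distinct second control are dropped from both
sets, so the two sets cover the same errors and are center-disjoint.
All randomness flows from one session seed through stable per-stage hashes,
so identical inputs and seed reproduce the sets exactly.

## Slowing metrics

Slowing of a transition of duration `d` is `100·(d − ref)/ref`, with `ref`
the block's mean within-correct-trial transition duration. Zero means
block-typical speed; the measure is scale-free (rescaling a block's
timebase cancels). Trial-level speed uses only the four within-sequence
transitions; between-trial transitions enter only as error onset/offset.
Within-error transitions are split at the first wrong key: `within_pre` /
`within_post` average transitions whose both endpoints lie strictly
before / after it; transitions touching the wrong key itself belong to
neither bin, and prefix-only errors put all internal transitions in
`within_pre`. The trial-level "error" value averages all error transitions
(onset + within + offset). Phases with no constituent transition are
absent, not zero, and absence propagates. When a subject has several
errors, errors are weighted equally (per-error means averaged), then
subjects are weighted equally — the two-stage summary-statistics flow.

Group tests: two-tailed one-sample and paired t (scipy), and a one-way
repeated-measures ANOVA whose Greenhouse–Geisser epsilon comes from the
double-centered sample covariance of conditions (ε = 1 exactly for 2-level
designs; cross-checked against `pingouin.rm_anova`). Zero-variance input
yields an absent p with a diagnostic rather than a number.

## GLM

* **HRF**: canonical double-gamma (peak 6 s, undershoot 16 s, unit
  dispersions, ratio 6, 32-s support), unit-peak normalized, zero at t = 0.
  The task literature specifies no kernel beyond "hemodynamic impulse
  response function"; these are the standard parameters, exposed in
  `HrfSpec`.
* **Design**: regressors built at microtime resolution (TR/16), convolved,
  sampled at scan times. Sticks carry unit mass (the column is the shifted
  kernel); epochs are trapezoid-integrated so the plateau height is
  grid-independent. DCT drift columns up to the 128-s cutoff are appended
  as nuisance (a projection equivalent to pre-filtering that keeps the
  dof bookkeeping explicit), motion enters unconvolved, intercept last.
* **Separate models**: one model per errorless-block trial ordinal (12 for
  the default layout) plus one per error-period role (PreE2, PreE1, E,
  PostE1, PostE2), each role model carrying the role's regressor and the
  matched-control regressor. Onset policy `first_wrong_key` and duration
  policy `actual_duration` are available variants.
* **Prewhitening**: two-pass AR(1) — OLS, pooled lag-1 residual
  autocorrelation with a `+rank/n` first-order bias correction (OLS
  residuals understate the autocorrelation by about the model-dof
  fraction), whitening of data and design, refit. This is the same model
  class as REML-fit AR(1)+white noise at desk-scale cost; calibration is
  verified by simulation (φ recovered within 0.05, null t-contrast
  rejection inside the binomial band).
* **Matched contrasts**: default pools each condition into one regressor
  and contrasts +1/−1; a per-pair beta-series mode (one regressor per
  trial, averaged pairwise differences) exists because "trial-by-trial" is
  ambiguous between the two. They agree exactly on balanced noiseless
  designs.
* **ROIs**: spheres in the volume's own mm frame, voxel-center inclusion
  (≤, inclusive), 6-mm default radius (4 mm for small subcortical
  structures); no atlas registration. Group inference is a random-effects
  one-sample t per ROI with Bonferroni over the family (α/25 = 0.002 for
  the standard 25-ROI set), and a GG-corrected ANOVA over the phase course.
  Cluster-level random-field correction is out of scope.

## Synthetic world

Behavioral generator defaults: 14 blocks × 60 keys, log-normal inter-press
intervals (mean 250 ms, SD 50 ms — fast continuous tapping; log-normal for
positivity and right skew, as no distribution is prescribed), +0.5%
per-block slowing drift, ~0.3 errors per block (≈ 4 per session, the
typical observed per-subject count), error phases ×1.5 and PostE1 ×1.1 —
i.e. the +50% within-error and +10% post-error slowing the recovery tests
target. Blocks end after exactly 60 presses; a trailing partial sequence
becomes a residual, as in real logs.

BOLD generator: sustained block amplitude 1, GO transient 1, per-trial
transient 0.5, role deltas +1 at E and −1 at PostE1/PostE2 (the
instantaneous-positive / delayed-negative pattern), AR(1) noise (φ = 0.3,
SD 1) and a 250-s sinusoidal drift. Synthesis runs on a 10× finer grid than
the analysis microtime and uses a sinusoid rather than the DCT basis, so
generator and fitter share neither time base nor drift basis; event onsets
are time-locked to the analysis microtime grid (the stated-onset
convention — no slice-reference shifting).

What the green tests establish: the pipeline recovers injected behavioral
multipliers and BOLD amplitudes without bias when the modeled effects are
the only structure present, stays calibrated under AR(1) noise, and
sign-recovers the delayed negative post-error deltas end-to-end. What they
do not: real data have learning curves, motion, physiological noise, and
spatially structured signal, none of which the generator emulates.

## Known limitations

* **Adjacent-trial leakage.** At the default tapping rate trial onsets are
  ~1.3 s apart while the HRF spans ~30 s; shifted HRFs correlate ≈ 0.9.
  A single-role model cannot prevent unmodeled neighboring-trial signal
  from projecting onto its regressor. With the default generator the −1
  deltas at PostE1/PostE2 leak into the E regressor with combined weight
  above 1, so the injected +1 at E reads out negative in the matched
  contrast — the full five-role sign pattern is *not* recoverable in this
  world, only the delayed negative part is. This is a property of
  event-related designs at this trial rate, not of the implementation
  (noiseless simulation shows the same bias), and is the reason per-trial
  estimates from such designs should be read as leakage-mixed courses
  rather than isolated trial responses.
* Pooled-φ prewhitening assumes one AR(1) coefficient per run (all series
  pooled); per-series noise models are not provided.
* BOLD input is TSV time-by-series (or arrays in memory); volumetric NIfTI
  I/O is limited to what `sphere_roi_values` needs (arrays + voxel
  geometry), and no preprocessing (realignment, normalization, smoothing)
  is performed.
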