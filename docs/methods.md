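# Methods

`pran` implements a complete analysis chain for studying the
**pre-activation negativity (PrAN)**: an early (≈136–280 ms post word
onset) negative ERP deflection whose amplitude grows as the set of possible
continuations of a spoken word-initial fragment shrinks.  The chain has
four stages — lexical-competition scoring, ERP epoch reduction, inferential
statistics, and a synthetic-data generator that makes every stage testable
end to end without any external corpus or recording.

## Lexical competition from a pronunciation lexicon

The unit of analysis is the **word-initial fragment (WIF)**: the segments
of a word up to and including its first vowel, which must carry primary
stress, paired with the word accent (Swedish accent 1 or accent 2) realized
on that vowel.  Accent matters because the two Swedish word tones cue very
different continuation sets — accent 2 appears on all productive compounds,
so accent-2 fragments have roughly an order of magnitude more possible
continuations.

The **lexical competition** of a WIF is its cohort size: the number of
lexicon word forms that share the WIF (segments *and* accent) and satisfy
the study constraints — nouns (`word_class == "NN"`), polysyllabic
(≥ 2 vowel nuclei), initial-syllable stress, corpus frequency ≥ 2.
Decisions a user should know about:

- The carrier word is included in its own cohort (cohort size, not
  "neighbors minus self").
- Homograph lines (same orthography, different pronunciation) count as
  distinct competitors; the lexicon is treated as a full-form list.
- Polysyllabicity is computed from vowel-nucleus count, not from syllable
  boundary markers, so lexica without `$` markers work.
- Counts are log-transformed (natural log) and z-scored with the sample-SD
  (n−1) convention over exactly the analyzed WIF set.  The z-scores are
  invariant to the log base; `ln` is declared only so intermediate values
  are reproducible.
- If all counts are equal the z-scores are emitted as zeros with a warning
  rather than NaN, keeping degenerate synthetic cases runnable.

The pronunciation dialect is deliberately minimal: whitespace-tokenized
segment symbols with `"1`/`"2` stress-accent markers that attach to the
next vowel token and `$` as an ignorable syllable boundary.  Real lexica in
wide multi-field layouts are mapped in through a `column_map`
(field indices of orthography, word class, pronunciation) and a custom
vowel inventory; no grapheme-to-phoneme conversion is attempted.

The frequency covariate used in the two-predictor regression is the
**mean** corpus frequency of the WIF's qualifying cohort words (log,
z-scored).  The summed cohort frequency is not used because it is
confounded with the competitor count itself (sum ≈ count × mean), which
made the two-predictor design matrix nearly collinear.

## ERP reduction

Epochs are subject × item × channel × sample arrays in μV, time-locked to
F0 (pitch) onset, on a uniform grid covering at least −200…280 ms.  Input
is assumed already band-pass filtered and ocular-corrected; only the
±100 μV amplitude-rejection step is part of the analysis logic.  The
reduction is:

1. **Baseline correction** over −200…0 ms (inclusive endpoints): each
   trace's baseline mean is subtracted, so baseline means vanish to
   numerical precision and the operation is idempotent.
2. **Artifact rejection**: an epoch is dropped if any channel/sample
   magnitude strictly exceeds the threshold (default 100 μV).
3. **WIF averaging**, two-stage: within each subject across that subject's
   surviving epochs of a WIF (items sharing a WIF are pooled first), then
   an unweighted mean across subjects.  Weighting subjects by surviving
   epoch counts is *not* done; the unweighted grand average is the
   conventional choice.
4. **Windowed ROI means**: the mean over ROI channels × window samples,
   with both window endpoints inclusive (a sample exactly at 136 or 280 ms
   is in).  The whole reduction is linear in the input amplitudes.

Two montages are built in: `exp1_3` (6 ROIs × 2 channels: F7/F3, F4/F8,
T7/C3, C4/T8, P7/P3, P4/P8) and `exp2` (9 ROIs × 6 channels on a full
3 × 3 anterior–central–posterior × left–mid–right grid).

## Statistics

**Median split.** WIFs ranked by raw competitor count and halved; boundary
ties are broken lexicographically by WIF key so the split is deterministic,
and with an odd n the median element joins the high group.  Group means/SDs
are reported on the raw count scale.

**Repeated-measures ANOVA.** Classical univariate within-subjects
factorial decomposition on subject × cell means (factors Competitors ×
Antpost × Laterality for the omnibus test).  Each effect is tested against
its own effect-by-subject interaction with uncorrected integer degrees of
freedom; partial eta squared is SS_effect/(SS_effect+SS_error), identical
to df·F/(df·F + df_error).  Greenhouse–Geisser epsilon is computed per
effect (orthonormal-contrast covariance) and reported, but never applied.
Zero-variance effects yield F = 0 rather than NaN.  Missing cells are an
error — no imputation.  Follow-up ("simple effects") ANOVAs run the same
machinery on an ROI subset, either keeping the surviving topographic
factors or collapsing the subset to a single Competitors test.

**Standardized regression.** Windowed amplitudes are z-scored either
against a supplied study mean/SD (the presets carry −2.44/0.91,
−1.46/1.36 and −2.15/1.42 μV) or self-referenced.  Ordinary least squares
with intercept, in two layouts chosen to match the printed df patterns of
the original analyses:

- *two-predictor* (competition + frequency): long format over
  WIF × selected-ROI observations (e.g. 52 WIFs × 2 ROIs → F(2, 101));
- *single-predictor*: ROI-averaged per WIF (52 WIFs → F(1, 50)).

The competition coefficient is evaluated **one-tailed in the positive
direction** — the a-priori hypothesis is that amplitude becomes less
negative as competition rises — while frequency is two-tailed.  With both
variables z-scored, the single-predictor slope equals the Pearson
correlation and R² equals its square; p-values come from exact t/F
distributions, not permutation.  No sphericity correction, no
multiple-comparison correction across ROIs, and no mixed-effects models
are applied: the machinery mirrors the parametric analyses it re-implements.

## Synthetic data generator

**Lexicon.** The generator *constructs* each WIF's cohort rather than
sampling it: for each of `n_wifs` distinct onset+vowel prefixes (each used
with both accents, as in the study stimuli) it draws a cohort size from a
log-normal with per-accent means 24.8 (accent 1) and 248.5 (accent 2)
words and log-space SD 0.7 — the right-skewed shape implied by cohort SDs
comparable to their means — then writes exactly that many qualifying
entries.  Realized counts therefore equal the recorded ground truth
exactly.  Distractor entries (default 5 % each) fail exactly one named
filter: verb word class, stress on the second vowel, monosyllabic, or
corpus frequency < 2.  Identical seeds give byte-identical files.

**EEG.** One epoch per subject × WIF item.  Inside the analysis window the
signal is

    study_mean + study_sd · β · z(log C) · gain(channel) + subject offset + item offset

with white sample noise (SD 5 μV) everywhere and a constant per-epoch
drift (SD 5 μV).  Design notes:

- The effect is a boxcar confined to the window — the analysis only reads
  windowed means, so waveshape realism is out of scope.
- Subject and item offsets are also window-internal: a constant-per-epoch
  offset would be removed exactly by baseline correction and would leave
  no between-item variance for the regression to see.
- The topographic gain is 1.0 over all left-hemisphere ROIs and 0.25
  elsewhere, giving the left-lateralized effect topography while leaving
  the slope unattenuated over the ROI sets the regressions pool.
- The item-offset SD is derived from a target R² by
  `study_sd · |β| · sqrt((1−R²)/R²)` (defaults target R² = 0.15); with
  β = 0 a fallback of 0.9 · study_sd is used — the null calibration of the
  one-tailed test is exact at any noise level.
- Artifacts are opt-in (`artifact_rate`, default 0): selected epochs get a
  ±150 μV spike and are recorded in the ground truth, so rejection can be
  checked exactly.

What the generator does **not** emulate: phonotactically valid Swedish,
realistic EEG spectra, ocular or muscle artifacts, trial-to-trial latency
jitter, or item counts per WIF > 1.  Passing tests therefore demonstrate
that the *analysis logic* is correct and calibrated, not that the pipeline
is robust to every property of real recordings.

## Validation and problem sizes

The test suite checks each stage against an independent oracle: competitor
counts against a literal double-loop enumeration (50 random lexicons of up
to 5000 entries), WIF averaging against nested-loop averaging, the ANOVA
against statsmodels' `AnovaRM` (50 random designs, agreement to 1e-8;
`AnovaRM` is the cross-check, never the implementation), and regression
identities against numpy correlations.  Effect-size recovery runs the full
simulate→reduce→regress pipeline at the study conditions (18–20 subjects,
52 or 72 fragments, planted slopes 0.387/0.302/0.397 with noise tuned to
R² ≈ 0.09–0.16) over 500 replicates per slope, requiring mean bias ≤ 0.02;
type-I calibration uses 2000 null replicates.  `scripts/acceptance.py`
re-runs the same computations (300 recovery replicates per experiment,
1000 null replicates, a 1000-prefix lexicon for the accent ratio) and
writes the resulting numbers as JSON.

## Known limitations

- The NST `"b_ao+"`-style encoding is not parsed natively; real NST files
  need a symbol-mapping step to the whitespace dialect (the `+` marker
  semantics are not reproduced).
- Items are keyed by WIF; per-word (sub-WIF) item effects are not modeled.
- The ANOVA requires a complete subject × cell design; heavy artifact
  rejection that empties a cell is an error rather than an imputation.
- One item per WIF in the generator means item and WIF variance are
  confounded by construction; that is exactly the variance the regression
  treats as residual.
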