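# Methods

This note documents the models, algorithms and design choices behind
`gonogopca`: a pipeline for condition-wise temporal principal-component
analysis (PCA) of event-related potentials (ERPs) from an equiprobable
auditory Go/NoGo task run as a placebo/caffeine within-subject crossover,
together with the synthetic session generator used to validate it.

## The analysis model

ERP components are modelled as separable space–time patterns. For a
dataset of average waveforms (one 19-channel waveform per subject ×
block × drug × condition), the temporal PCA treats **time points as
variables** and **subject × block × channel waveforms as cases**. With
the default geometry (epochs −100..750 ms at 512 Hz, half-sampled to
256 Hz) each case is a 218-sample row; 26 subjects × 2 blocks × 19
channels give the 988 × 218 case matrix (case-to-variable ratio 4.53);
the default generator uses 24 subjects (912 cases).

Each of the four datasets (Go/NoGo × placebo/caffeine) is decomposed
separately. Decomposing conditions jointly is known to misallocate
condition-specific variance across conditions ("smearing"); four separate
PCAs avoid that at the cost of requiring an explicit cross-condition
component-matching step (below).

**Covariance PCA.** The case matrix is column-centered and its 218 × 218
covariance matrix (denominator *n* − 1) eigendecomposed. Unrotated
loadings are eigenvectors scaled by √eigenvalue, so loadings carry µV
units and factor scores are standardized; `scores @ loadings.T` plus the
column means reproduces the input exactly when all factors are kept.
Eigenvalues below 10⁻¹² × λ_max are zeroed (loadings and scores set to 0).

**Varimax rotation.** The full factor set (all 218 factors — "unrestricted"
rotation) is rotated by the SVD-based Varimax algorithm with Kaiser (row)
normalization: loading rows are divided by their communalities before
rotation and restored after. The Varimax criterion is recorded per
iteration and is non-decreasing up to round-off; convergence tolerance
1e−9 on the relative criterion increment, at most 1000 iterations
(non-convergence returns the best iterate with a flag). Because the
rotation acts orthogonally on the factor axis, reconstruction, communality
per time point and total explained variance are all invariant. Rotated
factors are re-ordered by percent variance and sign-flipped so the peak
loading is positive; component polarity is carried by the scores. A
loading-weighting variant of the rotation can be selected
(`kaiser=False`, plain covariance loadings); it is approximate and off by
default.

**Selection.** Factors are selected in decreasing variance order while
their rotated percent variance is ≥ the primary floor (default 2%). For
the caffeine decomposition, a factor whose label matches a component
selected in the corresponding placebo (reference) solution is additionally
selected when its variance exceeds the fallback floor (default 1%). Both
floors are parameters; they are conventional pruning limits, not tested
hypotheses.

**Labelling.** Candidate factors (variance ≥ fallback floor) are scored
against a component template library: a template is admissible when its
latency window contains the factor's peak-loading latency (windows:
N1-1 70–130, PN 130–260, P2/N2b 160–280, P3a 250–400, P3b 280–450,
SW1 350–600, SW2 450–750, LP 500–750 ms; configurable), and the score is
the Tucker congruence between the factor's grand-mean amplitude
topography and the template's signed topography. Assignment is greedy by
descending score, one factor per label, ties broken toward the
higher-variance factor; factors without an admissible template or with
best score < 0.5 are `unknown`. Because the case matrix is
column-centered, factor topographies live in a space where the
channel-mean pattern has been absorbed into the column means; template
maps are therefore centered (channel mean removed) before comparison.

**Component amplitude.** The "peak component amplitude" of factor *k* for
subject *s* at channel *c* is the factor score of case (*s*, block, *c*)
times the loading value at the factor's peak-loading latency, averaged
over blocks. An alternative reading (signed maximum of the reconstructed
component over time) differs only by a positive factor per component and
would not change any congruence or *F* statistic.

**Reconstitution.** Per-site grand-mean waveforms are rebuilt from the
selected factors plus column means and compared with the raw grand means
by Pearson correlation; the difference waveform is also emitted. Keeping
all factors reproduces the raw data to float64 round-off (~1e−5 µV on
~40 µV signals).

## Cross-condition matching

Same-label components from the placebo and caffeine solutions of one
stimulus condition are compared with Tucker's congruence coefficient
r_c = Σaᵢbᵢ/√(Σaᵢ²Σbᵢ²), computed **both** on the temporal loadings and
on the grand-mean topographies; classification uses the smaller of the
two (conservative; both are reported): r_c ≥ 0.95 "equality",
0.85 ≤ r_c < 0.95 "similarity" (the conventional printed bands leave
0.94–0.95 unassigned; it is classed downward as similarity), otherwise
"unmatched" and excluded from drug statistics. Topographic similarity is
additionally quantified by the Pearson correlation over the 19 sites
(df = 17), with the two-sided p from t = r√(df/(1 − r²)). Note that the
grand-mean amplitude maps have exactly zero channel mean (standardized
factor scores sum to zero over cases), so on these maps the congruence
coefficient and the Pearson correlation coincide; both are still
reported, matching the conventional presentation.

## Topographic statistics

Component amplitudes are analyzed on a 3 × 3 grid: sagittal rows
frontal/central/parietal × lateral columns left/midline/right — F3/Fz/F4,
C3/Cz/C4, P3/Pz/P4, except for PN, whose temporal focus is captured by
swapping the hemispheric pairs outward to F7/8, T7/8, P7/8.

Planned single-df contrasts: F>P (±1/3 on frontal/parietal cells),
C>F/P (central +1/3, frontal and parietal −1/6), L>R, M>L/R, and their
four sagittal × lateral elementwise products. Every contrast reduces to a
one-sample t on per-subject contrast scores; F = t², df = (1, n − 1),
partial eta squared η_p² = F/(F + df_error). Drug terms use the
caffeine-minus-placebo cell differences; the Drug main effect weighs all
nine cells equally (1/9).

The analysis is two-step. Step 1 establishes each component's placebo
topography; its significant contrasts (p ≤ α, default 0.05) form the
component's **defining topography**. Step 2 tests caffeine effects:
observed *increases* of the global (Drug main) term or of
Drug × defining-topography terms are tested one-sided (the amplification
prediction); unpredicted decreases and non-defining terms keep two-sided
probability. "Observed increase" is operationalized as the mean
drug-difference score sharing the sign of the placebo mean score on that
contrast (for the global term: the sign of the component's grand-mean
placebo amplitude). Each result carries a rule trace. No multiplicity
correction is applied: the contrasts are planned and within the effect
degrees of freedom. Under a null simulation, the one-sided family rejects
at α by construction; counting the two-sided decrease family on top gives
≈ 1.5α — the two families answer different questions and are reported
separately. Block is averaged out before the drug analysis, so all
component contrasts have df = (1, n − 1).

The behavioral battery is six paired one-tailed t-tests (Go omission %,
fast-RT %, delayed-RT %, NoGo commission %, Go mean RT, within-subject RT
SD), each predicting a reduction under caffeine; t is computed on
placebo − caffeine and p = P(T ≥ t), df = n − 1.

## Preprocessing

1. **Ocular correction**: scalp channels are regressed on the bipolar
   EOG derivations (VEOG = above − below eye; HEOG = left − right
   canthus), pooled per subject × session; the least-squares contribution
   is subtracted. Identically-zero regressors are dropped (no ocular
   signal); a regressor stuck at a non-zero constant raises (broken
   electrode, singular fit). Template- or ICA-based correction is out of
   scope.
2. **Filtering**: 25 Hz low-pass, 4th-order Butterworth applied
   forward–backward (zero phase). The 24 dB/octave slope designation
   names the per-pass asymptote; the family (Butterworth) is a package
   choice, as slope alone does not fix it.
3. **Epoching**: −100..750 ms on a left-closed grid (t_k = tmin + k/f_s,
   t_k < tmax): 436 samples at 512 Hz, 218 after half-sampling — the
   endpoint convention is chosen to produce exactly these counts.
   Baseline: per-channel prestimulus (t < 0) mean subtracted.
4. **Artifact rejection**: an epoch is flagged iff any *scalp* sample
   exceeds ±75 µV; EOG channels are exempt.
5. **Behavioral validation**: NoGo responses (commissions), Go
   non-responses (omissions), and Go RTs outside the individual mean
   ± 1.5 SD (SD with ddof = 1) are flagged. RT statistics pool both
   blocks of a subject × session; whether the original criterion was
   per block or per session is ambiguous, and per-session is the more
   stable estimate. Identical RTs (SD = 0) exclude nothing. Fast-RT and
   delayed-RT "errors" are defined as RTs below/above those same bounds.
   Artifact and behavioral flags are independent columns, so the steps
   commute.
6. **Averaging**: accepted epochs averaged per subject × drug × block ×
   condition (scalp channels only), then half-sampled by taking every
   second sample — no anti-alias refilter, since the data are already
   low-passed at 25 Hz, far below the decimated Nyquist of 128 Hz.

## The synthetic generator

The generator emulates the study conditions end to end: 24 subjects,
2 sessions (placebo/caffeine, shared subjects), 2 blocks of 150 tones
(75 Go/75 NoGo, randomized within block) at 1100 ms SOA, 19 scalp + 4 EOG
channels at 512 Hz. Every trial's clean signal is
Σ_k shape_k(t) · w_k(channel) · condition-mult · drug-mult · subject
factor · block factor.

- **Templates**: Gaussian temporal bumps (peak, σ, signed peak amplitude
  in µV) at 100/170/230/300/395/460/560/690 ms for
  N1-1/PN/P2-N2b/P3a/P3b/SW1/SW2/LP, with amplitudes −9/−5.5/7.5/9/13/
  7.5/6/5 µV — adult grand-average scale. N1-1 and PN are shared between
  conditions; P3b is Go-only; P3a is NoGo-dominant (Go multiplier 0.6);
  P2/N2b, SW1 and LP are NoGo-only; SW2 appears in both. Drug
  multipliers default to 1.0 (no planted effect).
- **Topographies** are drawn as 2-D Gaussian lobes on the schematic head
  (frontocentral N1-1, bilateral-temporal PN, vertex P3a, left-parietal
  P3b, central SW1, frontal-negative/parietal-positive SW2, hemispheric
  centroparietal LP) and then **symmetrically (Löwdin) orthogonalized in
  the channel-mean-centered space**. This is the minimal deformation that
  makes the planted factor scores exactly uncorrelated over cases — the
  identifiability condition under which the planted solution is an
  orthogonal rotation of the PCA basis and simple-structure rotation can
  recover it. Raw overlapping lobes leave score correlations of 0.6–0.9,
  and no rotation method can then separate the planted factors (recovery
  plateaus near congruence 0.9 even without noise). The small flanking
  polarity reversals the orthogonalization introduces mirror those of
  real component head maps.
- **Amplitude spread**: log-normal subject × component factors
  (σ = 0.3) and block × component drift factors (σ = 0.25), both drawn
  independently of the drug label (a crossover shares subjects across
  arms; block drift models within-session arousal fluctuation).
- **Noise**: stationary AR(1) background (coefficient 0.9 in time,
  8 µV SD per channel) mixed across channels by the Cholesky factor of an
  exponential-decay spatial correlation (length 0.6 head units), plus
  sparse artifact transients: with probability 0.025 per trial, a 250 ms
  sin² burst with log-normal peak (median 120 µV, random sign) centred on
  a random channel with spatial spread. The split matters: rejection at
  ±75 µV is driven by the sparse transients (~2% of trials, matching
  accepted-trial counts near 64 of 75 for Go and 72–73 for NoGo, mean
  ≈ 68–70), while the background sets the residual noise in the averages
  (~1 µV), so the selected components carry a realistic ~85–90% of the
  dataset variance.
- **Blinks**: sin² pulses (300 ms, 250 µV bipolar-VEOG peak) at 12/min,
  placed uniformly in the epoch; they appear on VEOGU/VEOGL with gains
  +0.6/−0.4 and propagate to the scalp with frontally weighted gains
  (0.02 + 0.30·((y+1)/2)³ of the bipolar signal — ~0.30 at Fp, ~0.02
  occipitally). Ground truth stores the scalp/bipolar-VEOG gains, so the
  regression step has a recoverable target. EOG channels carry 4 µV
  independent noise (this sets a ~3% attenuation floor on coefficient
  recovery, within the 5% recovery tolerance).
- **Behavior**: Go RTs are ex-Gaussian (µ = 265, σ = 35, τ = 50 ms,
  floor 120 ms → mean ≈ 315 ms, SD ≈ 61 ms); omissions at 2%,
  commissions at 1.5% — placebo-scale values; the drug arms share rates
  by default. Single-trial SNR has no empirical anchor in the target
  literature; the noise parameters above are the package's defaults and
  are all exposed in `GeneratorConfig`.
- **Determinism**: one seed drives named sub-streams (subjects, blocks,
  sequences, noise, behavior, blinks, artifacts); subject and block
  factors come from drug-independent streams. Identical seeds give
  bit-identical sessions; result directories re-render byte-identically.

Ground truth (templates, shapes, topographies, subject/block factors,
EOG gains, config) is attached to every generated `EpochSet`, so recovery
tests never re-derive it.

### What the generator does and does not emulate

It reproduces the study's design geometry, rejection rates, behavioral
rates, component schema and realistic amplitude/noise scales. It does
**not** model: trial-to-trial latency jitter or amplitude habituation,
non-Gaussian loading shapes, volume-conducted source correlations beyond
the planted maps, alpha or other rhythmic background structure,
drug effects on noise or behavior (unless configured), or any
pharmacokinetics. Passing recovery tests therefore demonstrates the
correctness of the decomposition machinery under the planted factor
model, not that real ERP data satisfy that model.

## Numerical and degenerate-input choices

- Covariance uses ddof 1; centering by column means of the case matrix.
- Zero-variance PCA directions: loadings/scores zeroed (epsilon guard).
- Varimax on near-zero communality rows: rows with communality < 1e−12
  are normalized by 1 instead.
- Contrast scores that are constant to round-off (flat maps under
  zero-sum contrasts) are treated as exactly degenerate: F = 0, p = 1.
- RT bounds with SD = 0 exclude nothing; a subject session without any
  responded Go trial is an error.
- Epochs too close to a recording edge are skipped with a logged warning.
- Congruence of a zero vector and correlation of a constant map raise.

## Problem sizes in the validation suite

The test suite validates at the study's own scale: the shared fixture is
one full crossover (24 subjects, 2 × 150 trials × 2 arms, ~69 accepted
trials per average). Monte-Carlo calibration of the test statistics runs
2000 replicates at the amplitude/behavior level; the power check for a
planted 30% Go-P3b caffeine amplification runs 8 seeded full-pipeline
replicates (each an independent 24-subject crossover of the Go stream).
Structural checks use the 26-subject geometry. These sizes are the
package's validation choices and are reproduced by `scripts/acceptance.py`.

## Known limitations

- The matching step pairs components by label only; no Procrustes or
  re-rotation to a common space (deliberately out of scope).
- The labelling score is a hard latency window plus topographic
  congruence; heavily overlapping unknown components can both fall in one
  window and one will be left `unknown`.
- Fast/delayed RT error definitions follow the ±1.5 SD bounds; other
  conventions (fixed ms cutoffs) would change those two behavioral
  measures only.
- EDF support is plain EDF (16-bit, 1 s records, integer-rate) with an
  event/trigger channel, written by a minimal in-package writer and read
  through `mne`; EDF+ annotations are not used.
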