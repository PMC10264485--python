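# Methods

`lexread` implements a complete analysis pipeline for word-level reading
times: it scores how consistently a word's orthography points to its meaning,
estimates how predictable each word token is in its sentence context, derives
first-pass eye-movement measures from fixation streams, joins everything into
modelling records with standard exclusions, and fits a penalized regression
in which the two lexical variables interact through a tensor-product smooth.
A synthetic-data generator with stored ground truth makes every stage
testable end to end without external corpora, embedding spaces, or
eye-tracking data.

## Orthography–semantics consistency (OSC)

For a target word *t* with orthographic relatives r_1 … r_k — every lexicon
word containing *t* as a contiguous substring, including *t* itself —

    OSC(t) = Σ_x f(r_x) · cos(t, r_x) / Σ_x f(r_x),

the frequency-weighted mean cosine between the target's embedding and its
relatives' embeddings. Scores are convex combinations of cosines, so they lie
in [−1, 1] and in practice mostly in [0, 1]; a word whose only relative is
itself scores exactly 1 and is flagged *degenerate*, because a constant has
no explanatory value downstream and such rows are excluded before modelling.

Decisions worth noting:

- **Relative criterion.** Substring at any position (prefix, infix, suffix).
  Published examples of orthographic families are mostly prefixal; the
  position-free rule matches the verbal definition ("contained in") and the
  prefix families are a subset of it. Existing OSC resources appear to admit
  occasional edge-case relatives that are not strict substring matches; we do
  not try to reverse-engineer those.
- **Weights.** Raw frequency counts, no log — the weighting in the defining
  formula — even though the regression covariate is log frequency.
- **Zero frequencies.** Relatives with zero counts keep weight 0. If *every*
  relative has zero frequency the unweighted mean of cosines is returned and
  the row flagged (`zero_frequency_fallback`), avoiding 0/0 while preserving
  the formula's limit.
- **Degeneracy tolerance.** |OSC − 1| < 1e-9 counts as "equal to 1"
  (floating-point safety).
- Words lacking an embedding yield a flagged missing row, never a silent
  drop; case is normalised by lowercasing.

## Surprisal

Surprisal of token w_t is −log P(w_t | w_1 … w_{t−1}). The conditional
model is a trainable n-gram language model (default order 3), standing in
for the neural estimates often used with this measure: the downstream model
only requires a well-formed conditional distribution, and a count-based model
keeps the pipeline self-contained and exactly reproducible. Smoothing is
add-k (default k = 1) or interpolated absolute discounting (Kneser–Ney-style
recursion bottoming out in a uniform distribution); both give strictly
positive probabilities over the vocabulary plus the end-of-sentence marker,
so surprisals are finite and non-negative, and every context distribution
sums to 1 (tested to 1e-9). Natural log is the default unit (nats); base 2
is selectable, and the regression stage is invariant to the choice up to a
linear rescaling of the covariate.

Out-of-vocabulary handling replaces training hapaxes with an unknown type by
default, giving unseen words genuine probability mass. A pure unigram model
carries no notion of sentence termination, so the end marker participates in
the outcome space only for order ≥ 2.

Consistency: on 50,000 tokens generated from a five-state first-order chain
with an explicit per-state end probability, the trigram's mean absolute
surprisal error over contexts observed ≥ 100 times is ≈ 0.03–0.04 nats. The
end event must be part of the generating chain for this comparison to be
meaningful: truncating sentences at an externally drawn length would make
every continuation probability over-estimated by −log(1 − p_end) ≈ 0.1 nats
relative to the chain truth.

## Eye-movement measures

From one trial's ordered fixation stream the extractor derives, per word:

- **first-fixation duration** — duration of the first fixation, reported
  only when the word received more than one first-pass fixation
  ("first of many"); the "more than once" condition is evaluated within the
  first pass, not the whole trial.
- **gaze duration** — sum of the contiguous run of fixations on the word from
  first entry (the run ends when the eyes leave the word in any direction).
- **right-bounded time** — all fixations on the word before the first
  fixation on any word to its right.
- **regression-path (go-past) time** — all fixations on the word *and on
  earlier words* from first entry until the first fixation to its right.

Wherever defined, first-fixation ≤ gaze ≤ right-bounded ≤ regression-path.
A word entered only after material to its right was fixated has no first-pass
measures (flagged `regressive_entry`); a never-fixated word is `skipped`.
If the trial ends before the eyes move past the word, open windows
accumulate to the end of the trial. The extractor also records the minimum
first-pass fixation duration per word, which the exclusion stage needs.
Input is a single merged/monocular event stream with precomputed interest
areas; binocular reduction, blink handling and pixel-to-word mapping are
upstream concerns.

Correctness is checked two ways: exhaustively against an independent
event-simulation oracle on all 9,330 fixation sequences of length ≤ 5 over
3 words with durations in {100, 200} ms, and by property tests (ordering
chain, sum conservation) on random streams.

## Assembly and exclusions

Records join the chosen dependent variable with OSC, surprisal, word length,
natural-log frequency (zero counts bumped to 1 and counted) and sentence
position, under inner-join semantics with per-source missing-value
accounting; duplicate keys in any source are an error. Exclusions run in a
fixed order with a per-step report: (1) OSC missing, (2) OSC equal to 1,
(3) duration bounds — eye tracking: any first-pass fixation < 50 ms or gaze
> 1,200 ms; self-paced reading: RT < 150 ms or > 1,500 ms. All bounds are
strict, so values exactly at a bound survive, and the operation is
idempotent. Percentages are reported against each step's input count — the
unambiguous denominator. For the first-fixation dependent variable,
single-fixation words drop out automatically because that measure is
defined as first-of-many.

## The interaction model

For log-transformed reading time y:

    y = β₀ + β₁·length + β₂·log-frequency + β₃·position
        + f(OSC, surprisal) + z_subject + z_word + ε

- **f, tensor form:** a tensor-product smooth built from cubic B-spline
  marginal bases (default 5 × 5) in the Eilers–Marx P-spline construction —
  one uniform knot sequence extended beyond each boundary, so the null space
  of the order-2 difference penalty is exactly the linear functions and the
  tensor penalty's joint null space is exactly the bilinear plane. One
  smoothing parameter per direction; one sum-to-zero constraint (24 free
  columns at the default basis).
- **f, linear form:** the parametric columns [osc, surprisal, osc·surprisal].
- **Random effects:** ridge-penalized subject and word intercepts — the
  ridge parameter plays the role of σ²/σ_b², so these approximate spline/
  Gaussian random effects in the same penalized-least-squares machinery.
- **Smoothing selection:** GCV (default) or a Gaussian REML criterion with
  σ² profiled out, both minimized by coordinate-wise golden-section search
  over log₁₀λ (tolerance 1e-6, bounds 10⁻⁴–10⁸).
- **Summaries:** effective degrees of freedom per term are the trace of the
  term's block of (X'X + S)⁻¹X'X; standard errors come from the Bayesian
  posterior covariance σ²(X'X + S)⁻¹; smooth-term p-values use an
  approximate F reference on edf. These mirror the table structure of mixed
  GAM software without reproducing its exact machinery. Deviance explained
  is 1 − RSS/TSS (Gaussian case). Fitted + residuals reconstruct the
  response exactly, and residuals are orthogonal to unpenalized columns.

### Linear-vs-tensor comparison

The comparison statistic is

    F = [(RSS_lin − RSS_te) / (edf_te − 3)] / [RSS_te / (n − edf_te,total)].

Two aspects required care:

1. **Nuisance smoothing is held fixed.** OSC is a word-level covariate, so
   freely re-selected word intercepts in the bilinear model can absorb the
   very surface under test and equalise the residuals. The random-effect
   smoothing parameters selected for the tensor model are therefore reused
   when fitting the bilinear form, making the comparison nested in the
   interaction term only.
2. **The null reference is simulated, not nominal.** Because the tensor's
   smoothing parameters are selected on the same data, the nominal F
   distribution is anti-conservative (empirically 8–12% size at nominal 5%).
   The default reference is a parametric bootstrap: responses are simulated
   from the fitted linear model — with random effects *redrawn* iid at their
   estimated variance components (σ̂_b² = σ̂²/λ_b), not the fitted BLUPs,
   which would leak absorbed surface structure into the null — and the
   statistic recomputed with tensor smoothing re-selected. The Monte Carlo
   statistic is the nominal F p-value, which puts replicates with different
   selected edf on one scale; with B = 19 replicates the α = 0.05 decision
   is an exact-size Monte Carlo test (B is configurable; power simulations
   here use B = 39). A tensor term whose selected edf exceeds 3 by less
   than one full degree of freedom has collapsed onto its bilinear null
   space and the comparison is reported inconclusive, preferring the simpler
   form — as does any p ≥ 0.05.

REML selection is used for the comparison simulations (it collapses the
smoother under the null more reliably than GCV); either selector gives
exact test size under the bootstrap reference.

### Model criticism and the surface

Model criticism removes records with |residual|/σ̂ > 2.5 (σ̂² = RSS/(n−edf))
and refits the identical specification; removing over half the data raises.
On clean Gaussian data the rule removes ≈ 2Φ(−2.5) = 1.24% of points; the
per-coefficient shift from a 1.2% symmetric trim is random with standard
deviation ≈ SE·√(6.8·m/n) ≈ 0.3 SE, so stability is assessed on the mean
absolute shift across replicates, not a single draw.

`predict_surface` evaluates the fit on an (OSC, surprisal) grid with linear
covariates at their training means and random effects at zero, with
pointwise standard errors, per-point extrapolation flags, and the training
points as rug coordinates. Surface-recovery checks correlate the fitted and
planted surfaces on a grid over the central 2.5–97.5% quantile box of the
training covariates — the data-supported region where such surfaces are read
against their rugs; full-range grids include unsupported corners where any
smoother extrapolates.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *structure* of a sentence-reading study:

- **Lexicon.** Morphological-looking families: a stem plus suffixed members.
  Stems are drawn substring-free over one alphabet half and suffixes over
  the other, so relative extraction is exactly family membership. Member
  embeddings are α·core + √(1−α²)·noise (unit-normalised) with per-family
  coherence α ~ U(0,1) by default; stems of single-member families score
  exactly 1 (the degenerate atom), and at α = 0 a stem's expected score is
  its own frequency share. Frequencies are Zipf-like over a random ranking.
- **Corpus.** Sentences from a first-order Markov chain over the stems with
  sparse Dirichlet(0.1) transition rows; the sampled per-token surprisals
  spread over roughly 0–12 nats. True surprisal is stored per token.
- **Reading times.** log duration = β₀ + covariate effects + surface(OSC,
  surprisal) + subject + word + ε with defaults β₀ = 5.36 for gaze (≈ 213
  ms; 5.63 ≈ 280 ms is used for self-paced conditions), β_length = 0.006,
  β_log-freq = −0.01, β_position = −0.007, subject SD 0.10, word SD 0.05,
  residual SD 0.25 — magnitudes conventional for log-millisecond
  reading-time regressions. The linear surface uses β_osc = −0.039,
  β_surprisal (configurable; −0.003 in recovery conditions) and
  β_interaction = 0.006. The dip surface adds to a linear surprisal effect
  a negative Gaussian bump (amplitude −0.15 log-units ≈ 14% shorter
  durations at its centre, widths 0.15 in OSC and 1.5 nats in surprisal)
  centred at OSC 0.4 and the corpus-median surprisal: faster reading where
  both variables are mid-range, the qualitative pattern such surfaces show.
  The amplitude default was calibrated so the planted nonlinearity sits
  clearly above the detection threshold of the comparison test at n = 5,000
  (a power simulation should plant an effect its test is meant to detect).
- **Fixation streams.** Gaze is emitted as one or two contiguous fixations
  (refixation probability 0.30); with probability 0.15 a regression — a
  look-back to a random earlier word plus a return fixation — precedes the
  rightward exit, so right-bounded and go-past exceed gaze; words are
  skipped with probability 0.10. The intended gaze is stored as the same
  left-to-right float sum the extractor accumulates, so the round trip is
  bit-exact.

**Identifiability note.** OSC is constant within a word type, so the surface
is only identifiable against word intercepts when word types recur across
sentence contexts with different surprisal values. Simulation conditions
therefore use few subjects and many sentences (e.g. 5 × 140 at n ≈ 5,000),
mirroring real designs where all subjects read the same large sentence set
and the same words recur at different surprisal levels.

What the generator does **not** emulate: cognitively plausible saccade
generation (landing positions, skipping as a function of length or
predictability), spillover or autocorrelated residuals, non-Gaussian RT
tails beyond lognormality, binocular disparity, or any real embedding
geometry. Passing tests therefore demonstrate that the machinery recovers
what it assumes; they do not validate the lognormal-additive model for real
reading data.

Determinism: all randomness flows through one integer-seeded generator;
regeneration and full pipeline reruns are bit-identical.

## Numerical choices and degenerate inputs

- Normal equations solved by Cholesky; random-effect λ has a floor of 10⁻⁴
  within selection, keeping the system positive definite despite the
  intercept/indicator confound (which the ridge resolves).
- λ = 0 is permitted when fixed explicitly (the least-squares oracle);
  λ → ∞ collapses a term onto its penalty null space (tested to ~10⁻³
  relative).
- Fewer unique covariate values than marginal basis functions, constant
  covariates, non-finite values, unordered fixation events, out-of-range
  word indices, duplicate join keys, and mixed real+synthetic pipeline
  configurations all raise explicit errors.
- Unknown subject/word levels at prediction time contribute zero (population
  level prediction).

## Known limitations

- The penalized fit is dense-matrix; designs beyond ~50k rows × ~2k columns
  would need sparse or block solvers.
- Smooth-term p-values are approximate (edf-based F); only the
  linear-vs-tensor decision carries the bootstrap calibration.
- The tensor smooth is isotropic in neither variable but shares one basis
  family; no automatic basis-size selection.
- The n-gram surprisal is a stand-in: absolute surprisal values differ from
  neural language-model estimates, though the pipeline is agnostic to the
  source so long as the per-token table schema is respected.
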