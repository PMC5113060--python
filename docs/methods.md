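# Methods notes

## Task model

The probabilistic selection task is represented as three trained symbol
pairs (AB, CD, EF) with complementary positive-feedback probabilities
(0.8/0.2, 0.7/0.3, 0.6/0.4), criterion-gated training blocks of 60 trials
(20 per pair, shuffled with at most 3 identical pairs in a row), and a
no-feedback test phase of the 12 novel cross-pairings, 8 repetitions each
with left/right order counterbalanced. The learning criterion is ≥60%
A-choices on AB trials and ≥55% C-choices on CD trials within a single
block, computed over responded trials. The session-time limit of real
experiments is represented by `max_blocks` (default 12); agents that never
reach criterion are flagged excluded rather than dropped silently. The
equal per-pair allocation within a block and the interleaving cap are design
choices (the constraint can be disabled); stimulus timing, response windows
and screen positions are outside the trial-log abstraction.

The test schedule contains only the 12 novel pairs. Published work with
this task is not always explicit about test-phase length; the repetition
count is therefore configurable (`test_reps_per_pair`) rather than fixed.

## Choice model and likelihoods

Value updates use the rectified-prediction-error form
`q += alpha_approach*max(r-q, 0) + alpha_avoid*min(r-q, 0)`. With binary
rewards and values in [0, 1] this is identical to gating the rate on the
outcome; the rectified form is kept because it defines behaviour for any
(q, r) and makes the positive/negative split explicit. Only the chosen
symbol updates — no fictive updating of the unchosen alternative.

The softmax is parameterised as a temperature: the exponent is
`(q_first - q_second) / beta`, so small β → greedy choice. The logistic is
evaluated in its numerically stable branch form and is finite for exponents
of at least ±700. Initial values are `q0 = 0.5`, the midpoint of the
outcome scale (configurable); an agent with flat values is exactly at
chance, which makes the random-choice null the n·ln 2 boundary of the fit.

Likelihoods replay the participant's *observed* choices and outcomes —
they never re-simulate. The test-phase likelihood replays training to
obtain the final value table under the candidate learning rates, then
scores each responded test choice through the softmax on those frozen
values; learning rates act on this likelihood only through the final
values. Probabilities are floored at 1e-300 before the log (with a
warning); with β bounded below at 0.01 and values in [0, 1] the floor is
never reached in practice. Non-responded trials are skipped everywhere,
including Q-updating.

## Estimation

Per participant × phase × variant, the NLL is minimised with L-BFGS-B over
bounded parameters: rates in [0, 1], temperature in [0.01, 10] (the bounds
exclude degenerate step/flat softmax; estimates within 1e-6 of a bound are
flagged `at_bound`). Ten local searches start from Halton points in the
interior of the box; start temperatures are log-uniform in [0.02, 2]
because fitted temperatures concentrate well below 1. Convergence is 1e-6
on the NLL; the best start wins, and results are deterministic given the
seed (per-fit seeds in cohort batches are SHA-256-derived from the batch
seed and the fit coordinates). Fits require at least 10 scored trials. The
sequential likelihood recursion is JIT-compiled (numba); a pure-Python
replay of the same recursion is kept as a reference implementation and the
two are cross-checked in the tests, along with a brute-force
product-of-probabilities oracle.

Model comparison uses per-participant AIC (2·NLL + 2k, k = 2 or 3) and
pseudo-R² against the n·ln 2 random-choice null; cohort-level selection is
a two-sided paired t-test on per-participant AICs.

## Group statistics

Learner classification uses strict inequality: a participant is an
approach learner only if select-A strictly exceeds reject-B; ties fall to
avoidance (configurable). Training curves are per-pair logistic
regressions of the correct-choice indicator (A, C or E chosen) on the
within-pair trial number; complete separation is flagged and the slope
reported at a cap of ±5 log-odds per trial. Questionnaire subscales are
z-scored within cohort with the sample-SD (n−1) convention; the BAS
composite z-scores the sum of Drive, Fun Seeking and Reward
Responsiveness. The 2×2 Group × within-factor interactions are computed as
pooled-variance independent t-tests on within-participant difference
scores, algebraically identical to the split-plot ANOVA interaction
(F = t², verified against a brute-force sums-of-squares oracle). The
Spearman correlation matrix is reported with a configurable Bonferroni
divisor (default 105, the all-pairs convention for a matrix of this
structure).

## Synthetic cohorts

Each synthetic agent has two parameter sets. The working-memory system
(`train_params`) drives and learns from training; rates are drawn uniformly
— α_Approach from (0.12, 0.45), α_Avoid from (0.005, 0.15), matching the
positive-feedback dominance typical of fitted training-phase parameters.
The training temperature is drawn from (0.30, 0.50): higher than typical
*fitted* temperatures, chosen so that simulated agents need more than a
single block to reach criterion, as human cohorts do — a softmax-Q agent at
the literal fitted parameters is a far cleaner learner than the humans
those parameters summarise.

The habitual system (`test_params`) learns from the same trial history and
drives test choices. Dual-system agents keep everything except the rate
asymmetry: habitual rates are `mean(WM rates) ∓ h/2` with
h ~ U(−0.4, 0.4), so overall plasticity is held at the WM level and the
asymmetry h = α_Avoid − α_Approach is the single habitual degree of
freedom. The habitual temperature is drawn low, U(0.05, 0.12) — the
habitual read-out is modelled as the sharper, overtrained channel.
Positive h (relatively faster learning from negative feedback) produces
better select-A than reject-B in this task, i.e. approach learners, which
is the crossover direction the analysis is designed to detect.

Trait latents are linear-Gaussian in the standardised asymmetry:
SR−SP = coupling·z(h) + noise, split symmetrically into SR and SP latents
with additional idiosyncratic scatter, then converted to integer subscale
sums on the instruments' raw scales (SR/SP 0–24, BIS 7–28, BAS subscales
4–16 and 5–20). Defaults (coupling 1.2, noise SD 0.4, idiosyncratic SD
0.3) give a strong trait–asymmetry link, consistent with the large group
differences this design is meant to emulate. BIS/BAS latents are drawn
independently of the learning parameters, so they act as null traits.

What the generator does *not* emulate: attention lapses, response-time
structure, non-responses, within-session drift in temperature, and item
level questionnaire responses. Passing the end-to-end tests therefore shows
that the pipeline recovers the structure this generative model encodes —
not that real cohorts satisfy that model.

## Validation experiments and problem sizes

Recovery experiments use a fixed-length design of six 60-trial blocks (360
training trials, no criterion gating) so every agent contributes equally.
Parameter recovery fits 200 agents with rates from U(0.05, 0.5) and
temperature from U(0.1, 0.5); recovery is summarised as Spearman
correlations between truth and estimate (≈0.72–0.80 per parameter). With
far fewer test trials the test-phase surface is weakly identified, which
is why cohort-level conclusions about the habitual system rest on group
statistics rather than individual point estimates. Model recovery uses
cohorts of 40 (two-rate generators have |α_Approach − α_Avoid| ≥ 0.2) and
20 replicate cohorts for the paired-AIC power check. The group-level
pattern check uses the default 60-agent cohort and 10 replicate cohorts
for the null (WM) interaction. The mechanism curve simulates 500 agents
per grid point of α_Approach ∈ {0.05, …, 0.8} at fixed α_Avoid = 0.1,
β = 0.25, four blocks: select-A accuracy falls monotonically in
α_Approach, the small-learning-rates-help effect that probabilistic
feedback produces. These sizes keep the full validation suite at a few
minutes on one CPU while leaving all effects well resolved.

## Known limitations

- Standard errors / posterior uncertainty on per-participant parameters
  are not computed; the pipeline is maximum-likelihood only.
- The habitual-system account is a read-out assumption (frozen end-of-
  training values), not a mechanistic model of consolidation.
- The generator's trait coupling is linear-Gaussian by construction;
  nothing in the pipeline tests nonlinear trait–learning relationships.
- Exclusion handling reproduces the criterion rule only; instruction
  failures and other human exclusion reasons have no analogue.
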