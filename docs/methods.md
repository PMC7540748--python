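# Methods

## The dependency measure

The unit of analysis is one participant in one condition. The data are the
outcomes (correct/incorrect) of the six directed retrieval trials per
three-element event: the ordered pairs of the role triple (animal, object,
location), each tested as cue → target.

Six 2×2 contingency tables are built per participant. For each role X there
is a *common-cue* table pairing the trials X→Y and X→Z, and a *common-target*
table pairing Y→X and Z→X; every directed pair therefore enters exactly one
table of each kind. A table classifies each of the N events into
correct–correct, correct–incorrect, incorrect–correct or incorrect–incorrect
by the joint outcome of its two trials, so cell counts sum to N.

Per table, observed concordance is (N_CC + N_II)/N. The independent model
predicts concordance P₁P₂ + (1−P₁)(1−P₂) from the participant's marginal
accuracies P₁, P₂ on the table's two directed pairs — the concordance
expected if the two trials were independent coin flips at the participant's
own accuracy. Both quantities are averaged over the six tables with equal
weight (the tables share N by design) and the dependency score is their
difference. Identities that the tests pin down exactly:

- all trials correct (or all incorrect): both proportions are 1, dependency 0 —
  the reason ceiling performers are uninformative and excluded;
- a perfectly all-or-none participant with half the events fully retrieved:
  observed concordance 1, every marginal 0.5, independent model 0.5,
  dependency 0.5;
- under trialwise-independent outcomes the expected score is 0 (verified by
  simulation to Monte-Carlo precision).

Marginals are participant-level accuracies per directed pair within the
condition, pooled over blocks; no smoothing or continuity correction is
applied anywhere — the statistic is purely descriptive and the exclusion
rules handle the degenerate ceiling/floor cases. The assignment of directed
pairs to tables is the unique one consistent with "shares a cue" / "shares a
target" for a role triple; it is fixed in `table_definitions` and exercised
by the structural tests.

## Scoring and exclusions

Missing responses (time-outs) are scored as incorrect before any analysis;
the per-participant missing proportion is reported but plays no further role.
Exclusion thresholds are inclusive — accuracy ≥ 0.95 excludes as "ceiling",
accuracy ≤ 0.30 (when a floor rule is configured) as "floor". The accuracy
they apply to is pooled across conditions by default; `condition_mean` scope
averages per-condition accuracies instead, for two-condition within-subject
designs. With balanced trial counts the two coincide.

## Inference

One-sample t tests are two-sided against 0; Cohen's d is the sample mean over
the sample standard deviation, identically t/√n. Welch's two-sample test uses
the Satterthwaite df and reports d with the pooled standard deviation.

The Bayes factor is the Jeffreys–Zellner–Siow one-sample form: under H1 the
standardised effect δ has a Cauchy(0, r) prior (default r = 0.707); the
marginal likelihood of the observed t is

    m1(t) = ∫ f_nct(t; ν = n−1, ncp = δ√n) · Cauchy(δ; 0, r) dδ,

and BF10 = m1(t)/f_t(t; ν), BF01 = 1/BF10. The integral is evaluated with
adaptive quadrature over (−∞, ∞) at absolute/relative tolerance 1e−8; if the
error estimate exceeds tolerance the integral is retried split at the
likelihood peak δ = t/√n and an error is raised if it still fails. The
implementation agrees with `pingouin.bayesfactor_ttest` (the BayesFactor
convention) to better than 0.1 % across the tested (t, n, r) range, and is
strictly decreasing in |t|, symmetric in ±t, and → 1 as r → 0. Robustness
sweeps evaluate BF01 on an increasing grid of prior widths (default
0.5, 0.707, 1.0 — a conventional narrow/default/wide triple). No
multiple-testing correction is applied anywhere, matching the reporting
convention of the designs this package targets.

Power for the one-sample test is exact: with noncentrality δ√n and ν = n−1,
two-sided power at level α is P(T > t_crit) + P(T < −t_crit) under the
noncentral t. `required_n` inverts this by bracket-doubling plus bisection,
exploiting monotonicity in n, and returns the minimal integer n.

## The synthetic generator

The generator encodes the structure the statistic is built to detect, as the
simplest latent model with an all-or-none signature. Per event, a holistic
indicator is drawn with probability `h` (the mixture weight). Holistic
events receive a single memory draw with success probability `a_h` that
decides all six trials together; non-holistic events draw six independent
Bernoulli(`a_i`) memory outcomes. Any trial whose memory failed still
succeeds by guessing with probability `guess` (0.25 for 4AFC), independently
across trials and with no lure-similarity structure. Participant
heterogeneity shifts `a_h` and `a_i` jointly on the log-odds scale by a
N(0, `hetero_sd`) draw per participant (default sd 0.5, reproducing a
realistic between-participant accuracy spread with one parameter).

Defaults: 45 participants, 15 events, `a_h` = 0.75, `a_i` = 0.55 (chosen once
to put simulated accuracy in the 0.6–0.7 range typical of the task),
`guess` = 0.25, `hetero_sd` = 0.5, and mixture weight `h` = 0.202. The
mixture weight was calibrated by large-sample Monte Carlo (150 000
participants, two seeds) so that the population effect size of the
dependency score, d = mean/sd, is ≈ 0.86 — the reference effect size used
for power planning in this paradigm. These are modelling choices of this
package: the paradigm itself specifies no generative model.

Randomness: participant k's data come from
`default_rng(SeedSequence((seed, k)))`, so any participant's data are
byte-identical whatever the cohort size, and the whole dataset is
reproducible from (config, seed). The same draws feed both the trial-level
path (`simulate_participant`, which lays outcomes onto the counterbalanced
schedule) and the vectorised path (`simulate_outcomes`) used by calibration
studies.

The closed-form oracle `expected_dependency_oracle` enumerates the joint
distribution of the two trials of a table (they share the event, hence the
holistic indicator and, for holistic events, the memory draw): with
P₁₁, P₀₀ the concordant-cell probabilities and p the marginal accuracy, the
large-N dependency is (P₁₁ + P₀₀) − (p² + (1−p)²), identical for all six
tables by symmetry. It requires `hetero_sd` = 0; finite event counts add an
O(1/N) bias to the independent-model term, so simulated means are compared
to the oracle at large N.

### Trial schedule

Encoding (separated regime): three blocks, each containing one pairwise
association from every event; events are partitioned into three groups that
rotate through the association types by a 3×3 cyclic latin square, so every
block holds N/3 of each pair type and every event contributes each of its
three associations exactly once. Retrieval: two direction sets (each
association cued both ways across the experiment), each set three blocks of
one trial per event, again with N/3 of each association type per block. The
counterbalance index (mod 6) selects the latin-square row for block order
and which cue direction is tested first. N must be divisible by 3.

## What the simulations do and do not show

Passing the calibration suite shows that the statistic is unbiased under
trialwise independence (type-I error of the one-sample t within [0.03, 0.07]
at α = 0.05 over 2000 replicate 20-participant studies) and that the full
pipeline recovers a planted holistic signal with approximately the power the
noncentral-t analysis predicts. It does not validate the psychological model
against real behaviour: the generator has no trial-timing, modality,
fatigue or lure-similarity effects, no response-time structure, and its
missing-response rate is zero. A known property worth noting: the mixture
generator's dependency scores are mildly right-skewed (skewness ≈ +0.3 at
the default setting), which makes simulated t-test power run one to two
percentage points above the normal-theory value at the same population d;
the calibration test's Monte-Carlo tolerance absorbs this at its replicate
count, but exact agreement with normal-theory power should not be expected
from this (or any) bounded, mixture-generated score.

## Numerical and degenerate-input policy

Zero-variance samples and n < 2 are errors for every t-based routine (an
all-zero dependency vector has no defined t statistic). Empty accuracy
scopes, empty contingency tables and incomplete events raise errors naming
the offending participant/event/pair. `simulate_experiment` with zero
participants returns an empty summary without error. All arithmetic is
double precision; dependency identities (difference of the two averaged
proportions, bounds in [−1, 1]) hold to machine precision and are asserted
in the property tests.
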