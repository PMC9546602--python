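# Methods

This note documents the models, estimators, defaults, and design
decisions behind `quadbias`, and what the synthetic-data generator does
and does not emulate.

## The task and its data model

A seven-block IAT produces, per participant, a sequence of trials with a
block index, stimulus category (ingroup face, outgroup face, pleasant
word, unpleasant word), a first-response accuracy, and a
latency-to-correct-response in ms. Blocks 3, 4, 6, 7 are critical;
blocks 1, 2, 5 are practice. Because the order of the two critical block
pairs is randomized between participants, the data model stores the
**semantic pairing** per trial — which target group currently shares a
response key with "pleasant" — and never a physical key side. All
modeling reduces a session (or a pooled set of sessions) to an 8-cell
table of correct/incorrect counts per (category × pairing).

Files are UTF-8 delimited text (comma or tab, auto-detected, header
required) with configurable column names, so typical
demonstration-website exports can be mapped without rewriting.

## The Quad model

Five probabilities: two association-activation parameters
(`ac_a`, `ac_b`), detection `d_detect`, overcoming-bias `ob`, and
guessing `g` (probability of guessing the pleasant-assigned key). One
`d_detect`, `ob`, `g` is shared across all cells; only AC is duplicated.

**Specification.** The model assumes a compatibility structure: the
dominant valence of the underlying associations matches the measured
bias direction. The *outgroup-bias* specification therefore estimates
`ac_a` = favored-outgroup-with-pleasant and `ac_b` =
disfavored-ingroup-with-unpleasant; the *ingroup-bias* specification
mirrors the roles. Each association is active on its target group's face
trials and (by default) on its own valence's word trials, in both
pairings; it pushes toward the correct key exactly in the pairing where
its group and valence share a key, and toward the incorrect key in the
other pairing. A `faces_only` activation map is available for the
convention in which attribute trials carry no association.

**Tree.** With an active association of strength `a` and per-cell
correct-guess probability `g_cell` (`g` when the correct key is
pleasant-assigned, `1 − g` otherwise):

* association conflicts with the correct response:
  `P(error) = a·d·(1 − ob) + a·(1 − d) + (1 − a)(1 − d)(1 − g_cell)`
* association agrees: `P(error) = (1 − a)(1 − d)(1 − g_cell)`
* no association: `P(correct) = d + (1 − d)·g_cell`

`enumerate_paths` generates the explicit branch list; the closed forms
above are used for fitting, and the test suite requires the two to agree
to 1e-12 over a full parameter grid. Note one subtlety: because guessing
is directional (toward the pleasant-assigned key), face-cell accuracy is
not pairing-invariant even with both ACs at zero unless `g = 0.5`; word
cells are.

## D-scores

The improved scoring algorithm, adapted to latency-to-correct recording:
no error penalty is added because the error cost is already embedded in
the latency. Trials slower than 10,000 ms are dropped; a participant is
excluded when more than 10% of remaining critical latencies are under
300 ms. D is computed per block pair — (3, 6) and (4, 7) — as the mean
latency difference between the lower-status-favoring and the
higher-status-favoring pairing divided by the SD of that pair's pooled
latencies, then averaged; positive D = preference for the higher-status
group. Classification uses strict inequalities at a ±0.15 threshold
(exactly ±0.15 stays unclassified); lower-status participants with
D > 0.15 and higher-status participants with D < −0.15 count as
outgroup-biased.

Subsample descriptives report n, fraction, mean (SD), one-sample t and
Cohen's d against zero, and a pooled-SD independent-groups standardized
difference between the outgroup- and ingroup-biased subsamples (the two
subsamples are disjoint people, so a paired comparison is not defined;
degenerate subsamples are flagged rather than silently dropped).

## Maximum-likelihood fitting and contrasts

The likelihood is a product of 8 binomials. Free parameters are
optimized on the logit scale (L-BFGS-B) from a fixed all-0.5 start plus
20 uniform random restarts by default; ties are broken by the
lexicographically smallest parameter vector so results are stable across
restart orderings. Goodness of fit is the likelihood-ratio statistic
G² = 2(LL_saturated − LL_model), reported under the conventional χ²
label with df = 8 − (free parameters) and misfit effect size
w = √(G²/N); Pearson's X² is reported alongside.

Planned contrasts are nested constraint tests: refit with `ac_a = ac_b`,
`ac_a = 0`, or `ac_b = 0` and compare Δχ² to χ² with df = parameters
removed. Zero constraints place the null on the parameter boundary,
which makes the χ²(1) reference conservative; results carry a
`boundary_null` flag instead of an adjusted reference. Fits with any AC
estimate below 1e-4 carry a degenerate-fit warning, since flat
likelihood directions (notably AC–OB trade-offs when associations are
weak) are a known feature of this model family, and standard errors from
the inverse observed information are reported with NaN marking flat or
boundary directions rather than hiding them. Constrained fits may
nominally "beat" the baseline by optimizer noise; differences within
5e-4 are clipped to zero and anything larger raises.

At the conditions used in the recovery checks (e.g. generating values
0.25/0.10/0.85/0.50/0.55), the Fisher-information SEs of `ac_a` and `ob`
are roughly 0.02 and 0.06 even at 100,000 trials per cell: point
recovery of those two parameters is intrinsically noisy however good the
optimizer, while fits to counts placed exactly at the model's expected
proportions recover all parameters to ~1e-3.

## Hierarchical Bayesian estimation

The hierarchy is a beta-MPT: participant *i*'s parameter
θ<sub>p,i</sub> ~ Beta(α_p, β_p) independently per process parameter,
with group mean μ_p = α_p/(α_p+β_p) and concentration κ_p = α_p+β_p.
Priors: μ_p ~ Uniform(0, 1); κ_p = 2 + Exponential(rate 0.1) (weakly
informative, keeps the population density off the degenerate spikes).
This family was chosen over a latent-trait hierarchy because group-mean
contrasts need no cross-parameter correlation structure and the
hyperparameter count stays small.

Sampling is Metropolis-within-Gibbs with three move types per sweep:

1. a joint random-walk on each participant's logit(θ), vectorized over
   participants (conditionally independent given the hyperparameters);
2. per-parameter random-walk updates of μ (logit scale) and κ
   (log-shifted scale);
3. a joint non-centered move of all ten hyperparameters that carries
   every θ along its population quantile
   (θ′ = F⁻¹<sub>α′,β′</sub>(F<sub>α,β</sub>(θ))), with a proposal
   covariance adapted from warmup history.

Move 3 is what makes the sampler usable here: the centered moves alone
stall on the AC–OB likelihood ridge (split-R̂ near 1.9 at practical
chain lengths), while the quantile-transport move lets the population
and the individuals travel the ridge coherently. Step sizes and the
proposal covariance adapt only during warmup and are frozen afterwards,
so retained draws satisfy detailed balance; identical configuration and
seed give identical draws. The sampler reproduces its priors exactly in
a likelihood-free run and recovers generating group means to ~0.01 when
individual data are strong (≥ ~1000 trials/participant). At the 120
trials/participant typical of a single IAT, the posterior along the
AC–OB ridge is intrinsically wide (SD ≈ 0.07–0.12 for μ_ac and μ_ob with
200 participants); contrasts between the two AC means are much better
determined than either mean alone, which is why the planned contrasts
are the primary read-out.

Convergence is summarized by split-R̂ and bulk ESS (ArviZ) on all
group-level means and concentrations; the reporting gate is R̂ ≤ 1.05
and ESS ≥ 400, and failing it flags the summary (and any downstream
report) rather than raising. Defaults: 2 chains × 1000 retained draws
(the minimum 2000 total used for intervals), 500 warmup.

**Absolute fit (T1).** For each posterior draw, expected counts are the
per-cell totals times that draw's model probabilities; T1 is the
χ²-style discrepancy Σ (observed − expected)²/max(expected, 0.5) over
the 16 cell×outcome counts, and a replicated dataset with matched trial
counts is drawn from the same posterior draw. The posterior-predictive
p-value (ppp) is the fraction of draws whose replicated T1 is at least
the observed T1. The ε = 0.5 floor guards small expected counts at the
participant level; the discrepancy form and floor are this package's
operationalization (documented, configurable), as is the 500-draw
subsample used for the check.

**Dual-specification classification.** Both specifications are fit to
the full sample and each participant's ppp is read off per
specification. A specification "fits" at ppp ≥ 0.05; neither fitting,
or both fitting within a tie window of 0.01, excludes the participant;
otherwise the better-fitting specification's direction is assigned.
Posterior-predictive checks re-use the data and are conservative, so
per-participant discrimination at 120 trials is modest — in generator
validation, outgroup-generated participants are labeled outgroup-biased
about 4–5× as often as ingroup-biased, with the tie rule absorbing
genuinely ambiguous cases.

**Contrasts.** Group-mean differences are draw-wise, summarized by the
mean and equal-tailed 95% interval (2.5%/97.5% quantiles), with
"excludes zero" read directly from the interval. Because group means
live in (0, 1), a raw interval can never contain 0 exactly; the
"distinguishable from zero" read-out therefore asks whether the 2.5%
quantile exceeds a small `near_zero_delta` (default 0.005). This is an
explicit operationalization, always reported next to the raw interval.

## Explicit bias

Feeling thermometers are 0–10 integers with midpoint 5 as neutrality.
Classification is the sign of outgroup − ingroup warmth; ties are
excluded. Summaries give each thermometer's mean (SD), one-sample t and
Cohen's d = (mean − 5)/SD against the midpoint, and a paired
standardized difference between the two thermometers (mean within-person
difference over the SD of within-person differences — here the same
people rate both groups, so pairing is correct). Report tables round to
2 decimals.

## Synthetic-data generator

The generator emulates demonstration-website-style samples so every
stage of the pipeline runs without any external download. Per
participant: a mixture component (defaults 0.35 outgroup-biased / 0.40
ingroup-biased / 0.25 indifferent, roughly the proportions seen in large
lower-status internet samples), process parameters drawn from the
component's Beta populations (default means 0.25/0.10/0.85/0.50/0.55
under the component's own specification, concentration 20), a randomized
critical-block order, trial accuracies simulated from the Quad tree, and
thermometers rounded from latent warmth (SD 1.8; warm toward the favored
group). Latency is a 300 ms floor plus a lognormal body (log-mean
log 350, log-SD 0.4); on trials where the participant's active
association pushes against the correct key, the trial is slowed by
`inflation_ms` (default 150 ms) times the association strength. That
single latent association thus drives both accuracy and latency, so
D-scores correlate with the generating AC asymmetry by construction —
the same coupling the analysis assumes in real data. The indifferent
component has equal ACs and zero inflation.

What the generator does **not** emulate: realistic response-time
distributions fitted to real sessions, stimulus-level variation,
practice effects, block-order effects, or any correlation between
process parameters within person. Passing recovery and classification
tests on this generator therefore demonstrates internal consistency of
the pipeline under its own assumptions, not measurement validity on
real participants.

A six-participant hand-checkable fixture (`fixture_small`) with
deterministic latencies, two deliberate errors, and one participant per
edge case (unclassified, thermometer tie, fast-trial exclusion) anchors
the file-format, tally, and classification tests.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to give stable statistics at
interactive runtimes on a single CPU: 500 replications at 2,000
trials/cell for the likelihood-ratio null calibration; 200 participants
× 120 trials for hierarchical recovery (2 chains, 1000 retained draws
each); 200 participants for classification validity; 150 participants
per inflation level for the D-threshold monotonicity check. Optimizer
tolerance is 1e-11 (relative) on the log-likelihood; probabilities are
clipped at 1e-12 inside likelihoods; degenerate inputs (zero-trial
cells, SD-zero samples, empty subsamples) are flagged or rejected with
named errors rather than propagated as NaN.

## Known limitations

* AC and OB are weakly identified in this 8-cell design when
  associations are weak; both estimators surface this (flat-direction
  SEs, wide ridge-aligned posteriors, degenerate-fit warnings) but
  cannot remove it.
* The χ²(1) reference for zero constraints is conservative at the
  boundary; no corrected reference is provided.
* The per-participant T1 classification is conservative by construction
  (posterior-predictive double use of data); its fit threshold and tie
  window are conventions, exposed in configuration.
* The hierarchical model assumes independent Beta populations per
  parameter; correlated individual differences are out of scope.
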