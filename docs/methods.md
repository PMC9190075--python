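# Methods

## The decision problem

Depression affects roughly one in ten women in early pregnancy and is
frequently missed in routine maternity care. The package models the
costs and health consequences, from the first antenatal appointment to
three months after birth (about nine months), of four ways of
identifying depression at that first appointment:

* **Whooley** — the two Whooley case-finding questions (positive if
  either is answered yes);
* **EPDS** — the Edinburgh Postnatal Depression Scale, positive at a
  score of 13 or more;
* **Whooley–EPDS** — the Whooley questions followed, for Whooley
  positives only, by the EPDS (positive only if both are positive);
* **no screen** — routine clinical assessment by the midwife without a
  screening instrument.

The evaluation takes a health-and-social-care payer perspective, in
2015/16 GBP, with no discounting (the horizon is under a year).
Outcomes are quality-adjusted life years (QALYs).

## Model structure

A decision tree classifies each woman as a true positive (TP), false
positive (FP), true negative (TN) or false negative (FN). For
single-stage strategies the joint class probabilities are built from the
marginal probability of a positive screen and the conditional
probabilities P(depressed | positive) and P(not depressed | negative);
for the two-stage strategy, stage-one negatives and stage-one positives
who screen negative on the EPDS are pooled as screen negatives, each
stratum with its own true-negative share. Complementary branch
probabilities are never stored independently — always computed as one
minus the primary — so every branch pair is exactly normalised (the
source tables' printed complements occasionally sum to 1.0001 from
rounding).

The treatment pathway is shared by all four strategies. Screen
positives enter psychological treatment: a fraction `p_fsh = 0.7921`
receive facilitated self-help (£759) and the rest a high-intensity
psychological intervention (£3114). Response probabilities derive from
relative risks of no improvement (0.73 and 0.48) times the absolute
risk of no improvement without treatment (0.67), giving 0.5109 and
0.6784. Depressed women who screen negative recover spontaneously with
probability 0.33; of the remainder, 0.1025 are identified later within
the horizon (41% over 36 months scaled linearly to 9 months) and then
follow the same treatment pathway as true positives; the rest stay
depressed and untreated. False positives consume 20% of treatment
resources and, in the base case, suffer no quality-of-life decrement.

Three QALY trajectories cover the nine months: depressed→non-depressed
0.6553, depressed→depressed 0.5991, non-depressed→non-depressed 0.7422.
These are used as published: they cannot be recomputed exactly from the
published state utilities (0.678/0.888 antenatal, 0.771/0.907 postnatal
depressed/not) because the transition-timing assumption behind the
area-under-the-curve calculation is not recoverable.

Three leaf assignments are not stated explicitly by the source model and
were fixed by requiring the published per-arm means to be reproduced:
false negatives who recover spontaneously accrue the non-depressed
other-care cost (£1680) and the recovery QALY; later-identified false
negatives receive the full treatment cost and the same response
probabilities and QALYs as true positives (no penalty for the delayed
start); and every woman in an arm incurs that arm's screening cost
(including the £7.95 no-screen conversation). Other health and social
care costs are £2005 (depressed) and £1680 (not depressed) per nine
months. The two-stage screening cost is the Whooley cost plus the EPDS
cost weighted by the probability of a positive first stage
(£4.53 + 0.0895 × £9.38 ≈ £5.37).

Arm value = screening cost + Σ class probability × class (QALY, cost).
With the default parameters this gives (QALYs, £): EPDS (0.7305, 1798),
Whooley (0.7302, 1772), Whooley–EPDS (0.7302, 1747), no screen
(0.7255, 1764) — within half a QALY point ×10⁻³ and £2 of the published
table; the residuals come from the inputs being printed to four decimal
places.

## Incremental analysis

ICERs, strict dominance and extended dominance follow the standard
frontier algorithm: sort by cost, remove arms that are weakly worse on
both axes, then remove interior arms while adjacent incremental ICERs
fail to increase strictly. At the defaults, no screen is strictly
dominated by Whooley–EPDS, and the Whooley falls to extended dominance
between Whooley–EPDS and EPDS, leaving a two-point frontier.

Two ICER conventions are exposed. The library computes ratios of
full-precision deltas by default. Published tables of this kind print
the ratio of the rounded deltas (cost to whole pounds, QALYs to four
decimals); `icer(..., rounded=True)` implements that convention, and it
is what the acceptance script reports. Ratios with a ~0.0002-QALY
denominator amplify any £1 residual in the deltas: the EPDS-vs-Whooley
pairwise ICER computed from printed-precision inputs is £130,000/QALY
versus the published £135,000 for this reason (the Whooley vs
Whooley–EPDS ratio, £240,000, reproduces exactly). A negative ICER is
flagged with its dominance status, never reported as a bare number.

## Probabilistic sensitivity analysis

Every uncertain parameter has a sampling distribution: probabilities are
`Beta(e, e(1−m)/m)` where `e` is the weighted event count behind the
estimate (so the distribution mean equals the point estimate exactly);
costs are gamma by method of moments with SE = 30% of the mean; QALY
trajectories are beta by method of moments with SE = 30% of the value
(their published normal CIs exceed 1 and cannot be honoured by any
distribution on [0, 1]). Degenerate parameters (mean 0 or 1, zero cost)
stay fixed. Derived quantities — the weighted two-stage screening cost,
all pathway composites — are recomputed from each draw. The two
treatment-response probabilities are sampled directly as betas around
their derived means rather than re-sampling the underlying relative and
absolute risks, matching the granularity at which the distributions are
declared. Structural constants (horizon, the 20% FP resource fraction,
the FP QALY multiplier) do not vary.

Each arm's cost-outcome column is sampled **independently** — its own
draws of all parameters, not common random numbers across arms. This is
a deliberate choice: with common draws the shared QALY-trajectory and
other-care draws move all four arms almost in lockstep, incremental
scatters collapse into a half-plane, and the two-stage arm wins the
net-benefit comparison almost half the time; with independent columns
the incremental scatter spreads over all four quadrants in roughly
equal shares and the four arms' acceptability probabilities at
£20,000–£30,000/QALY come out near 26/26/26/22% — the qualitative and
quantitative pattern reported for this model. `run_psa(...,
common_draws=True)` provides the alternative for users who want the
between-arm contrast isolated from shared parameters.

CEACs are computed by the net-benefit rule: at each willingness-to-pay
λ on a £0–£50,000 grid (step £1,000, covering the NICE £20,000–£30,000
band), an arm's probability of being cost-effective is the fraction of
iterations in which it attains the maximal `λ·QALY − cost`, with exact
ties split equally, so each row sums to one by construction. A
convergence diagnostic recomputes the CEAC at cumulative block sizes
and reports the largest probability change between the final two blocks
(< 0.01 at 5,000 iterations, the default and published iteration
count). All randomness flows from one integer seed through
`numpy.random.SeedSequence`; identical seeds give bit-identical draw
tables.

## Sensitivity scenarios

Thirteen one-way scenarios re-run the full analysis with declarative
overrides: (1a/1b) no-screen accuracy replaced by GP-detection
meta-analytic values (positive 0.25, PPV 0.40, NPV 0.8667) with the
contact cost at £31 or £0 — event counts for their betas are recovered
by inverting the printed binomial CIs; (2a/2b) all treated women on one
modality; (3a/3b) later identification 5%/20%; (4) a 2% QALY decrement
for false positives; (5a/5b) depressed-state utilities ±15%, with the
two depressed QALY trajectories rescaled by the ratio of an
area-under-the-curve proxy (six months at the antenatal utility plus
three at the postnatal, in years) at adjusted versus base utilities —
the recovery trajectory rescales only its antenatal component; (6a/6b)
FP resource fraction 10%/30%; (7a/7b) spontaneous recovery 0%/50%.
Scenario 2a/2b is read as *all* treated women switching modality; the
narrower reading (only moderate-severity women) would need a severity
split that is not published. Scenario application is pure (the base
parameter set is never mutated) and each scenario draws from an
independent child of the run seed, so results do not depend on which
subset of scenarios is run.

## Synthetic cohorts and the microsimulation oracle

`cohort.simulate_cohort` emulates the cross-sectional accuracy survey
behind the screening parameters: per-woman true status at the
block-implied prevalence (~0.101), a Whooley result by
sensitivity/specificity, and an EPDS result whose accuracy is
*conditional on the Whooley result* — the dependence needed to
reproduce the two-stage conditional probabilities (marginally
independent errors cannot). EPDS accuracy among Whooley negatives is
solved so the overall EPDS marginal matches the single-stage block; the
survey's stratified sampling weights are not emulated (simple random
sampling targets the weighted probabilities directly). Severity is not
simulated; treatment modality is drawn directly at 0.7921/0.2079.

The module serves two verification purposes. *Parameter recovery*:
re-estimated strategy probabilities (with raw counts attached for beta
construction) match their generating values within three binomial
standard errors at n = 200,000. *Oracle*: walking each woman through
the tree with Bernoulli draws at every chance node reproduces the
analytic arm means within three Monte-Carlo standard errors. Because
the source accuracy blocks imply slightly different prevalences (the
unaided-detection data come from a different study implying ~0.139),
per-arm oracle cohorts are generated from each arm's own block, which
makes the microsimulation estimate unbiased for the analytic value.
What passing these checks shows is internal consistency of the analytic
expectation against brute force — not external validity of the survey
accuracies themselves.

## Numerical and engineering choices

* Probabilities are validated to [0, 1], branch pairs normalised by
  construction, outcome distributions checked to sum to 1 within 1e-9.
* The tree is plain algebra on parameter values, so the same code
  evaluates scalars (base case) and numpy arrays (vectorised PSA
  draws); 5,000 iterations take well under a second.
* The YAML configuration tree mirrors the parameter hierarchy one key
  per parameter; unknown keys are hard errors (a silently ignored typo
  in a scenario override would corrupt results). Overriding a
  probability re-centres its beta and keeps the event-count dispersion
  unless new counts are supplied; overriding a cost restores the
  30%-of-mean SE rule unless an SE is given.
* Exact (cost, QALY) ties between arms stay on the frontier together
  and split CEAC probability equally.
* Reported tables round QALYs to four decimals and costs to whole
  pounds, matching the conventions of the published comparison table.

## Known limitations

* The nine-month horizon excludes longer-run consequences of treated or
  untreated depression, and all benefits accrue to the mother only.
* Depression onset after a true-negative screen is not modelled, and
  spontaneous recovery applies only to false negatives.
* Parameters are sampled from marginal distributions; no correlation
  structure (beyond the within-arm draw) is available to impose.
* The synthetic cohort reproduces the survey's weighted probabilities,
  not its sampling design; estimator dispersion under the original
  stratified design would differ.
* Base-case reproduction is limited by the four-decimal precision of
  the published inputs; ratio statistics with near-zero denominators
  (pairwise ICERs) inherit that limit amplified.
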