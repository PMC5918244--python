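# Methods

This note records the models, estimators, and design choices behind
`citfit`, in the spirit of a statistical methods appendix.  Nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Relative fitness from serial-transfer competitions

A competition assay mixes a focal strain A and a reference strain B,
plates the mixture (initial platings), propagates it through `d` daily
growth cycles with `F`-fold dilutions at the `d − 1` transfers between
the platings, and plates again (final platings).  Plate counts convert
to densities as `colonies × dilution / volume`; densities, not raw
counts, enter the estimator so that platings with different dilution
schemes combine correctly.  The Malthusian parameter of each competitor
is

    m = ln( d_final · F^(d−1) / d_initial ) / d ,

where the `F^(d−1)` factor restores the expansion removed by the
intervening transfers: the platings bracket `d` growth cycles but only
`d − 1` dilutions.  Relative fitness is `W = m_a / m_b`.  The per-day
normalization `1/d` cancels in `W` and is kept only so `m` is readable
as a daily rate.

Degenerate inputs: a zero-colony plate yields density 0 with a logged
warning and invalidates the replicate (no imputation); a reference with
`m_b ≤ 0` invalidates the assay; colony counts outside the 30–300
countable-range heuristic are used as-is with a warning, never
corrected.  `PlateCount` accepts non-integer counts so that noise-free
simulated assays can carry exact expected values; observed data are
integral.

## Combining paired competitions

A knock-in assay produces two replicate sets per strain: the *Cit
competition* (construct vs. control, carrying the effect of interest
plus the Ara marker) and the *Ara competition* (marker control).  These
are unpaired experiments, so the combined effect is the product of the
two sample means, and each bootstrap draw resamples the two sets
independently and multiplies the resampled means (product of means, not
mean of products).  Defaults: B = 10,000 draws, 95% percentile
intervals.  p-values use the add-one rule `(k + 1)/(B + 1)` so they are
never exactly zero; ties at the null count toward both tails; two-sided
p is `min(1, 2·min(p_lower, p_upper))`.  Percentile intervals were
chosen over BCa as the minimal-assumption default.  Where a t-test is
called for, Welch's unequal-variance form is used throughout.

Randomness is reproducible: one global seed per run, with per-strain
substreams derived from `(seed, crc32(strain))` so results are
independent of processing order.

Known small-sample behaviour, measured by the suite: with n ≈ 10
replicates per set the percentile CI covers the truth ~92% of the time
rather than 95%, and the two-sided bootstrap p is anticonservative by
O(1/n) — enough to fail a Kolmogorov–Smirnov uniformity check at 1000
simulations.  At n = 30 (the deepest replicate plan in the motivating
study) coverage sits at 93–95% and calibration passes comfortably.  The
coverage and calibration experiments therefore run at n = 30; conclusions
drawn from n ≈ 6–12 replicate sets inherit the extra ~2–3% optimism.

## Lineage ordering and epoch clustering

Strains are ordered by isolation generation along the root-to-terminal
path of the supplied phylogeny (the terminal being the innovation's
progenitor).  A strain's divergence is the branch length hanging off
that path; strains diverged by more than 5,000 generations (default) are
excluded as unrepresentative of the main lineage, as are strains listed
in an explicit exclusion config (e.g., private subclades with their own
shared effect shifts — these are curated, not auto-detected).  Without a
tree, a per-strain divergence column in the metadata serves the same
purpose.

Clustering is greedy and time-directed: the current group is extended
with the next strain iff **all** pairwise two-sided bootstrap tests
among the tentative members are non-significant after Bonferroni
correction.  The correction family is configurable:

* `family="lineage"` (default): α is divided by the number of pairwise
  tests among all ordered strains, m(m−1)/2.  This controls the
  familywise probability of any spurious split across the whole
  reconstruction at ≈ α, which is what a step-change reconstruction
  needs — with 12 strains in 4 true blocks the suite measures ≥ 95/100
  exact recoveries.
* `family="group"`: α divided only by the k(k−1)/2 pairs within the
  tentative group.  This is the most local reading, but its familywise
  split error is ≈ α *per block* (measured ~57/100 exact recoveries
  under identical conditions), so it is not the default.

Note the bootstrap p floor: with corrected threshold α/K, B must exceed
~2K/α for any test to be able to reject; a warning fires otherwise.

A strain adjacent to a group boundary that is individually compatible
with every member of *both* flanking groups, while the groups differ
from each other, is reported as an **intermediate**: it most likely
spans the branch on which the effect changed and contributes to neither
pooled estimate.  (A strict "test the strain that broke the group" rule
cannot ever fire — the breaking strain is by construction incompatible
with the group it broke — so the check is applied by peeling candidates
off both sides of each boundary after the greedy pass.)

The pooled effect of a group is the equal-weight per-strain combination:
point = mean of member points; draw b of the group = mean over members
of their (independently generated) draw b; CI = percentiles of those
group draws.  Equal weighting per strain (not per replicate) was chosen
so that heavily replicated strains do not dominate an epoch.

Classification per strain: significant benefit (one-tailed p < α for
effect > 1), significant deficit (one-tailed p < α for effect < 1,
flagged *severe* below W = 0.80, i.e. a > 20% cost), else neutral, with
a flag when a one-tailed test cannot rule out a benefit ≥ 1%
(threshold 1.01, p ≥ α).

## Competing-mutation models

The fitness trajectory under diminishing-returns epistasis is the power
law `W(t) = (a·t + 1)^b`, defaults a = 0.0842 /gen and b = 0.0061
(dimensionless).  The accumulation of beneficial mutations is
`n = c·√t` with c = 0.135, i.e. the n-th beneficial mutation fixes at
`t_n = (n/c)²` with selection coefficient `s_n = W(t_n) − W(t_{n−1})`
(t₀ = 0).  The schedule telescopes exactly: Σ s_n = W(t_N) − 1, an
identity the suite verifies to 12 significant digits.  Between events,
s(t) is the right-continuous step function taking value s_n on
(t_{n−1}, t_n].  Schedules default to covering 40,000 generations.

Two caveats are inherent to the printed parameters and carried, not
corrected: (i) the (a, b) pair yields W(50,000) ≈ 1.05, a transformed
scale rather than the experiment's full ~1.7-fold fitness gain — the
*differences* s_n are the quantity used; (ii) late-epoch s(t) is tiny
(~0.05%), so even a +0.4% epoch clears it nominally.  The per-group
verdict therefore comes in two strengths: `driver` / `suppressed` /
`marginal` from the pooled point against s(t) at the span's start,
midpoint, and end, and a conservative flag requiring the CI lower bound
to clear s(t) at all three.

An alternative model of successive sweeping cohorts is exposed only as
a plug-in (`register_sweep_plugin`): its defining recurrences live
outside this package, so `citfit` validates the contract (t strictly
increasing, s > 0) and otherwise treats it as opaque.

## qRT-PCR quantification

Technical replicates are averaged per gene first; then
`ΔCq = Cq(target) − mean over reference genes of Cq`, biological
replicates are averaged, `ΔΔCq = ΔCq(strain) − ΔCq(calibrator)`, and
`R = 2^(−ΔΔCq)`.  Reference genes are combined by unweighted mean Cq.
The CI on R is a Welch t-interval on ΔΔCq, exponentiated (the interval
flips: lower ΔΔCq means higher R).  Primer efficiency is reported from
the dilution-series slope, `E = (10^(−1/slope) − 1)·100%`, for quality
control only — R uses the ideal-doubling form, not efficiency-corrected
(Pfaffl-style) quantification.

## Synthetic data

The generator exists so every stage can be tested against known truth.

* **Competitions**: deterministic expected densities from Malthusian
  growth (reference expands `reference_daily_growth`-fold per day,
  default 100, matching the transfer dilution so densities cycle; the
  focal strain's rate is `true_w` times the reference's), plus noise at
  the physically honest place — Poisson counts on the plates (default)
  or lognormal flask-to-flask density noise.  Zero noise inverts to
  `true_w` exactly (≥10 significant digits, tested).
* **Lineage studies**: a caterpillar tree with strains attached to the
  backbone at their isolation generation by 1-generation private
  branches; epoch-structured true effects, defaults
  (+1.7%, −5.4%, +0.4%, +2.4%) × 3 strains, replicate W values drawn
  Normal(truth, 0.005) with n = 10 per competition and a neutral Ara
  marker (a non-neutral marker option exists and cancels in the
  combined estimate by construction).  These are W-level draws — the
  fast path for statistical experiments; count-level simulation is the
  slow path through the same fitness estimator.
* **qPCR**: stable reference genes across strains; a strain with true
  fold change f has target Cq = baseline − log₂(f) + Normal(0, sd) per
  well.

What the generator does **not** emulate: day-to-day environmental
drift shared across replicates, marker-by-background interactions,
frequency-dependent fitness (the population-context assay class is
carried as a label, not a distinct generative model), non-normal
replicate noise in the W-level path, and qPCR efficiency differences
between genes.  Passing tests therefore demonstrate correctness of the
estimators and procedures under clean sampling assumptions, not
robustness to those real-data effects.

## Problem sizes used by the suite and acceptance script

Monte-Carlo experiments run at: 200 seeded 6-replicate Poisson
competition studies; 1000 simulated combined effects for CI coverage
(B = 2000 within each) and 1000 for null calibration; 100 seeded
four-epoch lineage studies at B = 10,000; 500 seeded qPCR tables.  The
full suite runs in a few minutes on one CPU; the acceptance script in
well under a minute.

## Known limitations

* Percentile-bootstrap small-sample optimism as quantified above.
* Greedy time-directed clustering does not globally optimize the
  partition; pathological orderings could in principle be split
  differently by an exhaustive search.
* The severe-deficit flag thresholds the point estimate (W < 0.80);
  it is not itself a test against 0.80.
* Count-level competition CSVs are trusted to carry consistent dilution
  metadata; no plausibility check beyond the countable-range warning.
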