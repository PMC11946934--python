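# Methods

## Problem and data model

The quantity of interest is the distribution of causes of maternal death —
seven mutually exclusive groups (abortion, embolism, haemorrhage,
hypertensive disorders, pregnancy-related sepsis, other direct, indirect) —
per country, aggregated to regions and the world over a 2009–20 analysis
window. Inputs are (i) *observations*: per country-period cause-of-death
counts from one of four source tiers (confidential enquiry, CRVS, national
report, subnational study), each with the total maternal deaths identified
(`n_total`) and the subset with an assigned cause (`n_assigned`); and (ii)
an exogenous *envelope* of total maternal deaths and the HIV-attributable
proportion per country-year, consumed as-is and never re-estimated. The
model estimates non-HIV deaths only; HIV/AIDS-related indirect deaths enter
at aggregation time through the envelope's HIV share.

Maternal suicide and late maternal deaths (>42 days and <1 year after the
end of pregnancy, ICD-10 O96/O97) are deliberately outside the modelled
simplex: suicide because routine CRVS coding cannot link suicide to
pregnancy status (so only specialised sources are usable and results are
reported descriptively, without uncertainty intervals), late deaths because
they are excluded from the envelope's definition of maternal death.

## Cause taxonomy and ICD-10 mapping

The coordinate order of the seven groups is fixed package-wide
(`matcod.causes.CAUSES`). ICD-10 codes are assigned by longest-prefix match
against a versioned, user-replaceable CSV. The shipped default was
reconstructed from ICD-10 chapter-O block titles; judgement calls a user
may wish to override by editing the mapping file:

- O10 (pre-existing hypertension), O24–O25, O98, O99 → indirect;
  O11–O16 → hypertensive disorders.
- Haemorrhage timing: O20/O44–O46 antepartum, O67 intrapartum, O72
  postpartum. Sepsis timing: O23 antepartum, O75.3 intrapartum, O85–O86
  postpartum.
- O88 only → embolism (puerperal venous complications O87 stay in other
  direct).
- O63 (long labour) → other direct/other; O64–O66 → obstructed labour.
- O95 (obstetric death of unspecified cause) → other direct/other, a
  placeholder pending an authoritative allocation rule.
- X60–X84 → the special `suicide` label; codes outside the mapped range →
  `not_maternal`.

## Estimation model

With `K = 7` causes and reference cause `other_direct`, country `c` has
additive log-ratios `η_c ∈ ℝ^{K−1}`, and `p_c = softmax_complete(η_c)`.

- Country level: `η_c ~ MVN(μ_r(c), Σ)` with one covariance `Σ` shared
  globally. `Σ` is parameterised by its Cholesky factor `L` with lognormal
  priors on the diagonal (median 0.3, log-SD 1) and `N(0, 0.3²)` on the free
  off-diagonal entries — a weakly-informative prior with full support on
  SPD matrices chosen over an LKJ construction because its unconstrained
  gradient is simple and, in every regime we tested, the posterior over `Σ`
  is data-dominated.
- Region level: `μ_r = μ₀ + τ z_r`, `z_r ~ N(0, I)`, `τ ~ HalfNormal(1)`,
  `μ₀ ~ N(0, 2² I)`.
- Observation level: `counts_o ~ Multinomial(n_assigned_o,
  softmax_complete(η_c + δ_o))` with `δ_o ~ N(0, (σ_{s(o)} · inflate_o)² I)`.
  The four per-source SDs are built as cumulative sums of positive
  increments (lognormal(median 0.1, log-SD 1) priors), which enforces the
  reliability ordering confidential enquiry ≤ CRVS ≤ national report ≤
  subnational study by construction.
- Partial assignment: `inflate_o = sqrt(n_total/n_assigned) ≥ 1` widens the
  observation-level noise when only a subset of deaths has an assigned
  cause. A documented alternative (`partial_assignment="effective_n_only"`)
  relies solely on the reduced multinomial size.
- Time: one time-constant composition per country over the window,
  applied to every envelope year at aggregation. Year effects are out of
  scope.

Observations with `n_assigned = 0` are excluded from the likelihood with a
warning. Countries with no observations keep their place in the parameter
vector, so their posterior is exactly the region-level predictive — the
mechanism by which data-free countries are estimated.

## Posterior computation

Sampling uses the package's own Hamiltonian Monte Carlo (`matcod.hmc`):
static leapfrog trajectories with jittered length, dual-averaging step-size
adaptation (target acceptance 0.85), and a diagonal mass matrix estimated
from the second half of a warmup window. Everything is non-centred and
unconstrained (log transforms for scales; the analytic gradient is verified
against finite differences in the test suite). Defaults: 4 chains × 500
warmup + 500 draws, 64 leapfrog steps. Convergence screening uses split
R-hat (< 1.05) and bulk ESS (> 400) via `arviz` over the global mean,
region SD, source SDs and all country effects; results failing a threshold
are returned flagged `converged=False`, never discarded silently. Isolated
energy-threshold rejections are counted but only a divergence rate above
0.5% of draws flags the fit.

Sampler correctness is checked two independent ways: a two-cause reduction
with fixed hyperparameters against 1-D numerical quadrature of the exact
posterior (agreement within 0.01 on posterior mean and SD of the
proportion), and a Kolmogorov–Smirnov comparison of a data-free country's
draws against fresh region-predictive draws.

## Aggregation conventions

Per draw, country deaths by cause are `envelope_deaths_c × p*_c`, where
`p*` incorporates the country's death-weighted HIV proportion `h` as
`p*_k = (1−h)p_k` for non-indirect causes and `p*_ind = (1−h)p_ind + h`.
Regional and global draws are sums of country draws, and regional
proportions are ratio-of-sums per draw — so cause deaths sum *exactly* to
the envelope at every level, within each draw. Summaries (median, 10th,
90th percentile) are computed independently per quantity; consequently
subgroup medians need not add up to their parent's median, and the package
reproduces that convention deliberately rather than renormalising.

Subgroup splits (haemorrhage/sepsis timing; other-direct subtypes) are
conditional hierarchical multinomials over the subgroup set, fitted with the
same machinery on the observations that report subgroup counts, using the
observation's parent-cause count as the `n_total` for inflation. Subgroup
deaths per draw are parent deaths × subgroup fraction, exact by
construction. With no subgroup data at all the split falls back to the
prior hierarchy, flagged with a warning.

## Descriptive analyses

Suicide: a country contributes if its pooled non-CRVS observations record at
least one maternal suicide; its proportion is summed suicides over summed
maternal deaths, and regional averages are unweighted country means (a
death-count-weighted option exists but is off by default, matching the
unweighted-averages reading of the reporting convention). Late deaths: per
country, summed late deaths over summed maternal deaths up to 42 days;
ratios above 1 are legitimate (some confidential-enquiry systems record more
late than early deaths); values below 0.005 render as "<0·01" in formatted
tables while the raw value is retained.

## Synthetic-data generator

`matcod.simulate.generate` draws datasets from the structure the model
assumes: logistic-normal country compositions around region means (default
global composition haemorrhage-led: 27% haemorrhage, 25% indirect, 16%
hypertension, 8% abortion, 7% each embolism/sepsis, 10% other direct),
region and country SDs 0.3 on the log-ratio scale, source noise SDs
(0.05, 0.10, 0.15, 0.25) in reliability order, two observations of 150–250
deaths per country, partial assignment uniform on (0.8, 1.0) with the same
`sqrt` noise inflation the model applies (making the default configuration
well-specified for calibration checks), 15% of countries with no data,
postpartum-dominant Dirichlet timing splits, suicide counts only in
non-CRVS sources for a minority of countries, and late counts in
CRVS/enquiry sources. A Dirichlet-multinomial truth family is available for
misspecification testing. All randomness flows from one master seed through
named substreams, so generation is byte-identical under a fixed seed.

What the generator does *not* emulate: reporting and publication bias,
ICD miscoding beyond the partial-assignment mechanism, within-country time
trends, and the literature-search process. Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the assumed data
process, not robustness to every pathology of real data.

## Validation study and problem sizes

`matcod.validation.calibration_study` simulates 5 regions × 5 countries with
two ~200-death observations per country (all countries observed), fits, and
pools two independent replicate datasets — 350 country×cause checks — per
master seed. Pooling replicates matters: within one dataset all checks share
a single draw of the hierarchy, so single-dataset coverage is itself highly
variable even under perfect calibration. Two supporting facts established
during development: (i) under full self-consistency (hyperparameters drawn
from the model's own priors) the posterior is calibrated — pooled z-scores
of true country effects have SD ≈ 1.00; (ii) at the generator's fixed
hyperparameters, country-level 80%-interval coverage centres near 0.78,
mildly below nominal, as expected when the truth fixes hyperparameters
rather than drawing them from the prior. Typical results: median MAE on
country proportions ≈ 0.015, pooled coverage ≈ 0.80. These problem sizes
(two datasets, 4×500+500 draws) keep a full validation run around a minute
on a single core while leaving quantile Monte-Carlo error well below the
quantities being checked.

## Numerical choices and degenerate inputs

- Reference cause `other_direct`; results are invariant to this choice
  (verified by refitting with a different reference; medians agree within
  Monte-Carlo error).
- `softmax_complete` subtracts the row maximum before exponentiating;
  non-finite inputs raise.
- Simplex invariants are enforced to 1e-10 on every posterior draw; death
  conservation holds to machine precision (relative 1e-9 asserted).
- Zero-count observations, countries without data, empty subgroup data and
  zero late-death denominators all degrade gracefully (skip/fallback with
  warnings) rather than erroring mid-pipeline.
- CRVS rows overlapping a confidential enquiry for the same country-period
  are dropped by default (`prefer_enquiry="drop"`), or reclassified into the
  least-trusted tier under `"downweight"`.
- Observation eligibility by reference-period midpoint is exposed as a flag
  (`Observation.eligible`), not silent row dropping, for auditability.

## Known limitations

- The ICD mapping is a reconstruction; the mapping file is versioned and
  replaceable precisely so an authoritative code list can be dropped in.
- `Σ` is shared globally; regionally varying cause correlations are not
  modelled.
- The model is time-constant within the window; envelope-driven changes in
  death counts over years are reflected, compositional trends are not.
- Static-trajectory HMC is tuned for this posterior's scale; radically
  larger hierarchies may need longer trajectories (`leapfrog_steps`) or more
  warmup.
- Suicide misclassification (e.g. as accidental injury) is discussed in the
  literature but not modelled; reported suicide proportions are lower
  bounds.
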