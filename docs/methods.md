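# Methods

`censusmrp` estimates all-cause excess mortality from a repeated-census
survey design: one in-person household census (January 2020) followed by
two telephone rounds (May and November 2020) that re-enumerate members and
collect death reports for January 2019 through October 2020 (study months
1–22). Because telephone nonresponse is substantial and plausibly related
to demographics, stratum-level mortality is modeled and then reweighted to
the census composition — multilevel regression and poststratification
(MRP).

## Reference population and cleaning rules

The reference population is the census roster of consenting households,
plus members recorded by telephone who had been overlooked in person, plus
household members who reportedly died in 2019 (and therefore predate the
census), and excluding in-migrants who joined a household after the
census. Death reports are name-keyed; reports are merged into one death
when the normalized name (lower-cased, punctuation stripped) matches
exactly, reported ages differ by ≤ 2 years, and reported death months
differ by ≤ 1 (transitively within a name group). The merged record takes
its identity fields verbatim from a canonical member report (earliest
month, then lowest age, then input order) — taking a real report rather
than an average makes the merge provably idempotent — and the modal cause;
cause disagreements are logged. There is no phonetic matching and no
probabilistic linkage; rows that cannot be attached to a known household
are quarantined, not dropped. Deaths reported only by a household other
than the decedent's own (neighbor reports) are excluded from model inputs.

Exposure is tabulated in person-months over month × 10-year-age-bin ×
sex × household-education cells (22 × 9 × 2 × 3 = 1188). A household is
under observation through April 2020 if it answered only round 1, through
October 2020 if it answered round 2, and not at all otherwise. Age
advances on the census-date anniversary (birth dates are unknown); the
death month counts as a full exposed month so cell deaths never exceed
cell trials. Household education is the band shared by the household
(none / primary / secondary+). Poststratification weights are the January
2020 census shares of the 54 (age bin, sex, education) triples.

## The hierarchical logistic model

Cell deaths are binomial in cell exposure:

```
deaths_c ~ Binomial(exposure_c, p_c)
logit p_c = mu + a_age + a_sex + a_edu + a_moy
            + pairwise interactions (age:sex, age:edu, sex:edu)
            + 1{month >= onset} * (d0 + d_age + d_sex + d_edu)
```

The baseline layer uses month-of-year seasonality (12 levels), not
calendar month; the pandemic-excess layer is a single regime switch from
the onset month (February 2020 by default; May and August are fitted for
sensitivity). Ordered effect vectors — baseline age, month-of-year, and
excess age — carry lag-1 autoregressive priors, `v_k = rho v_{k-1} + z_k`
non-centered with `rho = tanh(r)`, `r ~ N(0,1)` (support (−1,1)) and a
half-normal prior on the innovation scale; the vector is centered for
identifiability against the intercept. Pairwise interactions are
exchangeable with a shared half-normal scale (hierarchical shrinkage).
Default scales on the logit scale: intercept 5, main effects 1, shrunk
terms 0.5 — wide enough that the prior-predictive annualized rate for the
80+ bin spans 150/1000 well inside its central mass. A saturated
1188-parameter cell model is deliberately avoided: at a few hundred
deaths it is unidentifiable, and hierarchical main effects with shrunk
two-way interactions is the standard MRP reading. The excess layer uses
main effects only by default; pairwise excess interactions and a
month-varying excess are available as configuration switches, as are
no-pooling (fixed-scale) and reduced-model variants used by the test
oracles.

Centered fixed-scale categorical effects are parameterized on an
orthonormal basis of the sum-to-zero subspace (k−1 free parameters). The
induced prior on the coefficients is identical to centering an iid
normal draw, but the unidentified mean direction disappears, which
matters for sampler geometry under wide priors.

## Inference

Sampling is Hamiltonian Monte Carlo with analytic gradients (verified
against finite differences in the test suite; a numba-compiled kernel is
asserted equal to the pure-numpy reference path). Warmup interleaves
dual-averaging step-size adaptation (target acceptance 0.8) with diagonal
mass estimation over expanding memory windows; after each mass update the
step size is re-initialized and re-adapted. Trajectory lengths are
jittered uniformly below ~3 integration-time units; a transition with
energy error above 1000 (or a non-finite Hamiltonian) is a divergence and
is rejected. Defaults follow the reference analysis scale — 4 chains,
3000 post-warmup draws each, warmup equal to draws — but every test and
the acceptance script run reduced chains/draws (2×400–500 for replicate
recovery studies; 4×1500 at target acceptance 0.9 for the convergence
contract, the standard setting when occasional divergences appear at the
default 0.8), sized so the whole
default pytest run completes on one CPU in well under half an hour.
Convergence is summarized by split-R̂ and bulk ESS (via arviz) plus the
divergence count; `check_diagnostics` passes only when R̂ ≤ 1.01
everywhere with zero divergences, and flags (rather than raises on)
failures. Chains are initialized with overdispersed jitter with the
intercept started at the pooled empirical logit.

## Poststratification and reporting

For each posterior draw, population monthly mortality over a month window
is the census-weighted sum over strata of the stratum's window-average
death probability; the excess is `100 × (pandemic / comparator − 1)`
computed per draw (ratio of window-average rates, not mean of monthly
ratios) and summarized by quantiles (50% and 95% intervals). The
comparator for a 2020 window is the month-matched 2019 window (February–
October 2020 vs February–October 2019). Age-specific estimates renormalize
weights within each bin; an empty bin is flagged absent rather than
reported as zero. Annualized rates use deaths/population × 12/months ×
1000 throughout. `aggregate_excess_log_odds` reports the census-weighted
mean of the per-cell logit difference between a pandemic month and its
month-matched 2019 counterpart — under a uniform injected effect it
recovers the generator's log odds ratio, which is the estimand of the
effect-recovery tests.

## The synthetic-survey generator

The generator inverts the analysis model and reproduces the survey's
observation process; its defaults are the survey's reported margins:
16,054 households with a size distribution of mean ≈ 5.22 (the both-rounds
ratio 58,806/11,256) and 2.1% single-member households; a young age
pyramid (census mean age ≈ 27 after the adult-head rule, see below);
annual hazards per 10-year bin rising from 0.5/1000 (ages 10–19) to
150/1000 (80+), sex-split ±16%, chosen so the both-rounds crude
annualized rate lands near 5.9/1000; flat month-of-year effects; an
overlook probability of 9.9%, monthly joiner rate 0.0078 per household,
and a 12% duplicate-report rate for decedents aged 50+ (a second,
randomly chosen reached household re-reports the death with the name
reformatted, age ±1, month ±1). Round reach is household-level: a
logistic model on household-head age, sex and education plus a shared
household random effect (SD 1.2), with intercepts calibrated to 91% /
74% / 70% (round 1 / round 2 / both); a household with no living member
at interview time cannot respond — hence a single-member household's
death is never observable. The default pandemic effect is ln(0.92)
(−8% in the death odds) from February 2020, the study's central
estimate; recovery tests override it (0, +0.3 uniform, +0.5 confined to
80+). Annual hazards convert to monthly as `p_m = 1 − (1 − p_y)^(1/12)`;
timing resolution is the calendar month.

The first member drawn for each household comes from the adult (18+)
pyramid and acts as head; this shifts the realized age composition a few
points toward adult bins relative to the raw pyramid, an effect absorbed
in calibration and tested explicitly. The economic module samples 20% of
round-1-reached households (plus a fresh 8% in round 2) and draws
lognormal usual incomes with May/November ratios matching the reported
means for salaried and self-employed earners, and food-unavailability
rates of 24.7% (May) and 8.9% (November).

What the generator does **not** emulate: recall error in reported death
timing (the real survey shows a May-2019 spike attributed to "about a
year ago" rounding, which concentrates reported deaths inside the
comparison windows — synthetic window death counts therefore run ~5–10%
below the reported 289/276), stigma-driven underreporting beyond the
single-member rule, births, out-migration, spatial structure, and
telephone-number mechanics. Passing recovery tests therefore demonstrate
that the pipeline recovers known effects under the design's nonresponse
and reporting structure, not that the model is robust to recall bias.

## Problem sizes used by tests and the acceptance script

Replicate recovery studies run the full ~16k-household population per
replicate (effect sizes are data-limited; smaller populations could not
resolve a 0.3 log-OR within ±0.15) with reduced MCMC as above; unit and
property tests use 300–3000 households. The acceptance script runs one
default-condition pipeline (2 chains × 500 draws) plus May/August onset
refits and reports worked-example statistics recomputed from their
printed inputs.

## Known limitations

Posterior-mean recovery of a uniform excess log-OR is noise-limited by
the ~600 observed deaths (replicate SD ≈ 0.09 around the truth), so a
±0.15 acceptance band on single replicates holds with high but not
certain frequency. Duplicate-report merging keeps the earliest plausible
death month, which can shift a merged death one month earlier. The
exposure denominator treats overlooked members as present from January
2019, per the reference-population definition. The dedup rule is exact on
normalized names; homonyms within a reporting cluster would merge if ages
and months agree.
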