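# Methods

## Scope and model of the system

`liverflux` treats the fasting liver as a single metabolic network at
pseudo-steady state (*S·v* = 0) in each of two physiological windows: an
early post-absorptive window (5–7 h of food deprivation, glycogenolysis
still supplying about half of glucose output) and a late window (10–13 h,
glycogen nearly exhausted, gluconeogenesis and ketogenesis dominant). The
liver's interaction with plasma is represented entirely by exchange
reactions — boundary reactions with a single metabolite; negative flux is
uptake, positive is secretion (COBRA convention). Everything
condition-specific enters through bounds: exchange-rate intervals from
physiological measurements and central-carbon flux intervals from isotope
tracer estimates. Gene regulation is deliberately absent: the scored
contrast is driven by flux constraints, with an optional per-reaction
weight vector as the hook for expression-derived weights (default: all
weights 1).

Strict inequalities in the mathematical statement of the flux constraints
are implemented as non-strict LP bounds; strict versions are not
representable in LP and the distinction has measure zero.

## Production demand and scores

For a metabolite *m* under one condition:

1. **Capability.** cap(*m*) = max secretion flux of *m* subject to
   *S·v* = 0 and the bounds (plain FBA; solved with HiGHS via
   `scipy.optimize.linprog`). If *m* has no secretion-capable exchange, a
   temporary one with bounds (0, 1000) is added for the query. If a
   metabolite has several exchanges, the most permissive (largest upper
   bound, ties by id) is used — a deterministic choice.
2. **Demand.** X(*m*) = min Σ *w*<sub>j</sub>|*v*<sub>j</sub>| subject to
   the same constraints plus secretion ≥ required rate. The absolute value
   is linearized by splitting each flux into nonnegative forward/reverse
   parts; with positive weights the optimum drives one part of each pair to
   zero, so the objective equals the weighted total flux. Variable order is
   fixed, so results are deterministic.

**Required rate.** The required secretion is `v_opt_fraction` (default
0.9) of capability. The default mode (`shared`) uses the *same* target in
both conditions — the fraction of the smaller of the two capabilities — so
the two demands price equal output and the score contrasts *route
economics* (which pathways must carry flux), not output volume. The
alternative `per_condition` mode targets each condition's own capability;
it makes the demand scale with capability, so a metabolite whose cheap
route *opens up* late (e.g. ketone bodies when fatty-acid uptake rises)
would be penalized for its larger late target and score as depressed —
inverting the intended physiological reading. We default to `shared` and
keep `per_condition` available for comparison. The default fraction 0.9
(rather than 1.0) keeps the demand LP off the optimum face of the
capability LP, where solver tolerances make the constraint set fragile;
on the toy network the sentinel signs are insensitive to the fraction.

**Scores.** X_raw = (X_early − X_late)/(X_early + X_late) ∈ [−1, 1];
antisymmetric under swapping conditions. Positive X_raw means production
got cheaper late → predicted plasma increase. Raw scores are z-transformed
(population SD) across all scored metabolites; metabolites with zero
capability or an infeasible demand in either condition are flagged
(`zero_capability` / `infeasible`) and excluded from the z population —
scoring a metabolite the network cannot secrete is meaningless, and
including such rows would corrupt μ and σ for the rest. X_raw at
(0, 0) is undefined and yields the `zero_capability` flag, not a zero
score. If all raw scores coincide (e.g. identical conditions) the
z-transform raises a degenerate-σ error rather than emitting noise.

Numerical tolerances: capabilities below 1e−9 count as zero; steady-state
residuals of returned flux vectors are checked in tests at
≤ 1e−6·max(1, max|v|); demand optimality is verified against brute-force
oracles at 1e−6.

## Condition bounds

`ConditionBounds` carries exchange and central-carbon ("mfa") overrides
separately; applying a condition intersects each override with the model's
declared bounds (tighter wins) and is idempotent. Fractional precursor
contributions to glucose output (glycogen / glycerol / lactate-and-amino-
acids, summing to ~100%) are converted to absolute intervals as
fraction × total output ± a relative tolerance; the total output itself is
always a caller-supplied number in model flux units, since only the
fractions, not absolute fluxes, are tabulated portably. Measured-flux
intervals are applied as given in the bounds TSV (mean ± k·SE upstream;
the interval width is the data preparer's choice, not hard-coded here).

## The toy liver network

The generator builds a 20-metabolite, 35-reaction network: glycogen
phosphorylase, glucose-6-phosphatase, a lumped aldolase/FBPase step with
2:1 triose→hexose stoichiometry (so three-carbon precursor fluxes are
counted in triose units and glucose in hexose units), glycerol kinase,
LDH (reversible), alanine transaminase, pyruvate carboxylase, PEPCK,
PDH, citrate synthase, a lumped TCA oxidation step, β-oxidation,
ketogenesis, two acylcarnitine syntheses, a bile-acid synthesis from
acetyl-CoA, maltose release/synthesis, and a two-ammonia urea stub, plus
14 exchanges.

The two bound sets encode the fasting trajectory: total glucose output
capacity 100 (early) vs 70 (late, the ~30% decline), with precursor
allowances in the published proportions — glycogenolysis capped at 48
(48%) early and 1.61 (2.3%) late, glycerol 15% → 23.4%, lactate 33% → 59%,
amino acids 4% → 15.3% (three-carbon units doubled). The glucose exchange
is forced to at least 70% of capacity (an obligatory systemic supply);
fatty-acid and ammonia allowances rise late (lipolysis, proteolysis).
Uptake allowances are one-sided (0 to cap) rather than forced bands, so
the early precursor mix *emerges* from cost minimization under the caps
rather than being dictated.

Planted truths are constructive, not asserted: each sentinel product has a
cheap route gated by a condition-dependent allowance and an expensive
always-open fallback, so the sign of its demand change follows from
arithmetic on route costs (the table in `synthetic.py`'s docstring gives
the mechanisms). Urea is scored but *not* planted: its nitrogen-supply
signal is small relative to the network's baseline flux and its sign is
not guaranteed by construction. Six sentinels (2 depressed, 4 elevated)
require six mechanistically distinct route pairs, which is why the network
carries ~35 reactions rather than a bare gluconeogenic skeleton.

## Count simulation

Early counts per metabolite are LogNormal(μ_m + δ_s, σ) with μ_m uniform
on [ln 10⁴, ln 10⁶], per-study baseline shifts δ_s ~ N(0, 0.25) standing
in for the different dosing vehicles (they cancel in fold changes), and
σ = 0.3 by default; late counts multiply the location by the planted fold
change. Study sizes default to 8/8/9 animals per time point. Missingness
is left-censoring: values below the study's detection floor (the
`missing_rate` quantile of that study's values, default 10%) are masked —
the mechanism under which minimum-value imputation is the natural fill.
The simulator does not attempt platform artifacts (batch drift,
heteroscedastic ion counts, correlated metabolites), so passing tests
demonstrate correctness of the procedure, not robustness to every failure
mode of real MS data.

## Bootstrap direction calling

Per metabolite: for each replicate and each study with n_s animals, n_s
late and n_s early counts are drawn with replacement (animals differ
between time points, so draws are independent) and ratioed elementwise;
the Σn_s fold values are pooled and averaged — studies thereby weigh in
proportion to their size. B = 10⁵ replicates by default; the 99% CI is the
0.5th–99.5th percentile interval with linear-interpolation (type-7)
percentiles; elevated/depressed requires the whole CI above/below 1, and
a CI touching 1 exactly is "unchanged". Metabolites absent from a study
simply contribute nothing from it; metabolites observed nowhere in scope
are dropped with a record. Each metabolite's random substream derives from
the master seed plus a CRC of its id, so calls are independent of table
order and bit-reproducible.

**Calibration.** The elementwise-ratio estimator targets E[late/early].
For lognormal noise this is e^{σ²} times the median fold change (~1.094 at
σ = 0.3), while the CI half-width at Σn_s = 25 is ≈ 2.58·0.097 ≈ 0.25, so
under the null the bias consumes ~1σ of the margin and the false-call rate
runs at ~5–8% (all elevated calls) instead of the nominal 1%. The
`ratio_of_means` estimator (per-study ratio of resampled means, pooled
with size weights) has bias O(cv²/n) ≈ 1% and stays near nominal (~1–2%
measured). The elementwise reading is kept as the default because it is
the procedure as described; the validation module
(`liverflux.validation.direction_recovery`) measures both, and the test
suite intentionally carries one failing assertion documenting the
default's null miscalibration under the design conditions. Power is a
non-issue: planted 2×/0.5× fold changes are recovered essentially always
under either estimator.

Problem sizes used by the shipped experiments — 40 + 40 planted and 420
null metabolites at B = 10⁴ — were chosen to estimate a ≥95% recovery
and a ~1–8% false-call rate with adequate precision while keeping the
whole validation run in seconds.

## Concordance

Only metabolites with an observed direction (elevated/depressed) and a
score row are compared; calls without a score are reported as unmapped.
A zero score or a flagged status yields "no prediction", counted
discordant by default (conservative; configurable to exclude). Accuracies
are reported as integer percents (and at full precision in machine
output). Significance uses the exact binomial test against p₀ = 0.5:
one-sided ("this accurate or better by chance") for the overall accuracy;
doubled-smaller-tail two-sided for pathway subsets, which at p₀ = 0.5
coincides with the minimum-likelihood definition (cross-checked against
`scipy.stats.binomtest`).

## Pipeline and reproducibility

Stages communicate only through the declared TSV/JSON dialects. `run-all`
validates the config (a seed is mandatory whenever anything stochastic
runs, before any compute), executes constraints → scoring → calling →
concordance, and writes a manifest with the config hash, seed and library
versions but no timestamps — two runs of one config produce byte-identical
outputs. CLI exit codes: 2 validation, 3 infeasibility, 4 I/O.

## Known limitations

- The shared-target demand reading is this package's resolution of an
  ambiguity in the method description; `per_condition` is provided but
  inverts capability-gated signs (see above).
- The toy network omits cofactor balancing (ATP/NAD), lower glycolysis
  below G6P, and compartmentation; it is a scoring test-bed, not a
  physiological model.
- The bootstrap caller inherits the mean-ratio bias discussed above; with
  real data of lower replicate noise the effect shrinks quadratically
  with σ.
- Per-pathway binomial tests on very small subsets (n < 8) have almost no
  power; their p-values are reported for completeness, not inference.
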