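# Methods

This note documents the statistical models behind `pathsig`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that make results reproducible.

## Per-probe spike-and-slab differential expression

Each probe is modeled independently. Let the treatment and control arms
have n_t and n_c log2-scale observations with common residual variance
σ², observed mean difference d, and within-arm sum of squares SS_w on
df_w = n_t + n_c − 2 degrees of freedom. The hypotheses are

* spike: the true mean difference δ = 0, prior weight 1 − ρ;
* slab: δ ~ Normal(0, g·σ²), prior weight ρ;

with σ² ~ scaled-inverse-chi-square(ν₀, s₀²) in both. Because d | δ, σ² ~
Normal(δ, σ²·v) with v = 1/n_t + 1/n_c, and SS_w | σ² ~ σ²·χ²(df_w), the
marginal likelihoods integrate analytically and the Bayes factor is

    BF10 = sqrt(v / (v+g)) · ((d²/v + Q) / (d²/(v+g) + Q))^a,

with Q = SS_w + ν₀·s₀² and a = (1 + df_w + ν₀)/2. Then
π = ρ·BF10 / (ρ·BF10 + 1 − ρ). The reported effect is the conjugate
shrinkage estimate β = d·g/(g+v) — the posterior mean *under the slab*,
not multiplied by π; the projection score applies the π factor separately,
so shrinking β by π as well would double-count the evidence. σ² is
reported as the slab-posterior mean and floored at 10⁻⁶ so the projection
weight β/σ² stays finite for degenerate (zero-variance) probes. The
closed form is verified in the tests against direct numerical integration
of the marginal likelihoods over σ².

Defaults: ρ = 0.01 (roughly a percent of the transcriptome responding, a
conventional sparsity level for acute single-stress experiments), g = 4
(slab standard deviation twice the residual sd — effects worth calling
are comparable to or larger than noise), ν₀ = 3 with s₀² = 0.1 (a weak
prior centered on a typical post-normalization residual variance; with
arms of ≥ 2 replicates the data dominate it quickly). All four are exposed
in `SignaturePrior`.

`fit_signature` pools every sample of the two arms by default; a
`time_point` argument restricts to one stratum. Pooling matches the
generator, in which the treatment effect is constant across time points,
and gives the effective n per arm that makes effect recovery accurate;
per-time-point signatures are available when the response is expected to
evolve.

This is deliberately a per-probe model: it reproduces the (π, β, σ²)
contract of sparse-regression signature fitting without modeling
cross-probe correlation. Numerical agreement with any particular
multivariate implementation is not promised, and probe-level results
should be read as marginal summaries.

## Zero-transformation and fold-change filtering

Zero-transformation subtracts from each non-control sample the mean log2
expression of its matched control samples — per time point when
`match_time` is set — turning absolute expression into log2 ratios
against control. A stratum with no control sample is an error naming the
stratum; silently pooling controls across time would change the meaning
of the ratios.

The fold-change filter keeps probes with |log2 ratio| ≥ log2(f) in at
least m samples. The boundary is inclusive (a ratio of exactly 1.0 counts
as two-fold): the convention matters for reproducibility, so it is fixed
and tested rather than left to floating-point accident. Raising f or m
can only shrink the retained set; this monotonicity is a tested property.

## Hierarchical clustering

Display ordering uses agglomerative clustering with uncentered-correlation
distance (1 minus the cosine similarity of the raw rows) and average
linkage by default — the conventions of the classic microarray clustering
tools, where the uncentered variant respects the zero point of log2
ratios. Pearson (1 − r) and Euclidean distances and complete/single
linkage are selectable. Rows for which a correlation is undefined (zero
norm or zero variance) are assigned the maximal correlation distance 2.0
to every other row instead of crashing. Distance matrices are computed
in-package; the agglomeration itself is scipy's nearest-neighbor-chain
implementation, which is deterministic for a fixed input (exact distance
ties are resolved by scipy's internal order, not by a lowest-index rule).
Results can be exported as CDT + GTR files readable by Java TreeView,
writing 1 − height as the node similarity.

## Signature projection

The score of signature k in sample i is
s_ki = Σ_g π_gk · (β_gk/σ²_g) · x̃_gi over the signature probes present
in the cohort. Choices worth stating:

* **Weight form.** The precision weight β/σ² is the default: it is the
  natural regression-coefficient weighting when residual variances are
  heterogeneous, and it downweights noisy probes. β/σ is available via
  `weight="scale"` for sensitivity analyses.
* **Centering.** Cohort-mean centering is on by default. Without it the
  score carries an arbitrary offset Σ w_g·mean_g that depends on probe
  baselines, while the score is meaningful only as a relative quantity
  within a cohort. With centering, adding any constant to a probe's row
  leaves all scores unchanged (a tested invariant). Scores are therefore
  not comparable across cohorts.
* **Missing probes** are dropped with a logged count, never imputed;
  cross-platform probe matching is out of scope.

Score units are arbitrary (a weighted sum of log2 ratios); only ordering
and relative spacing matter, which is why the survival interface
dichotomizes by threshold and the continuous Cox coefficient on raw
scores is scale-dependent.

## Discordance screen

d_g = π_g,a · π_g,b · [sign(β_g,a) ≠ sign(β_g,b)] is the joint probability
of differential expression in both treatments under independence, counted
only for opposite directions — the minimal statistic respecting both
"significant" and "opposite". Probes with β = 0 in either signature have
no direction and are treated as concordant. Selection keeps the top
`top_frac` of shared probes with d > 0; probes tied exactly at the
quantile boundary are all included, so the selection cannot depend on
input order (with continuous π the tie case has measure zero, but the
rule matters for degenerate inputs). Swapping the two signatures yields
the same set with directions flipped, a tested symmetry.

## Survival analysis

**Kaplan-Meier.** Standard product-limit estimator; censored-only times
reduce the at-risk count without stepping the curve.

**Area between curves.** ∫|S₁ − S₂| computed exactly on the merged step
grid. The default horizon is the smaller of the two groups' largest
observed times, with each curve carried flat to that point: a curve is
never extrapolated beyond its own data, and without this cap a small
all-censored group (S ≡ 1 over a long follow-up) would accumulate
unbounded area against any event-bearing group.

**Optimal stratification.** Candidate thresholds are all midpoints
between consecutive distinct scores; splits leaving either group below
`min_group_frac` (default 0.1) of the cohort are inadmissible, because an
unconstrained scan degenerates toward single-sample groups. Ties in area
break toward the lower threshold for determinism. The result carries two
Cox fits: the binary high/low indicator (whose p-value inherits the
optimism of the optimized cutpoint — it is reported because it describes
the displayed curves, not because it is calibrated) and the continuous
score, whose p-value is uniform under the null (verified by simulation
with a KS test in the acceptance suite).

**Cox fit.** Single-covariate partial likelihood with Breslow handling of
tied event times, maximized by Newton's method with step halving;
convergence when the log-likelihood changes by < 10⁻⁹, at most 50
iterations. Breslow ties keep the risk-set sums as plain reverse
cumulative sums; at the cohort sizes and tie rates this package targets
the difference from Efron weighting is negligible. The covariate is
centered internally for numerical stability (this does not change the
coefficient). A monotone partial likelihood — perfect separation of event
order by the covariate, as happens when the earliest event carries all
the covariate mass — has no finite maximizer; the fit is then flagged
`diverged` with the coefficient capped at ±15. Standard errors are the
inverse square root of the observed information; p-values are Wald. The
implementation is cross-checked in the tests against a naive O(n²)
partial-likelihood maximizer and against lifelines.

## Synthetic data: what it emulates, what it does not

`simulate_invitro` draws per-probe baselines Normal(7, 1.5²) on the log2
scale (the typical post-normalization range; only the scale matters since
every downstream quantity is a difference), marks a fraction `frac_de`
(default 0.1) of probes as truly differential with effects of random sign
and magnitude uniform on [0.5·effect_scale, effect_scale] (default
effect_scale 2, i.e. two- to four-fold changes), and gives each probe a
residual variance drawn scaled-inverse-chi-square with scale
`noise_scale²` (default 0.5² — replicate noise well below typical
effects) and 8 degrees of freedom, producing the variance heterogeneity
the precision weights exist for. The default design is two arms ×
triplicates × four time points, with the treatment effect constant over
time. Residuals are i.i.d. normal.

`simulate_cohort` embeds a latent activity a_i ~ Normal(0, activity_sd²)
as x_gi = m_g + a_i·π_g·β_g + ε_gi with i.i.d. noise (default sd 0.3);
`simulate_survival` draws exponential event times with rate
base_rate·exp(log_hr·a_i) (default base rate 0.1 per time unit) and
independent exponential censoring (default rate 0.02, ≈ 20% censoring at
these settings).

Not emulated: probe-level intensity effects and normalization artifacts,
batch and array effects, cross-probe correlation, time-varying treatment
effects, non-proportional hazards, informative censoring, and any real
probe-to-gene structure. Passing tests therefore demonstrate that the
estimators recover the model they assume at realistic sizes and noise
levels — not that real cohorts satisfy those assumptions.

All generators run every draw from a single integer seed
(`numpy.random.default_rng`), and the pipeline derives per-stage sub-seeds
from its one global seed via `SeedSequence.spawn`, so identical configs
reproduce outputs bit-identically. An optional `truth` argument to
`simulate_invitro` re-uses a ground-truth table across runs, which is how
the tests build replicate experiments of one underlying response and
treatment pairs with exactly opposite effects.

## Problem sizes used in tests and the acceptance script

Recovery and calibration checks run at desk scale, chosen to keep each
claim statistically meaningful: 2000-probe experiments with 5 replicates
per arm for differential-expression ranking (AUC) and effect recovery;
100-tumor cohorts for projection fidelity; n = 200 with 100 replicates
for Cox log-hazard recovery; 200 simulations of n = 100 for null p-value
calibration; 1000 probes with 2% opposite-direction truth for the
discordance screen. The acceptance script averages small numbers of
replicates (5) for the heavier simulation stages; all its randomness
descends from the `--seed` argument.

## Known limitations

* The signature model is marginal per probe; correlated probes make the
  π values overconfident as joint statements.
* β is conditionally unbiased only under the slab; at small effective n
  the g/(g+v) shrinkage biases |β| downward by a factor v/(g+v).
* The optimized-cutpoint group p-value is anti-conservative by
  construction; use the continuous-score p for inference.
* Exponential event and censoring times satisfy proportional hazards by
  construction; the Cox recovery results say nothing about model
  misspecification.
* Scores are cohort-relative; comparing scores across cohorts or
  platforms requires harmonization that this package does not attempt.
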