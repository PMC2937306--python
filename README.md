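# pathsig

Tumor-microenvironment stresses — lactic acidosis, glucose deprivation,
hypoxia — leave transcriptional fingerprints that can be read back out of
patient tumor expression data. `pathsig` is a Python package for the
statistical machinery behind that read-out: it estimates in-vitro
gene-expression signatures from treatment-vs-control microarray
experiments, projects them onto tumor cohorts as per-sample
pathway-activity scores, screens pairs of signatures for genes regulated in
opposite directions by two stresses, and links activity scores to patient
survival through optimal Kaplan-Meier stratification and Cox
proportional-hazards models. It is aimed at computational biologists who
want a tested, reproducible reimplementation of this signature-projection
workflow, exercised end to end on synthetic data with the statistical
structure the analysis assumes.

## The model

**Signature estimation.** For each probe g, a conjugate spike-and-slab
model of the treatment-vs-control mean difference yields three quantities:
π<sub>g</sub>, the posterior probability of differential expression;
β<sub>g</sub>, the log2 effect (posterior mean under the slab); and
σ²<sub>g</sub>, the pooled residual variance. The slab is
Normal(0, g·σ²) with prior weight ρ and a scaled-inverse-chi-square prior
on σ², so the Bayes factor is closed-form.

**Projection.** The activity of signature k in tumor i is the weighted
inner product

&nbsp;&nbsp;&nbsp;&nbsp;s<sub>ki</sub> = Σ<sub>g</sub> π<sub>gk</sub> ·
(β<sub>gk</sub> / σ²<sub>g</sub>) · x̃<sub>gi</sub>,

where x̃<sub>gi</sub> is the tumor's log2 expression of probe g, centered
at the cohort mean. High scores mean the tumor's expression recapitulates
the in-vitro response; strongly reversed patterns score negative.

**Discordance screen.** For two signatures a, b the statistic
d<sub>g</sub> = π<sub>g,a</sub>·π<sub>g,b</sub>·[sign(β<sub>g,a</sub>) ≠
sign(β<sub>g,b</sub>)] ranks probes by the joint probability of being
regulated in *opposite* directions; the top fraction (e.g. 1%) is selected.

**Survival.** Scores are dichotomized at the threshold that maximizes the
area between the two groups' Kaplan-Meier curves, ∫|S₁(t) − S₂(t)|dt on
the merged step grid; significance comes from a Cox proportional-hazards
fit (partial likelihood maximized by Newton's method, Breslow ties),
reported both for the binary group indicator and for the continuous score.

A synthetic-data module generates two-arm expression experiments with
sparse true effects, tumor cohorts carrying a latent per-sample pathway
activity, and exponential survival times whose log-hazard is linear in
that activity — so every recovery claim in the test suite is checked
against known ground truth.

## Worked example

The bundled demo config simulates a 500-probe experiment (10% truly
differential probes, triplicates at two time points), fits the signature,
projects it onto a simulated 120-tumor cohort in which high pathway
activity is protective (log hazard ratio −1), and stratifies:

```bash
$ pathsig run --seed 11 --out-dir demo_run
pipeline done in 0.2s; threshold 295.9, area 18.39, group Cox p 0.00126, score Cox p 6.93e-13
```

Reading the numbers: the optimal split puts the 15 highest-scoring tumors
(scores above 295.9) in the high-activity group; the area between the two
Kaplan-Meier curves over the shared follow-up window is 18.39 time units;
the binary high-vs-low Cox fit gives p = 0.00126 (note this p follows an
optimized cutpoint and carries selection optimism), while the continuous
score — the calibrated test — gives p = 6.9e-13, with a negative
coefficient: higher predicted pathway activity, better survival.
`demo_run/` contains every intermediate artifact (expression, log2 ratios,
fitted signature, scores, survival table, stratification JSON) plus the
resolved config and a run report with file digests; rerunning with the
same seed reproduces all of them byte for byte.

The same stages are available piecewise (`pathsig simulate invitro`,
`zero-transform`, `filter`, `cluster`, `fit-signature`, `project`,
`discordance`, `stratify`, `km`) and as library functions
(`pathsig.fit_signature`, `pathsig.project_signature`, ...).

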