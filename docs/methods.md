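# Methods

`dynanet` analyses longitudinal panels of inflammatory mediators
(cytokines, chemokines, DAMPs) measured repeatedly in small cohorts or
culture experiments — e.g. a serum panel sampled daily in pediatric acute
liver failure (PALF) outcome subgroups, or hepatocyte supernatants sampled
over 1–48 h.  Three inferential layers are implemented, plus a generative
model used to validate all of them against known ground truth.

## Dynamic network analysis (DyNA)

For each pair of consecutive sampling times (d0–d1, d1–d2, …) and each
subgroup, the Pearson correlation of every mediator pair is computed over
the window's samples, and an undirected edge is drawn when
|r| ≥ threshold (default 0.85, **inclusive**; the sign of r is retained —
"parallel" vs "anti-parallel" trajectories).  Per interval, network
complexity is

    (N₁ + N₂ + … + Nₙ) / (n − 1)  =  2·E / (n − 1),

where Nᵢ is the degree of mediator i, E the edge count, and n the size of
the analysed panel *including unconnected mediators*.  The total number
of connections is E summed over all intervals.

Windowing admits two readings, both provided:

* `levels` (default) — the samples at the two boundary times are pooled
  across subjects; each (subject, time) sample is one observation.
* `differences` — per-subject changes across the interval are correlated,
  requiring both boundary samples.

Missing values are handled by pairwise deletion: each pair uses its own
complete observations.  A pair with fewer than `min_pairs` (default 4)
complete pairs, or with a zero-variance member, is *undefined* — it never
forms an edge and is reported with a reason, rather than treated as "no
correlation".  Zero-variance mediators still count in n for complexity:
they are part of the analysed panel.  Correlations are computed on
measured concentrations (not transformed), matching the edge rule's
definition on raw trajectories.

## Dynamic Bayesian network inference (DyBN)

A first-order DBN over the panel: the value of mediator i at time t+1 is
Gaussian given a parent set Pa(i) of mediator values at time t (fan-in ≤ 3
by default).  Self-loops (i ∈ Pa(i)) encode self-feedback.  Preprocessing
takes natural logs (concentrations are right-skewed) and z-scores each
mediator within the subgroup; subjects are treated as i.i.d. realizations
and their strict-consecutive transitions pooled — a gap in a subject's
series breaks the chain rather than bridging it.  Unequal grid spacing
(e.g. 6→24 h) is treated as one step and flagged in metadata.

### Scoring

Families are scored with the BGe marginal likelihood under a
Normal–Wishart prior: for a data block Y (N rows, d columns),

    p(Y) = π^(−Nd/2) · (α_μ/(α_μ+N))^(d/2) · |T₀|^(ν/2)/|T_N|^((ν+N)/2)
           · Γ_d((ν+N)/2)/Γ_d(ν/2),

with T_N = T₀ + S + (α_μN/(α_μ+N))·ȳȳᵀ (S the centered scatter) and the
family score log p(child ∪ parents) − log p(parents).  Defaults on
z-scored data: α_μ = 1, T₀ = 0.5·I, and ν = d + 2 for a block of size d.
With a scalar-diagonal T₀ this size-based degrees-of-freedom rule makes
the decomposition telescope, so Markov-equivalent structures receive
exactly equal scores (verified to 1e−10 in the tests, and the closed form
is verified against numerical Normal–Wishart integration).  All
hyperparameters are serialized with every result.

### Changepoints

The model is inhomogeneous: each node may have up to `k_max` (default 1)
changepoints at which the Gaussian parameters — not the structure — are
re-estimated per segment.  Segments must span at least 2 time steps; the
changepoint count has a truncated Poisson(λ=1) prior with positions
uniform over admissible configurations.  Short series (5–8 time points)
cannot support more segmentation, hence the conservative default.

### Sampling

Metropolis–Hastings over (parent set, changepoint vector) with
add/remove/swap parent and birth/death/relocate changepoint moves,
proposals uniform over the current neighbourhood with exact Hastings
correction.  Because a lag-1 DBN needs no acyclicity constraint, the
posterior factorises over children and the chain is run per child (the
identical kernel restricted to its independent component); this makes
exhaustive enumeration feasible for small panels and is used as the
sampler's oracle in tests.  Edge posteriors are sample frequencies; the
consensus graph keeps directed edges with posterior ≥ 0.5 (configurable);
self-feedback nodes have a surviving self-loop, and those with at least
one additional connection are labelled *central*.  Samplers are
deterministic given a seed; with `k_max = 0` the model reduces exactly to
a homogeneous first-order DBN.

A caveat surfaced by the synthetic studies: persistent between-subject
level differences (random intercepts) induce lag-1 autocorrelation after
pooling, which the model reads as self-feedback.  Self-loops should
therefore be interpreted as "history predicts the present within the
subgroup", which includes stable individual set-points, not only
dynamical feedback.

## Biomarker statistics

* **Mann-Whitney rank-sum** (two-sided, midranks): exact p when the
  smaller group has ≤ 8 observations and no ties occur, otherwise normal
  approximation with tie correction (scipy backend; enumeration oracle in
  the tests).
* **Spearman** rho = Pearson on midranks; exact permutation p for n ≤ 10
  (full n! enumeration), t-approximation above.  Used for mediator-vs-age
  screens when the dataset carries a per-subject age covariate.
* **ROC/AUC**: trapezoid AUC, equal to the normalized Mann-Whitney U
  (ties ½); orientation auto-chosen so AUC ≥ 0.5 and recorded; the optimal
  cutoff maximizes Youden's J with ties resolved to the lowest cutoff.
  Samples from all time points are pooled per subject group — flagged in
  the output as pseudo-replication, since repeated measures of one
  subject are not independent.
* **Volcano**: per-mediator fold change as the ratio of geometric means
  (appropriate for lognormal-like concentrations) over all pooled
  positive values, p from the rank-sum test on the same pooling; classes
  `up` (FC ≥ 2.0, inclusive, and p < 0.05) and `down` (FC ≤ 0.5 and
  p < 0.05); no multiple-testing correction, matching the screening
  character of the analysis.

## Synthetic data generator

The generator emulates the two study designs as presets and arbitrary
designs via `SyntheticSpec`.  Latent log-scale dynamics per subject:

    x[t+1,i] = a_i(t)·x[t,i] + Σ_j b_ij·x[t,j] + ε,  ε ~ N(0, s_ar²)

with per-mediator AR self-coefficients a_i (switchable at a changepoint),
directed couplings b, and stationary initialization.  Observations are
exp(baseline + log fold-change + age term + subject offset + x + channel
+ noise): positive and right-skewed, with multiplicative subgroup
effects to align with fold-change analyses, subject-level random
intercepts (baseline_log_sd), measurement noise, and
missing-completely-at-random dropout.

Interval-local correlations are planted through latent *channels*: a
mediator involved in any planted edge exchanges a fixed share of its
variance for a channel present at all time points, and the channels of a
planted pair are cross-correlated only at the two boundary times of the
target interval.  Marginal variances therefore stay flat over time,
nothing leaks into neighbouring windows, and the within-window
observed-scale Pearson correlation equals the target exactly in
population.  Because the observed scale is lognormal, the requested
correlation is first converted to a latent correlation by inverting the
lognormal moment formula; targets outside the attainable range (strong
negative correlations under wide noise are impossible for lognormal
variables) raise an infeasibility error before sampling, as do non-PSD
structures such as an r=0.95 hub with mutually uncorrelated leaves (plant
cliques instead).  Re-using a mediator in adjacent intervals is warned
about: the shared boundary time cannot carry both correlation patterns.

Preset study conditions:

* `palf_preset` — 28-mediator human serum panel, subgroups S (n=14) and
  NS (n=7), times d0–d7; GDF-15 ×4 and IL-6 ×2.5 up, MIG ×0.4 down in NS;
  HMGB1 high baseline in both; AR(0.7) self-feedback on HMGB1 and GDF-15;
  12 planted r=0.95 pair-windows in NS vs 5 in S; an HMGB1→MIG→GDF-15
  coupling chain only in S; mild negative age trends on two mediators;
  3% missingness.
* `hepatocyte_preset` — 23-mediator mouse panel, genotype × treatment
  arms (3–5 cultures), times 1, 3, 6, 24, 48 h; near-zero HMGB1 and
  attenuated GDF-15 in knockout arms; densest planted structure in
  WT+APAP.

Effect sizes are stylized order-of-magnitude choices (tagged as such in
the spec metadata), not fits to any published concentration ranges: the
cohort's true covariance is not recoverable from published figures.  What
passing tests show is that the *methods* recover known structure under
realistic panel shapes, noise and missingness — not that the synthetic
data reproduce any particular biological cohort; features of real data
deliberately not modelled include assay censoring floors/ceilings,
informative dropout (sicker patients die or are discharged), and
non-stationary population drift.

## Numerical and design choices

* Pearson thresholding uses exact inclusive comparison; no fuzz is added
  at the threshold.
* BGe computations use `slogdet`; a non-positive-definite posterior scale
  raises with a condition-number report rather than returning garbage.
* The MCMC proposal is neighbourhood-uniform with the |N(s)|/|N(s′)|
  Hastings factor, so detailed balance holds exactly on the discrete
  space; structure and changepoint move classes are chosen with equal
  probability when both exist.
* Ties at the Youden maximum resolve to the lowest cutoff; ROC
  orientation is recorded rather than silent.
* Degenerate inputs (empty subgroups, constant mediators, too-few
  complete pairs, single-class ROC labels) raise typed errors or are
  excluded with explicit reasons — never silently dropped.
* Default problem sizes in the validation suite (e.g. 50k MCMC iterations
  for the 3-node enumeration comparison, 10k for 5-node recovery, 100
  replicates for network-recovery rates) were chosen as the smallest runs
  that give stable Monte-Carlo estimates for these checks.

## Known limitations

* DyNA pools boundary-time samples by default; whether pooled levels or
  per-subject trajectories are the "right" reading is data-dependent, so
  both modes exist and outputs record which was used.
* With n=7 subjects a window holds 14 samples; near-threshold null
  correlations then cross 0.85 occasionally.  This small-sample noise is
  inherent to the thresholding method, visible in the synthetic runs, and
  the reason complexity contrasts rather than single edges are the robust
  readout.
* DyBN edge posteriors on 28 mediators from ~50–100 pooled transitions
  are diffuse; the consensus graph at 0.5 should be read as a screen, not
  a confirmed circuit.  Arrows carry no sign.
* The exact-permutation Spearman p enumerates n! orderings and is only
  engaged for n ≤ 10.
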