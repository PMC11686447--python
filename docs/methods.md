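# Methods

This note documents the models and procedures implemented in `glygolgi`,
the parameter choices that matter, and what the synthetic data do and do
not emulate.

## The glycan processing model

Each N-glycan is a composition vector `(man, agn, fuc, gal, sia)` —
mannoses (3–9), antenna GlcNAcs (0–4), core fucose (0/1), galactoses
(≤ agn) and sialic acids (≤ gal) — plus a boolean *lock* flag.  Branch
isomers are merged: this matches the resolution of capillary-
electrophoresis glycan profiling, which distinguishes compositions, not
arm positions.  Nine enzyme rules define the canonical pathway:

| enzyme | guard | effect |
|---|---|---|
| Man1 | man > 5, agn = 0 | man − 1 |
| Mgat1 | man = 5, agn = 0 | agn + 1 |
| Man2 | man = 5, agn = 1 | man → 3 (two trims collapsed) |
| Fut8 | agn ≥ 1, fuc = 0, gal = 0 | engage lock |
| Mgat2 | man = 3, agn = 1 | agn + 1 |
| Mgat4 | man = 3, agn = 2 | agn + 1 |
| Mgat5 | man = 3, agn = 3 | agn + 1 |
| GalT | agn ≥ 2, gal < agn | gal + 1 |
| SiaT | sia < gal | sia + 1 |

Man2's two sequential trims are one rule because no measured species lies
between them.  Fut8 requires an agalactosylated substrate — encoding that
galactosylation blocks subsequent core fucosylation, the converse of the
fucosylation/galactosylation competition.  Core fucosylation is modelled
as a two-step process: a Fut8 firing *locks* the glycan (no other enzyme
can act), and a separate exponential lock-resolution step at rate
`lock_resolution_rate` (default 8, dimensionless) completes the transfer.
This decouples Fut8's slow effective rate from the shared activity scale;
the cost is that locked glycans can be carried through cisternae
unprocessed.  A lock still engaged after the last cisterna is
force-resolved so no glycan is lost.  Hybrid/bisecting structures (Mgat3)
and O-glycan/glycolipid competition are out of model scope.

The reachable state space from Man9 under these rules has 76 states
(including locked intermediates) and is acyclic.

## The cisternal simulator

Glycans transit K cisternae in order (default K = 4, the classical
cis/medial/trans/TGN decomposition) and are simulated independently — no
inter-glycan competition for enzymes or donors, which real cells do have;
this is a stated limitation, not an approximation we quantify.  Within a
cisterna a glycan is a continuous-time Markov jump process whose
propensities are the per-enzyme, per-cisterna activities; residence time
per cisterna is fixed (default 1; activities and times are identifiable
only as products, so time is dimensionless and residence is pinned to 1
during fitting).  Exit at the residence deadline is exact by
memorylessness: the interrupted waiting time is simply redrawn in the next
cisterna.

Two samplers implement the identical process: a per-glycan reference
implementation in Python and a compiled (numba) kernel used for
production runs; tests compare their output distributions.  Because the
state space is finite and small, the exact terminal distribution is also
available as the product of per-cisterna matrix exponentials
(`ctmc_reference`); the stochastic samplers are validated against it to
total-variation distance ≈ sampling noise.  Default profile size is the
production setting of 10,000 glycans.

Flux localization of an enzyme is the normalized vector of its firing
counts per cisterna — the readout used to talk about *where* in the Golgi
an enzyme acts, as opposed to how much.

## ABC-MCMC fitting

The likelihood is intractable, so enzyme activities are inferred by
approximate Bayesian computation inside a Metropolis random walk: propose
activities, simulate a profile, accept only if the squared-difference
summary statistic Σ(sim − obs)² is within a tolerance ε.  The quadratic
statistic weighs all species symmetrically; dominant species carry most of
its value simply because large fractions admit large absolute errors.

Choices the original workflow leaves open, and what we settled on:

* **Parameterization.**  Default one activity per enzyme, uniform across
  cisternae (9 parameters); a free 9 × K mode exists
  (`param_mode="enzyme_cisterna"`) but is substantially harder to
  identify from a single profile.
* **Prior.**  Independent log-uniform on [0.1, 10].  Two decades centered
  on 1 covers every plausible activity fold-change; a wider scale-free
  prior leaves the posterior medians of weakly-informed activities
  dominated by prior wander at feasible chain lengths, which corrupts
  between-condition median comparisons.
* **Tolerance.**  ε starts at the 20th percentile of a 200-draw
  prior-predictive pilot and is annealed during burn-in (every 25 steps,
  ε ← max(floor, min(ε, 1.1 × current distance))) down to a floor of
  5 × the multinomial noise of the statistic, 2/n·(1 − Σp²), then frozen.
  A fixed pilot-quantile tolerance accepts essentially the whole prior.
* **Proposal.**  Gaussian random walk on log-activities with
  Haario-style adaptive covariance (empirical covariance of the chain
  history, scaled 2.38²/d, plus a nugget), adapted during burn-in only
  and frozen afterwards; a global step-size factor is tuned toward an
  acceptance rate in [0.1, 0.4] during burn-in.
* **Stochastic likelihood.**  One fresh simulation per proposal
  (pseudo-marginal style); each retained sample stores the seed of its
  accepted simulation, so recorded distances are exactly reproducible.
* **Chains.**  Default 4 parallel chains (the original study's 30-chain
  HPC setting is a config value), initialized over-dispersed from the
  best pilot draws, seeds spawned from one master seed.  50% burn-in,
  thinning 10.

Convergence is monitored with the classic Gelman–Rubin potential scale
reduction factor computed on log-activities; cluster-versus-cluster
comparisons exclude parameters with R̂ > 1.2 from significance claims.
Posterior shifts are scored per parameter by the posterior-median
log-ratio and a Mann–Whitney U test on pooled thinned samples (exact
enumeration below n, m ≤ 8, tie-corrected normal approximation above),
with Benjamini–Hochberg adjustment across parameters.

**Identifiability.**  A parameter is only as estimable as its fingerprint
on the profile.  Under a production-like G0F-dominant baseline, trimming
and branching enzymes are "fast enough" — the profile constrains them
only from below, their posteriors are one-sided ridges, and ratios of
their medians between two fits are noise.  Parameter-recovery experiments
therefore use `abc_recovery_parameters()`, a baseline in which every
enzyme is rate-limiting and every processing stage leaves visible
intermediates, so all nine activities have two-sided constraints.  This
is a property of the experiment design, not of the fitting code.

## Glycan-profile clustering

Profiles are clustered on raw fractions (a CLR option exists for
compositional treatment) after averaging duplicate measurements per
sample.  PCA is centered, unscaled by default, SVD-based.  k-means is
Lloyd's algorithm with k-means++ initialization, best of 10 restarts;
the elbow curve warm-starts each k from the previous centroids plus the
worst-fitted sample, which makes WCSS provably non-increasing in k.  The
cluster count is the largest relative WCSS drop, overridable by the user.

## Multiblock sparse PLS-DA

Expression preprocessing is log2(count + 1), then per-gene
centering/unit-scaling estimated on training folds only.  The 76-gene
N-glycosylation panel ships as an editable text resource
(`data/nglycogenes.txt`) covering LLO assembly, OST, ER lectins, Golgi
mannosidases, branching, fucosylation, galactosylation, sialylation and
nucleotide-sugar supply.

The multiblock sparse discriminant model follows the sGCCA/DIABLO
formulation: per component, block loading vectors are estimated by power
iterations on design-weighted cross-covariances (each block's update
target is the class-indicator score plus design-weighted scores of
connected blocks), with sparsity by hard-thresholding to the keepX
largest weights and renormalization; blocks deflate on their own scores.
Prediction projects test samples through the stored loadings/deflation
vectors and assigns the nearest class centroid in averaged-score space;
per-block scores support per-block AUC.  It is validated behaviourally
(separable fixtures, permutation nulls, planted-marker recovery), not by
numeric identity to any existing implementation.

The **design matrix** weight for a block pair is 1 when the pair's
first-sPLS-component score correlation reaches 0.8, else 0.1.  The
correlation is estimated **out-of-sample** (5-fold: loadings fit on
training splits, scores correlated on held-out samples): with more
features than samples, in-sample sPLS score correlations approach 1 even
between independent blocks, which would wrongly couple all blocks.

**Cross-validation and stability.**  Folds are stratified by class, and
duplicate measurements of one sample never straddle a train/test split.
A gene is *predictive* when selected in ≥ 7 of 10 folds.  Because
consecutive folds share ~90% of their training data, a deterministic
selector re-selects the same spuriously label-correlated genes in every
fold, making "stability" vacuous on null data.  Two safeguards give
selection frequency its intended meaning:

* per-fold randomised ranking weights (each gene's |weight| is
  multiplied by a U[0.5, 1] draw before thresholding, in the spirit of
  randomised/stability selection) — model selection is only reproducible
  when a gene's signal clearly dominates;
* an association screen: per fold, each panel gene is tested for a
  one-vs-rest class contrast of its training-fold log2 expression, with
  duplicate measurements averaged to the biological sample first (the
  sample, not the measurement, is the unit of evidence) and per-gene
  variances shrunk toward the panel median (moderated t, prior weight
  10) to stabilise the denominator at ~8 samples per class.  The
  per-gene p cutoff is 0.003, balancing power for a 2-fold marker
  against the 76-gene multiplicity.

A stable gene must clear ≥ 7/10 folds on *both* counts — model
selection and screen — counted separately, so two moderate per-fold
probabilities do not compound into a vanishing joint one.  Neither
safeguard alters the fitted models, predictions or AUCs.  Measured
operating point on the three-cluster preset (10 generator seeds,
keepX = 8): planted-marker sensitivity 0.9 with 0.1 false positives per
run at day 0; sample-level label permutation yields on average 0.8
stable genes and mean AUC 0.54.

AUC is the rank-based (Mann–Whitney) one-vs-rest formulation with
midrank ties, identical to trapezoidal ROC integration.  Pooled
cross-validated class scores are centered per sample before computing
AUC, removing fold-to-fold offsets of distance-based scores.
Hyperparameters (components, keepX) can be tuned by nested 10-fold CV
over a grid with a one-standard-error preference for sparser models; the
component default is the discriminant convention of classes − 1.

## Synthetic data

The generator emulates the *structure* of a confidential two-project CHO
study — it is not a simulation of any real dataset, and its centroids are
stylized, not digitized from figures.

* **Profiles.**  Project A: 26 samples, two clusters (Man5-dominant vs
  G0F-dominant, equal weight).  Project B: 27 samples, three clusters
  (G0 / G0F / G1F dominant; weights 0.35/0.35/0.30).  53 samples total,
  each measured twice.  A sample draws its cluster, then a sample-mean
  profile from a Dirichlet centered on the cluster centroid
  (concentration 300 — tight, well-separated clusters); replicates add
  Dirichlet noise at concentration 3000 around the sample mean.  The
  true within-sample replicate variance of the instrument is unknowable
  from published information; 3000 is a conservative default knob.
* **Expression.**  Per day (0/6/10), counts for the 76 panel genes plus
  124 background genes over every duplicate measurement (53 samples × 2
  = 106 rows per block).  Noise is hierarchical gamma–Poisson: the gamma
  factor (dispersion 0.1) is drawn once per sample per gene — biological
  variability shared by its duplicates — and each measurement adds
  independent Poisson counting noise.  Baseline log2 means are uniform
  on [3, 9].  Planted
  markers (project A: Alg5 up in the Man5 cluster; Man2a1 and Man1c1 up
  in G0F; project B: Alg5/Alg8 up in G0, Alg11/Dpm1 up in G0F,
  Slc35a2 (the UDP-Gal transporter) and St3gal1 up in G1F) are shifted
  by 1 log2 unit (2-fold) at day 0 in their cluster only.  Marker genes
  draw baselines from [6, 9]: a 2-fold shift on a near-silent gene is
  undetectable at this sample size regardless of method, and the
  emulated markers stand for genes whose differential expression was
  measurable.  An optional equicorrelated log-normal latent factor per
  sample provides an inter-gene-correlation knob (default off) for
  exploring collinearity effects on classifier performance.
* **ABC targets.**  `make_abc_target` applies per-enzyme fold-changes to
  a baseline parameter set and simulates the "observed" profile,
  returning the ground truth for recovery scoring.

What passing tests on these data do **not** show: robustness to
compositional measurement bias, batch effects, library-size variation,
realistic transcriptome-wide co-expression, or any guarantee about the
real study's genes — the generator plants clean effects in clean noise.

## Problem sizes and numerical choices

Defaults used by the test suite and the acceptance script (chosen as
desk-scale analysis settings):

* simulator validation at n = 10,000 glycans (the production profile
  size); TV tolerance 0.02 against the matrix-exponential solution on
  small networks;
* ABC fits at 4 chains × 1,500–2,000 steps, 3,000 glycans per proposal,
  150 pilot draws; the original 30-chain configuration remains available
  in `AbcConfig`;
* null-control cluster comparisons at 4 × 600 steps, 2,000 glycans;
* cross-validation at 10 folds, keepX = 8, components = classes − 1.

Ties in k-means restarts resolve by lowest WCSS; sPLS power iterations
converge at 1e-6 or stop at 500 iterations with a warning; profile rows
off unity by > 1e-3 on input are renormalized with a logged warning,
beyond validation tolerance they are rejected.  Degenerate cases (empty
clusters, zero within-chain variance, single-class AUC, zero enzyme flux)
raise or warn explicitly rather than returning silent defaults.

## Known limitations

* Independent glycans: no competition for enzymes, donors or transport.
* Fixed residence times; no vesicular recycling or stochastic exit.
* The enzyme-level ABC parameterization cannot express localization
  shifts (the 9 × K mode can, but is weakly identified from one
  profile); flux localization is read from firing counts instead.
* The sparse multiblock implementation reproduces the published
  algorithmic idea, not any package's numerical output.
* Synthetic data are structurally, not biologically, faithful.
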