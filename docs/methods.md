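# Methods

## The model

`dynomics` learns **two-time-slice dynamic Bayesian networks (2TBNs)** from
longitudinal multi-omic abundance data and then interrogates families of such
networks, learned from *nested omic subsets*, with two post-hoc analyses:

* **Unrolling** — a taxon–taxon edge in a coarse network (say, taxa-only `T`)
  that *disappears* in a finer network (`TM`, `TG`, `TGM`) while a mediator
  path through newly measured entities appears there
  (taxon → gene → metabolite → taxon in the fullest case) is *explained* by
  those intermediaries.
* **De-confounding** — a coarse edge that disappears in the finer network
  while a newly measured entity has edges into *both* endpoints is flagged as
  spurious, the new entity being a putative common cause. This probes the
  causal-sufficiency assumption that any single-layer analysis silently makes.

Every entity (taxon, gene, metabolite, clinical covariate) appears at two
slices, *t* and *t+1*. Edges are *intra* (within a slice, lag 0) or *inter*
(across slices, lag 1), and a typed permission table — the **skeleton** —
restricts which edges the structure learner may consider: taxa may drive gene
expression within a time point, genes may drive metabolite concentrations
within a time point, metabolites feed back on taxon abundances at the next
time point, and every entity keeps a self-loop to its next-slice copy. An
**augmented** variant additionally allows taxon → metabolite intra edges, for
metabolite production that gene profiling misses. Clinical covariates may act
on anything at the next time point and receive nothing.

Networks on reduced subsets cannot contain the missing layers, so their
skeletons *bridge* them: `derive_subset_skeleton` permits an edge src → dst at
lag L exactly when the full type graph contains a path src → … → dst whose
intermediate types are all absent from the subset and whose lags sum to L.
This yields taxon → taxon inter edges in `T`, taxon → metabolite intra plus
metabolite → taxon inter in `TM`, taxon → gene intra plus gene → taxon inter
in `TG`, and analogous closures for `G`, `M`, and `GM`. For `TGM` the table
is the stated skeleton itself. Users who want different tables can supply a
YAML permission file.

## Structure learning

Each next-slice variable receives an independent **family selection**: all
parent sets up to the parent bound (`max_parents`, default 3; the sweep grid
uses {3,4,5,6}) are scored with the penalized linear-Gaussian likelihood
−BIC/2 of the OLS fit with intercept, and the best-scoring family wins. Ties
go to smaller families, then lexicographic parent order, making the learner
deterministic. Candidate pools of ≤ 20 parents are searched exhaustively;
larger pools use greedy forward selection with one backward pass. Because
intra edges are typed acyclically (taxa → genes → metabolites, never back),
per-child selections always compose into a valid network.

Conditional models are fitted on the **centered log-ratio (CLR)** scale by
default (`transform="clr"`): per sample and omic type, log abundances are
centered. Relative-abundance normalization divides every entity of a type by
a common total, injecting a shared log-total term into each observed log
abundance; CLR cancels it exactly. Plain `log` and raw (`none`) scales are
available; edge weights are regression coefficients on the configured scale
and their signs are transform-invariant for the planted models used in
testing.

**Bootstrap confidence.** `n_bootstrap` (default 100) subject-level resamples
with replacement are drawn; a network is learned on each, and an edge enters
the consensus network iff it appears in at least `min_support` (default 10 %)
of repetitions. Its *bootstrap score* is the appearance fraction and its
weight the mean of its fitted coefficients over the repetitions in which it
appeared (not zero-filled). Repetition *r* uses seed `seed + r`. Per-subject
transition blocks are computed once and restacked per resample, which is
algebraically identical to relearning from a resampled table.

## Preprocessing and temporal alignment

The preparation pipeline mirrors standard longitudinal multi-omics practice:

1. **Normalization** — within each (subject, time point, omic type) group,
   values are divided by their sum (relative abundances). All-zero groups are
   an error, not a silent NaN.
2. **Scaling** — one global multiplier per omic type brings the overall gene
   and metabolite means to the taxa mean (their raw intensities are orders of
   magnitude smaller because there are many more of them). Applied before
   smoothing.
3. **Filtering** — metabolites without a compound-database annotation or with
   pooled variance below 1e-8 (configurable) are removed; subjects with fewer
   than five distinct time points in *any* measured omic layer are removed.
4. **Smoothing + resampling** — each (subject, entity) series is fitted with
   a cubic spline (interpolating at ≤ 8 points, otherwise a penalized
   smoothing spline with the penalty chosen by generalized cross-validation)
   and evaluated on a regular grid (default 7 days) spanning the subject's
   observed range; negative fitted values are clipped to zero. Series
   shorter than four points are an error.

**Temporal alignment** maps each subject's clock onto a reference subject's
clock with a linear warp t ↦ slope·t + offset (slope > 0). The warp is
fitted on one omic layer (taxa by default) by minimizing the mean squared
difference between the subject's splines evaluated in warped time and the
reference's splines, averaged over shared entities on the overlapping
interval; the same transformation is then applied to all of the subject's
omic layers (values never change, only time stamps). The reference is the
subject minimizing the total alignment error of all others onto it, ties
broken lexicographically. The optimizer is a grid search at 0.01 slope /
1-day offset resolution over slope ∈ [0.5, 2] and offset ∈ [−30, 30] days,
run hierarchically (a 5×-coarser pass, then a fine pass around its optimum)
and polished with Nelder–Mead; exact ties prefer the identity warp, so
aligning a subject to itself or aligning constant series returns (1, 0).
Subjects whose alignment error exceeds median + 2·IQR of the cohort are
treated as abnormal and dropped (configurable).

## Discovery scoring and reporting

Each unrolling or de-confounding carries the bootstrap scores of its
replacement edges and an **overall score**, their product (two edges for a
one-mediator unrolling or a common-cause fork; three for a fully unrolled
taxon → gene → metabolite → taxon chain — the product rule extended
multiplicatively). Self-loops may be unrolled (a taxon regulating itself
through a gene/metabolite cycle) but are never de-confounded (no distinct
pair). Full chains found in `TGM` gain one support count for each coarser
network (`TM`, `TG`) consistent with them. Rankings sort by overall score,
then support count, then endpoints. The proportion-unrolled table reports,
per experiment cell, the fraction of taxon–taxon edges of the `T` network
with at least one unrolling against `TGM`, `TG`, and `TM`, plus the mean
overall score; undefined cells are blank, distinguishing "no eligible edges"
from "none unrolled".

## The synthetic cohort generator

The generator plants exactly the two motifs the analyses are built to find:
mediation chains `taxonA → gene → metabolite → taxonB` and common causes
`metabolite → taxonA, metabolite → taxonB` *without* a direct taxon edge, so
that a taxa-only learner is expected to infer the spurious direct edge that
the finer networks then explain away. Dynamics are linear-Gaussian on a
latent log scale: every entity has a positive self-loop (coefficient uniform
in [0.4, 0.9]); planted cross edges have magnitude uniform in [0.3, 0.8]
with random sign. Models are redrawn (deterministically per seed) until the
implied system is clearly stable (spectral radius < 0.98) **and** no
entity's stationary latent sd exceeds 0.75 — without the variance bound,
chains of strong coefficients compound innovation variance into
near-integrated log abundances, which neither resembles real weekly
abundance fluctuation (a sd of 0.75 on the log scale already spans ~4.5-fold
swings) nor admits meaningful regression.

Default panel sizes are 27 taxa, 34 genes, and 19 metabolites, the size of a
curated longitudinal IBD multi-omics panel. Panel size matters beyond
realism: relative-abundance normalization couples every entity of a type
through the shared total ("compositional closure"), and the induced
dependencies scale like 1/(panel size). At 8 entities per type they are
genuine, detectable partial dependencies that flood the learned networks; at
the default sizes they fall below the BIC detection threshold. This is a
property of compositional data analysis generally, not of this
implementation.

Observations: taxa are exponentiated and renormalized to per-sample
compositions (they sum to 1 by construction); genes and metabolites are
exponentiated intensities with per-entity log baselines ~ N(0, 0.3). Each
subject is an **independent realization** of the process on an internal
7-day grid (50 burn-in steps discarded); observation times are stretched by
a per-subject warp slope drawn from [0.8, 1.25] and jittered by up to ±1
day, emulating irregular sampling at subject-specific speeds. An optional
`trajectory_sharing` fraction makes part of the innovation variance common
to all subjects; it is **off by default** because a cohort-level shared
drive is, to a pooled structure learner, an unmeasured confounder — at 0.5
sharing it measurably adds tens of systematic spurious edges. Alignment
recovery is therefore validated on explicitly constructed common-trajectory
cohorts (a reference curve warped by known slopes), not on the default
generator output.

What the generator deliberately does **not** model: sequencing count noise
(negative binomial, zero inflation), compositional sparsity, nonlinear or
non-stationary dynamics, and measurement batch effects. Passing recovery
tests therefore demonstrate correctness of the machinery under the model's
own assumptions, not performance on real sequencing data.

## The reference experiment and its thresholds

The repository's main stochastic check simulates the reference cohort (20
subjects × 30 time points, 3 chains, 2 confounders, innovation sd 0.1, seed
7), runs the full pipeline (preprocess → align → learn consensus networks for
T, TM, TG, TGM at 100 bootstraps → discover), and matches discoveries to the
planted motifs by entity identity. Recovery is evaluated on high-confidence
discoveries — every replacement edge at bootstrap support ≥ 0.9, the usual
stability-selection operating point — while the raw discovery lists are kept
alongside. The companion learner check fits a single network on the same
cohort with temporal irregularity switched off (identity warps, no jitter),
isolating family selection from warp handling, and scores planted-edge F1.
Problem sizes were chosen so the whole suite, including this experiment,
runs comfortably on one CPU.

## Numerical choices and degenerate inputs

* OLS is solved via shared Gram matrices per candidate pool; rank-deficient
  designs fall back to the pseudoinverse with a logged warning. Residual
  variance is floored at 1e-300 before the log, so noiseless fits score
  "very good" rather than crashing.
* Zero abundances survive normalization as zeros; the log/CLR transforms
  floor values at 1e-6 before the log.
* Edge-list TSVs are UTF-8, one row per edge, with a mandatory header;
  subset labels and metadata travel in `#` comment lines. Malformed rows
  (wrong column count, non-numeric weight, bootstrap score outside [0, 1],
  invalid lag) raise an error naming the line number.
* Entity-level collapsing keeps the higher-bootstrap-score edge when both
  lags connect the same entity pair (lower lag on exact ties).
* Bootstrap supports are exact fractions; the ≥ 10 % retention rule uses
  ordinary `>=`, so 10/100 repetitions is kept and 9/100 is dropped.

## Known limitations

* De-confounding can only nominate *measured* entities; genuinely latent
  confounders remain invisible, and the method inherits whatever biases the
  underlying structure learner has.
* BIC's fixed penalty admits a ~1 % false-entry rate per candidate; on
  80-entity panels the consensus networks therefore carry tens of
  low-support edges. The stability threshold handles this at discovery
  level, but the raw networks should be read with their bootstrap scores.
* Measurement error from compositional observation lets strong mediators
  occasionally proxy for their upstream taxa (reverse-direction intra
  edges), which is why discovery precision is evaluated at high support
  rather than on the unfiltered record lists.
* The linear warp family cannot express varying progression speed within a
  subject; that would need dynamic time warping, which is out of scope.
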