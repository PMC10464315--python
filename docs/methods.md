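# Methods

## The model

For each CpG and each sex stratum, methylation (rank-inverse-normal
transformed, see below) is modelled as

```
y_i = x_i'β + ε_i,    ε_i ~ N(0, φ_i),    φ_i = exp(z_i'γ)
```

with identical covariate sets in the mean design `x` and the dispersion
design `z`: intercept, age, cohort, the five measured leukocyte fractions
(CD8T, CD4T, NK, B, monocyte — granulocytes are the left-out remainder, so
their effect sits in the intercept; a purified-monocyte cohort swaps the
fractions for a single purity covariate), technical batches (sentrix
position, sample plate) one-hot encoded with the first level dropped, and
five latent factors. The age coefficient of the mean model is the aDMC
statistic; the age coefficient of the dispersion model — the slope of log
residual variance per year — is the aVMC statistic.

### Fitting

The fit alternates a weighted least-squares mean step (weights `1/φ_i`)
with a Fisher-scoring step for `γ` on the *restricted* likelihood
(REML), using

* score `U(γ) = ½ Z'(d − (1−h)φ)/φ`, where `d_i = e_i²` are squared
  residuals of the weighted mean fit and `h_i` its leverages, and
* information `I(γ) = ½ [Z' diag(1−2h) Z + Z'(H∘H)Z]`, with `H∘H` the
  elementwise square of the weighted hat matrix (computed from pairwise
  products of the thin-QR factor's columns, never forming `H`).

The scoring step is Levenberg-damped: if a step decreases the restricted
likelihood the damping constant is doubled and the step retried, so the
working likelihood is monotone across iterations. `γ` is initialised from
a weighted regression of `log(d/(1−h)) + 1.27` on `Z` (the offset is
−E[log χ²₁]). Convergence is declared when the score–step inner product,
or the restricted-likelihood change, falls below `tol·(|ℓ_R|+1)`
(default `tol = 1e-8`, `max_iter = 50`). Non-converged CpGs are returned
with a flag and excluded from hit calling.

Standard errors: `cov(β̂) = (X'WX)⁻¹` and `cov(γ̂) = I(γ)⁻¹`. Wald
z = coefficient/SE with a standard-normal reference, two-sided p.

A note on the exact leverage adjustment: a simpler and widely used
approximation — feeding `e²/(1−h)` to a gamma GLM with log link and prior
weights `(1−h)/2` — produces a noticeably conservative dispersion test in
simulation (null z SD ≈ 0.95, type-I error ≈ 0.03 at α = 0.05, n = 2000).
The exact REML information restores calibration (z SD ≈ 1.00, type-I
≈ 0.048). The implementation agrees with an independent REML-scoring
reference (R, `statmod::remlscore`) to ~1e-6 in `γ̂` on shared data; that
agreement is kept as a cross-check in the test suite.

Aliased design columns are dropped greedily in column order; missing
covariates exclude the sample from the scan; categorical covariates with a
single level are dropped before design construction.

## Preprocessing

* **Batch adjustment** (multi-cohort discovery only): per CpG, batch
  means are estimated jointly with covariate effects by least squares and
  removed, and per-batch residual scales are equalised to the pooled
  scale. This is a deliberately simplified location/scale analogue of
  empirical-Bayes batch correction: the RIN transformation applied
  immediately afterwards erases most distributional differences, so the
  extra shrinkage machinery buys little here. Batches with < 3 samples get
  location-only adjustment (their scale estimate is meaningless).
* **Rank-inverse-normal (RIN) transformation**, per cohort × sex and per
  CpG: `Φ⁻¹((r − 3/8)/(n + 1/4))` with average ranks for ties (Blom
  offsets — the convention in the EWAS usage of RIN). Missing values pass
  through; CpGs constant within a stratum carry no rank information and
  are dropped with a logged exclusion list. A fully tied vector maps to
  zeros by the average-rank formula itself.
* **Latent factors**: the top-k left singular vectors (default k = 5) of
  the data after projecting out the known design, column-centred. This
  plays the role surrogate-variable analysis plays in methylation EWAS —
  soaking up shared unmodelled structure — while being deterministic and
  directly testable. It is a stand-in estimator, not a reimplementation
  of the SVA permutation procedure. Note what it can and cannot do: the
  age-*orthogonal* part of an unmeasured confounder is captured and
  removed; any component collinear with age stays in the age coefficient
  by construction, which is exactly why composition-driven mean hits
  survive latent-factor adjustment (below).

## Empirical-null correction

Scan-wide z vectors are modelled as a three-component Gaussian mixture —
a dominant null plus one alternative component per side. The null
component's mean (**bias**) and SD (**inflation**) are estimated by
truncated-normal maximum likelihood on the statistics inside a window of
±2.2 current null SDs, re-centred iteratively (Nelder–Mead on (μ, log σ),
window updates until stable). The window keeps ≈ 97% of a pure null while
excluding essentially all of any signal component further than ~3 SDs
out; the estimator is location/scale equivariant by construction. The two
alternative components and the null weight π₀ are then fitted by EM with
the null held fixed (weight floor 0.5 on the null, alternatives kept
≥ 1.5 null SDs away on opposite sides) — these are diagnostics, not part
of the correction. Statistics are corrected as `z' = (z − bias)/inflation`
with two-sided normal p.

A plain soft-EM over all three components was tried first and rejected:
whatever the constraint set (weight floors, separation bounds, tied or
ordered component SDs), the alternatives absorb the null's shoulders and
the fitted null SD lands ~7% low on pure-null input — enough to break
p-value uniformity after correction. The central truncated-likelihood
estimator has no such leakage because signal components never enter the
fitting window. A median/MAD estimate is always computed alongside and
used as fallback for degenerate inputs; below 100 statistics the caller
falls back to it explicitly (the per-CpG expression correction does this
when few genes survive filtering).

Correction is applied per analysis stratum: dataset × sex × submodel for
the methylation scans, per CpG across genes for expression t statistics.

## Hit calling, replication, regions, annotation

Discovery: Bonferroni on corrected p (α = 0.05, m = converged CpGs in the
scan), per sex. Replication: for each hit class (aDMC / aVMC), BH-FDR is
applied to each replication cohort's corrected p-values over
`m_unique` = the union of discovery hits across sexes; a hit replicates
if `p_FDR < 0.05` *and* the corrected-statistic sign matches discovery
(zero sign never replicates); doubly replicated = both cohorts. CpGs
missing (or non-converged) in a replication set count as non-replicated
with the denominator unchanged.

Regions: greedy left-to-right extension over significant positions; a
region grows while the next significant CpG is ≤ 1 kb from the previous
member and the running count of non-significant array CpGs inside the
span stays ≤ 3; emitted at ≥ 3 members. The ≤ 1 kb rule binds consecutive
*significant* members (the published region-caller description is
ambiguous on this point; the choice is isolated in one function and
verified against a brute-force window enumeration). Distinct loci =
hits − in-region hits + regions.

Annotation axes: methylation level from *untransformed* per-sex discovery
mean betas (hypo < 0.25, hyper > 0.7 — thresholds at the male density
peaks, since intermediate methylation is the Xa-low/Xi-high signature);
CGI context from a BED track (0-based half-open, converted to 1-based
inclusive; islands beat shores; shores are ±2 kb); XCI status copied from
the nearest TSS when within 2 kb (ties to the lower coordinate), else
unannotated. Enrichment versus non-hit background CpGs: Pearson
chi-square, switching when any expected cell < 5 to Fisher's exact (2×2)
or a seeded Monte-Carlo conditional test (larger tables).

## The synthetic-data generator

The generator is allele-level by design: each CpG has baseline
methylation for Xa and Xi; males measure Xa, females the (Xa+Xi)/2
average plus measurement noise, clipped to [0,1]. This single choice
makes the headline structural facts *emerge*: escape-gene promoters
(Xa low, Xi low) give the female low mode, subject-to-XCI promoters
(Xa low, Xi high) the intermediate mode, gene bodies (high, high) the
high mode — trimodal in females, bimodal in males — and an Xa-planted
effect is diluted exactly ×2 in females.

Landscape: genes every ~24 kb, each with a promoter cluster of 5–8 CpGs
within −400/+600 bp of the TSS; promoter clusters are CGIs with a
probability calibrated so ≈ 35% of CpGs fall in islands; gene XCI status
drawn from (subject, escape, variable) = (0.75, 0.15, 0.10); remaining
CpGs intergenic. Baselines are truncated normals with symmetric bounds
(asymmetric clipping skews the mixture components enough for a
Gaussian-mixture BIC to prefer a spurious third male component).

Planted effects (defaults define the study):

* 60 Xi-variance CpGs, `γ1 = 0.03/yr`, planted **gene-cluster-wise** at
  subject-to-XCI genes preferring CGI promoters — regional
  destabilisation of Xi promoters is the phenomenon being emulated, and
  cluster planting is what makes variably methylated regions callable;
* 6 Xa-variance CpGs (`xa_specific`, visible in both sexes, diluted in
  females), 8 Xa-mean and 6 Xi-mean CpGs at `β1 = ±0.0015/yr` on the beta
  scale;
* 50 composition-driven CpGs (below).

Noise budget (a power design choice): allele noise SDs `sd_xa = 0.025`,
`sd_xi = 0.06`, measurement noise `sd_meas = 0.012`. The Xi allele is the
noisier compartment, which puts ≈ 75% of female beta variance on Xi;
a planted `γ1 = 0.03/yr` then has an effective measured log-variance
slope ≈ 0.022/yr against an SE of ≈ 0.003 at n = 600 (uniform ages
18–85), i.e. discovery z ≈ 7 and comfortable replication power at
n = 300. With a symmetric noise budget the Xi share drops to ~37% and the
planted effects sit below the Bonferroni threshold — an underpowered
study by construction. A variance effect planted on one allele scales
that allele's noise SD by `exp(γ1·(age − 51.5)/2)`; a mean effect moves
the allele mean linearly in age (slopes are beta-scale per year; the
age-range constraint caps realistic slopes at a few 1e-3 per year, since
betas live in [0,1]).

Cell-composition confounding is an *unmeasured*, age-drifting axis `u`
(think granulocyte/lymphocyte subtype shifts): `u = 0.025·(age−51.5) +
N(0,1)`. The five reported cell fractions load on `u` only weakly
(loadings −0.008…+0.003 against per-fraction noise 0.015, jointly
explaining ~30% of `u`), so adjusting for them leaves most of the
age-correlated signal at CpGs that load on `u` (loadings ≈ ±0.08 beta
per unit). Latent factors remove the age-orthogonal part of `u` but not
its drift. In the purified-monocyte cohort the axis is absent; instead a
purity covariate (mean 0.9, SD 0.04) scales per-CpG impurity offsets.
This reproduces the diagnostic contrast: composition-driven mean hits
replicate in whole blood and collapse in monocytes, while allele-level
variance hits replicate in both.

Default study sizes (desk scale): 2,000 CpGs; discovery 600 F / 450 M in
three sub-cohorts; two replication cohorts of 300 F / 250 M each (one
blood-like, one monocyte-like); ages uniform on 18–85. Expression:
300 genes (40% simulated lowly expressed to exercise the median-CPM < 1
filter), RNA-seq counts Poisson around log-normal library sizes, with a
handful of genes linearly linked to planted-variance CpG methylation
(slope 0.5 noise-SD units); 80% of discovery samples carry expression.

What the generator does **not** emulate: probe-level artifacts (detection
failures, cross-reactivity), realistic linkage disequilibrium of
methylation beyond promoter clusters, non-linear age trajectories,
age-dependent cell-fraction *variance*, loss-of-X or XCI skewing, and
count overdispersion beyond Poisson. Passing tests therefore demonstrate
that the statistical machinery recovers the planted structure under the
stated noise model — not that it is robust to every artifact of real
array data.

## Numerical choices and degenerate inputs

* Dispersion linear predictors are clipped at ±30 before exponentiation.
* `d = 0` residuals are floored at 1e-300 only inside logs.
* Empty hit sets short-circuit region calling and enrichment (no test is
  run on a degenerate table); zero-direction hits never replicate.
* The region caller and annotation are pure integer/interval logic with
  explicit tie rules (lower TSS coordinate wins; island body beats a
  neighbouring island's shore).
* All randomness flows through `numpy.random.default_rng` seeds; the
  pipeline derives stage seeds from one master seed via `SeedSequence`,
  and fixed seeds reproduce byte-identical outputs.

## Known limitations

* The latent-factor stand-in is SVD-based; studies whose confounders are
  strongly non-linear in the data may behave differently under true SVA.
* The simplified batch adjustment assumes batch effects are
  location/scale per CpG; interaction-type batch effects are out of
  scope.
* At very small strata (n ≲ 100 with the full covariate set) the
  dispersion model is weakly identified; fits there may not converge and
  are flagged and excluded rather than rescued.
* Replication-rate quantities at desk scale have Monte-Carlo spreads of
  a few percentage points across seeds; single-seed rates near a round
  threshold should be read with that in mind.
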