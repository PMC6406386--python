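# Methods

`ewistk` implements an epigenome-wide interaction study (EWIS): per-CpG
tests of whether blood DNA methylation modifies the association between BMI
(or 10-year BMI change) and adult-onset non-atopic asthma, followed by
pathway-level aggregation and region-level (DMR) detection. This note
records the statistical model, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the numerical
decisions a maintainer would want to know.

## Per-CpG interaction model

For CpG *i* with methylation residual `r_i` (see below), exposure `E`
(BMI in kg/m², or BMI change with the earlier BMI added to the adjustment
set), and case status `D`:

    logit P(D = 1) = b0 + bE·E + br·r_i + γ_i·(r_i × E) + covariates

Covariates: age (years), sex, education (low/middle/high), study area
(8 levels), pack-years, bench time (minutes), and six Houseman-style cell
fractions (B, CD4T, CD8T, NK, monocytes, eosinophils). Neutrophils are
deliberately excluded from the basic model: in non-atopic disease the
relevant immune response may run through neutrophil proliferation, so
adjusting for them can absorb the signal of interest. Sensitivity variants
add neutrophils or physical activity (rows with unknown activity are
dropped only in that variant).

Inference on γ_i is Wald (`z = γ̂/se`, two-sided normal p), which is
conventional for EWAS and supplies the Z statistics that enrichment and DMR
stages consume. Discovery is controlled by Benjamini–Hochberg at FDR 0.1
over the converged probes. `effect_per_sd = γ̂ × SD(r_i)` (SD over
non-missing samples) is a derived reporting column: log-odds change of the
BMI–asthma association per 1 SD of methylation.

Numerics: fits run through a batched damped-Newton engine (all probes share
the covariate block; per-probe residual and product columns are
standardized per probe; steps are clipped at 2, coefficients at ±30, and a
1e-9 ridge guards the information-matrix inverse when a sparse category
level — e.g. an education stratum with no cases — drifts to the boundary).
Iteration cap 100; convergence when the largest score component falls below
1e-6 or the deviance change below 1e-8. The engine is numerically identical
(coefficients and SEs to ~1e-8) to a per-probe statsmodels `Logit` maximum
likelihood fit, which remains available (`engine="per_probe"`) and serves
as the reference implementation in the tests. Separation is flagged by
|γ̂| > 15 or SE > 1000; such probes carry missing statistics and are
excluded from the BH family. The interaction product is built from centered
factors — an exact reparametrization (both main effects are in the model)
that removes the severe collinearity between `r` and `r×E` when the
exposure's coefficient of variation is small.

## Preprocessing

Beta values (methylated fraction, in [0,1]) are set to missing where the
detection p-value exceeds 1e-16; probes on sex chromosomes, externally
masked probes (multi-mapping/SNP-overlap surrogate), and probes with call
rate < 0.95 are removed (samples with call rate < 0.95 are reported, not
dropped). PCA is run on the 220 control probes with samples as
observations, columns centered but not scaled (the standard reading of the
control-probe adjustment; scaling is an open alternative the API exposes
via its own PCA helper). Each probe's beta vector is replaced by OLS
residuals on an intercept plus the first 30 PC scores; missing entries are
omitted pairwise and stay missing. Residualization is idempotent and leaves
residuals orthogonal to the retained PCs.

## Pathway enrichment (Monte-Carlo weighted KS)

CpGs map to a gene when they lie within the gene body ±200 bp (the
body-inclusive reading; a CpG may serve several pathways). A pathway's
statistic is the one-sided Kolmogorov–Smirnov distance
`D⁺ = sup_x [F_all(x) − F_pathway(x)]` between the ECDF of all analyzed
|Z| and of the pathway's |Z| — positive when the pathway's statistics are
stochastically larger. The null resamples size-matched CpG sets **without
replacement** from the analyzed universe (null pathways are subsets of the
real array, preserving its |Z| distribution exactly);
`mc_p = (1 + #{D⁺_b ≥ D⁺_obs})/(B + 1)` with B = 10,000 by default, so
mc_p is never 0. Multiplicity is handled by Westfall–Young min-p over the
shared replicate ensemble, reported as `adj_p` (monotone in mc_p,
never smaller). Enrichment is declared at mc_p < 0.05. Ties in |Z| are
handled by ECDF right-continuity, no jitter. A GSEA-style weighted
running-sum statistic is available as an alternative
(`gsea_running_sum_statistic`) but the resampling KS form is the default.

Sampling without replacement is exact: whole-row rejection sampling (with
replacement conditioned on distinctness) when collisions are rare, top-m of
iid uniform keys when the subset is a large fraction of the universe;
exactness is verified against complete subset enumeration on a 10-probe
universe.

## DMR detection

Interaction Z values are squared and smoothed per chromosome with a
Gaussian kernel: bandwidth λ = 1000 bp, scaling C = 2, σ = λ/C = 500 bp,
truncated at 3σ (per-neighbour truncation error < e^−4.5), weights
normalized to sum to 1. Under an iid χ²(1) null for Z², the smoothed
statistic S is approximated by Satterthwaite moment matching:
`S ~ a·χ²(ν)` with `a = Σw²`, `ν = 1/Σw²`; p is the upper tail at S/a.
The iid null ignores inter-CpG correlation exactly as the analytic null of
kernel-based DMR callers does; its empirical calibration on clustered
manifests is checked in the tests (approximately uniform p on
cluster-spaced subsets). BH runs over all analyzed CpGs genome-wide
(not per chromosome); CpGs with q < 0.05 are chained into regions while
consecutive members are ≤ λ apart; region bounds are the member-CpG span
(not extended by λ/2 — the alternative is noted as open). Regions are
annotated to genes whose promoter — the strand-aware 2000 bp window
upstream of the TSS, with a symmetric-window option — overlaps the region.
Regions without gene annotation are retained and counted; the
over-representation stage skips a variant when fewer than 25 annotated
genes accumulate (configurable), and uses a one-sided Fisher exact test per
pathway with BH across pathways.

## Synthetic cohorts

The generator emulates a nested case-control methylome study with the
reference design of 61 cases / 146 controls. CpGs sit in islands
(default 10 probes, intra-island gaps ≤ 80 bp, inter-island gaps
≥ 20 kb) so smoothing and region calling are meaningful; genes tile the
islands without overlap, each TSS placed at an island midpoint (mirroring
the promoter-centric probe placement of real arrays, so island DMRs can
overlap promoters while body CpGs feed pathway assignment); pathways are
mutually exclusive gene sets plus a "global" union. Beta values are logit-normal: a trimodal baseline
(hypo-/hemi-/hyper-methylated), sparse cell-composition loadings on
centered Dirichlet cell fractions, a latent batch term whose factors also
generate the 220 control probes, and N(0, 0.5²) individual noise, squashed
through the inverse logit (so beta is strictly inside (0,1)). Covariates
target the reference cohort's margins (BMI median ≈ 24.5–25.7 via a
0.06 log-odds/unit BMI main effect, 58% female with a 0.6 log-odds female
effect, ~2% missing physical activity, education 1/66/33%, eight areas);
ln hs-CRP is generated as −2.44 + 0.1·BMI + N(0, 0.75²), so the auxiliary
regression recovers a slope of 0.1. Only medians/margins are targeted —
full covariate shapes are not calibrated to any real cohort.

Disease is generated forward: the logistic model contains the covariate
main effects plus planted `γ_i·(E−Ē)·(β_i−β̄_i)` products (centering both
factors leaves the interaction log-odds per β-unit per exposure-unit
unchanged — the differences are main effects — while keeping the latent
scale bounded when many CpGs are causal); the intercept is bisected to a
target prevalence of 0.33 in an oversampled pool, then exactly 61 cases
and 146 controls are drawn. An optional `probe_seed` freezes the
CpG-level parameters so one "array" can be reused across cohorts.

What passing tests on these cohorts do **not** show: probe-chemistry
artifacts (Type I/II design bias), genuine cell-deconvolution error,
genomic inflation from population structure, and realistic inter-CpG
correlation within islands (island CpGs share baseline and batch terms but
have independent individual noise). One consequence worth knowing: because
logistic effects are non-collapsible, planting strong interactions at many
CpGs simultaneously attenuates every marginal per-CpG fit (unmodelled
heterogeneity acts like extra noise); recovery studies therefore plant
effects on bounded causal sets, and the per-CpG interaction magnitudes in
validation designs were chosen by a priori power calculation
(target non-centrality ≈ 5 at the 61/146 design for DMR blocks, γ = 2.5
per β-unit per BMI-unit; a balanced 2000/2000 cohort with a
mid-methylated, high-variance target CpG for coefficient recovery).

## Calibration at the reference scale

With 61 cases and ~23 design columns (events per variable ≈ 2.7), the Wald
interaction test is anti-conservative in a cohort-dependent way: across
global-null replicates at 207 samples the fraction of p < 0.05 averages
roughly 0.06–0.07 and swings between ~0.04 and ~0.09 from cohort to
cohort. This is a property of small-sample logistic inference, not of the
implementation — the batched engine matches statsmodels to ~1e-8, and a
from-scratch likelihood-ratio test is no better calibrated at this scale.
At larger n (e.g. the 4000-sample recovery design) calibration and CI
coverage are nominal. Genome-wide discovery claims at the reference scale
rest on the BH step at FDR 0.1, which remained empty in every global-null
replicate examined; pathway enrichment calibration is exact by
construction (resampling null).

## Problem sizes

Simulation-based checks run at desk scale, chosen as the package's own
test conditions: 20,000-CpG manifests for end-to-end runs and enrichment
calibration (1000 random pathways, B = 2000), 5000 CpGs × 20 replicates
for null calibration, 1000 CpGs × 50 replicates for DMR recovery, and
B = 10,000 only where the exactness check needs it. The acceptance script
uses further scaled-down replicate counts with the same designs.

## Known limitations

- The Satterthwaite null treats neighbouring Z² as independent; with very
  dense probe spacing the smoothed p-values are conservative at island
  centres and the BH threshold inherits that approximation.
- Westfall–Young adjustment uses per-pathway independent draws within each
  replicate; correlation between overlapping pathways is therefore not
  reflected in the joint null (the unadjusted mc_p is unaffected).
- The per-1-SD effect scaling uses the residual SD of the analyzed sample,
  so values are not transferable across cohorts with different residual
  variances.
- `ModelSpec` dummy-codes education and area against fixed reference
  levels (first level); interaction inference is invariant to that choice,
  main-effect columns are not.
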