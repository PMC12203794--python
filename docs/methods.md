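# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limitations of `episilence`.

## Per-probe EWAS

For each CpG probe, the β value (methylated fraction, in [0, 1]) is
regressed on the 0/1 driver-group indicator by ordinary least squares;
since the design is a single binary covariate this is algebraically the
equal-variance two-sample t-test, and the two-sided p-value uses the t
distribution with n−2 degrees of freedom. Missing β values are dropped
pairwise per probe. Probes with fewer than two usable samples in either
group are *kept* with p = 1 and an `insufficient_data` flag (silently
dropping probes would bias the genomic span B used later in the Šidák
correction); zero-variance probes report Δβ = 0, p = 1. Direction is
carried separately as Δβ = mean(high) − mean(low), so the same machinery
reports hyper- and hypomethylated regions.

## Combined-p DMR calling

The region caller reproduces the comb-p computation natively. Its
components are deliberately isolated behind seams (`AcfEstimate`,
`score_region`) because the published description leaves internals open;
the choices fixed here are:

- **ACF estimation.** Probit scores z = Φ⁻¹(1−p) are correlated per genomic
  lag bin (bin width 50 bp, max lag = `dmr_dist` = 1000 bp) over all
  same-chromosome probe pairs; Pearson correlations are clipped to
  [0, 0.99]. Bins with fewer than 10 pairs inherit the nearest populated
  bin's value; lags beyond the last bin extrapolate it. If the scores carry
  no variance at all (identical p everywhere) the estimate degenerates to
  ρ̂ = 0.99 and is flagged. p-values are clamped to [1e−300, 1−1e−16]
  before the probit throughout.
- **Window adjustment.** Each probe's p is replaced by the Stouffer–Liptak
  combination over all same-chromosome probes within ±dist/2, with
  σᵢⱼ read from the ACF bin of |posᵢ−posⱼ| (σ = 1 at lag 0). A probe with
  no neighbour keeps its raw p exactly.
- **Region growth.** Regions start at probes with adjusted p < 1e−5
  (`dmr_seed_p`) and extend over consecutive probes with adjusted p < 0.05
  (`dmr_region_filter_p`) provided each inter-probe gap ≤ 1000 bp;
  overlapping grown regions merge; regions with fewer than 2 probes
  (`dmr_region_filter_n`) are discarded. Equal-position probes are
  processed in manifest order. Direction is the sign of the members' mean
  Δβ, with ties resolved to "hypo" (conservative for hypermethylation
  calls).
- **Region scoring.** p_combined is the Stouffer–Liptak combination of the
  *raw* member p-values (σ again from the ACF). The Šidák correction uses
  exponent B/w, where w = region span in bp (end − start, minimum 1) and
  B = Σ over chromosomes of (max pos − min pos) of tested probes; the
  exponent is floored at 1, so p_šidák ≥ p_combined always. The
  numerically stable form −expm1((B/w)·log1p(−p)) is used.
- **Gene assignment.** A gene is called hypermethylated iff at least one
  hyper-direction DMR with p_šidák < 1e−5 (`gene_dmr_p`) contains a member
  probe annotated to that gene with region class TSS200, TSS1500 or 5′UTR.
  Multi-gene probes fan out to every annotation pair; the promoter-class
  filter is applied per pair. The gene threshold applies to the
  Šidák-corrected region p by default (configurable), since that is the
  quantity controlled for the number of effective tests.

Coordinates follow the Infinium convention: manifest positions are 1-based
single-bp CpG positions, all distance arithmetic uses them directly, and
emitted BED intervals are 0-based half-open (start = min pos − 1,
end = max pos).

## Differential expression, intersection, correlations

Expression is on the log2(1+x) scale; the fold change is 2^(Δ mean log2),
avoiding pseudocount choices. Two test backends exist — Welch t (default)
and Mann–Whitney — because two-group comparisons of log expression are
commonly run either way; the choice is a config switch recorded in output
headers. Benjamini–Hochberg is the only multiplicity procedure. A gene is
"down" iff FC ≤ 1/1.5 and adjusted p < 0.05 (symmetric for "up"). The
candidate list is the intersection of hypermethylated and downregulated
genes, ordered by best supporting DMR p. Pearson correlations (driver
expression vs promoter mean β, promoter β vs target expression, driver vs
target expression) use the two-sided t-based p on n−2 df; promoter mean β
is the per-sample mean over the gene's promoter-class probes.

## Survival screen

Kaplan–Meier, the two-group log-rank test (hypergeometric variance at each
distinct event time, χ² on 1 df) and the single-covariate Cox model are
implemented natively; the test suite cross-checks them against lifelines
and against closed-form/grid-search oracles. The Cox fit maximises the
Breslow-ties partial likelihood by Newton–Raphson with step-halving,
convergence tolerance 1e−9 on β, at most 50 iterations (Efron ties
available behind a flag). The covariate is standardized expression, so
HR = exp(β) is per 1 SD and HR < 1 means higher expression is protective.
Non-convergence or monotone-likelihood separation (|β| > 20) yields a
flagged result with p = NaN, counted as non-significant.

Per gene and cohort the screen requires Cox p < α AND log-rank p (median
split) < α AND HR < 1; a gene passes consensus with ≥ `consensus_min_cohorts`
(default 3) significant cohorts. No cross-gene multiplicity correction is
applied: the replication requirement across independent cohorts is the
guard, and this is documented rather than silently "improved".

## Alterations and strata

The LOF vocabulary is the closed set {stop_gained, start_lost,
frameshift_variant, inframe_deletion, inframe_insertion,
protein_altering_variant}; missense is excluded because its functional
impact is unresolvable without further annotation; unknown terms classify
as non-LOF with a logged warning. "Deleterious CNA" means deep deletion
(category −2) only — single-copy loss usually retains expression
(configurable). Frequencies are fractions of the full sample universe, and
the combined frequency uses union semantics.

Stratification of a target gene: LOFDEL = samples with a LOF mutation or
deep deletion of the target; METH = driver-high samples whose target
promoter mean β exceeds the 90th percentile of the driver-low population
AND whose target expression is below the cohort median, excluding LOFDEL
samples (genetic evidence takes precedence, guaranteeing disjoint strata);
CTRL = driver-low samples without a genetic target alteration. The
sample-level METH rule (quantile threshold + below-median expression) is
this package's operationalisation of a group-level description; the
quantile is exposed as a parameter.

## Pre-ranked GSEA

The enrichment score is the signed extremum of the weighted KS running sum
(hit increments |metric|^w normalised over the set's hits, default w = 1;
miss decrements 1/(N−N_hits)); w = 0 gives the unweighted KS used by the
oracle tests. Genes absent from the ranked universe are dropped before
scoring. Significance uses gene-label permutations (size-matched random
sets), the standard scheme for externally ranked input: NES = ES divided by
the mean |permutation ES| of matching sign, nominal p with add-one
correction over matching-sign permutations, and the NES-ratio FDR q of the
original GSEA procedure over the pooled observed and permuted NES. The
permutation null depends only on the intersected set size, so permutation
pools are cached per size; extrema of the piecewise-linear running sum are
evaluated only at hit boundaries, which is exact and O(k) per permutation.
Ranking ties break deterministically (metric descending, then symbol), and
results are byte-reproducible given the seed. When the positive and
negative running-sum extrema tie in magnitude to machine precision, the
reported sign is an arbitrary but deterministic choice.

## Synthetic cohorts

`SimulationConfig` defaults define the conditions the pipeline is evaluated
under: 8 cohorts of 300 samples, balanced bimodal driver (high ≈ N(6, 0.5),
low ≈ N(2, 0.5) log2 units), 300 genes of which 10 are planted targets,
8 promoter probes per gene spaced 100 bp (classes cycling
TSS1500/TSS200/5′UTR) plus 2 Body probes, promoter β baselines
U(0.15, 0.35) with Δβ = 0.3 added in driver-high samples for target
promoters, β noise Beta(μκ, (1−μ)κ) with κ = 50 (support-respecting, no
clipping artefacts), target downregulation of 1 log2 unit with expression
noise SD 0.25, relapse hazard λ = 0.05·exp(−0.7·z) with z the standardized
*functional* target expression, 30% censoring, and LOF/deep-deletion hits
planted in 10% of driver-low samples for the designated target (80%
mutations, 20% deep deletions) plus passenger missense and shallow-CNA
noise records. Only cohort 0 carries methylome and genomic tables; all
cohorts share the gene universe but draw independent samples. One RNG
stream per (cohort, table) is derived by counter-based seeding, so
regenerating one table never perturbs another.

Two generator choices deserve justification:

- **Functional hazard.** Mutated transcripts remain expressed at normal
  mRNA levels, yet a genetic hit to the designated tumour suppressor should
  confer the same relapse risk as epigenetic silencing of the programme.
  The hazard covariate is therefore the measured mean target expression
  minus one planted fold change for LOF/deleted samples. Tying hazard to
  measured mRNA alone would make the LOFDEL survival contrast undetectable
  by construction.
- **Expression noise SD = 0.25 log2 units.** The planted silencing is meant
  to emulate a strongly bimodal on/off pattern (as for master regulators
  such as GATA3 in breast tumours), where the silenced and expressed modes
  are well separated relative to within-group spread. The sample-level METH
  rule requires target expression below the cohort median; with half the
  cohort silenced the miss probability is Φ(−fc/(2σ)), so σ must be small
  against fc for the stratum to be recoverable — a property of the
  biological pattern being modelled, not of the inference machinery.

What the generator does *not* emulate: batch effects and platform
differences between cohorts, subtype-specific expression programmes,
segment-level (gene-correlated) copy-number structure, probe
cross-hybridisation, and downstream transcriptional consequences of target
inactivation (so the two GSEA contrasts share no planted signature — the
generator plants the targets' own depletion in METH only). Passing tests
therefore demonstrate correctness of the statistical machinery under the
planted causal structure, not robustness to real-data artefacts.

Censoring is independent exponential; the censoring rate is solved
numerically (Brent) so the expected censored fraction equals
`censor_rate`, keeping censoring non-informative given covariates and the
Cox estimator unbiased.

## Problem sizes and degenerate inputs

Default analyses run at 300 genes × 300 samples × ~3,000 probes per cohort;
null-calibration checks use ~20,000 probes × 200 samples; estimator
recovery uses n = 500 with 50–100 replicate seeds. Matrices load whole into
memory (the contract targets ≤ ~500k probes × ~1k samples). Degenerate
inputs fail loudly: constant driver expression, empty CTRL stratum,
zero-variance correlation inputs, sub-minimum group sizes and invalid
configuration keys or ranges all raise named validation errors rather than
propagating NaNs.

## Known limitations

- The DMR caller matches the *rules* of the published combined-p procedure,
  not the byte-level output of any particular executable; window centring,
  ACF binning and the Šidák exponent definition are fixed as stated above.
- The Cox implementation is univariate (the screen is univariate by
  design); no covariate adjustment, competing risks or time-varying
  effects.
- The sample-level METH criterion is a documented construction; group-level
  prose in the field leaves the numeric rule open.
- GSEA permutation counts below ~1000 make the smallest attainable nominal
  p about 1/(nperm+1); FDR q at small collection sizes is coarse.
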