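# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the known limits of `atacdiff`.

## Study design the package targets

The package implements the analysis chain of sorted-nuclei ATAC-seq
case-control studies of late-onset Alzheimer's disease (LOAD): nuclei from
frozen cortex are sorted into neuronal (NeuN+) and non-neuronal (NeuN-)
fractions, each fraction is sequenced per donor, and accessibility is
compared (a) between cell fractions and (b) between cases and controls
within a fraction, optionally stratified by sex. Comparison presets encode
this layout:

| preset | contrast | stratum | n (cases vs controls) |
|---|---|---|---|
| L1 | neuronal vs non-neuronal | all paired donors | 40 vs 40 (donor-blocked) |
| L2_neuronal / L2_non_neuronal | LOAD vs control | one fraction | 19 vs 21 |
| L3A / L3B | LOAD vs control | non-neuronal, F / M | 11 vs 11 / 8 vs 10 |
| L3C / L3D | LOAD vs control | neuronal, F / M | 11 vs 11 / 8 vs 10 |
| L3E | LOAD vs control | non-neuronal F, incl. unpaired donors | 14 vs 13 |

The published cohort descriptions are internally inconsistent about how the
nine unpaired non-neuronal donors split by sex and diagnosis; we follow the
methods-level group sizes (L3E = 14 vs 13) and define the default unpaired
group as 3 female mild-LOAD, 2 female control and 4 male control donors so
that both the unpaired count (9) and the L3E sizes hold exactly. Similarly,
the Level-3 stratum sizes imply 22 female / 18 male paired donors, which the
simulator adopts.

## Differential model

Counts are NB: `y_ij ~ NB(mu_ij, phi_i)` with
`log mu_ij = log(N_j f_j) + x_j' beta_i`. The design contains an intercept,
the selected covariates (continuous covariates centered and scaled,
categorical ones indicator-coded), donor indicator blocks for the paired
Level-1 comparison, and the group indicator last. Columns that are linearly
aliased with earlier ones (e.g. donor-constant covariates inside donor
blocks) are pruned greedily by rank; if the group indicator itself is
aliased the run aborts.

GLMs are fit by Fisher scoring (IRLS) batched across peaks, with
step-halving on deviance increases, a linear-predictor clip at ±30, and
convergence at relative deviance change < 1e-8 or 50 sweeps; non-converged
peaks are flagged and get p = 1 rather than aborting the run.

Dispersion estimation maximizes the Cox–Reid adjusted profile likelihood
(APL) on a 19-point log-spaced grid over [1e-4, 10], with parabolic
interpolation around the grid maximum:

- **common**: argmax of the APL summed over peaks;
- **trended**: peaks are binned by mean log2-CPM (up to 20 equal-occupancy
  bins, at least ~50 peaks per bin) and each peak takes the argmax of its
  bin's mean APL — a local-likelihood trend on abundance;
- **tagwise**: argmax of `APL_i + (prior_df / df_residual) * APL_bin`, an
  empirical-Bayes compromise whose prior-df default is 10; `prior_df = inf`
  returns the trend exactly. All estimates are floored at 1e-6.

All-zero peak rows are excluded from estimation (warned, recorded) and
assigned the common value; the contrast runner additionally pre-filters
peaks with fewer than 10 reads total (configurable) — count-poor peaks
carry almost no information and destabilize the quasi-dispersion moments.

The quasi-likelihood F-test fits the full and the nested reduced design at
the **trended** dispersion, forms quasi-dispersions
`s2_i = deviance_i / df_residual`, moderates them with an F-distribution
moment fit (log-variance mean/variance matched via digamma/trigamma, the
trigamma inverse solved by Newton iteration), and refers
`F = (deviance drop / ddf) / s2_post` to `F(ddf, df_prior + df_residual)`.
This is a compatible re-implementation of the standard NB-QLF scheme for
sequencing count matrices; numerical parity with any specific external
package is not claimed — instead calibration is demonstrated by simulation
(global-null type-I error ≈ 4.5% at nominal 5%, zero BH q < 0.05
discoveries in ≥ 90% of null replicates; see `tests/test_acceptance.py`).
Multiplicity is controlled by Benjamini–Hochberg; "adjusted p" and "q" are
used interchangeably. Direction labels: positive case-vs-control log2FC is
"more accessible in case".

## Normalization

TMM factors follow the classic recipe: reference sample = the one whose
upper-quartile count fraction is closest to the cohort mean; per sample,
peaks with zero counts in either member of the pair are dropped, M (log2
ratio) and A (average log2 abundance) values are doubly trimmed (30% of M,
5% of A, both tails, rank-based), and the factor is `2**` of the
inverse-asymptotic-variance weighted mean of the kept M values, with all
factors rescaled to geometric mean 1. The implementation agrees with the
reference R implementation (edgeR `calcNormFactors`) to ~1e-6 on random
matrices (cross-checked in the test-suite) and with an independent
brute-force evaluation of the trim formula exactly. Log-CPM uses a prior
count interpreted per million of effective library
(`prior_j = prior * eff_j / 1e6`, default prior 0.5), which makes the
transform exactly invariant to a joint rescaling of counts and libraries.

## Sample QC

Library complexity from read-position multisets: NRF = distinct/total
reads, PBC1 = single-read positions / distinct positions, PBC2 =
single-read / two-read positions (infinity sentinel when no position has
exactly two reads). "Normalized peak calls" is interpreted as peak calls at
FDR q < 0.01 per million uniquely mapped reads; samples below 100 are
removed, and among replicates of a (donor, fraction) pair only the one with
the highest normalized peak calls is kept — the only quantitative
signal-to-noise proxy the QC table supports. Outlier screening projects
samples onto the top 10 PCs of the log-CPM matrix and cuts a Ward-linkage
dendrogram into k clusters (default 2), flagging clusters at or below
max(1, 5% of samples). scipy's Ward (Ward.D2 on observations) is used; the
alternative classic-Ward-on-squared-distances variant produces the same
partitions in every configuration the tests construct, and the 5% cluster
threshold is our operationalization of by-eye outlier removal.

## Covariate selection

Candidates are typed from the metadata (object/bool columns categorical,
others continuous) and flagged technical or biological. Each iteration runs
PCA (centering only, no unit-variance scaling — standard for count-derived
log matrices) on the current matrix, regresses each candidate on each of
the first 10 PC score vectors (t-test for continuous, one-way ANOVA F for
categorical; constant candidates get p = 1 with a warning), and declares
significance at the Bonferroni level `alpha / (n_candidates * n_pcs)`.
Among significant candidates the ranking is: technical first, then larger
`sum_PC[-log10(p) * variance_share]`, then fewer parameters, then name.
The selected variable is regressed out of the matrix (means preserved) and
the loop continues on the residuals — residualization is cumulative, which
matches recomputing the PCA "independent of the selected variables" — until
no candidate is significant or every candidate is used. Missing metadata
are imputed by median (continuous) / mode with lexicographic tie-break
(categorical), with imputed cells flagged; chained-equation imputation is
deliberately out of scope.

## GWAS-window enrichment and annotation

Windows are tag-SNP position ±100 kb on the printed coordinate scale,
clamped at zero. A differential site overlaps a window if they share ≥ 1 bp
(every published worked-example peak is fully contained in its window, so
the ≥1 bp and containment readings agree there; the criterion is
configurable). The permutation null draws the observed number of sites
uniformly **without replacement** from the peak universe (sites are
distinct peaks); the statistic is distinct regions hit (default) or
distinct sites overlapping; the empirical p-value is
`(1 + #{perm >= obs}) / (1 + n_perm)` so it can never be zero. Drawn peaks
are not matched on width or GC; matching is a possible extension.

Feature annotation is by fixed precedence promoter > first exon > 5' UTR >
3' UTR > intragenic > intergenic, with the promoter defined as the 1 kb
upstream of the strand-aware TSS (TSS base included); every peak receives
exactly one label.

## Synthetic-data generator

The generator emulates the statistical structure of the emulated cohort:

- **Peaks**: lengths log-normal with median 500 bp (sigma 0.5 on the log
  scale), truncated to [100, 5000] bp — typical ATAC peak widths —
  allocated to chromosomes (including chrX/chrY) proportional to size and
  placed with ≥1 bp gaps.
- **Cohort**: 40 paired + 9 unpaired donors as above; per-donor neuronal
  percentage drawn from the published group means/SDs (35.27 ± 13.26
  control, 38.59 ± 14.70 mild, 19.16 ± 7.49 severe), so severe cases show
  the expected neuronal loss; two donors get missing PMI by default.
- **Counts**: relative abundances are softmax-normalized so expected column
  sums equal the drawn library sizes (log-normal, default mean 1e5 at desk
  scale — the emulated studies sequence ~2e7 reads, and the default exists
  to keep simulations fast; it is configurable). Dispersion
  `phi_i = phi0 + decay / mean_i` (default 0.1 + 0), counts via the
  gamma-Poisson mixture. Planted effects: cell-type log2FCs on 20% of
  peaks, disease log2FCs on 2% per fraction, |log2FC| uniform on [0.5, 2]
  with random sign — the magnitude of LOAD effects on accessibility is not
  published, so this range is a package choice, not an inference.
- **Sex restriction**: non-neuronal disease effects apply at full strength
  in females and attenuated (default factor 0.3) in males — an interaction
  switch rather than a separate generator, reflecting that male glia show
  similar but weaker trends.
- **Confounding**: one latent technical factor per sample; each technical
  covariate is `loading * latent + noise` mapped onto its natural unit
  scale (sort date is a binned categorical), and the same latent factor
  enters the count log-means with per-peak N(0, `latent_effect_sd`) weights
  — so nonzero loadings make covariates genuinely associated with the
  leading count PCs, and confounding strength is monotone in the loading.
- **Complexity streams**: read-position multisets with an exact
  distinct-fraction or an explicit multiplicity profile.
- **GWAS regions**: a configurable fraction of the differential peaks get a
  tag SNP at their midpoint (window covers them); remaining regions are
  rejection-placed so their windows avoid all differential peaks.

All randomness flows through one seed with fixed per-component child
streams, so identical config + seed gives byte-identical outputs and
partial reruns are reproducible.

What the generator does **not** emulate: read-level data (no FASTQ/BAM, no
fragment-size or Tn5 insertion structure), GC- or width-dependent coverage
bias, spatially correlated peaks, LD structure around GWAS SNPs, or
zero-inflation beyond NB. Passing tests therefore demonstrate correctness
of the statistical machinery under the NB-with-confounding data-generating
process, not robustness to every artifact of real ATAC-seq libraries.

## Problem sizes and numerical choices

Simulation studies in the tests and acceptance script use 2,000-peak
universes, 10–30 samples per group, 20–100 replicates, and 10,000
permutations where the permutation test itself is under study — sizes
chosen so the full suite runs in well under a minute per study while
keeping Monte-Carlo error far below the tested margins. Tolerances: IRLS
convergence 1e-8 (relative deviance), dispersion grid [1e-4, 10] with 19
points plus parabolic refinement, dispersion floor 1e-6, BH as implemented
in statsmodels, empirical p always in (0, 1]. Tie-breaks are deterministic
everywhere (lexicographic sample ids for replicate filtering and imputation
modes, candidate names in covariate ranking).

## Known limitations

- No exact numerical parity with any external NB-QLF implementation is
  claimed; the scheme is calibrated by simulation instead.
- The replicate signal-to-noise rule and the 5% outlier-cluster threshold
  are declared operationalizations of qualitative published criteria.
- The enrichment null draws peaks uniformly; width/GC-matched draws are not
  implemented.
- Level-1 pairing is an additive donor block, not a random effect.
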