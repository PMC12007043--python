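# Methods

`droughtgwas` re-implements, as a tested reusable pipeline, the analysis
chain used to dissect drought tolerance in a rapeseed (*Brassica juncea*)
diversity panel: fuzzy-membership comprehensive evaluation of multi-
environment stress phenotypes, kinship-corrected genome-wide association
with SNP-to-QTL integration, windowed-Fst selective-sweep scanning,
weighted gene co-expression module detection, GWAS x module candidate-gene
intersection, and regional LD / haplotype analysis. A synthetic-data
generator with planted structure makes every stage exercisable and testable
at desk scale.

## Phenotype scoring (fuzzy-membership comprehensive evaluation)

For each accession, trait, stress treatment and environment the relative
trait value is TR = Xd / Xc, the ratio of the replicate-mean under stress to
the replicate-mean under control. A yield-like trait additionally yields the
drought tolerance index DI = (YD/YP) x (YD/YD_bar), where YD and YP are the
stress and control yields and YD_bar is the panel mean of YD. The printed
form of this index in the source literature is typographically ambiguous;
we default to the dimensionless reading above (which produces values on the
conventional 0.3-0.6 scale) and expose the literal alternative
DI = (YD/YP) x YD_bar behind `di_formula="literal"`. Neither reading is
asserted to be the original intent.

The per-treatment relative traits (averaged over environments) plus DI form
the indicator matrix. Standardized indicators are decomposed by PCA;
components are retained until cumulative explained variance reaches 85%
(configurable), the retained component scores are the composite indicators
X_i, and the contribution-rate weights are w_i = P_i / sum P_i with P_i the
explained-variance proportions, so sum w_i = 1 exactly. Each composite
indicator is rescaled by the min-max membership function
mu(X_i) = (X_i - X_imin) / (X_imax - X_imin), and the composite drought
tolerance score is D = sum_i mu(X_i) w_i, which lies in [0, 1] and is linear
in the membership vector.

Tolerance classes come from Ward/Euclidean agglomerative clustering of the
membership vectors cut at k = 3 clusters, ranked by mean D into tolerant /
medium / sensitive. The choice of linkage and metric was open (the source
analysis shows a dendrogram without naming either); Ward on memberships is
reproducible, order-independent and scale-coherent with the membership
normalization. Descriptive statistics use sample sd, adjusted Fisher-Pearson
skewness, bias-corrected excess kurtosis and CV = 100 sd / mean.

Whether the membership function was applied to raw relative traits or to
PCA scores was also open; we apply it to PCA scores (composite indicators),
the standard fuzzy-evaluation practice consistent with contribution-rate
weighting. Accessions with missing indicator cells are dropped with a
logged report by default (mean imputation behind a flag).

## GWAS (EMMAX-style mixed model)

Kinship is the VanRaden genomic relationship matrix built from mean-imputed,
frequency-centred dosages scaled by 2 sum p(1-p). The association model is
the two-stage approximation: variance components of
y = Xb + g + e, g ~ N(0, sg^2 K), e ~ N(0, se^2 I) are estimated once by
REML under the intercept-only null, profiling the ratio delta = se^2/sg^2 on
a log grid with Brent refinement in the eigenbasis of the projected kinship;
each SNP is then tested by generalized least squares with delta fixed, a
Wald t test on n - 2 degrees of freedom. With K = I this reduces exactly to
ordinary least-squares regression (verified to 1e-8 in tests). SNP filters
default to MAF >= 0.05 and call rate >= 0.9 (the source is silent;
community defaults), with mean imputation of missing genotypes.

Thresholds: Bonferroni 0.05/n or the suggestive line 1e-4 (-log10 p >= 4);
both appear in the source methods and results respectively, so both are
exposed and neither is privileged. SNPs significant in >= 2 environments
(matched by chrom+pos) are "co-detected". Significant SNPs sorted by
position are chained into QTLs: adjacent SNPs join the same QTL iff their
distance is <= 100 kb and their genotypic r^2 exceeds 0.35 (single-linkage
chaining; the published rule names pairwise distance/LD without a linkage
topology, and chaining is deterministic). Candidate genes are collected
from +/-100 kb windows around each significant SNP, clipped to chromosome
bounds, with >= 1 bp interval overlap (1-based inclusive). The candidate
tables in the source print +/-400 kb windows while its methods say 100 kb;
the flank is a parameter defaulting to the methods value.

## Selective sweep (Weir-Cockerham Fst)

Per-site variance components a, b, c follow Weir & Cockerham (1984) for two
populations of unequal size with heterozygote-aware diploid counts; the
per-site estimate is a/(a+b+c) and may be negative. Windows of 100 kb
advance in 10 kb steps anchored at position 1; the window statistic is the
ratio of sums (sum a / sum(a+b+c)) over informative SNPs in the window,
mirroring the windowed output convention of the common VCF Fst tools, with
the mean of per-site ratios also reported. Windows without informative SNPs
are removed before the genome-wide top-5% cut (ranking undefined values is
meaningless); whether the original cut was genome-wide or per-chromosome is
unstated, genome-wide is used. Flagged windows merge into maximal regions,
which are intersected with GWAS candidate windows (>= 1 bp overlap) and the
genes inside the intersection reported.

## Co-expression modules (WGCNA-style, single block)

Genes expressed below 1 FPKM in fewer than 3 samples are removed. Unsigned
adjacency |cor|^beta with soft power beta = 9 (signed variant available) is
transformed to topological overlap
TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), and
1 - TOM is clustered by average linkage. The dynamic tree cut is a
documented simplification of the published hybrid algorithm: branches are
split recursively while a child still holds >= 50 leaves (minimum module
size); sub-minimum children are shaved off; shaved genes are then rescued
into the module whose eigengene they correlate with best when |kME| >= 0.5
(the PAM-like stage); modules whose eigengenes correlate above 0.75 merge
iteratively. Labels follow the conventional colour sequence by decreasing
size, "grey" meaning unassigned. Module eigengenes are the first principal
component of the module's standardized expression, unit variance, sign-
aligned with the module mean profile. Module-trait relationships are
Pearson correlations against one-hot treatment indicators with exact
t-transform p-values and star codes at 0.05/0.01/0.001.

Note: the claim sometimes made that TOM_ij >= a_ij always holds is false
for the literal formula; random correlation-based instances violate it at
small magnitudes. We therefore verify the TOM against an independent loop
transcription of the formula rather than asserting dominance.

Differential expression is a declared simple stand-in for off-the-shelf
negative-binomial callers: Welch's test on log2(FPKM+1) with
Benjamini-Hochberg correction, flagging |log2FC| > 2 and q < 0.01 (the
source's two stated threshold sets disagree; the stricter results-section
set is the default and both are parameters).

## Integration and regional haplotype analysis

Candidate genes are genes lying inside a significant SNP's window AND
assigned to a module from the user-supplied significant-module list; rows
are re-verified by interval arithmetic before emission and one gene hit by
several SNP windows yields several rows. Allele-phenotype association
partitions accessions by genotype class (hom-ref / het / hom-alt; missing
reported separately, never tested); two testable classes use Welch's test,
three use one-way ANOVA, classes under 2 carriers are reported but
excluded. The test family was not named in the source; Welch/ANOVA is the
conventional choice for class-mean comparisons.

Regional analysis of a user-specified interval computes the pairwise
genotypic r^2 matrix and D' from EM-estimated two-locus haplotype
frequencies (only the double-heterozygote class is phase-ambiguous;
iteration cap 100, tolerance 1e-8, log-likelihood non-decreasing by
construction and asserted in tests). The regional association scan is
simple linear regression per SNP without a kinship term (the regional
tool's convention) flagged at -log10 p >= 2.5. Haplotypes are exact groups
of unphased genotype strings (0/0, 0/1, 1/1 per SNP; 0/0 = identical to the
reference genome); accessions with > 10% missing calls in the region are
excluded with a logged list, remaining missing calls must match exactly
(missing is not a wildcard), and groups are numbered Hap1, Hap2, ... by
descending carrier count with lexicographic tie-break. The haplotype x
tolerance-class table reports per-class counts, percentages and an
exclusivity flag.

## Synthetic-data generator

The generator emulates the panel the analysis assumes, at desk scale
(defaults: 200 accessions, 5,000 SNPs on four 10 Mb A/B-labelled
chromosomes, 1,500 gene models, 5 traits x 3 treatments x 3 environments x
3 replicates, ~500-gene expression matrix over 24 samples).

Genotypes: LD arises block-wise, not from coalescent simulation. Each
50 kb block carries two complementary core haplotypes; the alt core
segregates at a frequency drawn from the MAF range, founder haplotypes
(24 per block) are copies of a core with 5% per-site divergence applied to
majority-core founders only (so no site loses its minor allele), and each
accession draws two founders plus 2% per-allele mutation noise and 1%
missing calls. This yields within-block r^2 around 0.5-0.6 and near-zero
between blocks — sufficient for r^2-based QTL merging and haplotype
analysis, without recombination-map realism. Inside the planted sweep
region the two subpopulations (tolerant/sensitive) draw founders from
separate pools whose core frequencies are split by
d = 2 sqrt(Fst_target q(1-q)) around an intermediate q (recentred rather
than clipped when a bound binds; strongly differentiated regions segregate
mid-range by construction); one of an accession's two haplotypes may cross
pools with 5% probability, so admixed accessions are heterozygous carriers.
Swept blocks carry homogeneous (unmutated) founder haplotypes, the reduced
haplotype diversity characteristic of a swept region. Realized
between-group Fst tracks the target monotonically (approximately 0.17 /
0.52 / 0.83 realized at targets 0.1 / 0.4 / 0.8) and complete
differentiation (target 1.0) produces subgroup-exclusive haplotypes.

Phenotypes: each measurement is mean(trait, treatment) x environment
multiplier x (1 + cv (g + e)), cv = 0.25 matching the 25-35% CVs typical of
such panels. The standardized deviation partitions into planted-QTL
variance (effect_size), a genome-wide polygenic term built from 2,000
random-weighted standardized dosages (so the kinship correction has real
structure to absorb), and residual noise, honoring the heritability
(default 0.5). Stress multipliers default to CK 1.0, M 0.6, S 0.35
(germination-rate-like reductions); chlorophyll-like traits rise under
stress via 1 + 0.5(1 - multiplier). Under stress the tolerant
subpopulation's traits shift up and the sensitive subpopulation's down by
`group_stress_effect` (default 0.15) — the panel the analysis assumes
contains genuinely differentiated material, and without this term
tolerance classes would be pure noise. With heritability 0 all genetic
terms vanish.

Expression: each planted module is driven by one latent factor constructed
to have the requested in-sample correlation (default 0.8) with a binary
treatment indicator (modules cycle through the non-control treatments);
gene values are linear in the factor (baseline U(5,50) FPKM, 30% relative
amplitude, random loading sign, per-gene noise scaled by `noise_sd` = 0.5)
and clipped at zero, so a noiseless module is perfectly internally
correlated. Background genes (200 by default) are independent noise.

Annotation: genes are placed one per equal-width slot per chromosome at a
random offset, guaranteeing non-overlap; lengths U(500, 5000) bp, 1-based
inclusive coordinates.

What the generator does NOT emulate — and hence what passing tests do not
show about real data: realistic recombination and LD decay, allele-
frequency spectra from demography, genotyping error structure beyond
uniform missingness, multi-QTL architectures with dominance or epistasis,
count-based expression noise (values are Gaussian around a linear factor
model, not negative-binomial), batch effects, and any sequence-level
features. Results on this generator demonstrate algorithmic correctness
and calibrated behaviour of the statistics, not expected performance on a
particular real panel. In particular the published analysis's headline
counts (77 significant SNPs, 27 QTLs, 24/139/30 classes, 35 sweep regions,
54/35/43 modules, 11 candidate genes, 125 regional SNPs, 12 haplotypes)
derive from raw panel data that is not available and are not reproduction
targets here.

## Numerical choices and degenerate inputs

- REML profile on log10(delta) in [-6, 6], 25-point grid + bounded Brent.
- Eigenvalues of K clipped at 0; non-PSD beyond -1e-6 aborts.
- Monomorphic or low-call-rate SNPs are reported untested, never dropped
  silently; sites monomorphic across both Fst groups carry a zero
  denominator and are excluded from window sums.
- Classification ties (all D equal) are flagged degenerate, not an error.
- Membership with max = min for an indicator aborts naming it.
- EM D' caps at 100 iterations, tolerance 1e-8 on frequencies.
- Problem sizes in tests and the acceptance script (200 x 5,000 GWAS,
  500-gene networks, 1,000-SNP sweep panels, 5 seeds per recovery suite)
  were chosen as the smallest scales at which the planted effects are
  comfortably detectable; they are the package's study-scale defaults.

## Known limitations

- Single-block co-expression only; very large gene sets would need
  blockwise partitioning.
- The simplified dynamic cut is not label-for-label compatible with the
  published hybrid tree-cut algorithm; recovery of planted structure, not
  parity, is the design goal.
- No population-structure PCs as fixed covariates; the kinship random
  effect is the only structure correction, as in the emulated analysis.
- Functional consequences of SNPs (missense/synonymous) are consumed from
  user tables, never computed (no CDS models in scope).
- No plotting; all outputs are flat tables suitable for external plotting.
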