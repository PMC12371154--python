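# Methods

## The detection problem

A dominant, hemizygous supergene haplotype produces a genomic segment
present in every S-morph individual (one copy) and in no L-morph individual.
The package localizes such a segment from two independent signals — read
coverage and genotype association — and characterizes it with LD,
molecular-evolution, repeat-enrichment and phenotype statistics. All
analyses are frequentist and assume unrelated (or family-pooled) individuals
with known morph labels; no kinship or structure correction is applied, and
the association stage is a plain case/control contrast.

## Variant-level filters (`io`)

Calls with depth < 5 or > 200 are set missing; sites with QUAL < 20 are
removed; sites where fewer than 90% of genotypes remain called are removed.
The missingness convention ("0.9") is ambiguous in common tooling; here it
is read as *keep sites with called fraction ≥ 0.9* and is configurable
(`FilterConfig.min_called_frac`). Heterozygous calls whose alt-read fraction
f = AD_alt/(AD_ref+AD_alt) falls outside the closed interval [0.2, 0.8] are
set missing (f exactly at a bound passes); homozygous calls are never
touched. Filters only remove sites or set calls missing — they never alter
a called dosage — and are idempotent. Coordinates are 0-based half-open
internally; VCF positions are converted on ingest. Repeat masking is
accepted as a pre-supplied BED exclusion track.

## Coverage scan (`covscan`)

Windows are fixed tiles (default 300 kb, half-open); a terminal tile shorter
than half the nominal size is kept but excluded from testing, since its
count is length-confounded. Normalization is counts/total-reads × scale; the
scale constant is arbitrary (units of "normalized coverage" are only
meaningful relative to the genome-wide median) and configurable.

Each tested window gets a two-sample Fisher–Pitman permutation test: the
statistic is the raw absolute difference of group means (equivalent
ordering to the t statistic under label permutation, stated explicitly for
reproducibility), two-sided because the recessive-specific signal requires
detecting S < L as well as L < S. When C(n, n_S) ≤ 100 000 the label
assignments are enumerated exactly and p is the exact proportion; otherwise
a Monte-Carlo estimate with the add-one rule p = (1+b)/(1+m) is used, which
cannot report 0 and differs from the plain b/m by ≤ 1e-6 at m = 10⁶. Inside
`hemizygosity_scan` the Monte-Carlo path shares one permutation matrix
across the windows of a scan: each window's p-value remains marginally
valid (the permutations are uniform and independent of the data), only the
joint dependence across windows changes, which Bonferroni correction does
not rely on. Bonferroni runs over all tested windows genome-wide (the
correction scope is a choice; per-contig correction would be less
conservative), and a window is significant iff p·n_windows ≤ α (default
0.01). When the permutation floor (2/C(n, n_S) exact, 1/(1+m) Monte-Carlo)
exceeds α/n_windows the scan warns that no window can reach significance at
that sample size.

Significant windows are classified against the genome-wide median m of
normalized coverage over all samples and tested windows: `S_hemizygous` if
median_L < 0.1·m and median_S ≥ 0.5·m; `recessive_specific` if
median_S/median_L ∈ [0.35, 0.65] (one copy vs two); otherwise `other`.
Adjacent same-class windows merge into regions. The 0.1/0.35/0.65 bounds
are loose by design — the biological contrast (≈0 vs ≈1, or ≈0.5 vs 1) is
extreme — and are parameters. Windows straddling a region boundary dilute
their signal and typically classify `other`; detected region edges are
therefore accurate to about one window.

## Association scan (`assoc`)

Sites with any missing call or minor allele frequency < 0.05 (computed on
called alleles) are removed; monomorphic sites go with them. LD pruning
guarantees that no surviving pair of variants closer than 50 kb has
dosage-r² > 0.2; conflicts are resolved greedily from the highest r²
down, dropping the lower-MAF member (tie: the downstream variant). This is
implemented over all close pairs directly rather than by sliding windows,
so the guarantee holds for every 50-kb interval regardless of chunking.

The per-SNP test dichotomizes samples as carriers (≥ 1 copy) of the
*minor* allele — minor defined per-site on the analyzed cohort, ties at 0.5
resolved toward the alt allele — and applies the two-sided Fisher exact
test (classical sum-of-extreme-tables rule, no mid-p) to the carrier×morph
2×2 table. With n_S = 11 and n_L = 7 the smallest attainable p (perfect
separation) is 1/C(18,7) ≈ 3.14×10⁻⁵. FDR control is Benjamini–Hochberg;
the significance threshold is a per-run parameter (0.05 or 0.01 are typical
choices depending on the analysis).

## LD (`ldscan`)

r² is the squared Pearson correlation of genotype dosages (composite LD):
the data are unphased, so haplotype-EM r² is not computed, and values can
differ slightly from phased r². The window-pair matrix uses all SNP pairs
with one member in each 100-kb window, subsampled (seeded) above
`max_pairs_per_cell` = 10 000 — medians are robust to subsampling. Cells
without pairs are empty (NaN). The target-vs-control contrast pools the
non-empty cell medians of each matrix into a two-sided Wilcoxon rank-sum
test (exact null when n₁·n₂ ≤ 10 000 without ties, otherwise normal
approximation with midrank-tie and continuity corrections). Cell medians
within a matrix share SNPs and are therefore positively dependent; the
Wilcoxon p is anti-conservative to that extent and should be read as a
descriptive contrast, which is how it is used.

## Molecular evolution (`molevo`)

NG86 counting: per codon, each position contributes
(synonymous single-base changes)/(single-base changes not creating a stop)
to the synonymous site count s, with n = 3 − s; sites are averaged over the
two sequences. Codon pairs differing at k > 1 positions average their
synonymous/nonsynonymous difference split over all k! mutational pathways
that avoid stop-codon intermediates; a pair connected only through stops is
excluded from both difference *and* site totals. Columns with a gap,
ambiguity code or stop codon in either sequence are dropped pairwise.
Proportions pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3), undefined (saturated) at p ≥ 3/4; ω = dN/dS is
undefined when dS = 0. Stop-codon handling matches the common MEGA-style
convention and is the main source of possible small discrepancies with
other NG86 implementations. Standard errors come from a seeded codon
bootstrap (B = 1000 by default; saturated replicates dropped and counted,
SE undefined when more than half saturate).

The strict clock is t = dS/(2μ) with μ in substitutions/site/year (default
7×10⁻⁹, a standard plant spontaneous rate); the SE propagates linearly.
Times print in Ma at one decimal. The LRT consumes log-likelihoods (or a
direct statistic) from external branch-model fits: statistic
2(lnL_alt − lnL_null) against χ²_df via the regularized incomplete gamma.
Maximum-likelihood branch-model fitting itself is a deliberate scope
boundary — only the test arithmetic lives here. Closest paralogs are
assigned by minimum pairwise NG86 dS (ties: lower dN, then id), replacing
graph-based orthology inference with a rule sufficient for within-genome
paralog dating.

## Repeat enrichment (`enrich`)

Per class, intervals are union-merged, intersected with the region, and
compared with the background = genome minus the region (so the region does
not contaminate its own null). In `bp` mode each region base pair is a
Bernoulli trial with p₀ = background class fraction; the p-value is the
exact two-sided binomial (sum of point probabilities ≤ observed) and
log₂FE = log₂((x/n)/p₀). Treating base pairs as independent trials ignores
the spatial autocorrelation of repeats, making p-values anti-conservative;
an `elements` mode (each annotated element a trial, success = midpoint in
region) is provided as a cruder but less autocorrelated alternative. The
effect size log₂FE is the primary readout.

## Phenotype statistics (`pheno`)

Organ lengths are modeled by sequential (Type-I) two-way ANOVA with morph
entered first, then treatment, then morph×treatment, F against the residual
mean square. For near-balanced designs Type-I and Type-III agree closely;
the sequential convention matches the default of standard linear-model
software. A constant response reports F and p as NA. Post hoc comparisons
use Tukey HSD on the morph×treatment cells: studentized-range quantile
q(0.95; k, df_res) (scipy's studentized_range distribution), Tukey–Kramer
standard error √(MSE/2·(1/nᵢ+1/nⱼ)) for unequal cells, adjusted p from the
same distribution. Style-cell lengths are averaged per flower section (10
cells per section) before modeling and log-transformed; the cell model adds
style section (bottom/middle/top) as a predictor and includes the
morph×treatment interaction by default (flag to drop it). Repeated flowers
per individual are treated as independent — a pseudo-replication caveat
carried over deliberately from the fixed-effects design this reproduces.

## Synthetic data (`sim`)

The generators emulate the statistical structure the analyses assume, not
sequence-level realism:

- **Genotypes.** Allele frequencies ~ Beta(0.8, 0.8) truncated to
  [0.05, 0.95]; Hardy–Weinberg sampling, morph-independent. LD comes from
  block-copying (each SNP copies a per-block template genotype with
  probability 0.9 per sample), not from a coalescent — sufficient to
  exercise r² and pruning code, but without realistic allele-frequency /
  LD joint structure or recombination maps. The designated associated SNPs
  are heterozygous in every S-morph sample and absent in L-morph samples —
  the deterministic signature of a dominant hemizygous haplotype.
- **Coverage.** Negative-binomial window counts (dispersion 30) around a
  per-sample lognormal depth factor; the hemizygous region drops L-morph
  means to 5% of baseline (residual mismapping rather than exact zero); a
  recessive-specific region halves the S-morph mean. Defaults: 300-kb
  windows, baseline normalized coverage 15, cohorts of 11 S + 7 L (the
  genotype default) or as supplied.
- **Presets.** Region sizes 260 kb / 1.2 Mb / 3.8 Mb (`tenue`,
  `grandiflorum`, `perenne`) centered on a contig 8× the region size, plus
  an equal background contig, all multiplied by `--scale`; the supergene
  contig gets contig-wide LD blocks (recombination suppression), the
  background contig 20-kb blocks.
- **Codon pairs.** Each codon evolves independently on the 61 sense codons
  under a symmetric CTMC (synonymous single-base changes rate 1,
  nonsynonymous rate ω, stop targets excluded); endpoint sampling via the
  matrix exponential, half the divergence on each branch from a uniform
  (stationary) ancestor. Total time is scaled so the expected number of
  synonymous events per NG86 synonymous site equals the target dS; with
  equal codon frequencies and no transition/transversion bias this is
  exactly the regime in which NG86 is approximately unbiased, and recovery
  runs confirm mean dS within ~1% and mean ω within ~3% of truth at
  dS = 0.3, ω = 0.3 (2000 codons).
- **Repeats.** Elements occupy non-overlapping fixed-length slots so the
  covered proportion equals the nominal density without union shrinkage;
  the enriched class's density is multiplied by `fold` inside the region.
- **Phenotypes.** length = baseline(morph) + effect(morph)·1[treated] +
  N(0, σ). Defaults: style baselines 4.0 (S) / 7.0 (L) mm, treatment effect
  0.82 mm in the S-morph and 0 in the L-morph, σ = 0.5 mm, 12 flowers per
  design cell; the cell-length generator uses a 12.6 μm S-morph effect with
  bottom/middle/top section factors and within-section cell scatter.

Passing tests on these generators demonstrate that the *statistical
machinery* is correct and calibrated (type-I control, power at the stated
effect sizes, estimator recovery); they do not validate robustness to
mapping artifacts, batch effects, population structure or reference bias in
real data.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script use reduced but adequate
sizes chosen for tight Monte-Carlo error at interactive runtimes: coverage
scans on 10-Mb contigs with 15+15 samples and 10⁴ permutations per window
(20 signal replicates, 50 null replicates), estimator recovery over 200
pairs of 2000 codons, LD contrasts on 1-Mb contigs, phenotype power and
coverage over 50–120 replicates. Permutation p-values use the add-one
estimator; exact enumeration replaces Monte Carlo whenever the assignment
count is ≤ 10⁵. Ties in LD pruning and closest-paralog selection break
deterministically (position, then id). All randomness flows through
`numpy.random.default_rng` seeds; pipeline stages derive their seeds from
the global seed plus a CRC of the stage name, so stages are individually
reproducible.

## Known limitations

- No kinship/structure correction in the association scan; families are
  treated as case/control pools.
- Composite (dosage) r² rather than haplotype r²; LD contrast p-values are
  descriptive under cell dependence.
- Base-pair binomial enrichment ignores repeat autocorrelation (see above).
- The NG86 estimator saturates near p = 3/4; saturated distances are
  reported as undefined rather than extrapolated.
- The coverage scan assumes read counts are exchangeable across morphs
  under the null within a window; strong GC or batch effects correlated
  with morph would violate this.
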