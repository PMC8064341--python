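# Methods note

This note records the statistical models, default parameters, numerical
choices and known limits of `eigensweep`. Everything here is the package's
own design; where a choice departs from common practice, the reason is given.

## Data model

Genotypes are biallelic and inbred/haploid-coded: one allele per call,
`0`/`1` plus a missing sentinel (`NA` on disk). Markers are typed `PAV` or
`SNP` (both biallelic). The chromosome universe defaults to the 14 A/B-genome
chromosomes of tetraploid wheat (1A–7B). Sample metadata carries an era label
(`landrace`/`modern`), an optional subpopulation label (`SP1`…, `admixed`)
and numeric covariates such as heading date.

## Marker QC (`qc`)

Four-stage filter chain, applied in order, each marker recorded with its
first failing reason:

1. **unmapped** — no genetic-map position;
2. **high_missing** — SNPs with missing rate > 0.30 (PAVs are exempt:
   absence is a legitimate PAV state, so a missing-rate rule for them would
   confound genotype with missingness);
3. **low_maf** — minor-allele frequency < 0.05 (monomorphic and all-missing
   markers fall here);
4. **duplicate** — identical call patterns. Two markers are duplicates when
   they agree at every jointly non-missing sample *and* the joint coverage is
   ≥ 0.90 of the panel. Drop policy: in a PAV/SNP pair the PAV is dropped; in
   a same-type pair the member with more missing data (ties broken toward the
   lexicographically larger id).

Per-marker PIC uses the Botstein formula `he − 2p²q²` (cap 0.375); gene
diversity `he = 1 − p² − q²` (cap 0.5) is reported alongside because
biallelic panels are summarised with either statistic.

*Limit*: the duplicate rule interacts with missingness. A duplicate that
inherits its original's ~10% missing pattern sits exactly at the 0.90 joint
-overlap boundary, so at the default simulated missing rate roughly a fifth
of planted duplicates legitimately escape the filter. This is a property of
the declared rule, not a bug; the filter is exact when missingness is low.

## Diversity and gene flow (`diversity`)

Nei's decomposition per locus with **unweighted** group means: the pooled
frequency is the simple mean of group frequencies, `H_T = 1 − p̄² − q̄²`,
`H_S` the unweighted mean of within-group `1 − p² − q²`, `D_ST = H_T − H_S`,
`G_ST = D_ST/H_T`, and `Nm = 0.5(1 − G_ST)/G_ST` computed from the
*unrounded* `G_ST`. Unweighted means keep `G_ST` insensitive to unequal
group sizes. `G_ST ≤ 0` is reported with an infinite-`Nm` flag rather than a
number. Pairwise decompositions exclude admixed samples.

## LD decay (`ld`)

`r²` is the squared Pearson correlation of 0/1 call vectors over jointly
non-missing samples, for every within-chromosome pair at map distance
≤ 50 cM, pooled per genome (A vs B). Pairs with < 10 joint samples are
skipped and counted. Significance uses the haploid χ² approximation
`χ² = n·r²` (1 df).

The decay distance is the first 0.01-cM grid point where a LOESS fit
(statsmodels `lowess`, `it=0`, `delta = 0.002 × range`) drops to the
genome-wide mean `r²`. **Span calibration**: the default span of 0.1 was
fixed by simulation against a closed-form oracle, not against any test. The
haplotype-copying generator plants `corr(x_i, x_j) = exp(−d/τ)`, so
`E[r²](d) ≈ exp(−2d/τ) + (1 − ρ²)²/n`, whose crossing with its own mean is
solvable by root-finding (`theoretical_ld_decay`). A span sweep gave
recovery ratios (estimate/planted) of 1.74 at span 0.5 but mean 1.04 with
range [0.96, 1.16] at span 0.1 over 20 seeds; 0.1 was frozen before the
recovery test was written.

The hotspot clustering window is the larger of the two per-genome decay
distances rounded **up** to 0.5 cM, with a 0.5 cM floor.

## Ordination (`ordination`)

Simple-matching distance `d = 1 − matches/joint` over jointly non-missing
markers; a pair with zero joint coverage is a hard error. PCoA is Gower
double-centering of `−½d²` followed by a dense symmetric eigendecomposition;
negative eigenvalues (the simple-matching distance is not guaranteed
Euclidean) are excluded from the percent-variance denominator and from the
usable axes. Axes are oriented so the landrace-era mean is positive, making
signs reproducible. Eigenvector phenotypes are the top-k axes standardised
to zero mean/unit (population) variance. The implementation is ~15 lines and
is cross-checked against `scikit-bio`'s PCoA in the test suite.

## eigenGWAS mixed model (`gwas`)

For each eigenvector phenotype `y`: `y = Xβ + Zu + e` with
`u ~ N(0, σ²_g K)`, VanRaden kinship `K = MMᵀ / Σ2p(1−p)` (PSD-clipped),
fixed effects = intercept + optional covariates + the leading genotype PCs
(default 6). Variance components by EMMA-style spectral REML in
`δ = σ²_e/σ²_g` (grid on log δ ∈ [−8, 8] plus bounded refinement), estimated
once on the null model and reused for every marker (P3D). Per-marker tests
are vectorised GLS via Frisch–Waugh residualisation with an F-test
(df = n − p − 1); missing calls are mean-imputed for the scan only.
`p3d=False` re-estimates δ per marker for verification. At `K = I` the model
collapses to OLS exactly; the suite asserts p-value agreement to 1e−8.

**Collinearity guard (deviation by design).** The phenotypes here are
eigenvectors of (almost) the same matrix whose PCs serve as fixed effects.
Under the linear simulator each eigen-phenotype is numerically identical
(R² > 0.999) to one genotype PC, so the textbook PCA+K design regresses the
response on itself and silently removes every signal (sweep sensitivity 0).
`mlm_scan` therefore drops, per trait, any fixed-effect PC whose absolute
correlation with that trait reaches 0.95; the exclusions are recorded in
`scan.attrs["pcs_used"]`. With the guard, sensitivity on the default
simulation is 1.0 across seeds. Set `collinearity_guard=None` to restore the
unguarded design.

Thresholds: a "moderate" line at −log₁₀p = 3 defines MTAs; the FDR line is
Benjamini–Hochberg at α = 0.05 pooled across all marker × eigenvector tests
(−log₁₀ of the largest rejected p, +∞ when nothing passes).

## Hotspots (`hotspots`)

Per chromosome, MTAs sorted by position; a gap strictly greater than
2 × decay window starts a new cluster (equivalent to single-linkage
transitive closure in 1-D, verified against brute force in the suite).
Clusters with ≥ 2 MTAs become hotspots `eigenQTL<chrom>.<idx>` with
confidence interval `[min − decay, max + decay]` clipped at 0; the rest are
singletons. Unmapped MTAs are a hard error, not silently dropped.

## Sweep labelling (`sweeps`)

Top markers: best −log₁₀p across eigenvectors strictly > 5. The panel is
split by the sign of PCoA axis 1 recomputed on the top markers only, with
the landrace-majority side as group 2. A marker is labelled a sweep when the
two groups' **major alleles differ** and **both** major-allele frequencies
are ≥ 0.80 (inclusive). Groups with no calls at a marker are flagged and
fail. The package bundles a published per-group frequency table for a
Mediterranean durum landrace/cultivar panel as the worked example for the
rule (35 of 35 rows pass at 0.80).

*Limit*: at the default simulated sweep contrast (δ = 0.7 between block
means) group-major frequencies often land below 0.8 after admixture and
drift, so the rule labels few or no simulated markers — the rule working as
specified. Enrichment tests plant δ = 0.85.

## Synthetic panel (`simulate`)

Balding–Nichols: ancestral `p ~ U(0.05, 0.95)`; subpopulation frequencies
`Beta(p(1−F)/F, (1−p)(1−F)/F)` with F = 0.05 across 5 subpopulations
(70 samples each) plus 50 marker-wise 50/50 admixed samples; 5000 markers on
14 × 152 cM chromosomes. Sweeps are planted as **clustered regions** (20
markers in clusters of 4 within ~1 cM): hotspot calling requires ≥ 2 MTAs
within the clustering window, so isolated planted sweeps could never be
recovered as hotspots — and swept haplotypes carry several linked markers in
real data. Sweep markers get an exact frequency separation of 0.7 between
the landrace block (SP1–3) and the modern block (SP4–5). Nuisance structure:
10% MCAR missingness on 30% of markers, 1% exact duplicates (`_dup`
suffix), 2% unmapped markers, and a heading-date covariate
`45 + 8·marker + N(0, 2)` tied to one marker.

*Limits*: markers are generated independently given the subpopulation
frequencies (no background LD — within-chromosome LD in the panel comes from
structure only), inheritance is haploid/inbred with no residual
heterozygosity, and missingness is MCAR rather than platform-structured. The
separate haplotype-copying generator exists precisely because the main panel
has no planted LD to recover.

## Pipeline (`pipeline`)

Stage order: qc → diversity → ld → ordination → gwas → hotspots → sweeps.
Every stage writes TSVs plus a `manifest.json` with SHA-256 hashes, the
normalised configuration and headline numbers, so a run is reproducible from
the manifest alone. Simulated runs additionally report recovery against the
generating truth (sensitivity = fraction of planted sweep markers inside any
hotspot CI on their chromosome; false-hotspot rate; `G_ST` error).
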