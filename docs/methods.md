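# Methods

This note documents the models, estimators and numerical conventions of
`tilarray`, and the design choices made where more than one defensible
convention exists.

## Discovery-side filtering of pooled variant calls

A Pool-Seq experiment estimates allele frequencies from read counts over
pooled DNA. Each candidate SNV carries per-pool depth and alternate
observations plus site evidence (strand split of the alternate support,
counts of reads placed to either side, properly-paired fractions). The
filters are deterministic predicates:

* **call support** — pass iff total alternate reads ≥ 3 *or* any single
  pool's alternate frequency > 0.02. Both thresholds are exposed
  (`min_alt_reads`, `min_pool_af`); the frequency comparison is strict.
* **interference** — a variant is removed iff another variant (of any
  type, including indel and multiallelic records excluded at load time)
  lies on the same sequence at distance `0 < |Δpos| < 40` bp. Removal is
  symmetric: both members of a close pair go, since neither has a clean
  flanking sequence for probe design. Implementation is a sorted
  neighbour scan, contract-tested against the all-pairs definition.
* **site quality** — summed-across-pools depth within [50, 150]
  (inclusive bounds; the summed convention reflects joint calling over
  the pools, a per-pool mode is available), ≥ 1 alternate read on each
  strand, ≥ 2 reads placed on each side of the site, and strictly more
  than 90 % properly-paired support for both the alternate and reference
  observations. Every failed clause is reported, not only the first.

Boundary semantics throughout: "at least n" is ≥, "above x" / "more than
x" is >, "within less than w" is strict <. A pair at exactly 40 bp
separation survives; a paired fraction of exactly 0.90 fails.

The pool-averaged minor allele frequency is the unweighted mean of
per-pool alternate frequencies over pools with nonzero depth, folded to
`min(f, 1−f)`.

## Array assembly

Candidates are classified against a GFF3 annotation with precedence exon
> intron > near-gene > intergenic, where near-gene means within 1,000 bp
(inclusive) of a gene boundary on either side, strand-ignored. Tiers are
filled in order:

1. a verbatim list of sex-associated markers;
2. candidates present in ≥ 1 external panel (positional match; allele
   matching optional). These bypass the MAF window — they were validated
   elsewhere — but still require a viable probe (class `recommended` or
   `neutral` on at least one strand) and a non-ambiguous allele pair;
   both requirements are flags;
3. exonic candidates passing the probe gate, the A/T–G/C exclusion
   (ambiguous pairs need two probes on the platform) and the MAF window
   [0.05, 0.45] (inclusive bounds; the upper bound guards against
   collapsed paralogues that masquerade as ~0.5-MAF SNPs);
4. spaced markers: non-overlapping 10-kb windows anchored at coordinate 1
   on every eligible sequence (all chromosomes plus the 130 longest
   scaffolds by default; the anchor is a convention — the final partial
   window is retained), each contributing its highest-MAF within-gene or
   near-gene candidate. MAF ties break by smallest position, then
   lexicographic allele pair, making the selection a pure function of its
   input. The remaining budget is filled greedily: repeatedly locate the
   1-Mb tile with the fewest selected markers that still holds an
   unselected eligible candidate (ties by sequence name, then start) and
   add its best candidate.

A candidate qualifying for several tiers is counted once, in the highest
tier. Re-running the assembly on its own output reproduces it unchanged.

## Probe-set classification and validation QC

With genotype calls only (no raw intensities), probe-set classes are
assigned per SNP in precedence order: call rate < 0.97 →
`CallRateBelowThreshold`; a single observed genotype class →
`MonoHighRes`; heterozygotes but no minor homozygote → `NoMinorHom`; all
three classes (subject to a heterozygote-excess cap, default off) →
`PolyHighResolution`; anything else → `Other`. The Off-Target Variant
class of intensity-based pipelines cannot be derived from calls — OTV-like
markers land in `Other`, and the classification is documented as
call-based, not a re-implementation of an intensity clustering workflow.

Matrix QC retains `PolyHighResolution` SNPs with call rate strictly
> 0.95, then samples with call rate strictly > 0.90, then re-checks SNP
call rates once on the reduced sample set. Identity-by-state between two
samples is the mean over co-called SNPs of `1 − |g_i − g_j|/2`; pairs
above 0.80 are resolved by dropping the later-indexed sample, processing
pairs in descending-IBS order. LD pruning is the standard greedy
keep-first scan: within a chromosome a SNP is dropped when its dosage r²
with any retained SNP within 500 kb exceeds 0.7 (the window is a
conventional choice; `window_bp=None` gives the exact all-pairs mode).

## Diversity statistics

Per SNP, Ho is the fraction of called genotypes that are heterozygous
and He is 2p̂(1−p̂) at the sample allele frequency; population values are
unweighted means over SNPs with ≥ 1 call, without a small-sample
correction (one is available by flag). Bootstrap CIs are percentile
intervals from resampling SNPs, the natural unit for a genome-wide,
per-population statistic; the experiment in the acceptance script
verifies 92–98 % empirical coverage at nominal 95 % when SNPs are iid
draws from a frequency spectrum. MAF categories are Common (≥ 0.3),
Intermediate ([0.1, 0.3)), Low ([0.05, 0.1)), Rare ((0, 0.05)) and Fixed
(= 0): boundary values deliberately land in the higher-MAF class, and a
marker is "informative" in a strain when its sample MAF exceeds 0.

## LD decay and the relatedness correction

Plain LD between two SNPs is the squared Pearson correlation of dosage
vectors over co-called samples. Small samples of related individuals
inflate r², so a corrected statistic r²_vs is provided: dosages
(mean-imputed) are whitened by the inverse Cholesky factor of a VanRaden
genomic relationship matrix `G = ZZ'/(2Σp(1−p))`, then centred at the
generalised-least-squares mean (projection on the whitened one-vector)
and correlated. The GRM of centred dosages is singular along the
one-vector; a relative ridge (1e-8 of the mean diagonal, escalated on
failure) makes the factorisation stable, and the GLS projection removes
the inflated null-direction component. The correction's contract —
enforced at 1e-10 in tests — is that an identity kinship reproduces plain
r² exactly. Numerical parity with any specific external implementation
of structure-and-relatedness-corrected LD is not claimed.

Decay curves assign a pair at distance d to bin `floor((d−1)/10,000)`,
average r² per bin within each chromosome, then unweighted across
chromosomes (a pooled mode exists); empty bins are reported empty (NaN),
not zero. The percentage drop between the near (10 kb) and far bin is
`100·(r²_near − r²_far)/r²_near` and may be negative.

## Structure PCA and Tracy–Widom testing

Dosages are mean-imputed per SNP, centred, and scaled by √(p̂(1−p̂))
(Patterson normalisation); monomorphic SNPs are dropped. The sample
covariance `XX'/n_snps` is eigendecomposed; coordinates are eigenvectors
scaled by √λ with the sign convention that each component's
largest-magnitude entry is positive. Leading eigenvalues are tested
sequentially: with m' eigenvalues remaining, the top one is standardised
using an effective marker count estimated from the spectrum's dispersion,
`n' = (m'+1)·S1²/(m'·S2 − S1²)` (a moment estimator that absorbs LD
between markers), and Johnstone's half-integer centring,

    l = m'·λ₁/S1,  μ = (√(n'−½) + √(m'−½))²/n',
    σ = (√(n'−½) + √(m'−½))/n' · (1/√(n'−½) + 1/√(m'−½))^(1/3),

and `(l−μ)/σ` is referred to the Tracy–Widom TW1 distribution. Testing
stops at the first component with p ≥ 0.05. TW1 is evaluated through the
shifted-gamma approximation (shape 46.446, scale 0.186054, shift
9.84801), which matches the exact distribution to ~1e-3 — tighter than
interpolating a sparse percentile table — and reproduces the published
critical values 0.9793 / 2.0234 / 3.2724 at 95/99/99.9 %. On null panels
(50 samples × 500 independent SNPs) the empirical type-I error at
nominal 5 % sits near 0.03, within the accepted [0.02, 0.08] band.
Admixture-style ancestry estimation is out of scope.

## The synthetic-data generator

The generator defines the study conditions and is itself tested code.

* **Annotation** — genes placed uniformly without overlap (2–20 kb, 1–5
  exons partitioning alternating exon/intron blocks), `gene_density` per
  Mb; placement failure after bounded retries is an explicit error.
* **Pooled calls** — two pools of 50 diploids; a combined ~90X site depth
  split between pools proportional to pool size, per-pool alternate
  counts binomial at the true allele frequency (no sequencing error by
  default; an error rate is a config knob). Clean sites are drawn to
  satisfy every QC clause; a configurable fraction of sites violates
  exactly one recorded clause each, which makes truth-vs-filter confusion
  matrices exact by construction. Interference violations get a partner
  SNV 1–39 bp away; all other sites keep > 80 bp clearance. The combined
  (not per-pool) reading of the ~90X design depth is what makes the
  50–150X coverage window meaningful for jointly-called pools; at
  configured depths outside that window the clamp is bypassed so
  depth-scaling studies (frequency recovery at 10⁴ reads per pool) work.
* **Genotype panels** — per population, SNP frequencies follow the
  Balding–Nichols model, Beta(p(1−F)/F, (1−p)(1−F)/F) around the
  ancestral frequency p with differentiation F; F = 0 keeps p. It is the
  standard F-model and makes heterozygosity and PCA expectations
  analytic. Haplotypes are latent-Gaussian AR(1) processes thresholded at
  Φ⁻¹(p): the latent correlation between adjacent markers is
  `exp(−ld_rho·distance)`, giving exact Hardy–Weinberg marginals with
  monotone distance-decaying LD. Note `ld_rho = 0` therefore means *no
  decay* (complete correlation along a chromosome), and large `ld_rho`
  means independent SNPs. The default `ld_rho = 5e-5`/bp puts the
  corrected near-bin (10 kb) mean r² near 0.2 with a far-distance floor
  around 0.07 at 15 samples — the magnitudes typical of domesticated
  tilapia lines. Missingness is injected per sample and per SNP.
* **Panels and scores** — each external panel takes an independent
  Bernoulli(`overlap_fraction`) subset of candidate positions plus decoy
  positions absent from the candidates; the probe-score table draws two
  classes per candidate from the four-level vocabulary
  (recommended/neutral/not_recommended/not_possible, default probabilities
  0.55/0.25/0.12/0.08).

All randomness flows from `SimConfig.seed` through salted child
generators, so identical configurations give byte-identical files.

What the generator does **not** emulate: read-level artefacts (mapping
error, reference bias, PCR duplicates), indel/multiallelic genotypes
beyond positional decoys, coalescent genealogies (LD is first-order,
without long-range haplotype structure), genotype-calling intensity
noise, and ascertainment of the marker panel itself. Passing tests
therefore demonstrate correctness of the estimators and selection logic
under the stated models, not robustness to raw-data pathologies.

## Problem sizes and numerical conventions

Test and acceptance experiments run at desk scale, chosen to keep Monte
Carlo error well inside the tested bands: 1,000-site variant sets for
filter confusion matrices; 100 random marker sets for the selection
oracle; 1,000-marker, 50-sample panels for LD decay shape; 500 panels ×
1,000 bootstrap replicates for CI coverage; 200 null replicates (50 × 500)
for the Tracy–Widom calibration; 15-samples-per-population, 2,000-SNP
panels at F_ST = 0.2 for the separation check. Percentages in reports are
computed by exact decimal arithmetic with half-away-from-zero rounding
and are always recomputed from counts. Two percentage styles printed in
the published platform report (0.5 % and 0.2 % for the MonoHighRes and
OTV classes) are inconsistent with any single rounding rule and are not
reproduced. Positions are 1-based inclusive everywhere, matching VCF and
GFF3.

## Known limitations

* OTV detection and heterozygote-excess cluster QC need raw intensities
  and are out of scope; the `Other` class absorbs them.
* The relatedness-corrected r²_vs is the kinship-whitened special case of
  structure-corrected LD; it does not model admixture covariates.
* The sparse-fill stage is a deterministic greedy stand-in for what is,
  in a real array project, a manual curation step.
* The exact published 65,450-marker list is not reproducible without the
  original pooled sequencing data; the toolkit reproduces the procedure
  and its arithmetic, not the marker list.
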