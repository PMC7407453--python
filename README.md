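# tilarray

A design and validation toolkit for SNP genotyping arrays built from
pooled-sequencing (Pool-Seq) variant discovery, modelled on the workflow
behind the open-access ~65K Nile tilapia (*Oreochromis niloticus*) array.

Aquaculture breeding programs increasingly rely on genome-wide SNP data,
but sequencing every candidate individually is expensive. A cheaper route
is to sequence pooled DNA from many individuals of the discovery strain
(here: two pools of 50 diploids at a combined ~90X site depth), estimate
allele frequencies from read counts, and select a panel of well-spaced,
assayable, informative markers for a fixed genotyping platform. `tilarray`
implements both halves of that project for population geneticists and
breeding-program researchers:

**Design side** — from a Freebayes-style pooled VCF to a tiered array:

1. call-support filter: keep sites with ≥ 3 alternate reads or a pool
   alternate frequency > 0.02;
2. interference filter: drop SNPs with any other variant closer than
   40 bp (both members of a close pair);
3. site-quality filter: summed depth in [50, 150], alternate support on
   both strands, ≥ 2 reads placed on each side, > 90 % properly-paired
   support for both alleles;
4. genic-context classification from GFF3 (exon > intron > ≤ 1 kb from a
   gene > intergenic);
5. tiered assembly: fixed sex-associated markers, then markers shared
   with external SNP panels, then exonic SNPs, then one highest-MAF SNP
   per 10-kb window (within-gene or near-gene, A/T and G/C pairs removed,
   pool-averaged MAF in [0.05, 0.45], a viable Axiom probe class), topped
   up from the emptiest 1-Mb regions.

**Validation side** — from genotype matrices to the population-genetic
battery: call-based Axiom-style probe-set classification
(PolyHighResolution, NoMinorHom, MonoHighRes, CallRateBelowThreshold,
Other), SNP/sample call-rate filters, identity-by-state de-duplication,
LD pruning; observed and expected heterozygosity (Ho = mean fraction of
heterozygous calls, He = mean 2p̂(1−p̂)) with SNP-resampling bootstrap
CIs; MAF informativeness categories and cross-strain informative-marker
Venn counts; LD decay as mean r² (plain, and corrected for relatedness by
whitening dosages with the inverse Cholesky factor of a VanRaden genomic
relationship matrix — r²_vs) in 10-kb distance bins; and PCA under
Patterson normalisation with Tracy–Widom significance of components.

A first-class synthetic-data module generates every input with known
ground truth — annotation, pooled calls with per-clause QC violations
recorded, panels/scores, and Balding–Nichols genotype panels with
distance-decaying LD — so the whole toolkit is testable offline.

## Worked example

Simulate a discovery run and design a small array:

```sh
tilarray simulate --seed 4 --n-sites 800 --out-dir demo
tilarray design --vcf demo/pooled.vcf --gff demo/annotation.gff3 \
    --scores demo/scores.tsv \
    --panels demo/panel_abbassa_breeding.tsv \
    --panels demo/panel_kenya_breeding.tsv \
    --target 150 --out-dir demo/design
```

prints

```json
{
  "n_markers": 150,
  "tiers": {
    "sex_marker": 0,
    "panel_overlap": 89,
    "exonic": 36,
    "spaced": 25,
    "sparse_fill": 0
  }
}
```

The 823 simulated call records (800 SNVs plus injected indels) pass
through the support, interference and quality filters; surviving
candidates are tiered. Here 89 markers were shared with the two external
panels (highest priority after sex markers), 36 further candidates sat in
exons, and the remaining budget was filled with the highest-MAF SNP per
10-kb window. `demo/design/array_design.tsv` lists each marker with its
tier, pool-averaged MAF and panel provenance, e.g.

```
marker_id    chrom  pos    ref  alt  tier           avg_maf  panel_hits
chr1_37131   chr1   37131  A    C    panel_overlap  0.337    panel_abbassa_breeding
```

Validation-side commands follow the same pattern (`tilarray qc`,
`stats`, `ld`, `pca`, `report`); see `--help` on each.

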