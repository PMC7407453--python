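"""Synthetic fixtures with known ground truth for the whole toolkit.

Everything downstream — pooled-variant filtering, array design, genotype
QC, popgen statistics, LD decay, structure PCA — is testable against data
generated here, with no external downloads:

* a gene/exon annotation with uniformly placed, non-overlapping genes;
* pooled-sequencing variant calls for two DNA pools of 50 diploids at a
  combined ~90X site depth, with caller-style evidence fields and an
  optional, exactly-bookkept fraction of sites that each violate one
  specific QC clause (the violated clause is the ground truth);
* external SNP panel position lists and a four-level probe-score table;
* multi-population genotype panels under the Balding-Nichols model
  (population frequencies Beta-distributed around an ancestral frequency
  with dispersion set by FST) with distance-decaying LD induced by a
  latent Gaussian AR(1) haplotype process.

All outputs are deterministic functions of ``SimConfig.seed``: two runs
with the same configuration are byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .array_design import ArrayDesign, GenomeAnnotation
from .genotype_qc import MISSING, GenotypeMatrix
from .variant_filter import (
    FilterConfig,
    PooledVariant,
    PooledVariantSet,
)

BASES = ("A", "C", "G", "T")

#: truth labels for deliberately injected QC violations
VIOLATION_KINDS = (
    "low_coverage", "high_coverage", "strand", "placement",
    "paired", "support", "interference",
)
TRUTH_CLEAN = "clean"
TRUTH_DROPOUT = "dropout"

# distinct deterministic sub-streams per generator function
_SALT_ANNOTATION = 11
_SALT_VARIANTS = 23
_SALT_PANEL = 37
_SALT_SCORES = 41
_SALT_GENOTYPES = 53


@dataclass
class PopSpec:
    """One population of a simulated genotype panel."""

    name: str
    n_samples: int
    fst: float
    ancestral_freqs: np.ndarray

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        self.ancestral_freqs = np.asarray(self.ancestral_freqs, dtype=float)
        if np.any((self.ancestral_freqs < 0) | (self.ancestral_freqs > 1)):
            raise ValueError("ancestral_freqs must lie in [0, 1]")


@dataclass
class SimConfig:
    """Reproducible study conditions for all simulators.

    ``target_depth`` is the combined read depth over both pools at one
    site (the sequencing design this emulates pooled 100 diploids at a
    combined ~90X, which the discovery-side 50-150X coverage window is
    calibrated to); it is split between pools proportionally to
    ``pool_sizes``.  ``ld_rho`` is the per-bp decay rate of the latent
    haplotype correlation (correlation exp(-ld_rho * distance)).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length_bp: int = 2_000_000
    gene_density: float = 20.0          # genes per Mb
    pool_sizes: tuple[int, ...] = (50, 50)
    target_depth: int = 90              # summed reads across pools per site
    ld_rho: float = 5e-5
    error_rate: float = 0.0             # optional sequencing error, default off

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chromosome_length_bp", "target_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(s <= 0 for s in self.pool_sizes):
            raise ValueError("pool sizes must be positive")

    def chrom_names(self) -> list[str]:
        return [f"chr{i+1}" for i in range(self.n_chromosomes)]

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimConfig) -> GenomeAnnotation:
    """Uniformly placed, non-overlapping genes with >= 1 exon each.

    The gene count per chromosome is ``round(gene_density * length / 1e6)``.
    Placement retries a bounded number of times; a density too high to
    place raises ``RuntimeError``.
    """
    rng = config.rng(_SALT_ANNOTATION)
    genes, exons = [], []
    length = config.chromosome_length_bp
    for chrom in config.chrom_names():
        n_genes = int(round(config.gene_density * length / 1e6))
        placed: list[tuple[int, int]] = []
        attempts = 0
        max_attempts = 200 * max(n_genes, 1)
        while len(placed) < n_genes:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not place {n_genes} non-overlapping genes on {chrom} "
                    f"({length} bp) after {max_attempts} attempts"
                )
            glen = int(rng.integers(2_000, 20_001))
            if glen >= length:
                continue
            start = int(rng.integers(1, length - glen + 1))
            end = start + glen - 1
            if any(start <= e and s <= end for s, e in placed):
                continue
            placed.append((start, end))
        placed.sort()
        for gi, (start, end) in enumerate(placed, 1):
            gene_id = f"{chrom}_gene{gi}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                {"chrom": chrom, "start": start, "end": end,
                 "strand": strand, "gene_id": gene_id}
            )
            n_exons = int(rng.integers(1, 6))
            # partition the gene into 2*n_exons-1 alternating exon/intron blocks
            cuts = np.sort(rng.choice(
                np.arange(start + 1, end), size=max(2 * n_exons - 2, 0), replace=False,
            )) if end - start >= 2 * n_exons else np.array([], dtype=int)
            bounds = [start, *cuts.tolist(), end + 1]
            for b in range(0, len(bounds) - 1, 2):
                e_start, e_end = bounds[b], bounds[b + 1] - 1
                if e_end >= e_start:
                    exons.append(
                        {"chrom": chrom, "start": int(e_start), "end": int(e_end),
                         "gene_id": gene_id}
                    )
    return GenomeAnnotation(
        genes=pd.DataFrame(genes, columns=["chrom", "start", "end", "strand", "gene_id"]),
        exons=pd.DataFrame(exons, columns=["chrom", "start", "end", "gene_id"]),
        chrom_lengths={c: length for c in config.chrom_names()},
    )


# ---------------------------------------------------------------------------
# pooled variants


def _draw_site(
    rng: np.random.Generator,
    maf: float,
    config: SimConfig,
    fcfg: FilterConfig,
    kind: str,
) -> dict:
    """Evidence fields for one site violating exactly ``kind`` (or none).

    Each violation kind breaks its own clause while keeping every other
    clause satisfied, so truth-vs-filter confusion matrices are exact.
    """
    n_pools = len(config.pool_sizes)
    shares = np.asarray(config.pool_sizes, float) / sum(config.pool_sizes)

    def pool_depths(total: int) -> np.ndarray:
        d = np.floor(total * shares).astype(int)
        d[0] += total - d.sum()
        return d

    def total_depth_clean() -> int:
        # clamp into the coverage window only when the configured depth
        # itself lies inside it; depth-scaling studies bypass the clamp
        if not fcfg.min_cov <= config.target_depth <= fcfg.max_cov:
            return int(rng.poisson(config.target_depth))
        while True:
            t = int(rng.poisson(config.target_depth))
            if fcfg.min_cov <= t <= fcfg.max_cov:
                return t

    def alt_counts(depths: np.ndarray, min_total: int) -> np.ndarray:
        f = maf if config.error_rate == 0 else min(
            1.0, maf * (1 - config.error_rate) + config.error_rate / 3
        )
        for _ in range(1000):
            a = rng.binomial(depths, f)
            if a.sum() >= min_total and np.all(a <= depths):
                return a
        return np.minimum(depths, np.maximum(rng.binomial(depths, f), 1))

    def strand_split(total_alt: int) -> tuple[int, int]:
        while True:
            fwd = int(rng.binomial(total_alt, 0.5))
            if 1 <= fwd <= total_alt - 1:
                return fwd, total_alt - fwd

    def placement(total: int) -> tuple[int, int]:
        while True:
            left = int(rng.binomial(total, 0.5))
            if left >= fcfg.min_side_reads and total - left >= fcfg.min_side_reads:
                return left, total - left

    def paired_clean() -> float:
        return float(rng.uniform(fcfg.min_paired_frac + 0.03, 1.0))

    if kind == TRUTH_DROPOUT:
        z = np.zeros(n_pools, dtype=int)
        return dict(depths=z, alts=z, fwd=0, rev=0, left=0, right=0,
                    paired_alt=0.0, paired_ref=0.0)

    if kind == "low_coverage":
        total = int(rng.integers(4 * n_pools + 4, fcfg.min_cov))
    elif kind == "high_coverage":
        total = int(rng.integers(fcfg.max_cov + 1, 2 * fcfg.max_cov))
    elif kind == "support":
        # one alt read per pool at a pool AF of at most the floor
        per_pool = np.ceil(1.0 / fcfg.min_pool_af).astype(int)
        depths = np.full(n_pools, per_pool, dtype=int)
        alts = np.ones(n_pools, dtype=int)
        fwd, rev = 1, alts.sum() - 1
        left, right = placement(int(depths.sum()))
        return dict(depths=depths, alts=alts, fwd=fwd, rev=rev, left=left,
                    right=right, paired_alt=paired_clean(), paired_ref=paired_clean())
    else:
        total = total_depth_clean()

    depths = pool_depths(total)
    alts = alt_counts(depths, min_total=max(fcfg.min_alt_reads, 4))
    total_alt = int(alts.sum())

    if kind == "strand":
        fwd, rev = (total_alt, 0) if rng.random() < 0.5 else (0, total_alt)
    else:
        fwd, rev = strand_split(total_alt)

    if kind == "placement":
        left = int(rng.integers(0, fcfg.min_side_reads))
        if rng.random() < 0.5:
            left, right = left, total - left
        else:
            left, right = total - left, left
    else:
        left, right = placement(total)

    if kind == "paired":
        paired_alt = float(rng.uniform(0.5, fcfg.min_paired_frac))
        paired_ref = paired_clean()
        if rng.random() < 0.5:
            paired_alt, paired_ref = paired_ref, paired_alt
    else:
        paired_alt, paired_ref = paired_clean(), paired_clean()

    return dict(depths=depths, alts=alts, fwd=fwd, rev=rev, left=left,
                right=right, paired_alt=paired_alt, paired_ref=paired_ref)


def simulate_pooled_variants(
    config: SimConfig,
    annotation: GenomeAnnotation,
    true_mafs: Sequence[float],
    violation_fractions: Mapping[str, float] | None = None,
    dropout_fraction: float = 0.0,
    indel_count: int = 0,
) -> tuple[PooledVariantSet, pd.DataFrame]:
    """Pooled variant calls with per-site ground truth.

    Sites are placed with >= ``interference_bp`` clearance from each other
    (interference-flagged sites get a deliberately close partner, both
    flagged).  Per-pool read counts are binomial at the site's true allele
    frequency and the pool's share of ``target_depth``; clean sites are
    drawn to satisfy every QC clause, violation sites to break exactly
    their recorded clause.  ``indel_count`` adds indel records (skipped on
    load, far from every SNV).

    Returns the variant set and a truth table (chrom, pos, true_maf, flag).
    """
    true_mafs = np.asarray(true_mafs, dtype=float)
    if true_mafs.size == 0:
        raise ValueError("true_mafs must be non-empty")
    if np.any((true_mafs < 0) | (true_mafs > 1)):
        raise ValueError("true_mafs must lie in [0, 1]")
    violation_fractions = dict(violation_fractions or {})
    unknown = set(violation_fractions) - set(VIOLATION_KINDS)
    if unknown:
        raise ValueError(f"unknown violation kinds: {sorted(unknown)}")

    rng = config.rng(_SALT_VARIANTS)
    fcfg = FilterConfig()
    n_sites = len(true_mafs)

    flags = np.array([TRUTH_CLEAN] * n_sites, dtype=object)
    order = rng.permutation(n_sites)
    cursor = 0
    for kind, frac in violation_fractions.items():
        k = int(round(frac * n_sites))
        flags[order[cursor:cursor + k]] = kind
        cursor += k
    k = int(round(dropout_fraction * n_sites))
    flags[order[cursor:cursor + k]] = TRUTH_DROPOUT
    cursor += k
    if cursor > n_sites:
        raise ValueError("violation fractions sum to more than 1")

    # lay out primary positions with clearance > interference window
    chroms = config.chrom_names()
    spacing = 2 * fcfg.interference_bp + 10
    per_chrom = int(np.ceil(n_sites / len(chroms)))
    capacity = (config.chromosome_length_bp - 100) // spacing
    if per_chrom > capacity:
        raise ValueError("too many sites for the configured chromosome length")
    positions: list[tuple[str, int]] = []
    for ci, chrom in enumerate(chroms):
        n_here = min(per_chrom, n_sites - ci * per_chrom)
        if n_here <= 0:
            break
        slots = rng.choice(capacity, size=n_here, replace=False)
        slots.sort()
        for s in slots:
            positions.append((chrom, int(50 + s * spacing + rng.integers(0, 10))))

    variants: list[PooledVariant] = []
    partner_positions: list[tuple[str, int]] = []
    truth_rows = []
    for (chrom, pos), maf, flag in zip(positions, true_mafs, flags):
        ref, alt = rng.choice(4, size=2, replace=False)
        ref_b, alt_b = BASES[ref], BASES[alt]
        site = _draw_site(rng, float(maf), config, fcfg, str(flag))
        v = PooledVariant(
            chrom=chrom, pos=pos, ref_allele=ref_b, alt_allele=alt_b,
            per_pool_depth=tuple(int(d) for d in site["depths"]),
            per_pool_alt_obs=tuple(int(a) for a in site["alts"]),
            alt_fwd=int(site["fwd"]), alt_rev=int(site["rev"]),
            reads_left=int(site["left"]), reads_right=int(site["right"]),
            paired_frac_alt=float(site["paired_alt"]),
            paired_frac_ref=float(site["paired_ref"]),
        )
        variants.append(v)
        truth_rows.append(
            {"chrom": chrom, "pos": pos, "true_maf": float(maf), "flag": str(flag)}
        )
        if flag == "interference":
            delta = int(rng.integers(1, fcfg.interference_bp))
            ppos = pos + delta
            pref, palt = rng.choice(4, size=2, replace=False)
            psite = _draw_site(rng, float(maf), config, fcfg, TRUTH_CLEAN)
            variants.append(
                PooledVariant(
                    chrom=chrom, pos=ppos, ref_allele=BASES[pref], alt_allele=BASES[palt],
                    per_pool_depth=tuple(int(d) for d in psite["depths"]),
                    per_pool_alt_obs=tuple(int(a) for a in psite["alts"]),
                    alt_fwd=int(psite["fwd"]), alt_rev=int(psite["rev"]),
                    reads_left=int(psite["left"]), reads_right=int(psite["right"]),
                    paired_frac_alt=float(psite["paired_alt"]),
                    paired_frac_ref=float(psite["paired_ref"]),
                )
            )
            truth_rows.append(
                {"chrom": chrom, "pos": ppos, "true_maf": float(maf),
                 "flag": "interference"}
            )

    vset = PooledVariantSet(variants=variants, n_pools=len(config.pool_sizes))
    # standalone indels, placed in leftover space away from every SNV
    if indel_count:
        taken = sorted(p for c, p in positions + partner_positions)
        for _ in range(indel_count):
            for _try in range(200):
                chrom = chroms[int(rng.integers(len(chroms)))]
                pos = int(rng.integers(50, config.chromosome_length_bp - 50))
                near = any(
                    v.chrom == chrom and abs(v.pos - pos) < 2 * fcfg.interference_bp
                    for v in variants
                )
                if not near:
                    vset.other_positions.append((chrom, pos))
                    break
    vset = vset.sorted()
    truth = pd.DataFrame(truth_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return vset, truth


def write_pooled_vcf(
    vset: PooledVariantSet,
    path: str | Path,
    config: SimConfig | None = None,
    indel_records: bool = True,
) -> None:
    """Serialize a pooled variant set as VCF v4.2.

    Site evidence goes into INFO (DP, AO, SAF, SAR, RPL, RPR, PAIRED,
    PAIREDR); per-pool depth and alternate observations into the DP/AO
    FORMAT fields of one column per pool.  Positions recorded in
    ``other_positions`` are emitted as simple insertion records so that
    loading skips (and counts) them.
    """
    n_pools = vset.n_pools
    pool_names = [f"pool{i+1}" for i in range(n_pools)]
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observations">',
        '##INFO=<ID=SAF,Number=A,Type=Integer,Description="Alt observations on forward strand">',
        '##INFO=<ID=SAR,Number=A,Type=Integer,Description="Alt observations on reverse strand">',
        '##INFO=<ID=RPL,Number=1,Type=Integer,Description="Reads placed left of the site">',
        '##INFO=<ID=RPR,Number=1,Type=Integer,Description="Reads placed right of the site">',
        '##INFO=<ID=PAIRED,Number=A,Type=Float,Description="Properly paired fraction of alt observations">',
        '##INFO=<ID=PAIREDR,Number=1,Type=Float,Description="Properly paired fraction of ref observations">',
        '##INFO=<ID=TYPE,Number=A,Type=String,Description="Allele type">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Per-pool read depth">',
        '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Per-pool alt observations">',
    ]
    if config is not None:
        for chrom in config.chrom_names():
            lines.append(
                f"##contig=<ID={chrom},length={config.chromosome_length_bp}>"
            )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(pool_names)
    )
    records: list[tuple[str, int, str]] = []
    for v in vset.variants:
        info = (
            f"DP={v.total_depth};AO={v.total_alt};SAF={v.alt_fwd};SAR={v.alt_rev};"
            f"RPL={v.reads_left};RPR={v.reads_right};"
            f"PAIRED={v.paired_frac_alt:.4f};PAIREDR={v.paired_frac_ref:.4f};TYPE=snp"
        )
        fmt = "\t".join(
            f"{d}:{a}" for d, a in zip(v.per_pool_depth, v.per_pool_alt_obs)
        )
        records.append(
            (v.chrom, v.pos,
             f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t100\t.\t"
             f"{info}\tDP:AO\t{fmt}")
        )
    if indel_records:
        for chrom, pos in vset.other_positions:
            info = ("DP=80;AO=20;SAF=10;SAR=10;RPL=40;RPR=40;"
                    "PAIRED=0.9500;PAIREDR=0.9500;TYPE=ins")
            fmt = "\t".join("40:10" for _ in range(n_pools))
            records.append(
                (chrom, pos,
                 f"{chrom}\t{pos}\t.\tA\tAT\t100\t.\t{info}\tDP:AO\t{fmt}")
            )
    records.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for _, _, line in records:
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# panels and probe scores

DEFAULT_PANEL_NAMES = (
    "abbassa_breeding", "abbassa_wild", "kenya_breeding", "tanzania", "wageningen",
)
DEFAULT_CLASS_PROBS = {
    "recommended": 0.55, "neutral": 0.25, "not_recommended": 0.12, "not_possible": 0.08,
}


def simulate_panels_and_scores(
    variants: PooledVariantSet | Sequence[PooledVariant],
    overlap_fraction: float,
    config: SimConfig,
    panel_names: Sequence[str] = DEFAULT_PANEL_NAMES,
    n_decoys: int = 50,
    class_probs: Mapping[str, float] = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """External panel position lists plus a probe-score table.

    Each panel independently contains ``overlap_fraction`` of the candidate
    positions plus ``n_decoys`` decoy positions absent from the candidates.
    The score table assigns every candidate a forward and reverse probe
    class drawn from the four-level vocabulary.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    vlist = list(variants)
    rng = config.rng(_SALT_PANEL)
    taken = {(v.chrom, v.pos) for v in vlist}
    panels: dict[str, pd.DataFrame] = {}
    for name in panel_names:
        rows = []
        if vlist and overlap_fraction > 0:
            hit = rng.random(len(vlist)) < overlap_fraction
            for v, h in zip(vlist, hit):
                if h:
                    rows.append({"chrom": v.chrom, "pos": v.pos,
                                 "ref": v.ref_allele, "alt": v.alt_allele})
        for _ in range(n_decoys):
            for _try in range(100):
                chrom = config.chrom_names()[int(rng.integers(config.n_chromosomes))]
                pos = int(rng.integers(1, config.chromosome_length_bp))
                if (chrom, pos) not in taken:
                    ref, alt = rng.choice(4, size=2, replace=False)
                    rows.append({"chrom": chrom, "pos": pos,
                                 "ref": BASES[ref], "alt": BASES[alt]})
                    break
        panels[name] = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])

    probs = dict(class_probs or DEFAULT_CLASS_PROBS)
    labels = list(probs)
    pvec = np.asarray([probs[l] for l in labels], dtype=float)
    pvec = pvec / pvec.sum()
    srng = config.rng(_SALT_SCORES)
    scores = pd.DataFrame(
        {
            "snp_id": [f"{v.chrom}_{v.pos}" for v in vlist],
            "probe_fwd_class": srng.choice(labels, size=len(vlist), p=pvec),
            "probe_rev_class": srng.choice(labels, size=len(vlist), p=pvec),
        }
    )
    return panels, scores


# ---------------------------------------------------------------------------
# genotype panels


def simulate_genotype_panel(
    design: ArrayDesign | pd.DataFrame,
    pops: Sequence[PopSpec],
    config: SimConfig,
    missing_rate_sample: float | Sequence[float] = 0.0,
    missing_rate_snp: float | Sequence[float] = 0.0,
    structure_expected: bool = False,
) -> GenotypeMatrix:
    """Multi-population diploid genotypes at the design's marker positions.

    Per population, each SNP's frequency is drawn from the Balding-Nichols
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p (F = 0
    keeps p itself); haplotypes then follow a latent Gaussian AR(1) along
    each chromosome with correlation exp(-ld_rho * distance), giving
    Hardy-Weinberg marginals with distance-decaying LD.  Missingness is
    injected per sample and per SNP (scalar rate or one rate per
    sample/SNP).
    """
    markers = design.markers if isinstance(design, ArrayDesign) else design
    if len(markers) == 0:
        raise ValueError("design is empty")
    if not pops:
        raise ValueError("at least one population required")
    if structure_expected and all(p.fst == 0 for p in pops):
        warnings.warn("fst=0 for every population: structure will be undetectable")
    rng = config.rng(_SALT_GENOTYPES)
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    n_snps = len(markers)

    # latent AR(1) coefficients between consecutive markers per chromosome
    a = np.zeros(n_snps)
    for i in range(1, n_snps):
        if chroms[i] == chroms[i - 1]:
            a[i] = np.exp(-config.ld_rho * abs(int(pos[i]) - int(pos[i - 1])))

    samples, populations, rows = [], [], []
    for spec in pops:
        p_anc = np.broadcast_to(spec.ancestral_freqs, (n_snps,)).astype(float)
        if spec.fst > 0:
            f = spec.fst
            alpha = p_anc * (1 - f) / f
            beta = (1 - p_anc) * (1 - f) / f
            pos_mask = (p_anc > 0) & (p_anc < 1)
            p_pop = p_anc.copy()
            p_pop[pos_mask] = rng.beta(alpha[pos_mask], beta[pos_mask])
        else:
            p_pop = p_anc
        thresh = norm.ppf(np.clip(p_pop, 1e-12, 1 - 1e-12))
        n_hap = 2 * spec.n_samples
        eps = rng.standard_normal((n_hap, n_snps))
        z = np.empty_like(eps)
        z[:, 0] = eps[:, 0]
        b = np.sqrt(1.0 - a ** 2)
        for i in range(1, n_snps):
            z[:, i] = a[i] * z[:, i - 1] + b[i] * eps[:, i]
        haps = (z < thresh).astype(np.int8)
        haps[:, p_pop == 0] = 0
        haps[:, p_pop == 1] = 1
        geno = haps[0::2] + haps[1::2]
        rows.append(geno)
        samples.extend(f"{spec.name}_{s+1}" for s in range(spec.n_samples))
        populations.extend([spec.name] * spec.n_samples)
    calls = np.vstack(rows).astype(np.int8)

    n_samples = len(samples)
    ms = np.broadcast_to(np.asarray(missing_rate_sample, float), (n_samples,))
    mn = np.broadcast_to(np.asarray(missing_rate_snp, float), (n_snps,))
    miss = rng.random((n_samples, n_snps)) < np.clip(
        ms[:, None] + mn[None, :], 0.0, 1.0
    )
    calls = np.where(miss, MISSING, calls).astype(np.int8)

    snps = markers[["chrom", "pos"]].copy().reset_index(drop=True)
    snps["ref"] = markers.get("ref", pd.Series(["A"] * n_snps)).to_numpy()
    snps["alt"] = markers.get("alt", pd.Series(["G"] * n_snps)).to_numpy()
    return GenotypeMatrix(
        samples=samples, populations=populations, snps=snps, calls=calls
    )


def default_design(
    config: SimConfig, n_snps: int, maf_range: tuple[float, float] = (0.05, 0.5),
) -> ArrayDesign:
    """Evenly spaced marker positions for validation-side simulations."""
    rng = config.rng(97)
    chroms = config.chrom_names()
    per_chrom = int(np.ceil(n_snps / len(chroms)))
    step = config.chromosome_length_bp // (per_chrom + 1)
    rows = []
    for chrom in chroms:
        for i in range(per_chrom):
            if len(rows) >= n_snps:
                break
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append(
                {"marker_id": f"{chrom}_{(i+1)*step}", "chrom": chrom,
                 "pos": (i + 1) * step, "ref": BASES[ref], "alt": BASES[alt],
                 "tier": "spaced", "avg_maf": float(rng.uniform(*maf_range)),
                 "panel_hits": ""}
            )
    return ArrayDesign(markers=pd.DataFrame(rows), target_size=n_snps)
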