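"""Tiered SNP-array design from filtered pooled-sequencing candidates.

The array is assembled in four tiers, in fixed priority order:

1. *sex_marker* — a fixed list of markers associated with phenotypic sex,
   included verbatim;
2. *panel_overlap* — candidates also present in at least one external SNP
   panel (cross-referencing mitigates ascertainment bias towards the
   discovery strain);
3. *exonic* — remaining candidates located in exons;
4. *spaced* / *sparse_fill* — remaining within-gene or near-gene (<= 1 kb)
   candidates picked one per 10-kb window by highest pool-averaged MAF,
   then topped up by repeatedly adding the best candidate from the 1-Mb
   region currently holding the fewest markers.

Before tiers 3-4, candidates must carry a viable array probe (class
``recommended`` or ``neutral`` on at least one strand), must not be an
A/T or G/C polymorphism (those need twice as many probes on the platform),
and must have a pool-averaged MAF inside ``[maf_lo, maf_hi]`` (the upper
bound guards against collapsed paralogues).  Panel-overlap candidates
bypass the MAF window but still need a viable probe by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .variant_filter import PooledVariant, pool_average_maf

logger = logging.getLogger(__name__)

CONTEXT_EXON = "exon"
CONTEXT_INTRON = "intron"
CONTEXT_NEAR_GENE = "near_gene_1kb"
CONTEXT_INTERGENIC = "intergenic"

TIER_SEX = "sex_marker"
TIER_PANEL = "panel_overlap"
TIER_EXON = "exonic"
TIER_SPACED = "spaced"
TIER_SPARSE = "sparse_fill"
TIER_ORDER = (TIER_SEX, TIER_PANEL, TIER_EXON, TIER_SPACED, TIER_SPARSE)

PROBE_CLASSES = ("recommended", "neutral", "not_recommended", "not_possible")
VIABLE_PROBE_CLASSES = frozenset({"recommended", "neutral"})
AMBIGUOUS_PAIRS = (frozenset({"A", "T"}), frozenset({"G", "C"}))


@dataclass
class GenomeAnnotation:
    """Gene/exon intervals in 1-based inclusive coordinates.

    ``genes`` columns: chrom, start, end, strand, gene_id.
    ``exons`` columns: chrom, start, end, gene_id.
    ``chrom_lengths`` maps sequence name to length (from ``##sequence-region``
    pragmas when read from GFF3).
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.genes) and (self.genes["start"] > self.genes["end"]).any():
            raise ValueError("gene interval with start > end")
        if len(self.exons) and (self.exons["start"] > self.exons["end"]).any():
            raise ValueError("exon interval with start > end")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_gff3(self, path: str | Path) -> None:
        """Serialize as GFF3 with gene and exon features."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in sorted(self.chrom_lengths):
                fh.write(f"##sequence-region {chrom} 1 {self.chrom_lengths[chrom]}\n")
            exons_by_gene: dict[str, pd.DataFrame] = {
                g: d for g, d in self.exons.groupby("gene_id")
            } if len(self.exons) else {}
            genes = self.genes.sort_values(["chrom", "start"]) if len(self.genes) else self.genes
            for row in genes.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\ttilarray\tgene\t{row.start}\t{row.end}\t.\t"
                    f"{row.strand}\t.\tID={row.gene_id}\n"
                )
                ex = exons_by_gene.get(row.gene_id)
                if ex is None:
                    continue
                for i, e in enumerate(ex.sort_values("start").itertuples(index=False), 1):
                    fh.write(
                        f"{e.chrom}\ttilarray\texon\t{e.start}\t{e.end}\t.\t"
                        f"{row.strand}\t.\tID={row.gene_id}.exon{i};Parent={row.gene_id}\n"
                    )

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GenomeAnnotation":
        """Load gene and exon features from a GFF3 file via gffutils."""
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        genes, exons = [], []
        for g in db.features_of_type("gene"):
            genes.append(
                {"chrom": g.seqid, "start": g.start, "end": g.end,
                 "strand": g.strand, "gene_id": g.id}
            )
        for e in db.features_of_type("exon"):
            parents = [p.id for p in db.parents(e, featuretype="gene")]
            if not parents:
                parents = list(e.attributes.get("Parent", ["?"]))
            exons.append(
                {"chrom": e.seqid, "start": e.start, "end": e.end, "gene_id": parents[0]}
            )
        chrom_lengths: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, chrom, _start, end = line.split()[:4]
                    chrom_lengths[chrom] = int(end)
                elif not line.startswith("#"):
                    break
        return cls(
            genes=pd.DataFrame(genes, columns=["chrom", "start", "end", "strand", "gene_id"]),
            exons=pd.DataFrame(exons, columns=["chrom", "start", "end", "gene_id"]),
            chrom_lengths=chrom_lengths,
        )


@dataclass
class CandidateSNP:
    """A filtered variant annotated for array selection."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    avg_maf: float
    context: str = CONTEXT_INTERGENIC
    panel_hits: frozenset[str] = frozenset()
    probe_classes: tuple[str, str] | None = None
    tier: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.avg_maf <= 0.5:
            raise ValueError(f"avg_maf out of [0, 0.5]: {self.avg_maf}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def allele_pair(self) -> frozenset[str]:
        return frozenset({self.ref_allele, self.alt_allele})

    @property
    def snp_id(self) -> str:
        return f"{self.chrom}_{self.pos}"


@dataclass
class DesignConfig:
    """Knobs of the tiered selection."""

    target_size: int = 65000
    window_bp: int = 10_000
    sparse_region_bp: int = 1_000_000
    n_scaffolds: int = 130
    maf_lo: float = 0.05
    maf_hi: float = 0.45
    flank_bp: int = 1000
    eligible_contexts: frozenset[str] = frozenset({CONTEXT_INTRON, CONTEXT_NEAR_GENE})
    tier2_bypass_maf: bool = True       # panel-overlap markers skip the MAF window
    tier2_require_probe: bool = True    # ... but still need a viable probe class
    missing_score_policy: str = "drop"  # candidates absent from the score table


@dataclass
class ArrayDesign:
    """Final ordered marker list with per-tier provenance.

    ``markers`` columns: marker_id, chrom, pos, ref, alt, tier, avg_maf,
    panel_hits (comma-joined).  No duplicate (chrom, pos).
    """

    markers: pd.DataFrame
    target_size: int
    window_bp: int = 10_000
    sparse_region_bp: int = 1_000_000
    n_scaffolds: int = 130

    def __post_init__(self) -> None:
        if len(self.markers):
            dup = self.markers.duplicated(subset=["chrom", "pos"])
            if dup.any():
                raise ValueError("duplicate (chrom, pos) in array design")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def tier_counts(self) -> dict[str, int]:
        counts = self.markers["tier"].value_counts().to_dict() if len(self.markers) else {}
        return {t: int(counts.get(t, 0)) for t in TIER_ORDER}

    @property
    def positions(self) -> list[tuple[str, int]]:
        return list(zip(self.markers["chrom"], self.markers["pos"]))

    def to_tsv(self, path: str | Path) -> None:
        self.markers.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "ArrayDesign":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(markers=df, target_size=kwargs.pop("target_size", len(df)), **kwargs)


# ---------------------------------------------------------------------------
# context classification


def _build_trees(annotation: GenomeAnnotation, flank_bp: int):
    """Per-chromosome interval trees for exons, genes, and flanked genes.

    intervaltree uses half-open intervals, so inclusive 1-based [start, end]
    becomes [start, end + 1).
    """
    exon_trees: dict[str, IntervalTree] = {}
    gene_trees: dict[str, IntervalTree] = {}
    near_trees: dict[str, IntervalTree] = {}
    for row in annotation.exons.itertuples(index=False):
        exon_trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end + 1)
    for row in annotation.genes.itertuples(index=False):
        gene_trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end + 1)
        near_trees.setdefault(row.chrom, IntervalTree()).addi(
            max(1, row.start - flank_bp), row.end + flank_bp + 1
        )
    return exon_trees, gene_trees, near_trees


def classify_context(
    variants: Sequence[PooledVariant | CandidateSNP],
    annotation: GenomeAnnotation,
    flank_bp: int = 1000,
) -> list[CandidateSNP]:
    """Assign each variant its genic context.

    Precedence: exon > intron (within gene, outside exons) > near-gene
    (within ``flank_bp`` of a gene boundary, boundary-inclusive) >
    intergenic.  Variants on chromosomes absent from the annotation are
    intergenic with a logged warning.
    """
    exon_trees, gene_trees, near_trees = _build_trees(annotation, flank_bp)
    known_chroms = set(gene_trees) | set(annotation.chrom_lengths)
    warned: set[str] = set()
    out: list[CandidateSNP] = []
    for v in variants:
        if isinstance(v, CandidateSNP):
            cand = v
        else:
            cand = CandidateSNP(
                chrom=v.chrom, pos=v.pos, ref_allele=v.ref_allele,
                alt_allele=v.alt_allele, avg_maf=pool_average_maf(v),
            )
        chrom, pos = cand.chrom, cand.pos
        if chrom not in known_chroms and chrom not in warned:
            logger.warning("chromosome %s absent from annotation; treating as intergenic", chrom)
            warned.add(chrom)
        if chrom in exon_trees and exon_trees[chrom].overlaps_point(pos):
            ctx = CONTEXT_EXON
        elif chrom in gene_trees and gene_trees[chrom].overlaps_point(pos):
            ctx = CONTEXT_INTRON
        elif chrom in near_trees and near_trees[chrom].overlaps_point(pos):
            ctx = CONTEXT_NEAR_GENE
        else:
            ctx = CONTEXT_INTERGENIC
        cand.context = ctx
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# per-candidate filters


def allele_and_maf_filter(
    candidates: Sequence[CandidateSNP],
    maf_lo: float = 0.05,
    maf_hi: float = 0.45,
) -> tuple[list[CandidateSNP], pd.DataFrame]:
    """Drop A/T and G/C polymorphisms and MAF outside [maf_lo, maf_hi].

    Bounds are inclusive: the removal rule is MAF < maf_lo or > maf_hi, so
    a candidate at exactly 0.05 or 0.45 survives.  Returns kept candidates
    and a per-removal report (reason ``ambiguous_alleles`` or ``maf``).
    """
    kept, rows = [], []
    for c in candidates:
        if c.allele_pair in AMBIGUOUS_PAIRS:
            rows.append({"chrom": c.chrom, "pos": c.pos, "reason": "ambiguous_alleles"})
        elif c.avg_maf < maf_lo or c.avg_maf > maf_hi:
            rows.append({"chrom": c.chrom, "pos": c.pos, "reason": "maf"})
        else:
            kept.append(c)
    return kept, pd.DataFrame(rows, columns=["chrom", "pos", "reason"])


def crossref_panels(
    candidates: Sequence[CandidateSNP],
    panels: Mapping[str, pd.DataFrame],
    match_alleles: bool = False,
) -> list[CandidateSNP]:
    """Tag each candidate with the external panels containing its position.

    Panels are DataFrames with columns chrom, pos (and ref, alt when
    ``match_alleles``).  Panel rows on chromosomes never seen among the
    candidates are skipped with a logged count.
    """
    cand_chroms = {c.chrom for c in candidates}
    lookup: dict[str, set] = {}
    for name, df in panels.items():
        unknown = (~df["chrom"].isin(cand_chroms)).sum() if len(df) else 0
        if unknown:
            logger.info("panel %s: %d entries on chromosomes absent from candidates", name, unknown)
        if match_alleles:
            lookup[name] = {
                (r.chrom, r.pos, frozenset({r.ref, r.alt}))
                for r in df.itertuples(index=False)
            }
        else:
            lookup[name] = set(zip(df["chrom"], df["pos"]))
    for c in candidates:
        key = (c.chrom, c.pos, c.allele_pair) if match_alleles else (c.chrom, c.pos)
        c.panel_hits = frozenset(n for n, s in lookup.items() if key in s)
    return list(candidates)


def probe_score_gate(
    candidates: Sequence[CandidateSNP],
    scores: pd.DataFrame,
    missing_policy: str = "drop",
) -> list[CandidateSNP]:
    """Keep candidates with at least one probe scored recommended/neutral.

    ``scores`` columns: snp_id, probe_fwd_class, probe_rev_class.  Unknown
    class labels raise; candidates absent from the table are dropped (with
    a warning) or kept per ``missing_policy``.
    """
    bad = set(scores["probe_fwd_class"]) | set(scores["probe_rev_class"])
    bad -= set(PROBE_CLASSES)
    if bad:
        raise ValueError(f"unknown probe class label(s): {sorted(bad)}")
    table = {
        r.snp_id: (r.probe_fwd_class, r.probe_rev_class)
        for r in scores.itertuples(index=False)
    }
    kept: list[CandidateSNP] = []
    n_missing = 0
    for c in candidates:
        classes = table.get(c.snp_id)
        if classes is None:
            n_missing += 1
            if missing_policy == "keep":
                kept.append(c)
            continue
        c.probe_classes = classes
        if VIABLE_PROBE_CLASSES & set(classes):
            kept.append(c)
    if n_missing:
        logger.warning(
            "%d candidates missing from the probe-score table (%s)", n_missing,
            "kept" if missing_policy == "keep" else "dropped",
        )
    return kept


# ---------------------------------------------------------------------------
# spacing


def _selection_sort_key(c: CandidateSNP) -> tuple:
    """Within-window preference: highest MAF, then smallest position, then
    lexicographic allele pair."""
    return (-c.avg_maf, c.pos, tuple(sorted({c.ref_allele, c.alt_allele})))


def windowed_selection(
    candidates: Sequence[CandidateSNP],
    window_bp: int = 10_000,
    eligible_contexts: Iterable[str] = (CONTEXT_INTRON, CONTEXT_NEAR_GENE),
    sequences: Iterable[str] | None = None,
) -> list[CandidateSNP]:
    """One marker per non-overlapping window: the eligible candidate with
    the highest pool-averaged MAF.

    Windows are ``[k*window_bp + 1, (k+1)*window_bp]`` in 1-based inclusive
    coordinates, anchored at 1 on every sequence.  ``sequences`` restricts
    selection (e.g. chromosomes plus the longest scaffolds); ``None`` means
    all.  Ties break by smallest position, then lexicographic allele pair.
    """
    eligible_contexts = set(eligible_contexts)
    allowed = set(sequences) if sequences is not None else None
    best: dict[tuple[str, int], CandidateSNP] = {}
    for c in candidates:
        if c.context not in eligible_contexts:
            continue
        if allowed is not None and c.chrom not in allowed:
            continue
        wkey = (c.chrom, (c.pos - 1) // window_bp)
        cur = best.get(wkey)
        if cur is None or _selection_sort_key(c) < _selection_sort_key(cur):
            best[wkey] = c
    return [best[k] for k in sorted(best)]


def sparse_fill(
    selection: Sequence[CandidateSNP],
    candidates: Sequence[CandidateSNP],
    region_bp: int = 1_000_000,
    target_size: int | None = None,
    eligible_contexts: Iterable[str] = (CONTEXT_INTRON, CONTEXT_NEAR_GENE),
    sequences: Iterable[str] | None = None,
) -> list[CandidateSNP]:
    """Top up the selection from the emptiest 1-Mb regions.

    Greedy loop: find the region (non-overlapping tiling anchored at 1)
    with the fewest already-selected markers that still holds an unselected
    eligible candidate; add that region's highest-MAF candidate; repeat
    until ``target_size`` or candidates run out.  Region ties break by
    chromosome name then region start; within a region the windowed tie
    rule applies.  An unreachable target returns the shortfall silently
    (callers report it).
    """
    if target_size is None:
        target_size = len(selection)
    selection = list(selection)
    if target_size <= len(selection):
        return selection
    eligible_contexts = set(eligible_contexts)
    allowed = set(sequences) if sequences is not None else None
    taken = {c.key for c in selection}

    region_of = lambda c: (c.chrom, (c.pos - 1) // region_bp)
    counts: dict[tuple[str, int], int] = {}
    for c in selection:
        counts[region_of(c)] = counts.get(region_of(c), 0) + 1
    # sorted per-region pools of available candidates
    pools: dict[tuple[str, int], list[CandidateSNP]] = {}
    for c in candidates:
        if c.context not in eligible_contexts or c.key in taken:
            continue
        if allowed is not None and c.chrom not in allowed:
            continue
        pools.setdefault(region_of(c), []).append(c)
    for k in pools:
        pools[k].sort(key=_selection_sort_key)
        counts.setdefault(k, 0)

    while len(selection) < target_size and pools:
        region = min(pools, key=lambda k: (counts[k], k))
        c = pools[region].pop(0)
        if not pools[region]:
            del pools[region]
        selection.append(c)
        counts[region] = counts.get(region, 0) + 1
    return selection


def eligible_sequences(
    chrom_lengths: Mapping[str, int],
    chromosomes: Iterable[str] | None = None,
    n_scaffolds: int = 130,
) -> set[str]:
    """Chromosomes plus the ``n_scaffolds`` longest remaining sequences.

    When ``chromosomes`` is None, sequences named ``chr*``/``LG*`` count as
    chromosomes and everything else as scaffolds.
    """
    if chromosomes is None:
        chromosomes = [
            c for c in chrom_lengths if c.lower().startswith(("chr", "lg"))
        ]
    chromosomes = set(chromosomes)
    scaffolds = sorted(
        (c for c in chrom_lengths if c not in chromosomes),
        key=lambda c: (-chrom_lengths[c], c),
    )
    return chromosomes | set(scaffolds[:n_scaffolds])


# ---------------------------------------------------------------------------
# assembly


def assemble_array(
    sex_markers: pd.DataFrame,
    candidates: Sequence[CandidateSNP],
    config: DesignConfig,
    sequences: Iterable[str] | None = None,
) -> ArrayDesign:
    """Build the final tiered design.

    ``sex_markers`` (columns chrom, pos, ref, alt) enter verbatim.
    Candidates must already carry context, panel hits and probe classes.
    A candidate qualifying for several tiers lands in the highest one.
    Tier 4 (spaced + sparse fill) consumes the remaining budget up to
    ``config.target_size``.
    """
    if not len(candidates) and not len(sex_markers):
        raise ValueError("empty candidate set")
    rows: list[dict] = []
    used: set[tuple[str, int]] = set()

    for r in sex_markers.itertuples(index=False):
        key = (r.chrom, int(r.pos))
        if key in used:
            continue
        used.add(key)
        rows.append(
            {"marker_id": f"{r.chrom}_{r.pos}", "chrom": r.chrom, "pos": int(r.pos),
             "ref": r.ref, "alt": r.alt, "tier": TIER_SEX, "avg_maf": np.nan,
             "panel_hits": ""}
        )

    def viable_probe(c: CandidateSNP) -> bool:
        return c.probe_classes is not None and bool(VIABLE_PROBE_CLASSES & set(c.probe_classes))

    def add(c: CandidateSNP, tier: str) -> None:
        used.add(c.key)
        c.tier = tier
        rows.append(
            {"marker_id": c.snp_id, "chrom": c.chrom, "pos": c.pos,
             "ref": c.ref_allele, "alt": c.alt_allele, "tier": tier,
             "avg_maf": c.avg_maf, "panel_hits": ",".join(sorted(c.panel_hits))}
        )

    # tier 2: external-panel overlaps, included directly
    for c in sorted(candidates, key=lambda c: c.key):
        if c.key in used or not c.panel_hits:
            continue
        if config.tier2_require_probe and not viable_probe(c):
            continue
        if not config.tier2_bypass_maf and not (
            config.maf_lo <= c.avg_maf <= config.maf_hi
        ):
            continue
        if c.allele_pair in AMBIGUOUS_PAIRS:
            continue
        add(c, TIER_PANEL)

    # tiers 3-4 draw from fully-gated candidates
    gated = [
        c for c in candidates
        if c.key not in used
        and viable_probe(c)
        and c.allele_pair not in AMBIGUOUS_PAIRS
        and config.maf_lo <= c.avg_maf <= config.maf_hi
    ]
    for c in sorted((c for c in gated if c.context == CONTEXT_EXON), key=lambda c: c.key):
        if len(rows) >= config.target_size:
            break
        add(c, TIER_EXON)

    budget = config.target_size - len(rows)
    if budget > 0:
        remaining = [c for c in gated if c.key not in used]
        spaced = windowed_selection(
            remaining, window_bp=config.window_bp,
            eligible_contexts=config.eligible_contexts, sequences=sequences,
        )
        spaced = spaced[:budget]
        filled = sparse_fill(
            spaced, remaining, region_bp=config.sparse_region_bp,
            target_size=budget, eligible_contexts=config.eligible_contexts,
            sequences=sequences,
        )
        spaced_keys = {c.key for c in spaced}
        for c in filled:
            add(c, TIER_SPACED if c.key in spaced_keys else TIER_SPARSE)

    markers = pd.DataFrame(
        rows,
        columns=["marker_id", "chrom", "pos", "ref", "alt", "tier", "avg_maf", "panel_hits"],
    )
    design = ArrayDesign(
        markers=markers, target_size=config.target_size,
        window_bp=config.window_bp, sparse_region_bp=config.sparse_region_bp,
        n_scaffolds=config.n_scaffolds,
    )
    if len(design) < config.target_size:
        logger.info(
            "design shortfall: %d markers for target %d", len(design), config.target_size
        )
    return design
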