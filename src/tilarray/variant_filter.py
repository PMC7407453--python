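"""Discovery-side QC of pooled-sequencing variant calls.

Pool-Seq variant discovery estimates allele frequencies from read counts
over pooled DNA rather than from individual genotypes.  The caller's output
therefore carries per-pool depth and alternate-observation counts plus
site-level evidence fields (strand split of the alternate support, read
placement balance, properly-paired fractions).  This module parses such a
VCF and applies deterministic rule-based filters to retain high-confidence
biallelic SNVs:

* call support — the site is kept when at least ``min_alt_reads`` reads
  support the alternate allele or any single pool's alternate frequency
  exceeds ``min_pool_af``;
* interference — SNVs with any other variant closer than
  ``interference_bp`` on either side are removed (both members of a close
  pair), because nearby polymorphisms compromise array probe hybridisation;
* site quality — summed depth within ``[min_cov, max_cov]``, alternate
  support on both strands, at least ``min_side_reads`` reads placed on each
  side of the site, and more than ``min_paired_frac`` of both alternate and
  reference observations coming from properly paired reads.

All filters are pure predicates over a single record (the interference
filter over a position list), so decisions are order-independent and
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: reason strings used in rejection reports, one per filter clause
REASON_SUPPORT = "support"
REASON_LOW_COV = "low_coverage"
REASON_HIGH_COV = "high_coverage"
REASON_STRAND = "strand"
REASON_PLACEMENT = "placement"
REASON_PAIRED = "paired"
REASON_INTERFERENCE = "interference"

#: INFO keys required on every SNV record of a pooled VCF
REQUIRED_INFO_KEYS = ("DP", "AO", "SAF", "SAR", "RPL", "RPR", "PAIRED", "PAIREDR")


@dataclass
class PooledVariant:
    """One biallelic candidate SNV with its pooled-calling evidence.

    Coordinates are 1-based.  ``per_pool_depth`` and ``per_pool_alt_obs``
    are aligned with the pool (sample) columns of the source VCF.
    ``alt_fwd + alt_rev`` equals the summed alternate observations;
    ``reads_left``/``reads_right`` count reads placed to either side of the
    site (all observations, not only alternate ones).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    per_pool_depth: tuple[int, ...]
    per_pool_alt_obs: tuple[int, ...]
    alt_fwd: int
    alt_rev: int
    reads_left: int
    reads_right: int
    paired_frac_alt: float
    paired_frac_ref: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if len(self.per_pool_depth) != len(self.per_pool_alt_obs):
            raise ValueError("per-pool depth and alt-obs lengths differ")
        for d, a in zip(self.per_pool_depth, self.per_pool_alt_obs):
            if a > d:
                raise ValueError(
                    f"{self.chrom}:{self.pos}: alt observations ({a}) exceed depth ({d})"
                )
        if self.alt_fwd + self.alt_rev != self.total_alt:
            raise ValueError(
                f"{self.chrom}:{self.pos}: strand split {self.alt_fwd}+{self.alt_rev} "
                f"!= total alt observations {self.total_alt}"
            )
        for name in ("paired_frac_alt", "paired_frac_ref"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")

    @property
    def total_depth(self) -> int:
        return int(sum(self.per_pool_depth))

    @property
    def total_alt(self) -> int:
        return int(sum(self.per_pool_alt_obs))

    @property
    def pool_afs(self) -> tuple[float, ...]:
        """Per-pool alternate allele frequencies; NaN for zero-depth pools."""
        return tuple(
            a / d if d > 0 else float("nan")
            for a, d in zip(self.per_pool_alt_obs, self.per_pool_depth)
        )


@dataclass
class FilterConfig:
    """Thresholds of the discovery-side filters.

    Defaults: >=3 alternate reads or per-pool AF > 0.02 for call support;
    a 40 bp interference window; summed coverage in [50, 150]; >=2 reads
    placed on each side; > 90 % properly-paired support for both alleles.
    """

    min_alt_reads: int = 3
    min_pool_af: float = 0.02
    interference_bp: int = 40
    min_cov: int = 50
    max_cov: int = 150
    min_side_reads: int = 2
    min_paired_frac: float = 0.90
    per_pool_coverage: bool = False  # apply the coverage clause per pool instead of summed

    def __post_init__(self) -> None:
        if self.min_cov >= self.max_cov:
            raise ValueError("min_cov must be < max_cov")
        for name in ("min_alt_reads", "min_pool_af", "interference_bp",
                     "min_cov", "min_side_reads", "min_paired_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PooledVariantSet:
    """Biallelic SNVs retained from a pooled VCF plus load bookkeeping.

    ``other_positions`` keeps the (chrom, pos) of records excluded at load
    time (indels, multiallelics): they still count as interfering variants
    for the spacing filter by default.
    """

    variants: list[PooledVariant] = field(default_factory=list)
    n_pools: int = 2
    n_skipped_indel: int = 0
    n_skipped_multiallelic: int = 0
    other_positions: list[tuple[str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def sorted(self) -> "PooledVariantSet":
        out = PooledVariantSet(
            variants=sorted(self.variants, key=lambda v: (v.chrom, v.pos)),
            n_pools=self.n_pools,
            n_skipped_indel=self.n_skipped_indel,
            n_skipped_multiallelic=self.n_skipped_multiallelic,
            other_positions=sorted(self.other_positions),
        )
        return out


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref != "-" and alt != "-"


def load_pooled_vcf(path: str | Path, n_pools: int) -> PooledVariantSet:
    """Read a pooled-calling VCF, keeping biallelic SNVs only.

    Per-pool depths and alternate observations are taken from the DP/AO
    FORMAT fields of the pool columns; site-level evidence from the INFO
    keys DP, AO, SAF, SAR, RPL, RPR, PAIRED and PAIREDR.  Indel and
    multiallelic records are counted, logged and retained as interfering
    positions.  A missing required INFO key raises ``ValueError`` naming the
    key and record.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    vcf = VCF(str(path))
    if len(vcf.samples) != n_pools:
        raise ValueError(
            f"expected {n_pools} pool columns, VCF has {len(vcf.samples)}: {vcf.samples}"
        )
    vset = PooledVariantSet(n_pools=n_pools)
    for rec in vcf:
        chrom, pos = rec.CHROM, rec.POS
        if len(rec.ALT) != 1:
            vset.n_skipped_multiallelic += 1
            vset.other_positions.append((chrom, pos))
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if not _is_snv(ref, alt):
            vset.n_skipped_indel += 1
            vset.other_positions.append((chrom, pos))
            continue
        info = dict(rec.INFO)
        for key in REQUIRED_INFO_KEYS:
            if key not in info:
                raise ValueError(
                    f"missing required INFO key {key!r} at record {chrom}:{pos}"
                )

        def _scalar(key: str) -> float:
            v = info[key]
            if isinstance(v, tuple):
                v = v[0]
            return float(v)

        depths = rec.format("DP")
        alts = rec.format("AO")
        if depths is None or alts is None:
            raise ValueError(f"missing per-pool DP/AO FORMAT fields at {chrom}:{pos}")
        per_pool_depth = tuple(int(max(x, 0)) for x in np.asarray(depths).reshape(-1))
        per_pool_alt = tuple(int(max(x, 0)) for x in np.asarray(alts).reshape(-1))
        vset.variants.append(
            PooledVariant(
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                per_pool_depth=per_pool_depth,
                per_pool_alt_obs=per_pool_alt,
                alt_fwd=int(_scalar("SAF")),
                alt_rev=int(_scalar("SAR")),
                reads_left=int(_scalar("RPL")),
                reads_right=int(_scalar("RPR")),
                paired_frac_alt=_scalar("PAIRED"),
                paired_frac_ref=_scalar("PAIREDR"),
            )
        )
    if vset.n_skipped_indel or vset.n_skipped_multiallelic:
        logger.info(
            "skipped %d indel and %d multiallelic records while loading %s",
            vset.n_skipped_indel, vset.n_skipped_multiallelic, path,
        )
    return vset


def call_support_filter(
    v: PooledVariant, cfg: FilterConfig | None = None
) -> tuple[bool, str | None]:
    """Minimum evidence for calling: enough alternate reads, or a pool AF
    above the frequency floor.  The two conditions are a disjunction."""
    cfg = cfg or FilterConfig()
    if v.total_alt >= cfg.min_alt_reads:
        return True, None
    afs = [f for f in v.pool_afs if not np.isnan(f)]
    if any(f > cfg.min_pool_af for f in afs):
        return True, None
    return False, REASON_SUPPORT


def quality_filter(
    v: PooledVariant, cfg: FilterConfig | None = None
) -> tuple[bool, list[str]]:
    """Site-quality clauses; returns every failed clause, not just the first.

    Coverage bounds are inclusive; the paired-fraction clause is a strict
    inequality (exactly 90 % fails); strand support requires at least one
    alternate read on each strand.
    """
    cfg = cfg or FilterConfig()
    reasons: list[str] = []
    if cfg.per_pool_coverage:
        if any(d < cfg.min_cov for d in v.per_pool_depth):
            reasons.append(REASON_LOW_COV)
        if any(d > cfg.max_cov for d in v.per_pool_depth):
            reasons.append(REASON_HIGH_COV)
    else:
        if v.total_depth < cfg.min_cov:
            reasons.append(REASON_LOW_COV)
        elif v.total_depth > cfg.max_cov:
            reasons.append(REASON_HIGH_COV)
    if v.alt_fwd < 1 or v.alt_rev < 1:
        reasons.append(REASON_STRAND)
    if v.reads_left < cfg.min_side_reads or v.reads_right < cfg.min_side_reads:
        reasons.append(REASON_PLACEMENT)
    if not (v.paired_frac_alt > cfg.min_paired_frac
            and v.paired_frac_ref > cfg.min_paired_frac):
        reasons.append(REASON_PAIRED)
    return (not reasons), reasons


def drop_interfering(
    variants: PooledVariantSet | Sequence[PooledVariant],
    cfg: FilterConfig | None = None,
    extra_positions: Iterable[tuple[str, int]] | None = None,
) -> tuple[list[PooledVariant], list[PooledVariant]]:
    """Remove SNVs with another variant strictly closer than the window.

    A variant goes when any other variant position on the same chromosome
    satisfies ``0 < |delta| < interference_bp``; both members of a close
    pair are removed.  ``extra_positions`` lets records excluded at load
    time (indels, multiallelics) still exert interference.

    Returns ``(kept, removed)`` in (chrom, pos) order.
    """
    cfg = cfg or FilterConfig()
    if isinstance(variants, PooledVariantSet):
        if extra_positions is None:
            extra_positions = variants.other_positions
        vlist = list(variants.variants)
    else:
        vlist = list(variants)
    vlist.sort(key=lambda v: (v.chrom, v.pos))

    pos_by_chrom: dict[str, list[int]] = {}
    for v in vlist:
        pos_by_chrom.setdefault(v.chrom, []).append(v.pos)
    for chrom, pos in extra_positions or ():
        pos_by_chrom.setdefault(chrom, []).append(pos)
    arr_by_chrom = {
        c: np.unique(np.asarray(p, dtype=np.int64)) for c, p in pos_by_chrom.items()
    }

    kept: list[PooledVariant] = []
    removed: list[PooledVariant] = []
    w = cfg.interference_bp
    for v in vlist:
        arr = arr_by_chrom[v.chrom]
        i = int(np.searchsorted(arr, v.pos))
        interferes = False
        # nearest strictly-smaller and strictly-larger positions
        if i > 0 and v.pos - arr[i - 1] < w and v.pos != arr[i - 1]:
            interferes = True
        j = i
        if j < len(arr) and arr[j] == v.pos:
            j += 1
        if j < len(arr) and arr[j] - v.pos < w:
            interferes = True
        (removed if interferes else kept).append(v)
    return kept, removed


def pool_average_maf(v: PooledVariant) -> float:
    """Minor allele frequency from the unweighted mean of per-pool AFs.

    Pools with zero depth are ignored; the mean alternate frequency is
    folded to ``min(f, 1 - f)``.
    """
    afs = [a / d for a, d in zip(v.per_pool_alt_obs, v.per_pool_depth) if d > 0]
    if not afs:
        raise ValueError(f"{v.chrom}:{v.pos}: no pool has nonzero depth")
    f = float(np.mean(afs))
    return min(f, 1.0 - f)


def apply_filters(
    vset: PooledVariantSet, cfg: FilterConfig | None = None
) -> tuple[list[PooledVariant], pd.DataFrame]:
    """Run support, interference and quality filters in discovery order.

    Returns the surviving variants and a rejection report with one row per
    rejected variant and a comma-joined list of failed clauses.
    """
    cfg = cfg or FilterConfig()
    reasons_by_key: dict[tuple[str, int], list[str]] = {}

    supported: list[PooledVariant] = []
    for v in vset:
        ok, reason = call_support_filter(v, cfg)
        if ok:
            supported.append(v)
        else:
            reasons_by_key.setdefault((v.chrom, v.pos), []).append(reason)

    spaced, interfering = drop_interfering(
        supported, cfg, extra_positions=vset.other_positions
    )
    for v in interfering:
        reasons_by_key.setdefault((v.chrom, v.pos), []).append(REASON_INTERFERENCE)

    passed: list[PooledVariant] = []
    for v in spaced:
        ok, reasons = quality_filter(v, cfg)
        if ok:
            passed.append(v)
        else:
            reasons_by_key.setdefault((v.chrom, v.pos), []).extend(reasons)

    report = pd.DataFrame(
        [
            {"chrom": c, "pos": p, "failed_clauses": ",".join(r)}
            for (c, p), r in sorted(reasons_by_key.items())
        ],
        columns=["chrom", "pos", "failed_clauses"],
    )
    return passed, report
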