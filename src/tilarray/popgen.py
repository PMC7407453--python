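"""Per-population summary statistics of array genotypes.

Observed heterozygosity (Ho) is the fraction of called genotypes that are
heterozygous, averaged over SNPs; expected heterozygosity (He) is the
Hardy-Weinberg 2p(1-p) at the sample allele frequency, averaged over the
same SNPs.  Confidence intervals for Ho come from a percentile bootstrap
over SNPs.  Markers are additionally binned into informativeness
categories by sample MAF, and cross-strain sharing of informative markers
(MAF > 0) is summarised as Venn-cell counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .genotype_qc import MISSING, GenotypeMatrix

MAF_COMMON = "Common"
MAF_INTERMEDIATE = "Intermediate"
MAF_LOW = "Low"
MAF_RARE = "Rare"
MAF_FIXED = "Fixed"
MAF_CATEGORIES = (MAF_COMMON, MAF_INTERMEDIATE, MAF_LOW, MAF_RARE, MAF_FIXED)


@dataclass
class PopSummary:
    """One population's diversity summary (one row of a Table-1-style report)."""

    population: str
    n_samples: int
    ho: float
    he: float
    ho_ci: tuple[float, float]
    maf_category_counts: dict[str, int]
    n_informative: int


def _per_snp_ho_he(m: GenotypeMatrix, population: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP observed and expected heterozygosity for one population.

    SNPs with zero called genotypes in the population are NaN.
    """
    idx = m.pop_index(population)
    calls = m.calls[idx]
    ok = calls != MISSING
    n = ok.sum(axis=0)
    n_het = ((calls == 1) & ok).sum(axis=0)
    alt = np.where(ok, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, n_het / n, np.nan)
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
    he = 2.0 * p * (1.0 - p)
    return ho, he


def heterozygosity(m: GenotypeMatrix, population: str) -> tuple[float, float]:
    """Population (Ho, He): unweighted means over SNPs with >= 1 call."""
    ho, he = _per_snp_ho_he(m, population)
    ok = ~np.isnan(ho)
    if not ok.any():
        raise ValueError(f"population {population!r} has no callable SNPs")
    return float(ho[ok].mean()), float(he[ok].mean())


def bootstrap_ci(
    m: GenotypeMatrix,
    population: str,
    stat: str = "ho",
    reps: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for Ho (or He), resampling SNPs.

    Resampling markers rather than individuals matches the genome-wide,
    per-population reporting of the statistic.  A single-SNP matrix yields
    a degenerate zero-width interval with a warning.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ho, he = _per_snp_ho_he(m, population)
    values = {"ho": ho, "he": he}[stat.lower()]
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError(f"population {population!r} has no callable SNPs")
    if values.size == 1:
        warnings.warn("single callable SNP: bootstrap interval is degenerate")
        return float(values[0]), float(values[0])
    rng = np.random.default_rng(seed)
    n = values.size
    idx = rng.integers(0, n, size=(reps, n))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def maf_categorize(m: GenotypeMatrix, population: str) -> dict[str, int]:
    """Count SNPs per MAF informativeness category in one population.

    Common: MAF >= 0.3; Intermediate: 0.1 <= MAF < 0.3; Low:
    0.05 <= MAF < 0.1; Rare: 0 < MAF < 0.05; Fixed: MAF == 0.  Boundary
    values land in the higher-MAF class.  SNPs with no called genotype are
    excluded.
    """
    maf = m.maf(m.pop_index(population))
    maf = maf[~np.isnan(maf)]
    return {
        MAF_COMMON: int((maf >= 0.3).sum()),
        MAF_INTERMEDIATE: int(((maf >= 0.1) & (maf < 0.3)).sum()),
        MAF_LOW: int(((maf >= 0.05) & (maf < 0.1)).sum()),
        MAF_RARE: int(((maf > 0) & (maf < 0.05)).sum()),
        MAF_FIXED: int((maf == 0).sum()),
    }


def n_informative(m: GenotypeMatrix, population: str) -> int:
    """Markers segregating (sample MAF > 0) in the population."""
    maf = m.maf(m.pop_index(population))
    return int((maf > 0).sum())


def informative_intersections(
    matrices_by_strain: Mapping[str, GenotypeMatrix] | GenotypeMatrix,
) -> tuple[dict[str, int], dict[frozenset, int]]:
    """Per-strain informative-marker counts and exclusive Venn cells.

    Accepts either one multi-population matrix (strains = its populations)
    or a mapping of per-strain matrices sharing the same SNP index.
    Returns ``(per_strain_totals, venn)`` where ``venn`` maps each
    non-empty strain subset to the count of SNPs informative in exactly
    that subset; cells containing a strain sum to its total.
    """
    if isinstance(matrices_by_strain, GenotypeMatrix):
        m = matrices_by_strain
        masks = {
            pop: m.maf(m.pop_index(pop)) > 0 for pop in m.population_names
        }
    else:
        ref_index = None
        masks = {}
        for name, m in matrices_by_strain.items():
            key = list(zip(m.snps["chrom"], m.snps["pos"]))
            if ref_index is None:
                ref_index = key
            elif key != ref_index:
                raise ValueError("strain matrices have mismatched SNP indices")
            masks[name] = m.maf() > 0
    strains = list(masks)
    totals = {s: int(masks[s].sum()) for s in strains}
    stack = np.vstack([masks[s] for s in strains])
    venn: dict[frozenset, int] = {}
    for k in range(1, len(strains) + 1):
        for subset in combinations(range(len(strains)), k):
            inset = np.ones(stack.shape[1], dtype=bool)
            for i in subset:
                inset &= stack[i]
            for i in range(len(strains)):
                if i not in subset:
                    inset &= ~stack[i]
            venn[frozenset(strains[i] for i in subset)] = int(inset.sum())
    return totals, venn


def pop_summaries(
    m: GenotypeMatrix,
    reps: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> list[PopSummary]:
    """Table-1-style rows: one diversity summary per population."""
    out = []
    for pop in m.population_names:
        ho, he = heterozygosity(m, pop)
        ci = bootstrap_ci(m, pop, reps=reps, level=level, seed=seed)
        out.append(
            PopSummary(
                population=pop,
                n_samples=int(m.pop_index(pop).size),
                ho=ho,
                he=he,
                ho_ci=ci,
                maf_category_counts=maf_categorize(m, pop),
                n_informative=n_informative(m, pop),
            )
        )
    return out


def summaries_to_frame(summaries: list[PopSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "population": s.population, "n_samples": s.n_samples,
            "he": s.he, "ho": s.ho,
            "ho_ci_low": s.ho_ci[0], "ho_ci_high": s.ho_ci[1],
            "n_informative": s.n_informative,
        }
        row.update({f"maf_{k.lower()}": v for k, v in s.maf_category_counts.items()})
        rows.append(row)
    return pd.DataFrame(rows)
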