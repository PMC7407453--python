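"""Validation-side genotype QC.

Mirrors the standard post-genotyping workflow for an Axiom-style array:
call-based probe-set classification, SNP and sample call-rate filtering,
identity-by-state (IBS) duplicate removal, and greedy LD pruning.  The
probe-set classes follow the Axiom vocabulary, with the restriction that
only genotype calls are available here: the Off-Target Variant class
requires raw intensity clusters and is therefore subsumed into ``Other``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel in the int8 call matrix

CLASS_POLY = "PolyHighResolution"
CLASS_NO_MINOR_HOM = "NoMinorHom"
CLASS_MONO = "MonoHighRes"
CLASS_CALLRATE = "CallRateBelowThreshold"
CLASS_OTHER = "Other"
PROBESET_CLASSES = (CLASS_POLY, CLASS_NO_MINOR_HOM, CLASS_MONO, CLASS_CALLRATE, CLASS_OTHER)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs diploid calls with population labels.

    ``calls`` is int8 with values 0/1/2 (alternate-allele dosage) and -1
    for missing.  ``snps`` columns: chrom, pos, ref, alt (1-based
    positions, sorted within chromosome).  ``populations`` aligns with
    ``samples``.
    """

    samples: list[str]
    populations: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)} samples, {len(self.snps)} snps)"
            )
        if len(self.populations) != len(self.samples):
            raise ValueError("populations must align with samples")
        if len(self.snps):
            for _, grp in self.snps.groupby("chrom", sort=False):
                if not grp["pos"].is_monotonic_increasing:
                    raise ValueError("SNP positions must be sorted within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def snp_call_rate(self) -> np.ndarray:
        return self.called().mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return self.called().mean(axis=1)

    def allele_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per SNP over called genotypes (NaN if
        nothing called)."""
        calls = self.calls if sample_idx is None else self.calls[sample_idx]
        ok = calls != MISSING
        n = ok.sum(axis=0)
        s = np.where(ok, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, s / (2.0 * n), np.nan)

    def maf(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        p = self.allele_freq(sample_idx)
        return np.minimum(p, 1.0 - p)

    def pop_index(self, population: str) -> np.ndarray:
        idx = np.array([i for i, p in enumerate(self.populations) if p == population])
        if idx.size == 0:
            raise KeyError(f"population {population!r} has no samples")
        return idx

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in sample_idx],
            populations=[self.populations[i] for i in sample_idx],
            snps=self.snps.iloc[snp_idx].reset_index(drop=True),
            calls=self.calls[np.ix_(sample_idx, snp_idx)],
        )

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, genotypes_path: str | Path, popmap_path: str | Path | None = None) -> None:
        """Write a SNP-rows x sample-columns table (0/1/2/NA) plus a popmap."""
        df = pd.DataFrame(
            np.where(self.calls == MISSING, np.nan, self.calls).T,
            columns=self.samples,
        )
        out = pd.concat([self.snps.reset_index(drop=True), df], axis=1)
        out.to_csv(genotypes_path, sep="\t", index=False, na_rep="NA", float_format="%.0f")
        if popmap_path is not None:
            pd.DataFrame({"sample": self.samples, "population": self.populations}).to_csv(
                popmap_path, sep="\t", index=False
            )

    @classmethod
    def from_tsv(cls, genotypes_path: str | Path, popmap_path: str | Path | None = None
                 ) -> "GenotypeMatrix":
        df = pd.read_csv(genotypes_path, sep="\t", dtype={"chrom": str})
        meta_cols = [c for c in ("chrom", "pos", "ref", "alt") if c in df.columns]
        snps = df[meta_cols].copy()
        geno = df.drop(columns=meta_cols)
        calls = geno.to_numpy(dtype=float).T
        calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
        samples = list(geno.columns)
        if popmap_path is not None:
            popmap = pd.read_csv(popmap_path, sep="\t").set_index("sample")["population"]
            missing = [s for s in samples if s not in popmap.index]
            if missing:
                raise ValueError(f"samples absent from popmap: {missing}")
            populations = [str(popmap[s]) for s in samples]
        else:
            populations = ["pop1"] * len(samples)
        return cls(samples=samples, populations=populations, snps=snps, calls=calls)


# ---------------------------------------------------------------------------
# probe-set classification


def classify_probesets(
    m: GenotypeMatrix,
    call_rate_min: float = 0.97,
    het_excess_max: float = 1.0,
) -> pd.Series:
    """Assign each SNP one call-based probe-set class.

    Order of precedence: call rate below ``call_rate_min`` ->
    CallRateBelowThreshold; one observed genotype class -> MonoHighRes;
    heterozygotes but no minor homozygote -> NoMinorHom; all three classes
    with heterozygote fraction <= ``het_excess_max`` -> PolyHighResolution;
    anything else -> Other.  The classes partition the SNP set.
    """
    if m.n_samples == 0:
        raise ValueError("cannot classify probesets with zero samples")
    ok = m.called()
    cr = ok.mean(axis=0)
    n0 = ((m.calls == 0) & ok).sum(axis=0)
    n1 = ((m.calls == 1) & ok).sum(axis=0)
    n2 = ((m.calls == 2) & ok).sum(axis=0)
    n_called = n0 + n1 + n2
    n_classes = (n0 > 0).astype(int) + (n1 > 0).astype(int) + (n2 > 0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_called > 0, n1 / n_called, 0.0)

    out = np.full(m.n_snps, CLASS_OTHER, dtype=object)
    minor_hom_absent = ((n0 == 0) | (n2 == 0))
    out[(n_classes == 2) & (n1 > 0) & minor_hom_absent] = CLASS_NO_MINOR_HOM
    out[(n_classes == 3) & (het_frac <= het_excess_max)] = CLASS_POLY
    out[n_classes <= 1] = CLASS_MONO
    out[cr < call_rate_min] = CLASS_CALLRATE
    return pd.Series(out, name="probeset_class")


def filter_matrix(
    m: GenotypeMatrix,
    snp_cr_min: float = 0.95,
    sample_cr_min: float = 0.90,
    keep_classes: frozenset[str] | set[str] = frozenset({CLASS_POLY}),
    probeset_classes: pd.Series | None = None,
    call_rate_min: float = 0.97,
) -> GenotypeMatrix:
    """Retain high-quality SNPs then high-quality samples.

    SNPs must be in ``keep_classes`` with call rate strictly above
    ``snp_cr_min``; samples need call rate strictly above
    ``sample_cr_min``.  SNPs first, then samples, then one re-iteration of
    the SNP call-rate check on the reduced sample set.
    """
    if probeset_classes is None:
        probeset_classes = classify_probesets(m, call_rate_min=call_rate_min)
    keep_classes = set(keep_classes)
    snp_idx = np.where(
        probeset_classes.isin(keep_classes).to_numpy() & (m.snp_call_rate() > snp_cr_min)
    )[0]
    m2 = m.subset(snp_idx=snp_idx)
    sample_idx = np.where(m2.sample_call_rate() > sample_cr_min)[0]
    if sample_idx.size == 0:
        raise ValueError("all samples removed by the call-rate filter")
    m3 = m2.subset(sample_idx=sample_idx)
    snp_idx2 = np.where(m3.snp_call_rate() > snp_cr_min)[0]
    m4 = m3.subset(snp_idx=snp_idx2)
    logger.info(
        "filter_matrix: %d/%d SNPs, %d/%d samples retained",
        m4.n_snps, m.n_snps, m4.n_samples, m.n_samples,
    )
    return m4


# ---------------------------------------------------------------------------
# IBS de-duplication


def ibs_matrix(m: GenotypeMatrix) -> np.ndarray:
    """Pairwise allele-sharing: mean over co-called SNPs of 1 - |gi-gj|/2.

    Pairs with no co-called SNP get 0 with a warning (IBS undefined).
    """
    g = m.calls.astype(np.float64)
    g[m.calls == MISSING] = np.nan
    n = m.n_samples
    out = np.ones((n, n))
    undefined = False
    for i in range(n):
        for j in range(i + 1, n):
            d = np.abs(g[i] - g[j])
            ok = ~np.isnan(d)
            if not ok.any():
                undefined = True
                out[i, j] = out[j, i] = 0.0
                continue
            out[i, j] = out[j, i] = 1.0 - d[ok].mean() / 2.0
    if undefined:
        warnings.warn("sample pair(s) with zero co-called SNPs; IBS set to 0")
    return out


def ibs_dedupe(m: GenotypeMatrix, ibs_max: float = 0.80) -> GenotypeMatrix:
    """Drop one member of every pair sharing more than ``ibs_max`` IBS.

    Pairs are processed by descending IBS; within each still-intact pair
    the later-indexed sample is dropped (first by input order wins).
    """
    if m.n_samples < 2:
        raise ValueError("ibs_dedupe needs at least 2 samples")
    ibs = ibs_matrix(m)
    pairs = [
        (ibs[i, j], i, j)
        for i in range(m.n_samples)
        for j in range(i + 1, m.n_samples)
        if ibs[i, j] > ibs_max
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    dropped: set[int] = set()
    for _, i, j in pairs:
        if i in dropped or j in dropped:
            continue
        dropped.add(j)
    keep = [i for i in range(m.n_samples) if i not in dropped]
    if dropped:
        logger.info("ibs_dedupe: dropped %d near-duplicate samples", len(dropped))
    return m.subset(sample_idx=keep)


# ---------------------------------------------------------------------------
# LD pruning


def _dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over co-called samples; NaN when either
    vector has zero variance."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(
    m: GenotypeMatrix,
    r2_max: float = 0.7,
    window_bp: int = 500_000,
) -> GenotypeMatrix:
    """Greedy keep-first LD pruning within each chromosome.

    Scanning left to right, a SNP is dropped when its dosage r^2 with any
    already-retained SNP within ``window_bp`` exceeds ``r2_max``; pass
    ``window_bp=None`` for an exact all-pairs mode.
    """
    keep_global: list[int] = []
    for chrom, grp in m.snps.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        retained: list[int] = []
        for k, j in enumerate(idx):
            drop = False
            for r in reversed(retained):
                if window_bp is not None and pos[k] - m.snps.at[r, "pos"] > window_bp:
                    break
                r2 = _dosage_r2(m.calls[:, r], m.calls[:, j])
                if not np.isnan(r2) and r2 > r2_max:
                    drop = True
                    break
            if not drop:
                retained.append(j)
        keep_global.extend(retained)
    keep_global.sort()
    logger.info("ld_prune: retained %d/%d SNPs", len(keep_global), m.n_snps)
    return m.subset(snp_idx=keep_global)
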