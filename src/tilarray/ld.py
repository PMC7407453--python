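"""Linkage-disequilibrium magnitude and decay.

LD between two SNPs is the squared Pearson correlation r^2 of their
genotype dosage vectors.  Because small family-structured samples inflate
r^2, a relatedness-corrected version is also provided: both dosage vectors
are whitened by the inverse Cholesky factor of a genomic relationship
(kinship) matrix before correlating, so that covariance induced purely by
relatedness is removed.  With an identity kinship the corrected statistic
reduces exactly to the plain r^2.

Decay curves average r^2 in 10-kb distance bins per chromosome and then
(unweighted) across chromosomes, out to 10,000 kb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from .genotype_qc import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    """Symmetric PSD genomic relationship matrix (VanRaden-type)."""

    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.samples), len(self.samples)):
            raise ValueError("kinship matrix shape does not match samples")
        if not np.allclose(v, v.T):
            raise ValueError("kinship matrix must be symmetric")
        self.values = v

    @classmethod
    def identity(cls, samples: list[str]) -> "KinshipMatrix":
        return cls(samples=samples, values=np.eye(len(samples)))


@dataclass
class DecayCurve:
    """Mean r^2 per distance bin for one population.

    ``bins`` columns: distance_lo, distance_hi (1-based inclusive bp),
    mean_r2 (NaN for empty bins), n_pairs.
    """

    population: str
    maf_threshold: float
    bins: pd.DataFrame

    def bin_at(self, distance_bp: int) -> pd.Series:
        """The bin containing ``distance_bp``."""
        sel = self.bins[
            (self.bins["distance_lo"] <= distance_bp)
            & (self.bins["distance_hi"] >= distance_bp)
        ]
        if sel.empty:
            raise KeyError(f"no bin contains distance {distance_bp}")
        return sel.iloc[0]


def estimate_kinship(m: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from centred, scaled dosages.

    G = Z Z' / (2 * sum p(1-p)) with Z the per-SNP mean-centred dosage
    matrix (missing calls mean-imputed).  Monomorphic SNPs carry no
    information and are excluded; an all-monomorphic input raises.
    """
    if m.n_samples < 2 or m.n_snps < 2:
        raise ValueError("kinship estimation needs >= 2 samples and >= 2 SNPs")
    p = m.allele_freq()
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not poly.any():
        raise ValueError("no polymorphic SNPs: kinship undefined")
    g = m.calls[:, poly].astype(float)
    pp = p[poly]
    g[m.calls[:, poly] == MISSING] = np.nan
    g = np.where(np.isnan(g), 2 * pp, g)
    z = g - 2 * pp
    denom = 2.0 * np.sum(pp * (1 - pp))
    k = z @ z.T / denom
    k = (k + k.T) / 2.0
    return KinshipMatrix(samples=list(m.samples), values=k)


def _whitener(kinship: KinshipMatrix, ridge: float = 1e-8) -> np.ndarray:
    """Lower Cholesky factor of K (with a tiny ridge for semidefiniteness)."""
    k = kinship.values
    n = k.shape[0]
    jitter = ridge * np.trace(k) / n
    for _ in range(8):
        try:
            return cholesky(k + jitter * np.eye(n), lower=True)
        except np.linalg.LinAlgError:
            jitter *= 10
    raise np.linalg.LinAlgError("kinship matrix is too ill-conditioned to factor")


def _sq_cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Squared cosine of two already-centred vectors."""
    na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
    if na == 0 or nb == 0:
        return np.nan
    r = (a @ b) / (na * nb)
    return float(r * r)


def _sq_corr(a: np.ndarray, b: np.ndarray) -> float:
    return _sq_cosine(a - a.mean(), b - b.mean())


def pairwise_r2(
    m: GenotypeMatrix,
    maf_min: float = 0.05,
    kinship: KinshipMatrix | None = None,
    max_bp: int = 10_000_000,
    max_pairs_per_chrom: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Same-chromosome pairwise LD after a MAF filter.

    SNPs with sample MAF <= ``maf_min`` are excluded (strict threshold,
    MAF > maf_min kept).  Plain r^2 correlates dosages over co-called
    samples; with a kinship matrix, missing dosages are mean-imputed and
    both vectors are whitened by the inverse Cholesky factor of K before
    correlating (r^2vs).  Zero-variance vectors make the pair NaN and a
    skip counter is logged.  ``max_pairs_per_chrom`` subsamples pairs for
    large inputs (seeded).

    Returns a DataFrame with chrom, pos_i, pos_j, distance_bp, r2.
    """
    maf = m.maf()
    keep = np.where(~np.isnan(maf) & (maf > maf_min))[0]
    sub = m.subset(snp_idx=keep)

    if kinship is not None:
        # generalised least squares: whiten dosages by the inverse Cholesky
        # factor of K, then centre at the GLS mean (project out the whitened
        # one-vector).  K is singular along the one-vector for a VanRaden GRM
        # built from centred dosages, so this projection also removes the
        # ridge-amplified component.  With K = I this is exactly Pearson.
        linv_applied = True
        g = sub.calls.astype(float)
        g[sub.calls == MISSING] = np.nan
        p = sub.allele_freq()
        g = np.where(np.isnan(g), 2 * p, g)
        L = _whitener(kinship)
        gw = solve_triangular(L, g, lower=True)
        u = solve_triangular(L, np.ones(g.shape[0]), lower=True)
        gw = gw - np.outer(u, (u @ gw) / (u @ u))
    else:
        linv_applied = False

    rng = np.random.default_rng(seed)
    rows = []
    n_skipped = 0
    for chrom, grp in sub.snps.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        ii, jj = np.triu_indices(len(idx), k=1)
        dist = pos[jj] - pos[ii]
        ok = dist <= max_bp
        ii, jj, dist = ii[ok], jj[ok], dist[ok]
        if max_pairs_per_chrom is not None and len(ii) > max_pairs_per_chrom:
            take = rng.choice(len(ii), size=max_pairs_per_chrom, replace=False)
            take.sort()
            ii, jj, dist = ii[take], jj[take], dist[take]
        for a, b, d in zip(ii, jj, dist):
            i, j = idx[a], idx[b]
            if linv_applied:
                r2 = _sq_cosine(gw[:, i], gw[:, j])
            else:
                x, y = sub.calls[:, i], sub.calls[:, j]
                cc = (x != MISSING) & (y != MISSING)
                if cc.sum() < 2:
                    r2 = np.nan
                else:
                    r2 = _sq_corr(x[cc].astype(float), y[cc].astype(float))
            if np.isnan(r2):
                n_skipped += 1
                continue
            rows.append((chrom, int(pos[a]), int(pos[b]), int(d), r2))
    if n_skipped:
        logger.info("pairwise_r2: skipped %d zero-variance pairs", n_skipped)
    return pd.DataFrame(rows, columns=["chrom", "pos_i", "pos_j", "distance_bp", "r2"])


def bin_decay(
    pairs: pd.DataFrame,
    bin_bp: int = 10_000,
    max_bp: int = 10_000_000,
    population: str = "",
    maf_threshold: float = 0.0,
    average: str = "within_chrom",
) -> DecayCurve:
    """Average r^2 in contiguous distance bins.

    A pair at distance d lands in bin ``floor((d-1)/bin_bp)`` (bin k spans
    ``[k*bin_bp + 1, (k+1)*bin_bp]``).  ``average='within_chrom'`` takes
    per-chromosome bin means then the unweighted mean across chromosomes;
    ``average='pooled'`` pools all pairs.  Bins with no pairs report NaN.
    """
    n_bins = int(np.ceil(max_bp / bin_bp))
    lo = np.arange(n_bins, dtype=np.int64) * bin_bp + 1
    hi = lo + bin_bp - 1
    mean_r2 = np.full(n_bins, np.nan)
    n_pairs = np.zeros(n_bins, dtype=np.int64)
    if len(pairs):
        pairs = pairs[pairs["distance_bp"] <= max_bp]
        b = ((pairs["distance_bp"] - 1) // bin_bp).to_numpy()
        counts = np.bincount(b, minlength=n_bins)
        n_pairs = counts[:n_bins]
        if average == "pooled":
            sums = np.bincount(b, weights=pairs["r2"].to_numpy(), minlength=n_bins)[:n_bins]
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_r2 = np.where(n_pairs > 0, sums / n_pairs, np.nan)
        elif average == "within_chrom":
            per_chrom = (
                pairs.assign(bin=b)
                .groupby(["chrom", "bin"], sort=False)["r2"]
                .mean()
                .reset_index()
                .groupby("bin")["r2"]
                .mean()
            )
            for bi, v in per_chrom.items():
                if bi < n_bins:
                    mean_r2[bi] = v
        else:
            raise ValueError(f"unknown averaging mode {average!r}")
    bins = pd.DataFrame(
        {"distance_lo": lo, "distance_hi": hi, "mean_r2": mean_r2, "n_pairs": n_pairs}
    )
    return DecayCurve(population=population, maf_threshold=maf_threshold, bins=bins)


def percent_drop(
    curve: DecayCurve, d_near: int = 10_000, d_far: int = 10_000_000
) -> float:
    """Percentage fall of mean r^2 between the near and far bins.

    100 * (r2_near - r2_far) / r2_near; negative values (LD rising with
    distance) are allowed and logged.
    """
    near = curve.bin_at(d_near)
    far = curve.bin_at(d_far)
    if near["n_pairs"] == 0 or np.isnan(near["mean_r2"]):
        raise ValueError(f"near bin at {d_near} bp is empty")
    if far["n_pairs"] == 0 or np.isnan(far["mean_r2"]):
        raise ValueError(f"far bin at {d_far} bp is empty")
    drop = 100.0 * (near["mean_r2"] - far["mean_r2"]) / near["mean_r2"]
    if drop < 0:
        logger.warning("negative LD drop (%.1f%%): r^2 increases with distance", drop)
    return float(drop)


def decay_curve(
    m: GenotypeMatrix,
    population: str,
    maf_min: float = 0.05,
    corrected: bool = True,
    bin_bp: int = 10_000,
    max_bp: int = 10_000_000,
    max_pairs_per_chrom: int | None = None,
    seed: int | None = None,
) -> DecayCurve:
    """Per-population decay curve, optionally relatedness-corrected."""
    sub = m.subset(sample_idx=m.pop_index(population))
    kin = estimate_kinship(sub) if corrected else None
    pairs = pairwise_r2(
        sub, maf_min=maf_min, kinship=kin, max_bp=max_bp,
        max_pairs_per_chrom=max_pairs_per_chrom, seed=seed,
    )
    return bin_decay(
        pairs, bin_bp=bin_bp, max_bp=max_bp,
        population=population, maf_threshold=maf_min,
    )


def plot_decay(curves: list[DecayCurve], path=None, ax=None):
    """Mean r^2 vs inter-marker distance (kb), one line per population."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for c in curves:
        mid = (c.bins["distance_lo"] + c.bins["distance_hi"]) / 2e3
        ok = c.bins["n_pairs"] > 0
        ax.plot(mid[ok], c.bins.loc[ok, "mean_r2"], marker=".", lw=1,
                label=f"{c.population} (MAF>{c.maf_threshold:g})")
    ax.set_xlabel("inter-marker distance (kb)")
    ax.set_ylabel(r"mean $r^2$")
    ax.set_xscale("log")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
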