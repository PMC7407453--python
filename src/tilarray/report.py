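"""Pipeline orchestration and bookkeeping reports.

Both pipeline drivers read one YAML configuration with ``design:`` and
``validation:`` blocks, run the corresponding modules in order, and emit a
``RunReport``: stage-by-stage counts with conservation checks (every
stage's input equals kept + rejected) and percentages that are always
recomputed from their counts at formatting time, never stored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import array_design as ad
from . import genotype_qc as qc
from . import ld as ldmod
from . import pca as pcamod
from . import popgen
from .variant_filter import FilterConfig, load_pooled_vcf, apply_filters

logger = logging.getLogger(__name__)


def format_percent(count: int, total: int, decimals: int = 1) -> str:
    """``100 * count / total`` rounded half-away-from-zero.

    Exact decimal arithmetic, so printed report percentages are a pure
    function of their counts.
    """
    if total == 0:
        raise ValueError("total must be > 0")
    pct = Decimal(count) * 100 / Decimal(total)
    q = Decimal(1).scaleb(-decimals)
    return str(pct.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunReport:
    """Counts per pipeline stage, with conservation asserted on append."""

    seeds: dict = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, n_in: int, n_kept: int, detail: dict | None = None) -> None:
        n_rejected = n_in - n_kept
        if n_rejected < 0:
            raise ValueError(f"stage {name}: kept ({n_kept}) exceeds input ({n_in})")
        self.stages.append(
            {"stage": name, "n_in": int(n_in), "n_kept": int(n_kept),
             "n_rejected": int(n_rejected), **(detail or {})}
        )

    def percent_kept(self, stage_name: str, decimals: int = 1) -> str:
        for s in self.stages:
            if s["stage"] == stage_name:
                return format_percent(s["n_kept"], s["n_in"], decimals)
        raise KeyError(stage_name)

    def to_dict(self) -> dict:
        return {"seeds": self.seeds, "config": self.config_echo, "stages": self.stages}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def _require_files(cfg: dict, keys: list[str]) -> None:
    for key in keys:
        path = cfg.get(key)
        if path is None:
            raise ValueError(f"config missing required input {key!r}")
        if isinstance(path, (list, tuple)):
            for p in path:
                if not Path(p).exists():
                    raise FileNotFoundError(f"{key}: {p}")
        elif not Path(path).exists():
            raise FileNotFoundError(f"{key}: {path}")


def run_design(config: dict | str | Path) -> tuple[ad.ArrayDesign, RunReport]:
    """Discovery VCF -> filtered candidates -> tiered array design.

    Config keys (under ``design:`` when nested): vcf, gff, panels (list of
    TSV paths), scores, sex_markers (optional TSV), n_pools, target_size,
    plus any FilterConfig / DesignConfig field.
    """
    cfg = _load_config(config)
    cfg = cfg.get("design", cfg)
    _require_files(cfg, ["vcf", "gff"])
    report = RunReport(config_echo=dict(cfg))

    fcfg = FilterConfig(**{
        k: cfg[k] for k in (
            "min_alt_reads", "min_pool_af", "interference_bp", "min_cov",
            "max_cov", "min_side_reads", "min_paired_frac",
        ) if k in cfg
    })
    dcfg = ad.DesignConfig(**{
        k: cfg[k] for k in (
            "target_size", "window_bp", "sparse_region_bp", "n_scaffolds",
            "maf_lo", "maf_hi", "flank_bp",
        ) if k in cfg
    })

    vset = load_pooled_vcf(cfg["vcf"], n_pools=cfg.get("n_pools", 2))
    n_raw = len(vset) + vset.n_skipped_indel + vset.n_skipped_multiallelic
    report.add_stage("load_vcf", n_raw, len(vset), {
        "skipped_indel": vset.n_skipped_indel,
        "skipped_multiallelic": vset.n_skipped_multiallelic,
    })

    passed, rejections = apply_filters(vset, fcfg)
    report.add_stage("variant_filters", len(vset), len(passed))

    annotation = ad.GenomeAnnotation.from_gff3(cfg["gff"])
    candidates = ad.classify_context(passed, annotation, flank_bp=dcfg.flank_bp)
    report.add_stage("classify_context", len(passed), len(candidates), {
        "contexts": pd.Series([c.context for c in candidates]).value_counts().to_dict(),
    })

    panels = {}
    for path in cfg.get("panels", []):
        panels[Path(path).stem] = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    ad.crossref_panels(candidates, panels)

    if cfg.get("scores"):
        scores = pd.read_csv(cfg["scores"], sep="\t")
        pool = ad.probe_score_gate(candidates, scores,
                                   missing_policy=dcfg.missing_score_policy)
        report.add_stage("probe_score_gate", len(candidates), len(pool))
    else:
        pool = list(candidates)

    sex_markers = (
        pd.read_csv(cfg["sex_markers"], sep="\t", dtype={"chrom": str})
        if cfg.get("sex_markers") else
        pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    )
    if dcfg.target_size == 0:
        design = ad.ArrayDesign(
            markers=pd.DataFrame(columns=[
                "marker_id", "chrom", "pos", "ref", "alt", "tier", "avg_maf", "panel_hits",
            ]),
            target_size=0,
        )
    else:
        sequences = None
        if annotation.chrom_lengths:
            sequences = ad.eligible_sequences(
                annotation.chrom_lengths, n_scaffolds=dcfg.n_scaffolds
            )
        design = ad.assemble_array(sex_markers, pool, dcfg, sequences=sequences)
    report.add_stage("assemble_array", len(pool) + len(sex_markers), len(design),
                     {"tier_counts": design.tier_counts,
                      "shortfall": max(dcfg.target_size - len(design), 0)})

    out_dir = cfg.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        design.to_tsv(out / "array_design.tsv")
        rejections.to_csv(out / "rejections.tsv", sep="\t", index=False)
        report.to_json(out / "design_report.json")
    return design, report


def run_validation(config: dict | str | Path) -> tuple[dict, RunReport]:
    """Genotypes -> QC -> diversity, LD decay and structure summaries."""
    cfg = _load_config(config)
    cfg = cfg.get("validation", cfg)
    _require_files(cfg, ["genotypes"])
    report = RunReport(config_echo=dict(cfg))
    seed = cfg.get("seed", 0)
    report.seeds["bootstrap"] = seed

    m = qc.GenotypeMatrix.from_tsv(cfg["genotypes"], cfg.get("popmap"))
    if not m.called().any():
        raise ValueError("genotype file contains no called genotypes")
    classes = qc.classify_probesets(m, call_rate_min=cfg.get("call_rate_min", 0.97))
    report.add_stage("classify_probesets", m.n_snps, m.n_snps,
                     {"class_counts": classes.value_counts().to_dict()})

    m_f = qc.filter_matrix(
        m,
        snp_cr_min=cfg.get("snp_cr_min", 0.95),
        sample_cr_min=cfg.get("sample_cr_min", 0.90),
        keep_classes=set(cfg.get("keep_classes", [qc.CLASS_POLY])),
        probeset_classes=classes,
    )
    report.add_stage("filter_matrix_snps", m.n_snps, m_f.n_snps)
    report.add_stage("filter_matrix_samples", m.n_samples, m_f.n_samples)

    m_d = qc.ibs_dedupe(m_f, ibs_max=cfg.get("ibs_max", 0.80)) if m_f.n_samples >= 2 else m_f
    report.add_stage("ibs_dedupe", m_f.n_samples, m_d.n_samples)

    # LD decay uses the pre-pruning matrix; structure and summaries the pruned one
    curves = []
    for maf_min in cfg.get("ld_maf_thresholds", [0.05, 0.1]):
        for pop in m_d.population_names:
            if m_d.pop_index(pop).size < 2:
                continue
            curves.append(ldmod.decay_curve(
                m_d, pop, maf_min=maf_min,
                bin_bp=cfg.get("ld_bin_bp", 10_000),
                max_bp=cfg.get("ld_max_bp", 10_000_000),
                max_pairs_per_chrom=cfg.get("ld_max_pairs_per_chrom"),
                seed=seed,
            ))

    m_p = qc.ld_prune(m_d, r2_max=cfg.get("r2_max", 0.7),
                      window_bp=cfg.get("ld_prune_window_bp", 500_000))
    report.add_stage("ld_prune", m_d.n_snps, m_p.n_snps)

    summaries = popgen.pop_summaries(
        m_p, reps=cfg.get("bootstrap_reps", 1000), seed=seed
    )

    pca_res = None
    if m_p.n_samples >= 3:
        n_comp = min(cfg.get("n_components", 10), m_p.n_samples - 1, m_p.n_snps)
        pca_res = pcamod.run_pca(m_p, n_components=n_comp)
    else:
        logger.warning("fewer than 3 samples after QC: PCA skipped")

    results = {
        "probeset_classes": classes,
        "summaries": summaries,
        "summary_table": popgen.summaries_to_frame(summaries),
        "decay_curves": curves,
        "pca": pca_res,
        "matrix": m_p,
    }
    out_dir = cfg.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results["summary_table"].to_csv(out / "pop_summaries.tsv", sep="\t", index=False)
        if curves:
            pd.concat(
                [c.bins.assign(population=c.population, maf_threshold=c.maf_threshold)
                 for c in curves]
            ).to_csv(out / "ld_decay.tsv", sep="\t", index=False)
        if pca_res is not None:
            pcamod.coordinates_frame(pca_res).to_csv(
                out / "pca_coordinates.tsv", sep="\t", index=False
            )
        report.to_json(out / "validation_report.json")
    return results, report
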