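"""Shared synthetic fixtures: everything is generated at test time."""

import numpy as np
import pandas as pd
import pytest

from tilarray.synthdata import (
    PopSpec,
    SimConfig,
    VIOLATION_KINDS,
    default_design,
    simulate_annotation,
    simulate_genotype_panel,
    simulate_panels_and_scores,
    simulate_pooled_variants,
    write_pooled_vcf,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=101, n_chromosomes=2, chromosome_length_bp=2_000_000,
                     gene_density=30)


@pytest.fixture(scope="session")
def annotation(sim_config):
    return simulate_annotation(sim_config)


@pytest.fixture(scope="session")
def flagged_variants(sim_config, annotation):
    """1,000-site pooled variant set with 2 % of sites per violation kind."""
    rng = np.random.default_rng(7)
    mafs = rng.uniform(0.05, 0.5, 1000)
    vset, truth = simulate_pooled_variants(
        sim_config, annotation, mafs,
        violation_fractions={k: 0.02 for k in VIOLATION_KINDS},
        indel_count=10,
    )
    return vset, truth


@pytest.fixture(scope="session")
def design_inputs(tmp_path_factory, sim_config, annotation, flagged_variants):
    """On-disk design-side inputs: VCF, GFF3, panels, scores, sex markers."""
    out = tmp_path_factory.mktemp("design_inputs")
    vset, truth = flagged_variants
    panels, scores = simulate_panels_and_scores(vset, 0.1, sim_config)
    annotation.to_gff3(out / "annotation.gff3")
    write_pooled_vcf(vset, out / "pooled.vcf", sim_config)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    panel_paths = []
    for name, df in panels.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        panel_paths.append(str(p))
    sex = pd.DataFrame(
        {"chrom": ["chr1", "chr1", "chr2"], "pos": [11, 22, 33],
         "ref": ["A", "C", "G"], "alt": ["G", "T", "A"]}
    )
    sex.to_csv(out / "sex_markers.tsv", sep="\t", index=False)
    return {
        "dir": out,
        "vcf": str(out / "pooled.vcf"),
        "gff": str(out / "annotation.gff3"),
        "truth": str(out / "truth.tsv"),
        "scores": str(out / "scores.tsv"),
        "panels": panel_paths,
        "sex_markers": str(out / "sex_markers.tsv"),
    }


@pytest.fixture(scope="session")
def two_pop_matrix():
    """Two populations at FST 0.2, 2,000 SNPs, 15 samples each, weak LD."""
    cfg = SimConfig(seed=55, ld_rho=1.0)
    design = default_design(cfg, 2000)
    rng = np.random.default_rng(3)
    anc = rng.uniform(0.1, 0.9, 2000)
    pops = [PopSpec("north", 15, 0.2, anc), PopSpec("south", 15, 0.2, anc)]
    return simulate_genotype_panel(design, pops, cfg)


@pytest.fixture(scope="session")
def hwe_matrix():
    """Single unstructured population at HWE, independent SNPs."""
    cfg = SimConfig(seed=56, ld_rho=1.0)
    design = default_design(cfg, 1500)
    rng = np.random.default_rng(4)
    anc = rng.uniform(0.1, 0.9, 1500)
    return simulate_genotype_panel(design, [PopSpec("gift", 40, 0.0, anc)], cfg)
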