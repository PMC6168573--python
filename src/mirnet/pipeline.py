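"""End-to-end pipeline: normalize -> DE -> integrate -> enrich -> candidates.

Reads a study directory laid out as :func:`mirnet.simulate.generate_study`
writes it (mrna_counts.tsv, mirna_counts.tsv, design.tsv, targets.tsv,
families.tsv, go_annotations.tsv, gene_sets.gmt), runs every stage and
writes all reports under an output directory. Every threshold actually
applied is logged and recorded in ``run_summary.yaml`` so a run is auditable.
Fixed (inputs, config, seed) => byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import candidates as cand
from . import diffexp, enrich, integrate, io, normalize
from .containers import MirnetError

log = logging.getLogger("mirnet")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and mode switches for a pipeline run.

    Defaults are the reference settings: DE calls at adjusted p < 0.05 and
    |fold change| > 2; targets at WCSP > 50 with >= 1 seed site; top 50
    expressed DEmiRs; >= 10 conserved targets per stage; 1,000 gene-set
    permutations with weight p = 1.
    """

    alpha: float = 0.05
    fc_threshold: float = 2.0
    wcsp_threshold: float = 50.0
    min_seed_sites: int = 1
    top_k: int = 50
    min_targets: int = 10
    n_perm: int = 1000
    gsea_weight: float = 1.0
    quantile: bool = True  # quantile-normalize after log2(+1)
    equal_var: bool = False  # pooled-variance t instead of Welch
    candidate_stage_scope: str = "union"  # or a stage label
    run_gsea: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.alpha, self.fc_threshold, self.wcsp_threshold, self.top_k, self.min_targets, self.n_perm) <= 0:
            raise MirnetError("all thresholds must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    integration: integrate.IntegrationResult
    cascades: list[cand.CandidateCascade]
    outdir: Path
    deg_table: object
    demir_table: object


STUDY_FILES = {
    "mrna_counts": "mrna_counts.tsv",
    "mirna_counts": "mirna_counts.tsv",
    "design": "design.tsv",
    "targets": "targets.tsv",
    "families": "families.tsv",
    "go_annotations": "go_annotations.tsv",
    "gene_sets": "gene_sets.gmt",
}


def run_pipeline(
    study_dir: str | Path, outdir: str | Path, config: PipelineConfig | None = None
) -> PipelineResult:
    """Execute the full analysis on a study directory and write all reports."""
    config = config or PipelineConfig()
    study_dir = Path(study_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: study_dir / v for k, v in STUDY_FILES.items()}
    for name, p in paths.items():
        if not p.exists():
            raise MirnetError(f"missing study input {name}: {p}")

    log.info(
        "thresholds: alpha=%s fc=%s wcsp>%s seed_sites>=%s top_k=%s min_targets=%s n_perm=%s weight=%s",
        config.alpha, config.fc_threshold, config.wcsp_threshold, config.min_seed_sites,
        config.top_k, config.min_targets, config.n_perm, config.gsea_weight,
    )

    design = io.read_design(paths["design"])
    mrna_counts = io.read_counts(paths["mrna_counts"], design, "mRNA")
    mirna_counts = io.read_counts(paths["mirna_counts"], design, "miRNA")
    registry = io.read_families(paths["families"])
    predictions = io.read_predictions(paths["targets"])
    go = io.read_go_annotations(paths["go_annotations"])
    gene_sets = io.read_gmt(paths["gene_sets"])

    # normalization chain for both layers; the linear filtered RPM matrix is
    # kept for the abundance ranking and the top-k share
    mrna_expr = normalize.normalize_chain(mrna_counts, quantile=config.quantile)
    mirna_rpm_linear = normalize.filter_all_zero(normalize.rpm(mirna_counts))
    mirna_expr = normalize.quantile_normalize(normalize.log2_shift(mirna_rpm_linear)) \
        if config.quantile else normalize.log2_shift(mirna_rpm_linear)
    io.write_expression(mrna_expr, outdir / "mrna_normalized.tsv")
    io.write_expression(mirna_expr, outdir / "mirna_normalized.tsv")

    qc = normalize.replicate_correlation(mrna_expr)
    qc.to_csv(outdir / "replicate_correlation.tsv", sep="\t", index=False)

    degs = diffexp.call_differential_all_stages(
        mrna_expr, design, config.alpha, config.fc_threshold, config.equal_var
    )
    demirs = diffexp.call_differential_all_stages(
        mirna_expr, design, config.alpha, config.fc_threshold, config.equal_var
    )
    io.write_de_table(degs, outdir / "deg_table.tsv")
    io.write_de_table(demirs, outdir / "demir_table.tsv")
    for stage in design.stages:
        log.info(
            "stage %s: %d DEGs, %d DEmiRs", stage,
            len(degs.de_features(stage)), len(demirs.de_features(stage)),
        )

    result = integrate.select_robust_families(
        demirs,
        degs,
        mirna_rpm_linear,
        predictions,
        registry,
        k=config.top_k,
        min_targets=config.min_targets,
        wcsp_threshold=config.wcsp_threshold,
        min_seed_sites=config.min_seed_sites,
    )
    for step, n in result.cascade:
        log.info("cascade %-24s -> %d families", step, n)
    integrate.export_network(result, outdir)

    # GSEA on the full mRNA ranking per stage (gene-set permutation null)
    if config.run_gsea:
        children = np.random.SeedSequence(config.seed).spawn(len(design.stages))
        for stage, child in zip(design.stages, children):
            ranked = enrich.rank_by_metric(mrna_expr, stage, design)
            gsea = enrich.permutation_significance(
                ranked,
                gene_sets,
                n_perm=config.n_perm,
                seed=np.random.default_rng(child),
                weight=config.gsea_weight,
            )
            gsea.to_csv(outdir / f"gsea_{stage}.tsv", sep="\t", index=False)

    # GO enrichment of the DEG sets per stage
    universe = set(mrna_expr.values.index)
    for stage in design.stages:
        query = degs.de_features(stage)
        if query:
            table = enrich.hypergeometric_enrich(query, go, universe)
            table.to_csv(outdir / f"go_enrichment_{stage}.tsv", sep="\t", index=False)

    # candidate cascades for the selected (stage-robust) families
    cascades = []
    stages = design.stages
    for fam in result.selected_families:
        direction = result.family_records[fam].consistent_direction(stages)
        cascades.append(
            cand.apoptosis_candidates(
                fam,
                direction,
                predictions,
                degs,
                go,
                stage_scope=config.candidate_stage_scope,
                wcsp_threshold=config.wcsp_threshold,
                min_seed_sites=config.min_seed_sites,
            )
        )
    cand.cascade_report(cascades, outdir / "candidate_cascade.tsv")
    cand.candidate_list(cascades, outdir / "candidate_genes.tsv")

    io.write_yaml(
        {
            "config": config.to_dict(),
            "selected_families": result.selected_families,
            "cascade": [[s, n] for s, n in result.cascade],
            "eliminated": result.eliminated,
            "top_share": result.top_share,
            "candidates": {c.family_id: sorted(c.final_candidates) for c in cascades},
        },
        outdir / "run_summary.yaml",
    )
    return PipelineResult(
        integration=result,
        cascades=cascades,
        outdir=outdir,
        deg_table=degs,
        demir_table=demirs,
    )
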