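"""End-to-end pipeline: simulate -> exposure -> progression -> QC ->
enrichment -> prioritization -> report.

The analysis cohort is built the way the source study reduced its
population: subjects need a computable exposure score (non-empty
window), a progression score (>= 2 visits by default), must survive the
relatedness exclusion (PI_HAT > 0.05), and must belong to one of the two
analysis subpopulations.  Display scales for both scores are anchored to
this final cohort, so the >= 1 prioritization thresholds are relative to
the analysed subjects only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enr
from . import exposure as expo
from . import prioritize as pri
from . import progression as prog
from . import qc
from .config import RunConfig, SimulationConfig
from .simulate import SyntheticCohort, generate_cohort, generate_replication
from .vcfio import write_tsv, write_vcf

__all__ = ["PipelineResult", "run_all", "write_outputs"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    longterm: pd.DataFrame
    discovered_clusters: list
    exposure_scores: pd.DataFrame
    progression_scores: pd.DataFrame
    progression_fit: prog.ProgressionFit
    kinship: pd.DataFrame
    related_removed: list[str]
    subpopulations: dict[str, list[str]]
    analysis_ids: list[str]
    eligibility: pd.DataFrame
    exclusions: pd.DataFrame
    enrichment: pd.DataFrame
    averaged: pd.DataFrame
    prioritized: pd.DataFrame
    genes: pd.DataFrame
    replication: pd.DataFrame | None
    additivity: dict
    report: pri.SummaryReport
    extras: dict = field(default_factory=dict)


def run_all(
    sim_config: SimulationConfig,
    run_config: RunConfig | None = None,
    include_replication: bool = True,
) -> PipelineResult:
    """Run every stage on a freshly generated synthetic cohort."""
    rc = run_config or RunConfig()
    cohort = generate_cohort(sim_config)
    subjects, visits = cohort.subjects, cohort.visits

    # exposure: long-term averages, cluster discovery, weighted score
    longterm = expo.longterm_average(
        cohort.applications, subjects, rc.window
    )
    try:
        discovered = expo.correlation_cluster(longterm, rc.cluster_cutpoint)
    except ValueError:
        discovered = []
    unexposable = set(longterm.attrs.get("unexposable", []))

    # progression: REML mixed model on the full cohort
    scores_all, fit = prog.progression_scores(
        visits, subjects, min_visits=rc.min_visits_for_score
    )
    scored_ids = set(scores_all["subject_id"])

    # relatedness exclusion
    kinship = qc.estimate_pihat(cohort.relatedness_genotypes)
    _, removed = qc.exclude_related(subjects, kinship, rc.ibd_threshold)

    subpops_all = qc.split_subpopulations(subjects)
    in_subpop = {s for members in subpops_all.values() for s in members}
    analysis_ids = [
        s
        for s in subjects["subject_id"]
        if s in scored_ids
        and s not in unexposable
        and s not in set(removed)
        and s in in_subpop
    ]
    subpops = {
        label: [s for s in members if s in set(analysis_ids)]
        for label, members in subpops_all.items()
    }

    # final display scores anchored to the analysis cohort
    exposure_scores = expo.weighted_cluster_score(
        longterm, cohort.cluster_spec, cohort=analysis_ids
    )
    eb = fit.eb_slopes.loc[fit.eb_slopes.index.intersection(analysis_ids)]
    progression_scores = prog.residualize_slopes(eb, subjects)

    # variant QC
    panel1, eligibility, excl_call = qc.apply_call_filters(
        cohort.panel,
        subpops,
        min_quality=rc.min_site_quality,
        min_depth=rc.min_depth,
        min_depth_fraction=rc.min_depth_fraction,
    )
    panel2, excl_region = qc.restrict_exonic_canonical(panel1)
    panel3, excl_gene = qc.apply_special_gene_rules(panel2)
    eligibility = eligibility.loc[panel3.variant_ids]
    exclusions = pd.concat(
        [
            excl_call.assign(stage="call_filters"),
            excl_region.assign(stage="exonic_canonical"),
            excl_gene.assign(stage="special_gene_rules"),
        ],
        ignore_index=True,
    )

    # enrichment vs matched reference populations
    enrichment = enr.enrich_all(
        panel3,
        cohort.reference,
        subpops,
        eligibility=eligibility,
        population_map=rc.population_map,
        alpha=rc.alpha,
        min_depth=rc.min_depth,
    )

    # prioritization and ranking
    averaged = pri.carrier_averages(
        enrichment, panel3, exposure_scores, progression_scores, subpops
    )
    prioritized = pri.threshold_prioritize(
        averaged, rc.exposure_min, rc.progression_min
    )
    prioritized = pri.composite_score(prioritized)
    additivity = pri.additivity_check(prioritized)

    replication = None
    if include_replication and len(prioritized):
        rep_pd, rep_hc = generate_replication(
            sim_config, cohort.panel, cohort.reference, cohort.truth
        )
        replication = enr.replication_test(
            list(prioritized["variant_id"].unique()),
            rep_pd,
            rep_hc,
            alpha=rc.alpha,
            min_depth=rc.min_depth,
        )

    genes = pri.gene_rollup(prioritized)
    report = pri.build_report(prioritized, genes, replication, additivity)

    return PipelineResult(
        cohort=cohort,
        longterm=longterm,
        discovered_clusters=discovered,
        exposure_scores=exposure_scores,
        progression_scores=progression_scores,
        progression_fit=fit,
        kinship=kinship,
        related_removed=removed,
        subpopulations=subpops,
        analysis_ids=analysis_ids,
        eligibility=eligibility,
        exclusions=exclusions,
        enrichment=enrichment,
        averaged=averaged,
        prioritized=prioritized,
        genes=genes,
        replication=replication,
        additivity=additivity,
        report=report,
    )


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write every table of a pipeline run (deterministic formatting)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    c = result.cohort
    write_tsv(c.subjects, out / "subjects.tsv")
    write_tsv(c.visits, out / "visits.tsv")
    write_tsv(c.applications, out / "applications.tsv")
    write_vcf(c.panel, out / "panel.vcf")
    write_tsv(c.reference, out / "reference_freq.tsv")
    write_tsv(c.gene_panel, out / "gene_panel.tsv")
    write_tsv(
        c.relatedness_genotypes.reset_index(), out / "genotypes.tsv"
    )
    c.truth.to_json(out / "truth.json")
    with open(out / "cluster_spec.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "cluster_id": c.cluster_spec.cluster_id,
                "members": c.cluster_spec.members,
                "beta_weights": c.cluster_spec.beta_weights,
            },
            fh,
            sort_keys=True,
        )
    with open(out / "discovered_clusters.yaml", "w") as fh:
        yaml.safe_dump(
            {
                cl.cluster_id: cl.members
                for cl in result.discovered_clusters
            },
            fh,
            sort_keys=True,
        )
    write_tsv(result.exposure_scores, out / "exposure_scores.tsv")
    write_tsv(result.progression_scores, out / "progression_scores.tsv")
    write_tsv(result.kinship, out / "kinship.tsv")
    write_tsv(result.exclusions, out / "exclusions.tsv")
    write_tsv(result.enrichment, out / "enrichment.tsv")
    write_tsv(result.averaged, out / "carrier_averages.tsv")
    write_tsv(result.prioritized, out / "prioritized.tsv")
    write_tsv(result.genes, out / "genes.tsv")
    if result.replication is not None:
        write_tsv(result.replication, out / "replication.tsv")
    with open(out / "report.md", "w") as fh:
        fh.write(result.report.to_markdown())
    if len(result.averaged):
        pri.plot_prioritization(result.averaged, out / "prioritization.png")
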