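"""End-to-end analysis pipeline over a simulated dataset, plus truth recovery.

Mirrors the study's arc: consolidate replicates per stage, partition the
tri-stage union into common/partial/stage-specific ACRs, quantify counts on
the common peaks, run DPI and DEG tests per stage pair, link promoter ACRs to
genes, correlate intensity with expression, cluster the DEG union into eight
patterns, test stage-specific-ACR gene overlap with clusters, integrate
DPI x DEG directions, and run motif enrichment on target promoter ACRs.

Counts for differential testing are quantified on the tri-stage merged
*common* ACRs, matching the study's choice to run differential peak
intensity on the ACRs present at all stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import landscape, linkage, integration
from .differential import (
    CountMatrix,
    CorrelationSummary,
    DifferentialResult,
    estimate_size_factors,
    filter_expressed,
    identify_degs,
    intensity_expression_correlation,
    nb_test_stages,
)
from .intervals import Peak, feature_proportions
from .simulate import STAGES, STAGE_PAIRS, SimulatedDataset, TruthSet


@dataclass
class PipelineResult:
    stage_sets: dict[str, landscape.StageACRSet]
    partition: landscape.SpecificityPartition
    proportions: dict[str, pd.DataFrame]
    chrom_corr: dict[str, float]
    common_counts: CountMatrix
    size_factors: pd.Series
    dpi: dict[tuple[str, str], DifferentialResult]
    promoter_assignment: linkage.PromoterAssignment
    expressed_genes: list[str]
    deg: dict[tuple[str, str], DifferentialResult]
    deg_union: set
    correlation: CorrelationSummary
    clusters: integration.ClusterAssignment | None
    specific_acr_genes: dict[str, set]
    cluster_overlap: pd.DataFrame | None
    quadrants: dict[tuple[str, str], integration.IntegrationQuadrants]
    motif_table: pd.DataFrame | None = None
    enrichment: landscape.EnrichmentResult | None = None


def quantify_common_counts(partition, dataset: SimulatedDataset) -> CountMatrix:
    """Counts for merged common ACRs, via their constituent sample counts.

    Consolidated peaks already carry per-sample sums of the replicate peaks
    they merged; common (tri-stage) peaks therefore hold all six samples.
    """
    cols = list(dataset.atac_counts.counts.columns)
    rows = {}
    for p in partition.common:
        counts = p.counts or {}
        rows[p.peak_id] = [int(counts.get(c, 0)) for c in cols]
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return CountMatrix(counts=mat, samples=dataset.atac_counts.samples.copy())


def stage_intensity_table(counts: CountMatrix, genes_peaks: dict) -> pd.DataFrame:
    """Gene x stage normalized promoter-peak intensity (replicate means)."""
    norm = counts.normalized()
    stage_mean = pd.DataFrame({
        s: norm[[c for c in norm.columns if c.startswith(s)]].mean(axis=1)
        for s in STAGES
    })
    rows = {}
    for gene, peak_ids in genes_peaks.items():
        ids = [p for p in peak_ids if p in stage_mean.index]
        if ids:
            rows[gene] = stage_mean.loc[ids].sum(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(STAGES))


def run_pipeline(dataset: SimulatedDataset, seed: int = 0,
                 n_permutations: int = 0) -> PipelineResult:
    """Run the full analysis; ``n_permutations > 0`` adds the enrichment null."""
    ann = dataset.annotation
    stage_sets = {
        s: landscape.consolidate_replicates(
            dataset.peaks[(s, 1)], dataset.peaks[(s, 2)], stage=s)
        for s in STAGES
    }
    partition = landscape.classify_specificity(stage_sets)
    proportions = {
        s: feature_proportions(stage_sets[s].peaks, ann) for s in STAGES
    }
    chrom_corr = {}
    for s in STAGES:
        _, r, r2 = landscape.chromosome_correlation(
            stage_sets[s].peaks, ann.chrom_sizes)
        chrom_corr[s] = r2

    common_counts = quantify_common_counts(partition, dataset)
    sf = estimate_size_factors(common_counts)
    common_counts.size_factors = sf
    dpi = {pair: nb_test_stages(common_counts, *pair) for pair in STAGE_PAIRS}

    all_merged = (partition.common + partition.partial
                  + [p for s in STAGES for p in partition.specific[s]])
    all_merged.sort(key=lambda p: (p.chrom, p.start, p.end, p.peak_id))
    assignment = linkage.assign_promoter_acrs(all_merged, ann)

    expr = dataset.expression
    expressed = filter_expressed(expr.fpkm, expr.samples)
    deg, deg_union = identify_degs(expr.count_matrix(), STAGE_PAIRS,
                                   genes=expressed)

    # intensity/expression correlation over genes with common promoter peaks
    common_ids = {p.peak_id for p in partition.common}
    genes_common_prom = {
        g: [rec["peak_id"] for rec in lst if rec["peak_id"] in common_ids]
        for g, lst in assignment.assignments.items()
    }
    genes_common_prom = {g: v for g, v in genes_common_prom.items() if v}
    intensity = stage_intensity_table(common_counts, genes_common_prom)
    correlation = intensity_expression_correlation(
        intensity, expr.stage_mean_fpkm())

    clusters = None
    overlap = None
    if len(deg_union) >= 8:
        stage_fpkm = expr.stage_mean_fpkm().loc[sorted(deg_union)]
        clusters = integration.cluster_degs(
            stage_fpkm, k=8, seed=seed,
            archetypes=dataset.config.cluster_pattern_archetypes)
    specific_genes = {}
    for s in STAGES:
        sa = linkage.assign_promoter_acrs(
            sorted(partition.specific[s],
                   key=lambda p: (p.chrom, p.start, p.end, p.peak_id)), ann)
        specific_genes[s] = sa.genes_with_acr()
    if clusters is not None:
        overlap = integration.cluster_overlap_fisher(
            specific_genes, clusters, universe=deg_union)

    quadrants = {
        pair: integration.integrate_dpi_deg(dpi[pair], deg[pair], assignment)
        for pair in STAGE_PAIRS
    }

    motif_table = None
    if dataset.sequences and dataset.truth.motif_placements:
        motif_table = motif_analysis(dataset, assignment, clusters)

    enrichment = None
    if n_permutations > 0:
        enrichment = landscape.permutation_enrichment(
            stage_sets[STAGES[0]].peaks, ann,
            n_permutations=n_permutations, seed=seed)

    return PipelineResult(
        stage_sets=stage_sets, partition=partition, proportions=proportions,
        chrom_corr=chrom_corr, common_counts=common_counts, size_factors=sf,
        dpi=dpi, promoter_assignment=assignment, expressed_genes=expressed,
        deg=deg, deg_union=deg_union, correlation=correlation,
        clusters=clusters, specific_acr_genes=specific_genes,
        cluster_overlap=overlap, quadrants=quadrants,
        motif_table=motif_table, enrichment=enrichment,
    )


def motif_analysis(dataset: SimulatedDataset,
                   assignment: linkage.PromoterAssignment,
                   clusters: integration.ClusterAssignment | None) -> pd.DataFrame:
    """Consensus-motif enrichment in target-cluster promoter ACR sequences.

    Targets are the promoter ACR sequences of genes assigned to the
    configured motif target clusters (the recovered clustering when
    available, the planted archetypes otherwise); background is every other
    promoter ACR sequence.  Sequences are taken from the planted peak
    intervals, which differ from the merged intervals only by the <= 20 bp
    replicate jitter at the edges.
    """
    cfg = dataset.config
    labels = clusters.labels if clusters is not None else dataset.truth.gene_clusters
    target_clusters = set(cfg.motif_target_clusters)
    target_seqs: dict[str, str] = {}
    background_seqs: dict[str, str] = {}
    for pid, pp in dataset.truth.planted_peaks.items():
        if pp.category != "promoter" or pp.host_gene is None:
            continue
        seq = dataset.sequences[pp.chrom][pp.start:pp.end]
        if labels.get(pp.host_gene) in target_clusters:
            target_seqs[pid] = seq
        else:
            background_seqs[pid] = seq
    if not target_seqs:
        return pd.DataFrame()
    return integration.motif_enrichment(
        target_seqs, background_seqs, cfg.motif_consensus_list, alpha=0.01)


# ---------------------------------------------------------------------------
# truth recovery metrics
# ---------------------------------------------------------------------------

def _overlaps_any(planted, peaks: list[Peak]) -> bool:
    for p in peaks:
        if (p.chrom == planted.chrom and
                min(p.end, planted.end) - max(p.start, planted.start) >= 1):
            return True
    return False


@dataclass
class RecoveryReport:
    specificity_recall: float
    common_recall: float
    promoter_assignment_recall: float
    cluster_ari: float
    n_clustered_truth_genes: int
    discordant_recovery: float
    dpi_recall: float
    dpi_sign_agreement: float
    fraction_positive: float
    median_r: float
    deg_union_size: int
    metrics: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "specificity_recall": self.specificity_recall,
            "common_recall": self.common_recall,
            "promoter_assignment_recall": self.promoter_assignment_recall,
            "cluster_ari": self.cluster_ari,
            "discordant_recovery": self.discordant_recovery,
            "dpi_recall": self.dpi_recall,
            "dpi_sign_agreement": self.dpi_sign_agreement,
            "fraction_positive": self.fraction_positive,
            "median_r": self.median_r,
        }


def evaluate_recovery(result: PipelineResult, truth: TruthSet) -> RecoveryReport:
    """Compare pipeline output with the planted truth (overlap-based)."""
    from sklearn.metrics import adjusted_rand_score

    # stage specificity
    spec_total = spec_hit = 0
    common_total = common_hit = 0
    for pid, label in truth.peak_labels.items():
        pp = truth.planted_peaks[pid]
        if label.startswith("specific:"):
            stage = label.split(":", 1)[1]
            spec_total += 1
            if _overlaps_any(pp, result.partition.specific[stage]):
                spec_hit += 1
        else:
            common_total += 1
            if _overlaps_any(pp, result.partition.common):
                common_hit += 1
    specificity_recall = spec_hit / spec_total if spec_total else float("nan")
    common_recall = common_hit / common_total if common_total else float("nan")

    # promoter assignment: planted promoter peak -> host gene recovered
    assigned_pairs = set()
    id_to_interval = {}
    for plist in ([result.partition.common, result.partition.partial]
                  + [result.partition.specific[s] for s in STAGES]):
        for p in plist:
            id_to_interval[p.peak_id] = p
    for gene, lst in result.promoter_assignment.assignments.items():
        for rec in lst:
            assigned_pairs.add((gene, rec["peak_id"]))
    prom_total = prom_hit = 0
    for pid, pp in truth.planted_peaks.items():
        if pp.category != "promoter" or pp.host_gene is None:
            continue
        prom_total += 1
        for gene, mid in assigned_pairs:
            if gene != pp.host_gene:
                continue
            p = id_to_interval.get(mid)
            if p is not None and _overlaps_any(pp, [p]):
                prom_hit += 1
                break
    promoter_recall = prom_hit / prom_total if prom_total else float("nan")

    # clustering
    ari = float("nan")
    n_truth = 0
    if result.clusters is not None and truth.gene_clusters:
        shared = sorted(set(truth.gene_clusters) & set(result.clusters.labels))
        n_truth = len(shared)
        if n_truth >= 2:
            ari = float(adjusted_rand_score(
                [truth.gene_clusters[g] for g in shared],
                [result.clusters.labels[g] for g in shared],
            ))

    # discordant genes
    off_diag = set()
    for quad in result.quadrants.values():
        off_diag |= quad.genes["atac_up_rna_down"] | quad.genes["atac_down_rna_up"]
    discordant_recovery = (
        len(off_diag & truth.discordant_genes) / len(truth.discordant_genes)
        if truth.discordant_genes else float("nan")
    )

    # DPI: recall and sign agreement over planted effects on recovered peaks
    planted_by_common = {}
    for p in result.partition.common:
        for pid, pp in truth.planted_peaks.items():
            if pid in truth.dpi_effects and _overlaps_any(pp, [p]):
                planted_by_common[p.peak_id] = pid
    total = hits = signs_ok = recovered_signed = 0
    for (a, b), res in result.dpi.items():
        for mid, pid in planted_by_common.items():
            expect = truth.dpi_expected_sign(pid, a, b)
            if expect == 0:
                continue
            total += 1
            row = res.table.loc[mid]
            if bool(row["significant"]):
                hits += 1
                recovered_signed += 1
                if int(np.sign(row["log2fc"])) == expect:
                    signs_ok += 1
    dpi_recall = hits / total if total else float("nan")
    dpi_sign = signs_ok / recovered_signed if recovered_signed else float("nan")

    return RecoveryReport(
        specificity_recall=specificity_recall,
        common_recall=common_recall,
        promoter_assignment_recall=promoter_recall,
        cluster_ari=ari,
        n_clustered_truth_genes=n_truth,
        discordant_recovery=discordant_recovery,
        dpi_recall=dpi_recall,
        dpi_sign_agreement=dpi_sign,
        fraction_positive=result.correlation.fraction_positive,
        median_r=result.correlation.median_r,
        deg_union_size=len(result.deg_union),
    )
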