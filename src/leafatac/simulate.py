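"""Synthetic multi-stage ATAC/RNA dataset generator with planted ground truth.

The generator emulates the statistical structure of a two-replicate,
three-stage (BBCH_11 / BBCH_13 / BBCH_17) leaf chromatin-accessibility study:

* a miniature genome of stranded gene models with exon/UTR structure;
* accessible chromatin regions (ACRs) planted per feature category, with
  category-dependent lengths, per-chromosome density proportional to
  chromosome length, shared peaks replicated across all stages and
  stage-specific peaks present in exactly one stage (<=20 bp replicate edge
  jitter keeps the >=1 bp reciprocal-overlap criterion intact);
* NB-distributed Tn5 count matrices with planted differential-intensity
  effects and stage-level intensity drift on shared peaks;
* gene expression (FPKM + raw exon counts) coupled to promoter accessibility,
  with eight planted expression-pattern archetypes and a small set of
  discordant genes whose accessibility coupling is sign-flipped (a repressor-
  binding caricature);
* Tn5 fragment files with a TSS pile-up component and a genome FASTA with
  consensus motifs embedded in designated promoter ACRs.

A single seed governs everything through a numpy SeedSequence spawn: each
artifact (genome, peaks, counts, expression, fragments, sequences) consumes
an independent child stream, so regenerating one artifact never perturbs the
others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .differential import CountMatrix
from .errors import ConfigError, SizingError
from .intervals import (
    FeatureCategory,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    Peak,
    write_bed,
    write_chrom_sizes,
    write_gff3,
    write_narrowpeak,
)

STAGES = ("BBCH_11", "BBCH_13", "BBCH_17")
STAGE_PAIRS = (("BBCH_11", "BBCH_13"), ("BBCH_11", "BBCH_17"),
               ("BBCH_13", "BBCH_17"))


def sample_ids() -> list[str]:
    return [f"{s}_rep{r}" for s in STAGES for r in (1, 2)]


def sample_table() -> pd.DataFrame:
    rows = [{"sample": f"{s}_rep{r}", "stage": s, "replicate": r}
            for s in STAGES for r in (1, 2)]
    return pd.DataFrame(rows).set_index("sample")


def _default_archetypes() -> tuple[tuple[float, float, float], ...]:
    """Eight distinct stage-pattern shapes, unit stage-sd, semantic order.

    1: first-stage up, 2: monotone decline, 3: last-stage down,
    4: first-stage down, 5: mid-stage down, 6: monotone rise,
    7: last-stage up, 8: mid-stage up.
    """
    base = np.array(
        [
            [2, -1, -1],
            [1, 0, -1],
            [1, 1, -2],
            [-2, 1, 1],
            [1, -2, 1],
            [-1, 0, 1],
            [-1, -1, 2],
            [-1, 2, -1],
        ],
        dtype=float,
    )
    z = (base - base.mean(axis=1, keepdims=True)) / base.std(axis=1, keepdims=True)
    return tuple(tuple(row) for row in z)


_DEFAULT_PLACEMENT = {
    "promoter": 0.25, "utr5": 0.05, "exon": 0.07,
    "intron": 0.28, "utr3": 0.05, "intergenic": 0.30,
}
_DEFAULT_LENGTHS = {
    "promoter": (400.0, 80.0), "utr5": (350.0, 70.0), "exon": (300.0, 60.0),
    "intron": (300.0, 60.0), "utr3": (600.0, 120.0), "intergenic": (200.0, 40.0),
}


@dataclass
class SimConfig:
    """Simulation parameters; defaults define the package's study conditions.

    Two replicates x three stages over a two-chromosome ~2 Mb genome with 300
    genes and ~600 planted ACRs.  Category placement probabilities and length
    parameters mirror the qualitative landscape the analysis expects
    (promoter/intron/intergenic-dominated placement; 3'UTR peaks longest,
    intergenic shortest).  See docs/methods.md for the rationale behind every
    numeric default.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_lengths: tuple[int, ...] = (1_200_000, 800_000)
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (1500, 3500)
    n_shared_peaks: int = 500
    n_specific_peaks_per_stage: tuple[int, int, int] = (60, 20, 20)
    category_placement_probs: dict = field(
        default_factory=lambda: dict(_DEFAULT_PLACEMENT))
    category_length_params: dict = field(
        default_factory=lambda: dict(_DEFAULT_LENGTHS))
    replicate_jitter_bp: int = 20
    min_peak_gap_bp: int = 45  # > 2 * jitter so planted peaks never merge

    # ATAC counts
    nb_dispersion: float = 0.05
    library_sizes: tuple[int, ...] = (
        1_000_000, 1_100_000, 950_000, 1_050_000, 900_000, 1_150_000)
    base_mean_log2: tuple[float, float] = (7.6, 1.0)  # log2 mean, sd (~200 median)
    intensity_drift_sd: float = 0.8  # per-stage log2 drift of shared peaks
    off_stage_mean_factor: float = 0.05  # residual signal of specific peaks
    dpi_log2fc: float = 2.5
    frac_dpi: float = 0.25

    # expression
    rna_library_sizes: tuple[int, ...] = (
        5_000_000, 5_500_000, 4_800_000, 5_200_000, 4_600_000, 5_400_000)
    expression_coupling: float = 1.0
    baseline_log2fpkm: tuple[float, float] = (2.5, 1.2)
    patterned_baseline_log2fpkm: tuple[float, float] = (3.0, 0.8)
    discordant_baseline_log2fpkm: tuple[float, float] = (3.5, 0.6)
    silent_gene_fraction: float = 0.10
    n_patterned_genes: int = 140
    archetype_amplitude: float = 2.5  # log2 stage-sd of archetype offsets
    cluster_pattern_archetypes: tuple = field(default_factory=_default_archetypes)
    specific_cluster_coupling: float = 0.8
    stage_archetype: dict = field(
        default_factory=lambda: {"BBCH_11": 1, "BBCH_13": 8, "BBCH_17": 7})
    n_discordant: int = 15

    # fragments & sequences
    n_fragments_per_sample: int = 40_000
    fragment_mixture: tuple[float, float, float] = (0.25, 0.55, 0.20)  # bg/peak/tss
    fragment_size: tuple[float, float] = (120.0, 40.0)
    tss_pileup_sd: float = 150.0
    promoter_fragment_weight: float = 1.5
    motif_consensus_list: tuple[str, ...] = ("TGACCA", "CACGTG")
    motif_target_clusters: tuple[int, ...] = (1, 7)
    motif_plant_prob: float = 0.8

    def __post_init__(self) -> None:
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ConfigError("chromosome_lengths length != n_chromosomes")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ConfigError("chromosome lengths must be positive")
        probs = self.category_placement_probs
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigError("category_placement_probs must sum to 1")
        if any(p < 0 for p in probs.values()):
            raise ConfigError("negative placement probability")
        for cat, (m, s) in self.category_length_params.items():
            if m <= 0 or s < 0:
                raise ConfigError(f"bad length parameters for {cat}")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if len(self.library_sizes) != 6 or len(self.rna_library_sizes) != 6:
            raise ConfigError("six samples (2 replicates x 3 stages) required")
        if self.n_discordant > self.n_genes:
            raise ConfigError("n_discordant exceeds n_genes")
        if len(self.cluster_pattern_archetypes) != 8:
            raise ConfigError("exactly 8 cluster archetypes required")
        if self.dpi_log2fc <= 0:
            raise ConfigError("dpi_log2fc must be positive")
        if not (0 <= self.frac_dpi <= 1):
            raise ConfigError("frac_dpi must be a proportion")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def streams(self) -> dict[str, np.random.Generator]:
        """Named independent RNG streams spawned from the single seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ["genome", "peaks", "counts", "expression", "fragments",
                 "sequences"]
        return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


@dataclass
class PlantedPeak:
    peak_id: str
    chrom: str
    start: int
    end: int
    category: str
    host_gene: str | None
    label: str  # "shared" or "specific:<stage>"

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def stages(self) -> tuple[str, ...]:
        if self.label == "shared":
            return STAGES
        return (self.label.split(":", 1)[1],)


@dataclass
class TruthSet:
    """Planted labels for recovery testing; see module docstring."""

    peak_labels: dict[str, str] = field(default_factory=dict)
    planted_peaks: dict[str, PlantedPeak] = field(default_factory=dict)
    dpi_effects: dict[str, dict] = field(default_factory=dict)
    stage_means: pd.DataFrame | None = None  # peak x stage NB means (pre size factor)
    gene_clusters: dict[str, int] = field(default_factory=dict)
    discordant_genes: set[str] = field(default_factory=set)
    motif_placements: dict[str, list] = field(default_factory=dict)
    expression_log2_mean: pd.DataFrame | None = None  # gene x stage

    def dpi_expected_sign(self, peak_id: str, stage_a: str, stage_b: str) -> int:
        """Expected log2FC sign (b over a) for a planted effect, 0 if none."""
        eff = self.dpi_effects.get(peak_id)
        if eff is None:
            return 0
        if eff["stage"] == stage_b:
            return int(np.sign(eff["log2fc"]))
        if eff["stage"] == stage_a:
            return -int(np.sign(eff["log2fc"]))
        return 0

    def to_json(self, path) -> None:
        payload = {
            "peak_labels": self.peak_labels,
            "planted_peaks": {k: asdict(v) for k, v in self.planted_peaks.items()},
            "dpi_effects": self.dpi_effects,
            "gene_clusters": self.gene_clusters,
            "discordant_genes": sorted(self.discordant_genes),
            "motif_placements": self.motif_placements,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _allocate_proportional(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of ``total`` items across weights."""
    quota = total * weights / weights.sum()
    alloc = np.floor(quota).astype(int)
    rem = total - alloc.sum()
    order = np.argsort(-(quota - alloc), kind="stable")
    alloc[order[:rem]] += 1
    return alloc


def generate_genome(config: SimConfig) -> GenomeAnnotation:
    """Deterministically generate stranded gene models with 2 kb flanks.

    Genes are allocated to chromosomes proportionally to length, packed with
    >=2 kb gaps (so promoter windows never intrude into neighbouring gene
    bodies), and given 1-4 exons with 5'/3' UTRs on the terminal exons.
    """
    rng = config.streams()["genome"]
    flank = 2000
    names = config.chrom_names()
    lengths = np.asarray(config.chromosome_lengths)
    per_chrom = _allocate_proportional(config.n_genes, lengths.astype(float))
    genes: list[GeneModel] = []
    gid = 0
    lo, hi = config.gene_length_range
    for chrom, chrom_len, n in zip(names, lengths, per_chrom):
        if n == 0:
            continue
        glens = rng.integers(lo, hi + 1, size=n)
        needed = int(glens.sum()) + flank * (n + 1)
        if needed > chrom_len:
            raise SizingError(
                f"{chrom}: {n} genes with 2 kb flanks need {needed} bp, "
                f"chromosome is {chrom_len} bp"
            )
        slack = int(chrom_len) - needed
        gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = flank + int(gaps[0])
        for i in range(n):
            L = int(glens[i])
            start, end = pos, pos + L
            strand = "+" if rng.random() < 0.5 else "-"
            max_exons = max(1, min(4, L // 450))
            k = int(rng.integers(1, max_exons + 1))
            nseg = 2 * k - 1
            base = 150
            extra = L - base * nseg
            w = rng.random(nseg)
            add = np.floor(w / w.sum() * extra).astype(int)
            add[0] += extra - add.sum()
            seglens = base + add
            bounds = np.concatenate([[0], np.cumsum(seglens)]) + start
            exons = [(int(bounds[j]), int(bounds[j + 1]))
                     for j in range(0, nseg, 2)]
            first, last = exons[0], exons[-1]
            u5_len = int(rng.integers(80, min(200, first[1] - first[0] - 50)))
            u3_len = int(rng.integers(80, min(200, last[1] - last[0] - 50)))
            if strand == "+":
                utr5 = [(first[0], first[0] + u5_len)]
                utr3 = [(last[1] - u3_len, last[1])]
            else:
                utr5 = [(last[1] - u5_len, last[1])]
                utr3 = [(first[0], first[0] + u3_len)]
            genes.append(GeneModel(
                gene_id=f"gene{gid:04d}", chrom=chrom, strand=strand,
                start=start, end=end, exons=exons, utr5=utr5, utr3=utr3,
            ))
            gid += 1
            pos = end + flank + int(gaps[i + 1])
    return GenomeAnnotation(dict(zip(names, map(int, lengths))), genes)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

class _Occupancy:
    """Per-chromosome blocked intervals with a fixed separation buffer."""

    def __init__(self, gap: int):
        self.gap = gap
        self.blocks: dict[str, list[tuple[int, int]]] = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        import bisect

        blocks = self.blocks.setdefault(chrom, [])
        i = bisect.bisect_left(blocks, (start - self.gap, start - self.gap))
        for j in (i - 1, i):
            if 0 <= j < len(blocks):
                s, e = blocks[j]
                if min(end + self.gap, e) > max(start - self.gap, s):
                    return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        import bisect

        bisect.insort(self.blocks.setdefault(chrom, []), (start, end))


def _category_anchor(rng, category: FeatureCategory, annotation: GenomeAnnotation,
                     chrom: str, genes_by_chrom) -> int | None:
    """Draw a candidate midpoint of the requested category on ``chrom``."""
    size = annotation.chrom_sizes[chrom]
    if category is FeatureCategory.INTERGENIC:
        return int(rng.integers(0, size))
    genes = genes_by_chrom[chrom]
    if not genes:
        return None
    g = genes[int(rng.integers(len(genes)))]
    if category is FeatureCategory.PROMOTER:
        a, b = g.promoter_window(size)
        margin = 30  # keep midpoints classifiable after <=20 bp jitter
        if b - a <= 2 * margin:
            return None
        return int(rng.integers(a + margin, b - margin))
    if category is FeatureCategory.UTR5:
        ivs = g.utr5
    elif category is FeatureCategory.UTR3:
        ivs = g.utr3
    elif category is FeatureCategory.EXON:
        ivs = g.exons
    elif category is FeatureCategory.INTRON:
        ivs = g.introns()
    else:  # pragma: no cover
        raise ConfigError(f"cannot anchor category {category}")
    if not ivs:
        return None
    s, e = ivs[int(rng.integers(len(ivs)))]
    if e <= s:
        return None
    return int(rng.integers(s, e))


def generate_acr_truth(annotation: GenomeAnnotation, config: SimConfig):
    """Plant shared and stage-specific ACRs; returns (replicate peaks, truth).

    Chromosomes are drawn with probability proportional to length, feature
    categories per ``category_placement_probs``, lengths per category, and a
    45 bp exclusion buffer guarantees that distinct planted peaks never touch
    even after replicate jitter.  Every planted peak appears (edge-jittered)
    in both replicates of each stage it is active in.
    """
    rng = config.streams()["peaks"]
    catmap = annotation.category_map()
    genes_by_chrom = annotation.genes_by_chrom()
    cats = [FeatureCategory[c.upper()] for c in config.category_placement_probs]
    probs = np.array([config.category_placement_probs[c.label] for c in cats])
    for cat in cats:
        if probs[cats.index(cat)] > 0 and cat is not FeatureCategory.INTERGENIC:
            if not annotation.genes:
                raise ConfigError(
                    f"category {cat.label} requested but annotation has no genes"
                )
    chrom_names = list(annotation.chrom_sizes)
    chrom_p = np.array([annotation.chrom_sizes[c] for c in chrom_names], dtype=float)
    chrom_p /= chrom_p.sum()
    occupancy = _Occupancy(config.min_peak_gap_bp)

    def plant_one(pid: str, label: str) -> PlantedPeak:
        for _ in range(500):
            cat = cats[int(rng.choice(len(cats), p=probs))]
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
            mid = _category_anchor(rng, cat, annotation, chrom, genes_by_chrom)
            if mid is None:
                continue
            m, s = config.category_length_params[cat.label]
            L = max(60, int(round(rng.normal(m, s))))
            start = mid - L // 2
            end = start + L
            size = annotation.chrom_sizes[chrom]
            if start < config.replicate_jitter_bp + 1 or \
               end > size - config.replicate_jitter_bp - 1:
                continue
            if FeatureCategory(catmap[chrom][mid]) is not cat:
                continue
            if not occupancy.free(chrom, start, end):
                continue
            occupancy.add(chrom, start, end)
            host = None
            if cat is not FeatureCategory.INTERGENIC:
                host = _host_gene(annotation, chrom, mid, cat)
            return PlantedPeak(pid, chrom, start, end, cat.label, host, label)
        raise SizingError(
            "could not place a peak after 500 attempts; genome too crowded"
        )

    truth = TruthSet()
    order: list[str] = []
    for i in range(config.n_shared_peaks):
        pid = f"p{i:05d}"
        truth.planted_peaks[pid] = plant_one(pid, "shared")
        truth.peak_labels[pid] = "shared"
        order.append(pid)
    idx = config.n_shared_peaks
    for stage, n_spec in zip(STAGES, config.n_specific_peaks_per_stage):
        for _ in range(n_spec):
            pid = f"p{idx:05d}"
            truth.planted_peaks[pid] = plant_one(pid, f"specific:{stage}")
            truth.peak_labels[pid] = f"specific:{stage}"
            order.append(pid)
            idx += 1

    J = config.replicate_jitter_bp
    peaks: dict[tuple[str, int], list[Peak]] = {}
    for stage in STAGES:
        for rep in (1, 2):
            out = []
            for pid in order:
                pp = truth.planted_peaks[pid]
                if stage not in pp.stages():
                    continue
                ds, de = rng.integers(-J, J + 1, size=2)
                start = pp.start + int(ds)
                end = pp.end + int(de)
                if end - start < 20:
                    end = start + 20
                out.append(Peak(
                    interval=GenomicInterval(pp.chrom, start, end, "."),
                    peak_id=f"{pid}:{stage}:rep{rep}",
                    stage=stage, replicate=rep,
                ))
            out.sort(key=lambda p: (p.chrom, p.start, p.end, p.peak_id))
            peaks[(stage, rep)] = out
    return peaks, truth


def _host_gene(annotation: GenomeAnnotation, chrom: str, pos: int,
               cat: FeatureCategory) -> str | None:
    """Gene owning a planted genic/promoter anchor point (nearest TSS on tie)."""
    best = None
    best_d = None
    for g in annotation.genes:
        if g.chrom != chrom:
            continue
        if cat is FeatureCategory.PROMOTER:
            a, b = g.promoter_window(annotation.chrom_sizes[chrom])
            inside = a <= pos < b
        else:
            inside = g.start <= pos < g.end
        if inside:
            d = abs(pos - g.tss)
            if best_d is None or d < best_d:
                best, best_d = g.gene_id, d
    return best


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB sample with Var = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_count_matrix(truth: TruthSet, config: SimConfig) -> CountMatrix:
    """NB Tn5 counts per planted peak x sample; records effects in ``truth``.

    Shared peaks receive per-stage log2 intensity drift ~ N(0, drift_sd) and a
    ``frac_dpi`` subset additionally a +/- ``dpi_log2fc`` shift in one
    designated stage (the planted DPI effects).  Stage-specific peaks retain
    only ``off_stage_mean_factor`` of their base signal outside their stage.
    Per-sample means scale with library-size factors normalised to geometric
    mean one.
    """
    rng = config.streams()["counts"]
    pids = list(truth.planted_peaks)
    n = len(pids)
    mu0, sd0 = config.base_mean_log2
    base = 2.0 ** rng.normal(mu0, sd0, size=n)
    shared_idx = [i for i, pid in enumerate(pids)
                  if truth.peak_labels[pid] == "shared"]
    means = np.zeros((n, 3))
    for i, pid in enumerate(pids):
        label = truth.peak_labels[pid]
        if label == "shared":
            drift = rng.normal(0.0, config.intensity_drift_sd, size=3)
            means[i] = base[i] * 2.0 ** drift
        else:
            stage = label.split(":", 1)[1]
            j = STAGES.index(stage)
            means[i] = base[i] * config.off_stage_mean_factor
            means[i, j] = base[i] * 2.0 ** rng.normal(0.0, config.intensity_drift_sd)
    n_dpi = int(round(config.frac_dpi * len(shared_idx)))
    if n_dpi > 0:
        chosen = rng.choice(shared_idx, size=n_dpi, replace=False)
        for i in sorted(chosen):
            j = int(rng.integers(3))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            means[i, j] *= 2.0 ** (sign * config.dpi_log2fc)
            truth.dpi_effects[pids[i]] = {
                "stage": STAGES[j], "log2fc": float(sign * config.dpi_log2fc)}
    libs = np.asarray(config.library_sizes, dtype=float)
    sf = libs / np.exp(np.mean(np.log(libs)))
    cols = sample_ids()
    counts = np.zeros((n, 6), dtype=np.int64)
    for c, col in enumerate(cols):
        stage = col.rsplit("_rep", 1)[0]
        j = STAGES.index(stage)
        counts[:, c] = _nb_draw(rng, means[:, j] * sf[c], config.nb_dispersion)
    truth.stage_means = pd.DataFrame(means, index=pids, columns=list(STAGES))
    return CountMatrix(
        counts=pd.DataFrame(counts, index=pids, columns=cols),
        samples=sample_table(),
    )


def simulate_null_counts(n_features: int, base_mean: float, dispersion: float,
                         seed: int, n_dpi: int = 0, dpi_log2fc: float = 0.0,
                         library_sizes=None) -> tuple[CountMatrix, pd.DataFrame]:
    """Stand-alone 2v2-per-stage NB count simulator for calibration studies.

    Draws every feature at a common base mean with no stage structure, then
    plants ``n_dpi`` features with a +/- ``dpi_log2fc`` shift in BBCH_13
    (sign alternating).  Returns the matrix and a truth frame with the planted
    log2 effect per feature (0 = null).  Used by the NB-test calibration and
    power analyses, where a clean null (no intensity drift) is required.
    """
    rng = np.random.default_rng(seed)
    if library_sizes is None:
        sf = np.ones(6)
    else:
        libs = np.asarray(library_sizes, dtype=float)
        sf = libs / np.exp(np.mean(np.log(libs)))
    lognorm_sd = 0.25  # mild feature-to-feature mean spread
    base = base_mean * 2.0 ** rng.normal(0.0, lognorm_sd, size=n_features)
    effect = np.zeros(n_features)
    if n_dpi > 0:
        idx = rng.choice(n_features, size=n_dpi, replace=False)
        signs = np.where(np.arange(n_dpi) % 2 == 0, 1.0, -1.0)
        effect[idx] = signs * dpi_log2fc
    cols = sample_ids()
    counts = np.zeros((n_features, 6), dtype=np.int64)
    for c, col in enumerate(cols):
        stage = col.rsplit("_rep", 1)[0]
        mult = 2.0 ** effect if stage == "BBCH_13" else 1.0
        counts[:, c] = _nb_draw(rng, base * mult * sf[c], dispersion)
    feats = [f"f{i:05d}" for i in range(n_features)]
    cm = CountMatrix(pd.DataFrame(counts, index=feats, columns=cols),
                     sample_table())
    return cm, pd.DataFrame({"log2fc": effect}, index=feats)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """Gene-level FPKM and raw exon counts over the six samples."""

    fpkm: pd.DataFrame
    counts: pd.DataFrame
    gene_lengths: pd.Series
    samples: pd.DataFrame

    def stage_mean_fpkm(self) -> pd.DataFrame:
        out = {}
        for stage in self.samples["stage"].unique():
            cols = self.samples.index[self.samples["stage"] == stage]
            out[stage] = self.fpkm[cols].mean(axis=1)
        return pd.DataFrame(out)

    def count_matrix(self) -> CountMatrix:
        return CountMatrix(counts=self.counts, samples=self.samples)


# accessibility-score shape constants: each promoter ACR contributes a
# length-scaled level term plus a log-ratio of its stage intensity to the
# reference mean, so expression responds near-unit-slope (in log2) to
# intensity changes in either direction while ACR presence still lifts the
# expression level.
ACC_LEVEL = 1.5
ACC_PSEUDO = 20.0
ACC_REF = 200.0


def _accessibility_score(truth: TruthSet, gene_peaks: dict[str, list[str]],
                         stage: str) -> pd.Series:
    """Length-scaled log-intensity of a gene's promoter ACRs at one stage."""
    vals = {}
    sm = truth.stage_means
    for gene, pids in gene_peaks.items():
        acc = 0.0
        for pid in pids:
            pp = truth.planted_peaks[pid]
            mu = float(sm.loc[pid, stage])
            acc += (pp.end - pp.start) / 400.0 * (
                ACC_LEVEL + np.log2((mu + ACC_PSEUDO) / (ACC_REF + ACC_PSEUDO))
            )
        vals[gene] = acc
    return pd.Series(vals, dtype=float)


def generate_expression_table(annotation: GenomeAnnotation, truth: TruthSet,
                              config: SimConfig) -> ExpressionTable:
    """FPKM/count tables coupled to promoter accessibility, with archetypes.

    Mean log2 FPKM per gene and stage is baseline + coupling * accessibility
    + archetype offset.  Raw exon counts are NB draws around the implied count
    mean (FPKM * exonic kb * library size / 1e6), and the reported FPKM is
    recomputed from the sampled counts so both surfaces stay consistent.

    Plant ordering: genes hosting stage-specific promoter ACRs join the
    stage-matched archetype with probability ``specific_cluster_coupling``;
    discordant genes are drawn from hosts of planted-DPI promoter peaks and
    have the coupling sign flipped; remaining archetype slots are filled from
    genes *without* shared promoter peaks, keeping the accessibility-coupled
    and programme-driven gene sets largely disjoint (see docs/methods.md).
    """
    rng = config.streams()["expression"]
    if truth.stage_means is None:
        raise ConfigError("generate_count_matrix must run before expression")
    genes = [g.gene_id for g in annotation.genes]
    gene_set = set(genes)
    # promoter peaks per gene, split by label
    prom_shared: dict[str, list[str]] = {}
    prom_all: dict[str, list[str]] = {}
    for pid, pp in truth.planted_peaks.items():
        if pp.category != "promoter" or pp.host_gene not in gene_set:
            continue
        prom_all.setdefault(pp.host_gene, []).append(pid)
        if pp.label == "shared":
            prom_shared.setdefault(pp.host_gene, []).append(pid)

    # --- discordant genes: hosts of DPI promoter peaks --------------------
    # prefer hosts with exactly one promoter ACR so the planted opposite-sign
    # coupling cannot be masked by a second, independently drifting peak
    dpi_prom_hosts = sorted({
        truth.planted_peaks[pid].host_gene
        for pid in truth.dpi_effects
        if truth.planted_peaks[pid].category == "promoter"
        and truth.planted_peaks[pid].host_gene is not None
    })
    single = [g for g in dpi_prom_hosts if len(prom_all.get(g, [])) == 1]
    multi = [g for g in dpi_prom_hosts if g not in single]
    if len(dpi_prom_hosts) < config.n_discordant:
        raise ConfigError(
            f"only {len(dpi_prom_hosts)} genes host planted-DPI promoter "
            f"peaks; cannot plant {config.n_discordant} discordant genes"
        )
    if len(single) >= config.n_discordant:
        discordant = set(rng.choice(single, size=config.n_discordant,
                                    replace=False).tolist())
    else:
        extra = rng.choice(multi, size=config.n_discordant - len(single),
                           replace=False).tolist()
        discordant = set(single) | set(extra)
    truth.discordant_genes = discordant

    # --- archetype assignment ---------------------------------------------
    clusters: dict[str, int] = {}
    for pid, pp in truth.planted_peaks.items():
        if (pp.category == "promoter" and pp.label.startswith("specific:")
                and pp.host_gene and pp.host_gene not in discordant):
            if rng.random() < config.specific_cluster_coupling:
                stage = pp.label.split(":", 1)[1]
                clusters[pp.host_gene] = config.stage_archetype[stage]
    pool = [g for g in genes
            if g not in clusters and g not in discordant and g not in prom_shared]
    rng.shuffle(pool)
    need = max(0, config.n_patterned_genes - len(clusters))
    for i, g in enumerate(pool[:need]):
        clusters[g] = (i % 8) + 1
    truth.gene_clusters = clusters

    # --- silent genes ------------------------------------------------------
    rest = [g for g in genes
            if g not in clusters and g not in discordant and g not in prom_all]
    n_silent = int(round(config.silent_gene_fraction * len(rest)))
    silent = set(rng.choice(sorted(rest), size=n_silent, replace=False).tolist()) \
        if n_silent else set()

    # --- per-gene, per-stage mean log2 FPKM --------------------------------
    arch = np.asarray(config.cluster_pattern_archetypes, dtype=float)
    acc = pd.DataFrame(
        {s: _accessibility_score(truth, prom_all, s) for s in STAGES}
    ) if prom_all else pd.DataFrame(columns=list(STAGES))
    mu_b, sd_b = config.baseline_log2fpkm
    mu_p, sd_p = config.patterned_baseline_log2fpkm
    log2mean = pd.DataFrame(0.0, index=genes, columns=list(STAGES))
    for g in genes:
        if g in silent:
            log2mean.loc[g] = -np.inf
            continue
        if g in discordant:
            # discordant genes must sit in the expressed stratum to be
            # observable as DEGs despite the repressive coupling term
            baseline = rng.normal(*config.discordant_baseline_log2fpkm)
        elif g in clusters:
            baseline = rng.normal(mu_p, sd_p)
        else:
            baseline = rng.normal(mu_b, sd_b)
        row = np.full(3, baseline)
        if g in clusters:
            row = row + config.archetype_amplitude * arch[clusters[g] - 1]
        if g in acc.index:
            coupling = -config.expression_coupling if g in discordant \
                else config.expression_coupling
            row = row + coupling * acc.loc[g].to_numpy()
        log2mean.loc[g] = row
    truth.expression_log2_mean = log2mean

    # --- counts and FPKM ----------------------------------------------------
    glen = pd.Series({g.gene_id: g.exonic_length for g in annotation.genes})
    libs = np.asarray(config.rna_library_sizes, dtype=float)
    cols = sample_ids()
    cnt = np.zeros((len(genes), 6), dtype=np.int64)
    fpkm = np.zeros((len(genes), 6))
    lmean = log2mean.to_numpy()
    glv = glen[genes].to_numpy(dtype=float)
    for c, col in enumerate(cols):
        stage = col.rsplit("_rep", 1)[0]
        j = STAGES.index(stage)
        fpkm_mean = np.where(np.isfinite(lmean[:, j]), 2.0 ** lmean[:, j], 0.0)
        count_mean = fpkm_mean * glv * libs[c] / 1e9
        draws = np.where(count_mean > 0,
                         _nb_draw(rng, count_mean, config.nb_dispersion), 0)
        cnt[:, c] = draws
        fpkm[:, c] = 1e9 * draws / (glv * libs[c])
    return ExpressionTable(
        fpkm=pd.DataFrame(fpkm, index=genes, columns=cols),
        counts=pd.DataFrame(cnt, index=genes, columns=cols),
        gene_lengths=glen,
        samples=sample_table(),
    )


# ---------------------------------------------------------------------------
# fragments and sequences
# ---------------------------------------------------------------------------

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def generate_fragments_and_sequences(annotation: GenomeAnnotation,
                                     truth: TruthSet, config: SimConfig):
    """Per-sample Tn5 fragment intervals and a genome FASTA with motifs.

    Fragment midpoints are a three-component mixture: uniform background,
    peak-centred Gaussians weighted by stage intensity (promoter peaks
    up-weighted), and an expression-weighted TSS pile-up.  Sequences are
    uniform-random ACGT with IUPAC consensus motifs instantiated inside the
    promoter ACRs of designated archetype genes.
    """
    frng = config.streams()["fragments"]
    srng = config.streams()["sequences"]
    if truth.stage_means is None or truth.expression_log2_mean is None:
        raise ConfigError("counts and expression must be generated first")
    chroms = list(annotation.chrom_sizes)
    sizes = np.array([annotation.chrom_sizes[c] for c in chroms], dtype=float)
    chrom_p = sizes / sizes.sum()
    pids = list(truth.planted_peaks)
    centers = np.array([truth.planted_peaks[p].midpoint for p in pids])
    plens = np.array([truth.planted_peaks[p].end - truth.planted_peaks[p].start
                      for p in pids], dtype=float)
    pchrom = np.array([chroms.index(truth.planted_peaks[p].chrom) for p in pids])
    prom_w = np.array([
        config.promoter_fragment_weight
        if truth.planted_peaks[p].category == "promoter" else 1.0 for p in pids])
    genes = annotation.genes
    tss = np.array([g.tss for g in genes])
    gchrom = np.array([chroms.index(g.chrom) for g in genes])
    lmean = truth.expression_log2_mean
    fragments: dict[str, list[tuple[str, int, int]]] = {}
    w_bg, w_peak, w_tss = config.fragment_mixture
    for col in sample_ids():
        stage = col.rsplit("_rep", 1)[0]
        n = config.n_fragments_per_sample
        n_bg, n_pk, n_ts = frng.multinomial(n, [w_bg, w_peak, w_tss])
        mids = []
        cidx = []
        if n_bg:
            ci = frng.choice(len(chroms), size=n_bg, p=chrom_p)
            mids.append((frng.random(n_bg) * sizes[ci]).astype(np.int64))
            cidx.append(ci)
        if n_pk and len(pids):
            w = truth.stage_means[stage].to_numpy(dtype=float) * prom_w
            w = np.maximum(w, 0)
            w = w / w.sum()
            pi = frng.choice(len(pids), size=n_pk, p=w)
            mids.append((centers[pi]
                         + frng.normal(0, plens[pi] / 4)).astype(np.int64))
            cidx.append(pchrom[pi])
        if n_ts and len(genes):
            expr = lmean[stage].reindex([g.gene_id for g in genes]).to_numpy()
            w = np.where(np.isfinite(expr), 2.0 ** expr, 0.0)
            if w.sum() <= 0:
                w = np.ones(len(genes))
            w = w / w.sum()
            gi = frng.choice(len(genes), size=n_ts, p=w)
            mids.append((tss[gi]
                         + frng.normal(0, config.tss_pileup_sd, n_ts)).astype(np.int64))
            cidx.append(gchrom[gi])
        mid = np.concatenate(mids) if mids else np.zeros(0, dtype=np.int64)
        ci = np.concatenate(cidx) if cidx else np.zeros(0, dtype=np.int64)
        flen = np.clip(frng.normal(*config.fragment_size, size=len(mid)),
                       30, 500).astype(np.int64)
        start = mid - flen // 2
        end = start + flen
        keep = (start >= 0) & (end <= sizes[ci].astype(np.int64))
        recs = sorted(
            (chroms[c], int(s), int(e))
            for c, s, e in zip(ci[keep], start[keep], end[keep])
        )
        fragments[col] = recs

    # --- sequences ----------------------------------------------------------
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, np.ndarray] = {
        c: alphabet[srng.integers(0, 4, size=annotation.chrom_sizes[c])]
        for c in chroms
    }
    placements: dict[str, list] = {}
    arch_genes: dict[int, list[str]] = {}
    for g, cl in sorted(truth.gene_clusters.items()):
        arch_genes.setdefault(cl, []).append(g)
    prom_peaks_by_gene: dict[str, list[str]] = {}
    for pid, pp in truth.planted_peaks.items():
        if pp.category == "promoter" and pp.host_gene:
            prom_peaks_by_gene.setdefault(pp.host_gene, []).append(pid)
    for motif, cluster in zip(config.motif_consensus_list,
                              config.motif_target_clusters):
        for g in arch_genes.get(cluster, []):
            pids_g = prom_peaks_by_gene.get(g)
            if not pids_g or srng.random() >= config.motif_plant_prob:
                continue
            pp = truth.planted_peaks[pids_g[0]]
            span = pp.end - pp.start - len(motif)
            if span <= 0:
                continue
            off = int(srng.integers(0, span))
            concrete = "".join(
                IUPAC[ch][int(srng.integers(len(IUPAC[ch])))] for ch in motif)
            if srng.random() < 0.5:
                concrete = _revcomp(concrete)
            pos = pp.start + off
            seqs[pp.chrom][pos:pos + len(motif)] = np.frombuffer(
                concrete.encode(), dtype=np.uint8)
            placements.setdefault(g, []).append(
                {"motif": motif, "chrom": pp.chrom, "position": pos,
                 "peak": pp.peak_id})
    truth.motif_placements = placements
    sequences = {c: arr.tobytes().decode() for c, arr in seqs.items()}
    return fragments, sequences


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
    return seq.translate(comp)[::-1]


# ---------------------------------------------------------------------------
# dataset bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    annotation: GenomeAnnotation
    peaks: dict[tuple[str, int], list[Peak]]
    atac_counts: CountMatrix
    expression: ExpressionTable
    fragments: dict[str, list[tuple[str, int, int]]]
    sequences: dict[str, str]
    truth: TruthSet


def generate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """Run every generator stage in order and bundle the results."""
    config = config or SimConfig()
    annotation = generate_genome(config)
    peaks, truth = generate_acr_truth(annotation, config)
    counts = generate_count_matrix(truth, config)
    _attach_counts(peaks, counts)
    expression = generate_expression_table(annotation, truth, config)
    fragments, sequences = generate_fragments_and_sequences(
        annotation, truth, config)
    return SimulatedDataset(config, annotation, peaks, counts, expression,
                            fragments, sequences, truth)


def _attach_counts(peaks, counts: CountMatrix) -> None:
    """Give each replicate peak its own sample's planted count."""
    for (stage, rep), plist in peaks.items():
        col = f"{stage}_rep{rep}"
        for p in plist:
            pid = p.peak_id.split(":", 1)[0]
            if pid in counts.counts.index:
                p.counts = {col: int(counts.counts.at[pid, col])}


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write every artifact as plain-text standard formats; returns paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["gff3"] = out / "genes.gff3"
    write_gff3(ds.annotation, paths["gff3"])
    paths["chrom_sizes"] = out / "genome.chrom.sizes"
    write_chrom_sizes(ds.annotation.chrom_sizes, paths["chrom_sizes"])
    for (stage, rep), plist in ds.peaks.items():
        key = f"peaks_{stage}_rep{rep}"
        paths[key] = out / f"{stage}_rep{rep}.narrowPeak"
        write_narrowpeak(plist, paths[key])
        bkey = f"bed_{stage}_rep{rep}"
        paths[bkey] = out / f"{stage}_rep{rep}.bed"
        write_bed(plist, paths[bkey])
    paths["atac_counts"] = out / "atac_counts.tsv"
    ds.atac_counts.counts.to_csv(paths["atac_counts"], sep="\t",
                                 index_label="peak_id")
    paths["fpkm"] = out / "fpkm.tsv"
    ds.expression.fpkm.to_csv(paths["fpkm"], sep="\t", index_label="gene_id",
                              float_format="%.6g")
    paths["exon_counts"] = out / "exon_counts.tsv"
    ds.expression.counts.to_csv(paths["exon_counts"], sep="\t",
                                index_label="gene_id")
    for col, frags in ds.fragments.items():
        key = f"fragments_{col}"
        paths[key] = out / f"fragments_{col}.bed"
        with open(paths[key], "w") as fh:
            for chrom, s, e in frags:
                fh.write(f"{chrom}\t{s}\t{e}\n")
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    paths["fasta"] = out / "genome.fa"
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in ds.sequences.items()]
    seqio_write(records, str(paths["fasta"]), "fasta")
    paths["truth"] = out / "truth.json"
    ds.truth.to_json(paths["truth"])
    return paths
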