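"""Expression clustering, set/motif enrichment and ATAC/RNA integration.

Differentially expressed genes are clustered into eight expression patterns
by seeded multi-start k-means on per-gene z-scored stage means, with cluster
labels mapped deterministically onto configured archetype patterns.  Overlap
of stage-specific-ACR gene sets with clusters, generic term enrichment and
consensus-motif enrichment all share one hypergeometric/Fisher core.  The
DPI x DEG integration places each gene with a significant promoter peak
change and a significant expression change into a concordance quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .differential import DifferentialResult
from .errors import ContractError
from .linkage import PromoterAssignment
from .simulate import IUPAC, _revcomp
from .stats import bh_adjust, hypergeom_tail


@dataclass
class ClusterAssignment:
    labels: dict[str, int]  # gene -> 1..k
    centroids: pd.DataFrame  # cluster x stage (z-scored space)

    def members(self, cluster: int) -> set[str]:
        return {g for g, c in self.labels.items() if c == cluster}


def _zscore_rows(mat: np.ndarray) -> np.ndarray:
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (mat - mean) / sd


def cluster_degs(stage_fpkm: pd.DataFrame, k: int = 8, seed: int = 0,
                 archetypes=None) -> ClusterAssignment:
    """k-means (10 starts, best inertia) on z-scored log2(FPKM+1) stage means.

    When ``archetypes`` (k x n_stages patterns) are given, clusters are
    renumbered by optimally matching centroids to archetypes (Hungarian
    assignment on Euclidean distance of z-scored patterns), so label c means
    "the cluster realizing archetype c".  Without archetypes, clusters are
    ordered by centroid argmax stage then norm — deterministic either way.
    """
    if len(stage_fpkm) < k:
        raise ContractError(f"{len(stage_fpkm)} genes cannot form {k} clusters")
    X = _zscore_rows(np.log2(stage_fpkm.to_numpy(dtype=float) + 1.0))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    cents = km.cluster_centers_
    if archetypes is not None:
        A = _zscore_rows(np.asarray(archetypes, dtype=float))
        if A.shape[0] != k:
            raise ContractError("need exactly k archetypes")
        cost = ((cents[:, None, :] - A[None, :, :]) ** 2).sum(axis=2)
        rows, cols = linear_sum_assignment(cost)
        relabel = {int(r): int(c) + 1 for r, c in zip(rows, cols)}
    else:
        order = sorted(
            range(k),
            key=lambda c: (int(np.argmax(cents[c])), -float(np.linalg.norm(cents[c]))),
        )
        relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = {g: relabel[int(c)] for g, c in zip(stage_fpkm.index, raw)}
    cent_df = pd.DataFrame(
        cents, columns=stage_fpkm.columns,
        index=[relabel[c] for c in range(k)],
    ).sort_index()
    return ClusterAssignment(labels=labels, centroids=cent_df)


def cluster_overlap_fisher(specific_genes: dict[str, set],
                           clusters: ClusterAssignment,
                           universe: set) -> pd.DataFrame:
    """Stage-set x cluster overlap table with one-sided Fisher p-values.

    Sets are intersected with the universe first; proportion = overlap /
    |set within universe| (0 with p = 1 for an empty set).
    """
    uni = set(universe)
    N = len(uni)
    cluster_ids = sorted(set(clusters.labels.values()))
    rows = []
    for name, genes in specific_genes.items():
        sel = set(genes) & uni
        n = len(sel)
        for c in cluster_ids:
            members = clusters.members(c) & uni
            K = len(members)
            k = len(sel & members)
            p = 1.0 if n == 0 else hypergeom_tail(k, N, K, n)
            rows.append({
                "set": name, "cluster": c, "overlap": k, "set_size": n,
                "cluster_size": K,
                "proportion": (k / n) if n else 0.0,
                "p": p,
            })
    return pd.DataFrame(rows)


@dataclass
class IntegrationQuadrants:
    """Per-comparison concordance quadrants of promoter DPI vs DEG calls."""

    counts: dict[str, int]
    genes: dict[str, set] = field(default_factory=dict)
    conflicting: set = field(default_factory=set)

    QUADRANTS = ("atac_up_rna_up", "atac_down_rna_down",
                 "atac_up_rna_down", "atac_down_rna_up")

    def concordant(self) -> int:
        return self.counts["atac_up_rna_up"] + self.counts["atac_down_rna_down"]

    def discordant(self) -> int:
        return self.counts["atac_up_rna_down"] + self.counts["atac_down_rna_up"]


def integrate_dpi_deg(dpi: DifferentialResult, deg: DifferentialResult,
                      assignment: PromoterAssignment) -> IntegrationQuadrants:
    """Quadrant counts for one stage comparison.

    A gene enters iff it has >= 1 significant promoter DPI peak and a
    significant DEG call in the same comparison; the quadrant is (sign of
    peak log2FC, sign of gene log2FC).  Genes whose promoter peaks change
    significantly in both directions are excluded and reported.
    """
    if (dpi.group_a, dpi.group_b) != (deg.group_a, deg.group_b):
        raise ContractError(
            f"comparison mismatch: DPI {dpi.group_a} vs {dpi.group_b}, "
            f"DEG {deg.group_a} vs {deg.group_b}"
        )
    sig_peaks = dpi.significant()
    peak_dir = sig_peaks["direction"].to_dict()
    gene_dirs: dict[str, set] = {}
    for gene, lst in assignment.assignments.items():
        for rec in lst:
            d = peak_dir.get(rec["peak_id"])
            if d in ("up", "down"):
                gene_dirs.setdefault(gene, set()).add(d)
    sig_genes = deg.significant()
    counts = {q: 0 for q in IntegrationQuadrants.QUADRANTS}
    genes: dict[str, set] = {q: set() for q in IntegrationQuadrants.QUADRANTS}
    conflicting = set()
    for gene, dirs in gene_dirs.items():
        if len(dirs) > 1:
            conflicting.add(gene)
            continue
        if gene not in sig_genes.index:
            continue
        atac = next(iter(dirs))
        rna = str(sig_genes.loc[gene, "direction"])
        q = f"atac_{atac}_rna_{rna}"
        counts[q] += 1
        genes[q].add(gene)
    return IntegrationQuadrants(counts=counts, genes=genes,
                                conflicting=conflicting)


def set_enrichment(target: set, universe: set, annotation_map: dict,
                   alpha: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``target`` per annotation term.

    Terms with no annotated gene in the universe are skipped.  The raw-p
    threshold flags significance (matching the study's convention); a BH
    column is reported alongside for reference.
    """
    target = set(target)
    universe = set(universe)
    if not target <= universe:
        raise ContractError("target must be a subset of the universe")
    N, n = len(universe), len(target)
    rows = []
    for term, genes in annotation_map.items():
        annotated = set(genes) & universe
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & target)
        rows.append({"term": term, "overlap": k, "set_size": n,
                     "annotated": K, "universe": N,
                     "p": hypergeom_tail(k, N, K, n)})
    df = pd.DataFrame(rows)
    if len(df):
        df["padj"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["p"] < alpha
        df = df.sort_values(["p", "term"]).reset_index(drop=True)
    return df


def _iupac_match(seq: str, motif: str, max_mismatches: int) -> bool:
    allowed = [set(IUPAC[c]) for c in motif]
    m = len(motif)
    for off in range(len(seq) - m + 1):
        mism = 0
        for i in range(m):
            if seq[off + i] not in allowed[i]:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            return True
    return False


def scan_motif(seq: str, motif: str, max_mismatches: int = 0) -> bool:
    """True iff the IUPAC consensus (either strand) occurs in ``seq``."""
    seq = seq.upper()
    return (_iupac_match(seq, motif.upper(), max_mismatches)
            or _iupac_match(seq, _revcomp(motif.upper()), max_mismatches))


def motif_enrichment(target_seqs: dict, background_seqs: dict, motifs,
                     alpha: float = 0.01, max_mismatches: int = 0) -> pd.DataFrame:
    """Per-motif one-sided Fisher enrichment of hit rates, target vs background.

    A sequence is a hit iff the consensus (or its reverse complement) matches
    at any offset with <= ``max_mismatches`` mismatches.  Motifs longer than
    every sequence are skipped with a warning.
    """
    import warnings

    rows = []
    n_t, n_b = len(target_seqs), len(background_seqs)
    for motif in motifs:
        bad = [c for c in motif.upper() if c not in IUPAC]
        if bad:
            raise ContractError(f"invalid IUPAC motif {motif!r}")
        if all(len(s) < len(motif) for s in
               list(target_seqs.values()) + list(background_seqs.values())):
            warnings.warn(f"motif {motif} longer than every sequence; skipped")
            continue
        k_t = sum(scan_motif(s, motif, max_mismatches)
                  for s in target_seqs.values())
        k_b = sum(scan_motif(s, motif, max_mismatches)
                  for s in background_seqs.values())
        # one-sided Fisher: enrichment of hits among targets
        p = hypergeom_tail(k_t, n_t + n_b, k_t + k_b, n_t)
        rows.append({"motif": motif, "target_hits": k_t, "target_n": n_t,
                     "background_hits": k_b, "background_n": n_b, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["significant"] = df["p"] < alpha
    return df
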