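"""Promoter-ACR / expression coupling analyses.

Links consolidated ACRs to genes through the 2 kb promoter window, then asks
how promoter ACR presence, multiplicity and length relate to expression:
grouping genes by promoter ACR count, splitting single-ACR genes into length
tertiles with a tie-balancing rule, and cross-tabulating expression bins
against promoter/gene-body ACR association.

Two-group expression comparisons use the two-sample Wilcoxon rank-sum test
(:func:`leafatac.stats.rank_test`): the groups are independent gene sets, so
the paired signed-rank variant does not apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError
from .intervals import GenomeAnnotation, Peak, intersect
from .stats import rank_test  # noqa: F401  (re-exported module surface)


@dataclass
class PromoterAssignment:
    """gene -> assigned promoter ACRs with (peak id, length, intensity)."""

    assignments: dict[str, list[dict]] = field(default_factory=dict)
    ambiguous: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    def count_of(self, gene: str) -> int:
        return len(self.assignments.get(gene, []))

    def genes_with_acr(self) -> set[str]:
        return {g for g, lst in self.assignments.items() if lst}

    def single_acr_genes(self) -> dict[str, dict]:
        return {g: lst[0] for g, lst in self.assignments.items() if len(lst) == 1}


def assign_promoter_acrs(acrs: list[Peak],
                         annotation: GenomeAnnotation) -> PromoterAssignment:
    """Assign each ACR whose classification position falls in a promoter
    window to the owning gene; overlapping-window conflicts go to the nearest
    TSS, exact ties to all tied genes (flagged in ``ambiguous``).

    Intensity is the sum of the peak's per-sample counts when present, else
    its interval score, else NaN.
    """
    out = PromoterAssignment()
    windows: dict[str, list[tuple[int, int, int, str]]] = {}
    for g in annotation.genes:
        a, b = g.promoter_window(annotation.chrom_sizes[g.chrom])
        if b > a:
            windows.setdefault(g.chrom, []).append((a, b, g.tss, g.gene_id))
    for lst in windows.values():
        lst.sort()
    for p in acrs:
        pos = p.position()
        hits = [
            (abs(pos - tss), gid)
            for a, b, tss, gid in windows.get(p.chrom, [])
            if a <= pos < b
        ]
        if not hits:
            continue
        best = min(d for d, _ in hits)
        winners = tuple(sorted(gid for d, gid in hits if d == best))
        if len(winners) > 1:
            out.ambiguous.append((p.peak_id, winners))
        if p.counts:
            intensity = float(sum(p.counts.values()))
        elif p.interval.score is not None:
            intensity = float(p.interval.score)
        else:
            intensity = float("nan")
        for gid in winners:
            out.assignments.setdefault(gid, []).append(
                {"peak_id": p.peak_id, "length": p.length,
                 "intensity": intensity})
    return out


@dataclass
class GroupComparison:
    groups: dict[str, list[str]]  # label -> gene ids
    medians: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)


def _compare_groups(labels, gene_groups, fpkm: pd.Series,
                    pairs) -> GroupComparison:
    medians = {}
    for lab in labels:
        vals = fpkm.reindex(gene_groups[lab]).dropna()
        medians[lab] = float(vals.median()) if len(vals) else float("nan")
    pvals = {}
    skipped = []
    for la, lb in pairs:
        xa = fpkm.reindex(gene_groups[la]).dropna().to_numpy()
        xb = fpkm.reindex(gene_groups[lb]).dropna().to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            skipped.append((la, lb))
            continue
        pvals[(la, lb)] = rank_test(xa, xb)
    return GroupComparison(groups=dict(gene_groups), medians=medians,
                           pairwise_p=pvals, skipped_pairs=skipped)


def expression_by_acr_count(assignment: PromoterAssignment, fpkm: pd.Series,
                            genes=None) -> GroupComparison:
    """Expression grouped by promoter ACR count {0, 1, 2, 3+}.

    ``genes`` is the universe (default: fpkm index); adjacent groups are
    compared with the two-sided rank-sum test.
    """
    universe = list(genes) if genes is not None else list(fpkm.index)
    labels = ["0", "1", "2", "3+"]
    groups: dict[str, list[str]] = {lab: [] for lab in labels}
    for g in universe:
        k = assignment.count_of(g)
        groups[str(k) if k < 3 else "3+"].append(g)
    pairs = list(zip(labels, labels[1:]))
    return _compare_groups(labels, groups, fpkm, pairs)


def length_tertiles(assignment: PromoterAssignment, fpkm: pd.Series,
                    genes=None) -> tuple[dict[str, list[str]], GroupComparison]:
    """Split single-promoter-ACR genes into length tertiles (top/middle/bottom).

    Genes are stably sorted by (ACR length descending, gene id); target group
    sizes are as equal as possible (ceil/floor of n/3).  A run of equal
    lengths straddling a group boundary is redistributed round-robin across
    the straddled groups so similar-length ACRs spread evenly — group sizes
    are preserved and the assignment is invariant to input order.
    """
    single = assignment.single_acr_genes()
    if genes is not None:
        single = {g: v for g, v in single.items() if g in set(genes)}
    n = len(single)
    if n < 3:
        raise ContractError(f"need >= 3 single-ACR genes, got {n}")
    ranked = sorted(single.items(), key=lambda kv: (-kv[1]["length"], kv[0]))
    sizes = [len(chunk) for chunk in np.array_split(np.arange(n), 3)]
    bounds = np.cumsum([0] + sizes)
    tentative = np.empty(n, dtype=int)
    for gi in range(3):
        tentative[bounds[gi]:bounds[gi + 1]] = gi
    final = tentative.copy()
    i = 0
    while i < n:
        j = i
        while j < n and ranked[j][1]["length"] == ranked[i][1]["length"]:
            j += 1
        span_groups = sorted(set(tentative[i:j]))
        if len(span_groups) > 1:
            counts = {g: int((tentative[i:j] == g).sum()) for g in span_groups}
            cycle = []
            remaining = dict(counts)
            while any(remaining.values()):
                for g in span_groups:
                    if remaining[g] > 0:
                        cycle.append(g)
                        remaining[g] -= 1
            final[i:j] = cycle
        i = j
    labels = ["top", "middle", "bottom"]
    groups: dict[str, list[str]] = {lab: [] for lab in labels}
    for (gene, _), gi in zip(ranked, final):
        groups[labels[gi]].append(gene)
    comparison = _compare_groups(labels, groups, fpkm, [("top", "bottom")])
    return groups, comparison


def acr_association_by_expression_bin(acrs: list[Peak],
                                      annotation: GenomeAnnotation,
                                      fpkm: pd.Series,
                                      assignment: PromoterAssignment | None = None
                                      ) -> pd.DataFrame:
    """Six expression groups x {promoter only, gene body only, both, none}.

    Group "0" holds FPKM = 0 genes; expressed genes split into quintiles
    (ties broken by gene id).  Gene-body association is any >=1 bp overlap of
    an ACR with the gene extent (UTRs included); promoter association is any
    assigned promoter ACR.  Row proportions sum to 1.
    """
    if assignment is None:
        assignment = assign_promoter_acrs(acrs, annotation)
    genes = [g for g in annotation.genes if g.gene_id in fpkm.index]
    sorted_acrs = sorted(acrs, key=lambda p: (p.chrom, p.start, p.end))
    gene_sorted = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    body_pairs = intersect(gene_sorted, sorted_acrs, min_overlap_bp=1)
    body_genes = {gene_sorted[i].gene_id for i, _ in body_pairs}
    prom_genes = assignment.genes_with_acr()

    zero = [g.gene_id for g in genes if fpkm[g.gene_id] == 0]
    expressed = sorted(
        (g.gene_id for g in genes if fpkm[g.gene_id] > 0),
        key=lambda gid: (fpkm[gid], gid),
    )
    bins: dict[str, list[str]] = {"0": zero}
    labels = ["q1", "q2", "q3", "q4", "q5"]
    for lab, idxs in zip(labels, np.array_split(np.arange(len(expressed)), 5)):
        bins[lab] = [expressed[i] for i in idxs]
    rows = []
    for lab in ["0"] + labels:
        members = bins[lab]
        classes = {"promoter_only": 0, "gene_body_only": 0, "both": 0, "none": 0}
        for gid in members:
            in_p = gid in prom_genes
            in_b = gid in body_genes
            key = ("both" if in_p and in_b else
                   "promoter_only" if in_p else
                   "gene_body_only" if in_b else "none")
            classes[key] += 1
        total = max(len(members), 1)
        rows.append({"group": lab, "n_genes": len(members),
                     **{k: v / total for k, v in classes.items()}})
    return pd.DataFrame(rows).set_index("group")
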