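"""ACR landscape: replicate consolidation, stage specificity, null enrichment.

The representative ACR set of a stage keeps only peaks supported by both
replicates (>= 1 bp reciprocal overlap) and merges each reciprocal group into
its union interval.  Stage specificity is decided on overlap-connected
components of the tri-stage peak union: a component touching one stage is
stage-specific, all three stages common, exactly two "partial" — the three
classes partition the merged union exactly.

Feature enrichment against a permutation null re-places the observed regions
uniformly at random (chromosome drawn proportional to length, lengths
matched to the observed multiset by default), classifies every permuted
region and compares observed category counts to the permutation mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError
from .intervals import (
    CATEGORIES,
    FeatureCategory,
    GenomeAnnotation,
    GenomicInterval,
    Peak,
    classify,
    intersect,
    merge,
)
from .stats import pearson_r


@dataclass
class StageACRSet:
    """Replicate-consolidated representative ACRs of one stage."""

    stage: str
    peaks: list[Peak]
    source: tuple[str, str] = ("rep1", "rep2")


@dataclass
class SpecificityPartition:
    common: list[Peak]
    specific: dict[str, list[Peak]]
    partial: list[Peak]

    def sizes(self) -> dict[str, int]:
        out = {"common": len(self.common), "partial": len(self.partial)}
        for stage, plist in self.specific.items():
            out[f"specific:{stage}"] = len(plist)
        return out


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # index category; observed/expected_mean/fold/p values
    n_permutations: int
    length_matched: bool = True


def _merge_counts(dicts) -> dict[str, int] | None:
    merged: dict[str, int] = {}
    for d in dicts:
        if d:
            for k, v in d.items():
                merged[k] = merged.get(k, 0) + v
    return merged or None


def _union_components(peaks: list[Peak]):
    """Overlap-connected components (>=1 bp) of a sorted peak list."""
    comps: list[list[Peak]] = []
    cur: list[Peak] = []
    cur_end = -1
    cur_chrom = None
    for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.end, p.peak_id)):
        if cur and p.chrom == cur_chrom and p.start < cur_end:
            cur.append(p)
            cur_end = max(cur_end, p.end)
        else:
            if cur:
                comps.append(cur)
            cur = [p]
            cur_chrom = p.chrom
            cur_end = p.end
    if cur:
        comps.append(cur)
    return comps


def consolidate_replicates(rep1: list[Peak], rep2: list[Peak],
                           stage: str | None = None) -> StageACRSet:
    """Keep reciprocally supported peaks and merge them into union intervals.

    A peak survives iff it overlaps (>= 1 bp) some peak of the other
    replicate; each overlap-connected group of surviving peaks becomes one
    merged ACR whose counts are the per-sample sums of its constituents.
    """
    if stage is None:
        stage = rep1[0].stage if rep1 else (rep2[0].stage if rep2 else "NA")
    if not rep1 or not rep2:
        warnings.warn(f"consolidate_replicates({stage}): empty replicate")
        return StageACRSet(stage=stage, peaks=[])
    pairs = intersect(rep1, rep2, min_overlap_bp=1)
    keep1 = {i for i, _ in pairs}
    keep2 = {j for _, j in pairs}
    supported = [rep1[i] for i in sorted(keep1)] + [rep2[j] for j in sorted(keep2)]
    merged: list[Peak] = []
    for k, comp in enumerate(_union_components(supported)):
        start = min(p.start for p in comp)
        end = max(p.end for p in comp)
        merged.append(Peak(
            interval=GenomicInterval(comp[0].chrom, start, end, "."),
            peak_id=f"{stage}_acr{k:05d}",
            stage=stage,
            replicate="merged",
            counts=_merge_counts(p.counts for p in comp),
        ))
    merged.sort(key=lambda p: (p.chrom, p.start, p.end))
    return StageACRSet(stage=stage, peaks=merged)


def classify_specificity(stage_sets: dict[str, StageACRSet]) -> SpecificityPartition:
    """Partition the tri-stage peak union into common / partial / specific.

    Components of the merged union are labelled by the set of stages that
    contributed peaks; component intervals become the reported merged peaks,
    carrying the union of constituent sample counts.
    """
    stages = list(stage_sets)
    everything: list[Peak] = []
    for s in stages:
        everything.extend(stage_sets[s].peaks)
    common: list[Peak] = []
    partial: list[Peak] = []
    specific: dict[str, list[Peak]] = {s: [] for s in stages}
    counters = {"common": 0, "partial": 0, **{s: 0 for s in stages}}
    for comp in _union_components(everything):
        present = {p.stage for p in comp}
        start = min(p.start for p in comp)
        end = max(p.end for p in comp)
        counts = _merge_counts(p.counts for p in comp)
        if len(present) == len(stages):
            pid = f"common_{counters['common']:05d}"
            counters["common"] += 1
            bucket = common
        elif len(present) == 1:
            stage = next(iter(present))
            pid = f"{stage}_only_{counters[stage]:05d}"
            counters[stage] += 1
            bucket = specific[stage]
        else:
            pid = f"partial_{counters['partial']:05d}"
            counters["partial"] += 1
            bucket = partial
        bucket.append(Peak(
            interval=GenomicInterval(comp[0].chrom, start, end, "."),
            peak_id=pid,
            stage=None if len(present) != 1 else next(iter(present)),
            replicate="merged",
            counts=counts,
        ))
    return SpecificityPartition(common=common, specific=specific, partial=partial)


def genome_fraction(acrs: list[Peak], chrom_sizes: dict[str, int]) -> float:
    """Total ACR bp divided by total genome bp (input merged first)."""
    if not acrs:
        return 0.0
    ivs = sorted((p.interval for p in acrs),
                 key=lambda iv: (iv.chrom, iv.start, iv.end))
    covered = sum(iv.length for iv in merge(ivs))
    return covered / sum(chrom_sizes.values())


def sample_random_regions(rng: np.random.Generator, lengths: np.ndarray,
                          chrom_names: list[str], sizes: np.ndarray):
    """Length-matched random regions: chromosome ~ length, start uniform.

    Returns (chrom index array, start array).  Raises if some region is
    longer than every chromosome.
    """
    if (lengths > sizes.max()).any():
        raise ValidationError("a region is longer than every chromosome")
    n = len(lengths)
    p = sizes / sizes.sum()
    ci = rng.choice(len(chrom_names), size=n, p=p)
    # re-draw chromosomes too small for their region
    bad = lengths > sizes[ci]
    while bad.any():
        ci[bad] = rng.choice(len(chrom_names), size=int(bad.sum()), p=p)
        bad = lengths > sizes[ci]
    span = (sizes[ci] - lengths + 1).astype(np.int64)
    starts = (rng.random(n) * span).astype(np.int64)
    return ci, starts


def permutation_enrichment(acrs: list[Peak], annotation: GenomeAnnotation,
                           n_permutations: int = 5000, seed: int = 0,
                           length_matched: bool = True,
                           fixed_width: int | None = None) -> EnrichmentResult:
    """Observed vs permutation-mean feature-category counts, with fold and p.

    Each permutation re-places |acrs| regions (observed lengths by default,
    ``fixed_width`` otherwise) uniformly across the genome, classifies their
    midpoints and records category counts.  Fold = observed / permutation
    mean; one-sided empirical p-values use the +1 correction, so p is never 0
    and never below 1/(n_permutations+1).  Random placement does not mask the
    observed loci.
    """
    if n_permutations < 1:
        raise ContractError("n_permutations must be >= 1")
    if not acrs:
        raise ContractError("empty ACR set")
    rng = np.random.default_rng(seed)
    catmap = annotation.category_map()
    chrom_names = list(annotation.chrom_sizes)
    sizes = np.array([annotation.chrom_sizes[c] for c in chrom_names],
                     dtype=np.int64)
    observed = np.zeros(len(CATEGORIES), dtype=np.int64)
    for p in acrs:
        observed[int(classify(p, annotation))] += 1
    if length_matched and fixed_width is None:
        lengths = np.array([p.length for p in acrs], dtype=np.int64)
    else:
        width = fixed_width or int(np.median([p.length for p in acrs]))
        lengths = np.full(len(acrs), width, dtype=np.int64)
    perm_counts = np.zeros((n_permutations, len(CATEGORIES)), dtype=np.int64)
    flat_maps = [catmap[c] for c in chrom_names]
    for it in range(n_permutations):
        ci, starts = sample_random_regions(rng, lengths, chrom_names, sizes)
        mids = starts + lengths // 2
        for k in range(len(chrom_names)):
            sel = ci == k
            if sel.any():
                cats = flat_maps[k][mids[sel]]
                perm_counts[it] += np.bincount(cats, minlength=len(CATEGORIES))
    expected = perm_counts.mean(axis=0)
    sd = perm_counts.std(axis=0, ddof=1) if n_permutations > 1 \
        else np.zeros(len(CATEGORIES))
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(expected > 0, observed / expected, np.nan)
    p_enrich = (1 + (perm_counts >= observed).sum(axis=0)) / (n_permutations + 1)
    p_deplete = (1 + (perm_counts <= observed).sum(axis=0)) / (n_permutations + 1)
    table = pd.DataFrame(
        {
            "observed": observed,
            "expected_mean": expected,
            "perm_sd": sd,
            "se_mean": sd / np.sqrt(n_permutations),
            "fold": fold,
            "p_enrich": p_enrich,
            "p_deplete": p_deplete,
        },
        index=[c.label for c in CATEGORIES],
    )
    return EnrichmentResult(table=table, n_permutations=n_permutations,
                            length_matched=length_matched and fixed_width is None)


def chromosome_correlation(acrs: list[Peak], chrom_sizes: dict[str, int]):
    """Per-chromosome normalized chromatin length vs observed peak count.

    normalized length = total peak count x chromosome length / genome length;
    the Pearson r (and r^2) between that and the per-chromosome counts
    quantifies how closely peak density tracks chromosome size.
    """
    if len(chrom_sizes) < 2:
        raise ContractError("need >= 2 chromosomes for a correlation")
    total = len(acrs)
    genome = sum(chrom_sizes.values())
    counts = {c: 0 for c in chrom_sizes}
    for p in acrs:
        if p.chrom not in counts:
            raise ValidationError(f"peak on unknown chromosome {p.chrom}")
        counts[p.chrom] += 1
    rows = []
    for c, size in chrom_sizes.items():
        rows.append({
            "chrom": c,
            "length": size,
            "normalized_length": total * size / genome,
            "count": counts[c],
        })
    table = pd.DataFrame(rows).set_index("chrom")
    r = pearson_r(table["normalized_length"], table["count"])
    return table, r, r * r
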