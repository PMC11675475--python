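"""Fragment-level signal: RPM binning, replicate concordance, metaprofiles.

A fragment contributes at a single position — its midpoint — which avoids
double counting; RPM (reads per million) divides each bin count by the total
number of in-bounds fragments times 1e-6.  TSS/TES metaprofiles average RPM
in fixed-width bins over strand-oriented windows, with genes grouped into
near-equal expression deciles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .intervals import GenomeAnnotation
from .stats import pearson_r


@dataclass
class BinnedSignal:
    bin_width: int
    chrom_sizes: dict[str, int]
    counts: dict[str, np.ndarray]  # per-chromosome bin counts
    total_fragments: int
    n_skipped: int = 0

    @property
    def rpm(self) -> dict[str, np.ndarray]:
        scale = 1e6 / max(self.total_fragments, 1)
        return {c: v * scale for c, v in self.counts.items()}

    def rpm_vector(self) -> np.ndarray:
        return np.concatenate([self.rpm[c] for c in sorted(self.counts)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.counts):
            rpm = self.rpm[chrom]
            for i, v in enumerate(rpm):
                rows.append((chrom, i * self.bin_width,
                             min((i + 1) * self.bin_width,
                                 self.chrom_sizes[chrom]), v))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "rpm"])


def _midpoints(fragments) -> pd.DataFrame:
    df = pd.DataFrame(fragments, columns=["chrom", "start", "end"])
    df["mid"] = (df["start"] + df["end"]) // 2
    return df


def binned_rpm(fragments, chrom_sizes: dict[str, int],
               bin_width: int = 1000) -> BinnedSignal:
    """Midpoint-binned fragment counts with RPM normalization.

    ``fragments`` is an iterable of (chrom, start, end).  Fragments whose
    midpoint falls outside the chromosome (or on an unknown chromosome) are
    skipped and counted in ``n_skipped`` with a warning.
    """
    if bin_width < 1:
        raise ContractError("bin_width must be >= 1")
    df = _midpoints(list(fragments))
    counts = {
        c: np.zeros(-(-size // bin_width), dtype=np.int64)
        for c, size in chrom_sizes.items()
    }
    skipped = 0
    total = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in chrom_sizes:
            skipped += len(sub)
            continue
        mids = sub["mid"].to_numpy()
        ok = (mids >= 0) & (mids < chrom_sizes[chrom])
        skipped += int((~ok).sum())
        binned = np.bincount(mids[ok] // bin_width,
                             minlength=len(counts[chrom]))
        counts[chrom] += binned[: len(counts[chrom])]
        total += int(ok.sum())
    if skipped:
        warnings.warn(f"binned_rpm: skipped {skipped} out-of-bounds fragments")
    return BinnedSignal(bin_width=bin_width, chrom_sizes=dict(chrom_sizes),
                        counts=counts, total_fragments=total, n_skipped=skipped)


def replicate_correlation(a: BinnedSignal, b: BinnedSignal) -> float:
    """Pearson r of RPM across all bins of two identically binned samples."""
    if a.bin_width != b.bin_width or a.chrom_sizes != b.chrom_sizes:
        raise ContractError("signals must share binning and chromosomes")
    return pearson_r(a.rpm_vector(), b.rpm_vector())


@dataclass
class MetaProfile:
    """Mean RPM per relative-position bin, per expression group."""

    positions: np.ndarray  # bin-start offsets relative to the anchor
    tss: pd.DataFrame  # group x position
    tes: pd.DataFrame
    group_sizes: dict[int, int]


def metaprofile(fragments, annotation: GenomeAnnotation, fpkm: pd.Series,
                window: int = 2000, n_groups: int = 10,
                bin_width: int = 10) -> MetaProfile:
    """Expression-decile TSS/TES accessibility metaprofiles.

    Genes are ranked by the supplied FPKM values (ties broken by gene id for
    determinism) and split into ``n_groups`` near-equal groups, group 1 lowest
    expression.  Fragment midpoints are averaged (RPM) in ``bin_width`` bins
    over [anchor - window, anchor + window); minus-strand genes are flipped so
    negative offsets always mean "upstream".
    """
    genes = [g for g in annotation.genes if g.gene_id in fpkm.index]
    if len(genes) < n_groups:
        raise ContractError(
            f"{len(genes)} genes cannot form {n_groups} expression groups")
    order = sorted(genes, key=lambda g: (fpkm[g.gene_id], g.gene_id))
    splits = np.array_split(np.arange(len(order)), n_groups)
    group_of: dict[str, int] = {}
    for gi, idxs in enumerate(splits, start=1):
        for i in idxs:
            group_of[order[i].gene_id] = gi

    df = _midpoints(list(fragments))
    total = len(df)
    mids_by_chrom = {
        chrom: np.sort(sub["mid"].to_numpy())
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    n_bins = (2 * window) // bin_width
    positions = np.arange(-window, window, bin_width)
    acc = {
        anchor: np.zeros((n_groups, n_bins)) for anchor in ("tss", "tes")
    }
    sizes = {gi: 0 for gi in range(1, n_groups + 1)}
    for g in order:
        gi = group_of[g.gene_id]
        sizes[gi] += 1
        mids = mids_by_chrom.get(g.chrom)
        if mids is None:
            continue
        for anchor, point in (("tss", g.tss), ("tes", g.tes)):
            lo = np.searchsorted(mids, point - window, side="left")
            hi = np.searchsorted(mids, point + window, side="left")
            if hi == lo:
                continue
            rel = mids[lo:hi] - point
            if g.strand == "-":
                rel = -rel - 1  # mirror so upstream stays negative
            binned = np.bincount((rel + window) // bin_width,
                                 minlength=n_bins)[:n_bins]
            acc[anchor][gi - 1] += binned
    scale = 1e6 / max(total, 1)
    frames = {}
    for anchor in ("tss", "tes"):
        mat = acc[anchor] * scale
        for gi in range(1, n_groups + 1):
            if sizes[gi]:
                mat[gi - 1] /= sizes[gi]
        frames[anchor] = pd.DataFrame(
            mat, index=range(1, n_groups + 1), columns=positions)
    return MetaProfile(positions=positions, tss=frames["tss"],
                       tes=frames["tes"], group_sizes=sizes)
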