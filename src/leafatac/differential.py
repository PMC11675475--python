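"""Negative-binomial differential testing for peak and exon counts.

Implements a self-contained DESeq2-style workflow: median-of-ratios size
factors, per-feature method-of-moments NB dispersions shrunk toward a fitted
log-linear mean-dispersion trend, a Wald test on the log2 fold change, and
Benjamini-Hochberg adjustment.  Significance follows the study criteria:
adjusted p < 0.05 and |log2FC| > 1.  Exact numerical parity with DESeq2's MAP
dispersion estimator, Cook's filtering or independent filtering is a
non-goal; calibration and power are validated by simulation instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError
from .stats import bh_adjust

PADJ_THRESHOLD = 0.05
LFC_THRESHOLD = 1.0
DISPERSION_FLOOR = 1e-8
SHRINKAGE_WEIGHT = 0.5  # weight of the trend in log-dispersion shrinkage


@dataclass
class CountMatrix:
    """Feature x sample integer counts with (stage, replicate) sample labels."""

    counts: pd.DataFrame  # features x samples, non-negative integers
    samples: pd.DataFrame  # index = sample id; columns stage, replicate
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ContractError("count columns must match sample table index")
        if (self.counts.to_numpy() < 0).any():
            raise ContractError("counts must be non-negative")

    def samples_for_stage(self, stage: str) -> list[str]:
        return list(self.samples.index[self.samples["stage"] == stage])

    def normalized(self) -> pd.DataFrame:
        sf = self.size_factors
        if sf is None:
            sf = estimate_size_factors(self)
        return self.counts / sf


@dataclass
class DifferentialResult:
    """Per-comparison differential table plus the comparison metadata."""

    group_a: str
    group_b: str
    table: pd.DataFrame = field(repr=False)  # index feature; lfc/p/padj/...

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def direction_of(self, feature: str) -> str:
        return str(self.table.loc[feature, "direction"])


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only features with positive counts in every sample contribute; if none
    exist the estimator falls back to library-size ratios with a warning.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    pos = (arr > 0).all(axis=1)
    if pos.sum() == 0:
        warnings.warn(
            "no feature with positive counts in all samples; "
            "falling back to library-size ratios"
        )
        libs = arr.sum(axis=0)
        if (libs <= 0).any():
            raise ContractError("cannot estimate size factors from empty library")
        factors = libs
    else:
        sub = arr[pos]
        log_geo = np.mean(np.log(sub), axis=1)
        ratios = np.log(sub) - log_geo[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def _fit_dispersion_trend(means: np.ndarray, disps: np.ndarray) -> np.ndarray:
    """Log-linear fit of dispersion on mean; returns trend value per feature.

    Falls back to the mean log-dispersion when too few positive estimates
    exist for a regression.
    """
    ok = (means > 0) & (disps > DISPERSION_FLOOR * 2)
    if ok.sum() < 10 or np.ptp(np.log(means[ok])) < 1e-6:
        fill = np.log(np.median(disps[disps > 0])) if (disps > 0).any() else np.log(0.1)
        return np.full_like(means, np.exp(fill))
    lx = np.log(means[ok])
    ly = np.log(disps[ok])
    slope, intercept = np.polyfit(lx, ly, 1)
    with np.errstate(divide="ignore"):
        trend = np.exp(intercept + slope * np.log(np.maximum(means, 1e-8)))
    return trend


def nb_test(counts: CountMatrix, group_a, group_b) -> DifferentialResult:
    """Wald NB test of group_b over group_a for every feature.

    Dispersions: per-feature pooled within-group method-of-moments on
    normalized counts, shrunk in log space toward a log-linear mean-dispersion
    trend (weight 0.5), floored at 1e-8.  log2FC is reported with a 0.5
    pseudocount on normalized group means whenever a mean is zero.  Features
    with all-zero counts across both groups are excluded from testing and
    from the BH denominator.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ContractError("nb_test requires >= 2 samples per group")
    sf = counts.size_factors
    if sf is None:
        sf = estimate_size_factors(counts)
    sub = counts.counts[group_a + group_b]
    raw = sub.to_numpy(dtype=float)
    sfv = sf[group_a + group_b].to_numpy(dtype=float)
    norm = raw / sfv
    na, nb = len(group_a), len(group_b)
    xa, xb = norm[:, :na], norm[:, na:]
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    tested = (raw.sum(axis=1) > 0)

    # --- dispersion: pooled within-group method of moments -----------------
    var_a = xa.var(axis=1, ddof=1)
    var_b = xb.var(axis=1, ddof=1)
    pooled_var = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    grand_mean = (na * mean_a + nb * mean_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = (pooled_var - grand_mean) / grand_mean**2
    disp_mom = np.where(np.isfinite(disp_mom), disp_mom, 0.0)
    disp_mom = np.maximum(disp_mom, DISPERSION_FLOOR)
    trend = np.maximum(_fit_dispersion_trend(grand_mean[tested], disp_mom[tested]),
                       DISPERSION_FLOOR)
    disp = np.full_like(disp_mom, DISPERSION_FLOOR)
    disp[tested] = np.exp(
        (1 - SHRINKAGE_WEIGHT) * np.log(disp_mom[tested])
        + SHRINKAGE_WEIGHT * np.log(trend)
    )
    disp = np.maximum(disp, DISPERSION_FLOOR)

    # --- Wald statistic on the log fold change ----------------------------
    # Var(k_s / sf_s) = mu / sf_s + alpha * mu^2 for NB counts with mean
    # mu * sf_s; the delta method gives Var(log mean estimate).
    inv_sf_a = np.mean(1.0 / sfv[:na])
    inv_sf_b = np.mean(1.0 / sfv[na:])
    use_pseudo = (mean_a == 0) | (mean_b == 0)
    ma = mean_a + np.where(use_pseudo, 0.5, 0.0)
    mb = mean_b + np.where(use_pseudo, 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_ln_a = (ma * inv_sf_a + disp * ma**2) / (na * ma**2)
        var_ln_b = (mb * inv_sf_b + disp * mb**2) / (nb * mb**2)
        lfc = np.log2(mb) - np.log2(ma)
        se_ln = np.sqrt(var_ln_a + var_ln_b)
        z = np.log(mb / ma) / se_ln
    from scipy.stats import norm as normal

    p = np.where(tested, 2.0 * normal.sf(np.abs(z)), np.nan)
    p = np.where(np.isfinite(p), p, 1.0)
    p[~tested] = np.nan
    padj = np.full_like(p, np.nan)
    if tested.any():
        padj[tested] = bh_adjust(p[tested])
    significant = (padj < PADJ_THRESHOLD) & (np.abs(lfc) > LFC_THRESHOLD)
    significant = np.where(tested, significant, False).astype(bool)
    direction = np.where(
        ~significant, "ns", np.where(lfc > 0, "up", "down")
    )
    table = pd.DataFrame(
        {
            "baseMeanA": mean_a,
            "baseMeanB": mean_b,
            "log2fc": lfc,
            "dispersion": disp,
            "p": p,
            "padj": padj,
            "significant": significant,
            "direction": direction,
            "tested": tested,
        },
        index=sub.index,
    )
    return DifferentialResult(group_a=str(group_a), group_b=str(group_b), table=table)


def nb_test_stages(counts: CountMatrix, stage_a: str, stage_b: str) -> DifferentialResult:
    """nb_test between the replicate samples of two stages (b over a)."""
    res = nb_test(counts, counts.samples_for_stage(stage_a),
                  counts.samples_for_stage(stage_b))
    res.group_a, res.group_b = stage_a, stage_b
    return res


def filter_expressed(fpkm: pd.DataFrame, samples: pd.DataFrame,
                     rule: str = "all_reps_one_stage",
                     threshold: float = 1.0) -> list[str]:
    """Expressed-gene filter on an FPKM table.

    Default rule retains genes with FPKM > threshold in *all* replicates of at
    least one stage.  The alternate rule "any_three_samples" retains genes
    with FPKM > threshold in any three samples overall.
    """
    arr = fpkm.to_numpy(dtype=float)
    if rule == "all_reps_one_stage":
        keep = np.zeros(len(fpkm), dtype=bool)
        for stage in samples["stage"].unique():
            cols = [fpkm.columns.get_loc(s)
                    for s in samples.index[samples["stage"] == stage]]
            keep |= (arr[:, cols] > threshold).all(axis=1)
    elif rule == "any_three_samples":
        keep = (arr > threshold).sum(axis=1) >= 3
    else:
        raise ValueError(f"unknown filter rule {rule!r}")
    return list(fpkm.index[keep])


def identify_degs(expr_counts: CountMatrix, stage_pairs, genes=None):
    """NB tests per stage pair on exon counts; returns (results, union set).

    ``genes`` restricts testing to an expressed-gene subset.  The union
    carries every gene significant in at least one comparison.
    """
    results: dict[tuple[str, str], DifferentialResult] = {}
    if genes is not None:
        expr_counts = CountMatrix(
            counts=expr_counts.counts.loc[list(genes)],
            samples=expr_counts.samples,
            size_factors=expr_counts.size_factors,
        )
    union: set[str] = set()
    for a, b in stage_pairs:
        res = nb_test_stages(expr_counts, a, b)
        results[(a, b)] = res
        union |= set(res.significant().index)
    return results, union


@dataclass
class CorrelationSummary:
    per_gene: pd.Series  # gene -> Pearson r across stages
    fraction_positive: float
    median_r: float
    n_genes: int
    n_excluded_zero_variance: int


def intensity_expression_correlation(
    stage_intensity: pd.DataFrame, stage_fpkm: pd.DataFrame
) -> CorrelationSummary:
    """Per-gene Pearson r between stage-level peak intensity and expression.

    Both inputs are gene x stage tables over the same stages; genes present in
    both and with nonzero variance in both vectors contribute.  With three
    stages each r uses three points — coarse per gene, but informative in
    aggregate, which is how the summary (fraction positive, median r) is used.
    """
    stages = [c for c in stage_intensity.columns if c in stage_fpkm.columns]
    if len(stages) < 2:
        raise ContractError("need >= 2 shared stages for correlation")
    common = stage_intensity.index.intersection(stage_fpkm.index)
    rs = {}
    excluded = 0
    xi = stage_intensity.loc[common, stages].to_numpy(dtype=float)
    yi = stage_fpkm.loc[common, stages].to_numpy(dtype=float)
    for i, gene in enumerate(common):
        x, y = xi[i], yi[i]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            excluded += 1
            continue
        rs[gene] = float(np.corrcoef(x, y)[0, 1])
    per_gene = pd.Series(rs, dtype=float)
    if len(per_gene) == 0:
        return CorrelationSummary(per_gene, np.nan, np.nan, 0, excluded)
    return CorrelationSummary(
        per_gene=per_gene,
        fraction_positive=float((per_gene > 0).mean()),
        median_r=float(per_gene.median()),
        n_genes=len(per_gene),
        n_excluded_zero_variance=excluded,
    )
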