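"""Promoter assignment, count/length groupings, expression bins, rank test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from leafatac.errors import ContractError
from leafatac.intervals import GeneModel, GenomeAnnotation
from leafatac.linkage import (
    PromoterAssignment,
    acr_association_by_expression_bin,
    assign_promoter_acrs,
    expression_by_acr_count,
    length_tertiles,
)
from leafatac.stats import rank_test

from conftest import make_peak


@pytest.fixture()
def two_gene_annotation():
    g1 = GeneModel("g1", "chr1", "+", 5000, 7000, exons=[(5000, 7000)])
    g2 = GeneModel("g2", "chr1", "+", 20000, 22000, exons=[(20000, 22000)])
    return GenomeAnnotation({"chr1": 40000}, [g1, g2])


# --------------------------------------------------------------- assignment

def test_assignment_window_boundaries(two_gene_annotation):
    ann = two_gene_annotation
    inside = make_peak("chr1", 3400, 3600, "in")       # midpoint 3500
    downstream = make_peak("chr1", 4951, 5051, "out")  # midpoint 5001 >= TSS
    asn = assign_promoter_acrs([inside, downstream], ann)
    assert [r["peak_id"] for r in asn.assignments["g1"]] == ["in"]


def test_assignment_nearest_tss_on_overlapping_windows():
    # two plus-strand genes with overlapping promoter windows
    g1 = GeneModel("g1", "chr1", "-", 1000, 3000, exons=[(1000, 3000)])
    g2 = GeneModel("g2", "chr1", "+", 4000, 6000, exons=[(4000, 6000)])
    ann = GenomeAnnotation({"chr1": 10000}, [g1, g2])
    # windows: g1 [3000,5000), g2 [2000,4000): overlap [3000,4000)
    near_g1 = make_peak("chr1", 3050, 3150, "a")  # midpoint 3100: d(g1)=100, d(g2)=900
    asn = assign_promoter_acrs([near_g1], ann)
    assert "g1" in asn.assignments and "g2" not in asn.assignments
    mid = make_peak("chr1", 3450, 3550, "tie")  # midpoint 3500: both 500 away
    asn = assign_promoter_acrs([mid], ann)
    assert "g1" in asn.assignments and "g2" in asn.assignments
    assert asn.ambiguous == [("tie", ("g1", "g2"))]


def test_assignment_recovery_on_default_dataset(recovery):
    assert recovery.promoter_assignment_recall >= 0.95


# ------------------------------------------------------------ count groups

def test_expression_by_count_groups_partition(two_gene_annotation):
    asn = PromoterAssignment(assignments={"g1": [{"peak_id": "p", "length": 100,
                                                  "intensity": 1.0}]})
    fpkm = pd.Series({"g1": 5.0, "g2": 1.0, "g3": 2.0, "g4": 0.5})
    comp = expression_by_acr_count(asn, fpkm)
    assert sorted(sum(comp.groups.values(), [])) == sorted(fpkm.index)
    assert comp.groups["1"] == ["g1"]
    # tiny groups: every adjacent pair skipped, none tested
    assert comp.pairwise_p == {}
    assert comp.skipped_pairs


def test_strong_coupling_orders_group_medians(default_dataset, pipeline_result):
    # per-gene median FPKM across samples: robust to stage-pattern archetypes
    fpkm = default_dataset.expression.fpkm.median(axis=1)
    comp = expression_by_acr_count(pipeline_result.promoter_assignment, fpkm)
    assert comp.medians["1"] > comp.medians["0"]
    assert comp.medians["2"] > comp.medians["1"]
    assert comp.pairwise_p[("0", "1")] < 0.05
    assert comp.pairwise_p[("1", "2")] < 0.05


# --------------------------------------------------------------- tertiles

def _assignment_with_lengths(lengths):
    return PromoterAssignment(assignments={
        f"g{i:02d}": [{"peak_id": f"p{i}", "length": L, "intensity": 1.0}]
        for i, L in enumerate(lengths)
    })


def test_tertiles_distinct_lengths():
    asn = _assignment_with_lengths([900, 800, 700, 600, 500, 400, 300, 200, 100])
    fpkm = pd.Series({f"g{i:02d}": 1.0 + i for i in range(9)})
    groups, _ = length_tertiles(asn, fpkm)
    assert groups["top"] == ["g00", "g01", "g02"]
    assert groups["middle"] == ["g03", "g04", "g05"]
    assert groups["bottom"] == ["g06", "g07", "g08"]


def test_tertiles_all_tied_round_robin():
    asn = _assignment_with_lengths([500] * 6)
    fpkm = pd.Series({f"g{i:02d}": 1.0 for i in range(6)})
    groups, _ = length_tertiles(asn, fpkm)
    assert {k: len(v) for k, v in groups.items()} == \
        {"top": 2, "middle": 2, "bottom": 2}


def test_tertiles_tie_run_straddling_boundary_spreads_evenly():
    # lengths: 2 distinct high, then a 5-run of ties straddling two boundaries
    asn = _assignment_with_lengths([900, 800] + [500] * 5 + [100, 50])
    fpkm = pd.Series({g: 1.0 for g in asn.assignments})
    groups, _ = length_tertiles(asn, fpkm)
    sizes = {k: len(v) for k, v in groups.items()}
    assert sizes == {"top": 3, "middle": 3, "bottom": 3}
    tied = [f"g{i:02d}" for i in range(2, 7)]
    spread = {k: len(set(v) & set(tied)) for k, v in groups.items()}
    assert spread == {"top": 1, "middle": 3, "bottom": 1}


def test_tertiles_permutation_invariant():
    rng = np.random.default_rng(0)
    lengths = list(rng.integers(100, 400, size=20)) + [250] * 5
    asn = _assignment_with_lengths(lengths)
    fpkm = pd.Series({g: 1.0 for g in asn.assignments})
    ref, _ = length_tertiles(asn, fpkm)
    shuffled_items = list(asn.assignments.items())
    rng.shuffle(shuffled_items)
    asn2 = PromoterAssignment(assignments=dict(shuffled_items))
    got, _ = length_tertiles(asn2, fpkm)
    assert {k: sorted(v) for k, v in ref.items()} == \
        {k: sorted(v) for k, v in got.items()}


def test_tertiles_require_three_genes():
    asn = _assignment_with_lengths([100, 200])
    with pytest.raises(ContractError):
        length_tertiles(asn, pd.Series({"g00": 1.0, "g01": 2.0}))


def test_planted_length_coupling_orders_tertiles(default_dataset,
                                                 pipeline_result):
    """Longer promoter ACRs carry more accessibility weight by construction,
    so the top length tertile should out-express the bottom one."""
    ds = default_dataset
    fpkm = ds.expression.fpkm.mean(axis=1)
    unpatterned = [g for g in fpkm.index if g not in ds.truth.gene_clusters
                   and g not in ds.truth.discordant_genes]
    groups, comp = length_tertiles(pipeline_result.promoter_assignment, fpkm,
                                   genes=unpatterned)
    assert comp.medians["top"] > comp.medians["bottom"]
    assert comp.pairwise_p[("top", "bottom")] < 0.05


# ------------------------------------------------------------ expression bins

def test_association_bins_classes_and_row_sums(two_gene_annotation):
    ann = two_gene_annotation
    acrs = sorted([
        make_peak("chr1", 3400, 3600, "prom_g1"),     # g1 promoter
        make_peak("chr1", 5500, 5600, "body_g1"),     # g1 body
        make_peak("chr1", 20500, 20600, "body_g2"),   # g2 body only
    ], key=lambda p: (p.chrom, p.start))
    fpkm = pd.Series({"g1": 10.0, "g2": 1.0})
    table = acr_association_by_expression_bin(acrs, ann, fpkm)
    # proportions per row sum to one
    cls = ["promoter_only", "gene_body_only", "both", "none"]
    nonempty = table[table["n_genes"] > 0]
    assert np.allclose(nonempty[cls].sum(axis=1), 1.0)
    # two expressed genes fall into the first two quintile bins
    assert table.loc["q2", "both"] == 1.0  # g1: promoter + body
    assert table.loc["q1", "gene_body_only"] == 1.0  # g2


def test_association_bins_no_peaks_all_none(two_gene_annotation):
    fpkm = pd.Series({"g1": 10.0, "g2": 0.0})
    table = acr_association_by_expression_bin([], two_gene_annotation, fpkm)
    nonempty = table[table["n_genes"] > 0]
    assert (nonempty["none"] == 1.0).all()


def test_association_both_proportion_monotone_under_coupling(default_dataset,
                                                             pipeline_result):
    ds = default_dataset
    fpkm = ds.expression.fpkm.mean(axis=1)
    all_merged = sorted(
        pipeline_result.partition.common + pipeline_result.partition.partial
        + [p for s in pipeline_result.partition.specific.values() for p in s],
        key=lambda p: (p.chrom, p.start))
    table = acr_association_by_expression_bin(
        all_merged, ds.annotation, fpkm, pipeline_result.promoter_assignment)
    both = table.loc[["q1", "q5"], "both"]
    assert both["q5"] > both["q1"]


# ---------------------------------------------------------------- rank test

def test_rank_test_exact_example():
    assert rank_test([1, 2, 3], [10, 20, 30]) == pytest.approx(0.1)


def test_rank_test_identical_multisets():
    assert rank_test([1, 2, 2, 3], [1, 2, 2, 3]) == pytest.approx(1.0, abs=1e-9)
    assert rank_test([5, 5], [5, 5]) == 1.0


def test_rank_test_matches_independent_enumeration():
    """Exact branch equals a from-scratch enumeration oracle with ties."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        x = rng.integers(0, 5, size=4).astype(float)
        y = rng.integers(0, 5, size=5).astype(float)
        pooled = np.concatenate([x, y])
        n = len(x)
        total = math.comb(len(pooled), n)

        def u_stat(xs, ys):
            return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

        u_obs = u_stat(x, y)
        le = ge = 0
        for comb in itertools.combinations(range(len(pooled)), n):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(comb)] = True
            u = u_stat(pooled[mask], pooled[~mask])
            le += u <= u_obs + 1e-9
            ge += u >= u_obs - 1e-9
        expected = min(1.0, 2 * min(le, ge) / total)
        assert rank_test(x, y) == pytest.approx(expected)


def test_rank_test_requires_two_per_group():
    with pytest.raises(ContractError):
        rank_test([1.0], [2.0, 3.0])
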