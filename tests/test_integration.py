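"""Clustering recovery, Fisher/hypergeometric behaviour, quadrant integration,
set and motif enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from leafatac.errors import ContractError
from leafatac.integration import (
    cluster_degs,
    cluster_overlap_fisher,
    integrate_dpi_deg,
    motif_enrichment,
    scan_motif,
    set_enrichment,
)
from leafatac.stats import fisher_2x2_greater, hypergeom_tail


def hypergeom_oracle(k, N, K, n):
    """Direct summation of the hypergeometric upper tail with exact integers."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


# ------------------------------------------------------------- clustering

def test_cluster_recovery_from_well_separated_archetypes():
    from sklearn.metrics import adjusted_rand_score
    from leafatac.simulate import SimConfig

    arch = np.asarray(SimConfig().cluster_pattern_archetypes)
    rng = np.random.default_rng(0)
    genes, labels = [], []
    rows = []
    for c in range(8):
        for i in range(25):
            noisy = 3.0 + 2.5 * arch[c] + rng.normal(0, 0.1, 3)
            rows.append(2.0 ** noisy)  # FPKM scale
            genes.append(f"g{c}_{i}")
            labels.append(c + 1)
    fpkm = pd.DataFrame(rows, index=genes,
                        columns=["BBCH_11", "BBCH_13", "BBCH_17"])
    got = cluster_degs(fpkm, k=8, seed=1, archetypes=arch)
    ari = adjusted_rand_score(labels, [got.labels[g] for g in genes])
    assert ari >= 0.9
    # archetype relabeling: planted cluster c should map to label c
    agree = np.mean([got.labels[g] == l for g, l in zip(genes, labels)])
    assert agree >= 0.9


def test_cluster_duplicates_and_determinism():
    rng = np.random.default_rng(2)
    fpkm = pd.DataFrame(rng.gamma(2, 10, size=(40, 3)),
                        index=[f"g{i}" for i in range(40)],
                        columns=["a", "b", "c"])
    fpkm.loc["g1"] = fpkm.loc["g0"]  # exact duplicate row
    a = cluster_degs(fpkm, k=4, seed=5)
    b = cluster_degs(fpkm, k=4, seed=5)
    assert a.labels == b.labels
    assert a.labels["g0"] == a.labels["g1"]


def test_cluster_k1_degenerate_and_too_few_genes():
    fpkm = pd.DataFrame([[1, 2, 3], [2, 3, 4], [5, 1, 2]],
                        index=list("abc"), columns=["x", "y", "z"])
    one = cluster_degs(fpkm, k=1, seed=0)
    assert set(one.labels.values()) == {1}
    with pytest.raises(ContractError):
        cluster_degs(fpkm, k=8, seed=0)


def test_end_to_end_cluster_ari(recovery):
    assert recovery.cluster_ari >= 0.9


# ----------------------------------------------------------------- Fisher

def test_hypergeom_tail_example_table():
    # N=20, K=4, n=5, k=3: direct summation oracle
    expected = hypergeom_oracle(3, 20, 4, 5)
    assert hypergeom_tail(3, 20, 4, 5) == pytest.approx(expected, rel=1e-12)
    assert fisher_2x2_greater(3, 2, 1, 14) == pytest.approx(expected, rel=1e-12)


def test_fisher_agrees_with_scipy():
    from scipy.stats import fisher_exact

    rng = np.random.default_rng(1)
    for _ in range(50):
        a, b, c, d = rng.integers(0, 15, size=4)
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        assert fisher_2x2_greater(int(a), int(b), int(c), int(d)) == \
            pytest.approx(p, rel=1e-9, abs=1e-12)


def test_cluster_overlap_perfect_containment():
    from leafatac.integration import ClusterAssignment

    members = {f"g{i}": 1 for i in range(10)}
    members.update({f"h{i}": 2 for i in range(100)})
    clusters = ClusterAssignment(labels=members, centroids=pd.DataFrame())
    table = cluster_overlap_fisher(
        {"set": {f"g{i}" for i in range(10)}}, clusters,
        universe=set(members))
    row1 = table[table["cluster"] == 1].iloc[0]
    row2 = table[table["cluster"] == 2].iloc[0]
    assert row1["proportion"] == 1.0
    assert row1["p"] < row2["p"]
    assert row1["p"] == pytest.approx(hypergeom_oracle(10, 110, 10, 10), rel=1e-9)


def test_cluster_overlap_empty_set_is_null():
    from leafatac.integration import ClusterAssignment

    clusters = ClusterAssignment(labels={"a": 1, "b": 2},
                                 centroids=pd.DataFrame())
    table = cluster_overlap_fisher({"s": {"zzz"}}, clusters, universe={"a", "b"})
    assert (table["proportion"] == 0).all()
    assert (table["p"] == 1.0).all()


def test_planted_specific_acr_genes_enrich_matching_cluster(default_dataset,
                                                            pipeline_result):
    """Stage-specific promoter-ACR genes are planted into stage-matched
    archetypes, so the matching cluster should carry the largest proportion."""
    res = pipeline_result
    table = res.cluster_overlap
    cfg = default_dataset.config
    for stage, arch in cfg.stage_archetype.items():
        sub = table[table["set"] == stage]
        if sub["set_size"].iloc[0] < 5:
            continue
        best = sub.loc[sub["proportion"].idxmax(), "cluster"]
        assert best == arch
        assert sub[sub["cluster"] == arch]["p"].iloc[0] < 0.05


# ------------------------------------------------------------- integration

def _diff_result(pairs, direction_map):
    from leafatac.differential import DifferentialResult

    idx = list(direction_map)
    sig = [direction_map[i] in ("up", "down") for i in idx]
    table = pd.DataFrame({
        "log2fc": [2 if direction_map[i] == "up" else -2 if direction_map[i] == "down" else 0
                   for i in idx],
        "padj": [0.001 if s else 0.9 for s in sig],
        "significant": sig,
        "direction": [direction_map[i] for i in idx],
    }, index=idx)
    return DifferentialResult(group_a=pairs[0], group_b=pairs[1], table=table)


def test_quadrant_placement_and_conflicts():
    from leafatac.linkage import PromoterAssignment

    dpi = _diff_result(("s1", "s2"), {"p1": "up", "p2": "down", "p3": "up"})
    deg = _diff_result(("s1", "s2"), {"gA": "up", "gB": "up", "gC": "down"})
    asn = PromoterAssignment(assignments={
        "gA": [{"peak_id": "p1", "length": 100, "intensity": 1}],
        "gB": [{"peak_id": "p2", "length": 100, "intensity": 1},
               {"peak_id": "p3", "length": 100, "intensity": 1}],  # conflict
        "gC": [{"peak_id": "p1", "length": 100, "intensity": 1}],
    })
    quad = integrate_dpi_deg(dpi, deg, asn)
    assert quad.counts["atac_up_rna_up"] == 1      # gA
    assert quad.counts["atac_up_rna_down"] == 1    # gC
    assert quad.conflicting == {"gB"}


def test_quadrants_comparison_mismatch_raises():
    from leafatac.linkage import PromoterAssignment

    dpi = _diff_result(("s1", "s2"), {"p": "up"})
    deg = _diff_result(("s1", "s3"), {"g": "up"})
    with pytest.raises(ContractError):
        integrate_dpi_deg(dpi, deg, PromoterAssignment())


def test_empty_dpi_gives_zero_quadrants():
    from leafatac.linkage import PromoterAssignment

    dpi = _diff_result(("s1", "s2"), {"p": "ns"})
    deg = _diff_result(("s1", "s2"), {"g": "up"})
    quad = integrate_dpi_deg(
        dpi, deg,
        PromoterAssignment(assignments={
            "g": [{"peak_id": "p", "length": 1, "intensity": 1}]}))
    assert sum(quad.counts.values()) == 0


def test_concordance_dominates_on_default_dataset(pipeline_result):
    total_conc = sum(q.concordant() for q in pipeline_result.quadrants.values())
    total_disc = sum(q.discordant() for q in pipeline_result.quadrants.values())
    assert total_conc > total_disc


def test_discordant_recovery_on_default_dataset(recovery):
    assert recovery.discordant_recovery >= 0.8


# ---------------------------------------------------------- set enrichment

def test_set_enrichment_oracle_and_skip():
    universe = {f"g{i}" for i in range(20)}
    target = {f"g{i}" for i in range(5)}
    annotation = {
        "term1": {f"g{i}" for i in range(4)},          # overlap 4
        "term2": {f"g{i}" for i in range(10, 14)},     # overlap 0
        "empty": {"outside"},                          # skipped
    }
    table = set_enrichment(target, universe, annotation)
    assert set(table["term"]) == {"term1", "term2"}
    p1 = table.set_index("term").loc["term1", "p"]
    assert p1 == pytest.approx(hypergeom_oracle(4, 20, 4, 5), rel=1e-9)


def test_set_enrichment_requires_subset():
    with pytest.raises(ContractError):
        set_enrichment({"x"}, {"y"}, {})


def test_set_enrichment_null_calibration():
    rng = np.random.default_rng(7)
    universe = [f"g{i}" for i in range(200)]
    ann = {f"t{j}": set(rng.choice(universe, size=20, replace=False))
           for j in range(60)}
    hits = 0
    trials = 20
    for _ in range(trials):
        target = set(rng.choice(universe, size=30, replace=False))
        table = set_enrichment(target, set(universe), ann, alpha=0.05)
        hits += int(table["significant"].sum())
    rate = hits / (trials * 60)
    assert rate <= 0.08  # ~alpha expected for a random target


# --------------------------------------------------------------- motifs

def test_scan_motif_forward_and_reverse_complement():
    assert scan_motif("TTACGTTT", "ACGT")
    assert scan_motif("AAACGTAA", "ACGT")  # revcomp of ACGT is ACGT
    assert scan_motif("TTGGTCAT", "TGACCA")  # reverse complement hit
    assert not scan_motif("AAAAAA", "ACGT")
    # N in the motif matches any sequence base
    assert scan_motif("TTACGT", "TANGT")


def test_scan_motif_iupac_degeneracy_and_mismatch():
    assert scan_motif("TGACCA", "TGAYCA")  # Y matches C
    assert not scan_motif("TGAGCA", "TGAYCA")
    assert scan_motif("TGAGCA", "TGAYCA", max_mismatches=1)


def test_motif_enrichment_planted_rates():
    rng = np.random.default_rng(5)

    def rand_seq(n):
        return "".join(rng.choice(list("ACGT"), size=n))

    motif = "TGACCA"
    targets = {}
    for i in range(50):
        seq = rand_seq(200)
        if i < 40:
            seq = seq[:90] + motif + seq[96:]
        targets[f"t{i}"] = seq
    background = {f"b{i}": rand_seq(200) for i in range(200)}
    table = motif_enrichment(targets, background, [motif])
    row = table.iloc[0]
    assert row["target_hits"] >= 40
    assert row["p"] < 0.01
    assert bool(row["significant"])


def test_motif_longer_than_sequences_skipped():
    with pytest.warns(UserWarning, match="skipped"):
        table = motif_enrichment({"a": "ACGT"}, {"b": "GGTA"}, ["ACGTACGTAA"])
    assert table.empty


def test_motif_enrichment_on_default_dataset(pipeline_result, default_dataset):
    table = pipeline_result.motif_table
    planted = default_dataset.config.motif_consensus_list[0]
    row = table[table["motif"] == planted].iloc[0]
    assert row["p"] < 0.01
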