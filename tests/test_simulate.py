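"""Generator determinism, planted-structure laws and coupling behaviour."""

import numpy as np
import pandas as pd
import pytest

from leafatac.errors import ConfigError, SizingError
from leafatac.intervals import FeatureCategory, classify, read_annotation
from leafatac.simulate import (
    STAGES,
    SimConfig,
    generate_acr_truth,
    generate_count_matrix,
    generate_dataset,
    generate_expression_table,
    generate_genome,
    simulate_null_counts,
    write_dataset,
)


def small_config(**kw):
    base = dict(
        seed=1, n_chromosomes=2, chromosome_lengths=(400_000, 200_000),
        n_genes=60, n_shared_peaks=100, n_specific_peaks_per_stage=(30, 10, 10),
        n_patterned_genes=32, n_discordant=4, n_fragments_per_sample=5000,
    )
    base.update(kw)
    return SimConfig(**base)


# ----------------------------------------------------------------- genome

def test_genome_deterministic_gff3_bytes(tmp_path):
    from leafatac.intervals import write_gff3

    cfg = SimConfig(seed=1, n_chromosomes=2,
                    chromosome_lengths=(200_000, 100_000), n_genes=20)
    for run in (1, 2):
        write_gff3(generate_genome(cfg), tmp_path / f"run{run}.gff3")
    assert (tmp_path / "run1.gff3").read_bytes() == \
        (tmp_path / "run2.gff3").read_bytes()


def test_genome_empty_case():
    cfg = SimConfig(seed=0, n_chromosomes=1, chromosome_lengths=(50_000,),
                    n_genes=0, n_discordant=0)
    ann = generate_genome(cfg)
    assert ann.genes == [] and len(ann.chrom_sizes) == 1


def test_genome_round_trips_through_parser(tmp_path):
    from leafatac.intervals import write_chrom_sizes, write_gff3

    cfg = SimConfig(seed=3, n_chromosomes=2,
                    chromosome_lengths=(200_000, 100_000), n_genes=20)
    ann = generate_genome(cfg)
    write_gff3(ann, tmp_path / "g.gff3")
    write_chrom_sizes(ann.chrom_sizes, tmp_path / "g.sizes")
    back = read_annotation(tmp_path / "g.gff3", tmp_path / "g.sizes")
    assert len(back.genes) == 20
    for g0, g1 in zip(sorted(ann.genes, key=lambda g: (g.chrom, g.start)),
                      back.genes):
        assert (g0.gene_id, g0.start, g0.end, g0.strand) == \
            (g1.gene_id, g1.start, g1.end, g1.strand)
        assert g0.tss == g1.tss and g0.exons == g1.exons
        if g0.strand == "+":
            assert g0.tss < g0.tes
        else:
            assert g0.tss > g0.tes


def test_genome_infeasible_packing_raises():
    cfg = SimConfig(seed=0, n_chromosomes=1, chromosome_lengths=(50_000,),
                    n_genes=30)
    with pytest.raises(SizingError):
        generate_genome(cfg)


# ------------------------------------------------------------------ peaks

def test_replicate_files_contain_expected_peak_counts():
    cfg = small_config()
    ann = generate_genome(cfg)
    peaks, truth = generate_acr_truth(ann, cfg)
    assert len(peaks[("BBCH_11", 1)]) == 130  # 100 shared + 30 specific
    assert len(peaks[("BBCH_11", 2)]) == 130
    assert len(peaks[("BBCH_13", 1)]) == 110
    assert len(peaks[("BBCH_17", 2)]) == 110
    assert len(truth.planted_peaks) == 150


def test_promoter_only_placement_lands_in_promoters():
    cfg = small_config(
        category_placement_probs={"promoter": 1.0},
        n_shared_peaks=60, n_specific_peaks_per_stage=(0, 0, 0),
    )
    ann = generate_genome(cfg)
    _, truth = generate_acr_truth(ann, cfg)
    for pp in truth.planted_peaks.values():
        assert ann.classify_point(pp.chrom, pp.midpoint) is FeatureCategory.PROMOTER
        assert pp.host_gene is not None


def test_peak_counts_proportional_to_chromosome_length():
    cfg = SimConfig(
        seed=5, n_chromosomes=2, chromosome_lengths=(1_000_000, 2_000_000),
        n_genes=240, n_shared_peaks=900, n_specific_peaks_per_stage=(0, 0, 0),
        category_placement_probs={"intron": 0.3, "intergenic": 0.7},
        n_patterned_genes=0, n_discordant=0,
    )
    ann = generate_genome(cfg)
    _, truth = generate_acr_truth(ann, cfg)
    counts = pd.Series([pp.chrom for pp in truth.planted_peaks.values()]).value_counts()
    frac_chr2 = counts["chr2"] / counts.sum()
    # binomial(900, 2/3): 4 sigma ~ 0.063
    assert abs(frac_chr2 - 2 / 3) < 0.065


def test_category_absent_raises():
    cfg = SimConfig(seed=0, n_chromosomes=1, chromosome_lengths=(100_000,),
                    n_genes=0, n_discordant=0,
                    category_placement_probs={"utr3": 1.0},
                    n_shared_peaks=5)
    ann = generate_genome(cfg)
    with pytest.raises(ConfigError):
        generate_acr_truth(ann, cfg)


# ----------------------------------------------------------------- counts

def test_size_factor_recovery_from_planted_library_sizes():
    from leafatac.differential import estimate_size_factors

    libs = SimConfig().library_sizes
    cm, _ = simulate_null_counts(3000, 300, 0.05, seed=2, library_sizes=libs)
    sf = estimate_size_factors(cm)
    expected = np.asarray(libs, float) / np.exp(np.mean(np.log(libs)))
    assert np.allclose(sf.to_numpy(), expected, rtol=0.05)


def test_doubled_library_size_doubles_size_factor():
    from leafatac.differential import estimate_size_factors

    cm, _ = simulate_null_counts(
        1000, 300, 0.05, seed=3,
        library_sizes=(2_000_000, 1_000_000, 1_000_000, 1_000_000,
                       1_000_000, 1_000_000))
    sf = estimate_size_factors(cm)
    others = sf.iloc[1:].mean()
    assert sf.iloc[0] / others == pytest.approx(2.0, rel=0.05)


def test_null_counts_have_no_stage_structure():
    from leafatac.differential import estimate_size_factors, nb_test_stages

    cm, _ = simulate_null_counts(2000, 400, 0.05, seed=11)
    cm.size_factors = estimate_size_factors(cm)
    res = nb_test_stages(cm, "BBCH_11", "BBCH_13")
    assert res.table["significant"].mean() <= 0.05


def test_planted_dpi_signs_recorded_and_realized():
    cfg = small_config(intensity_drift_sd=0.0)
    ann = generate_genome(cfg)
    _, truth = generate_acr_truth(ann, cfg)
    generate_count_matrix(truth, cfg)
    assert len(truth.dpi_effects) == round(cfg.frac_dpi * cfg.n_shared_peaks)
    sm = truth.stage_means
    for pid, eff in truth.dpi_effects.items():
        j = list(STAGES).index(eff["stage"])
        others = [k for k in range(3) if k != j]
        ratio = np.log2(sm.loc[pid].iloc[j] / sm.loc[pid].iloc[others].mean())
        assert np.sign(ratio) == np.sign(eff["log2fc"])
        assert abs(ratio) == pytest.approx(cfg.dpi_log2fc, abs=1e-9)


# ------------------------------------------------------------- expression

def test_fpkm_consistent_with_counts_and_library_size(default_dataset):
    expr = default_dataset.expression
    libs = np.asarray(default_dataset.config.rna_library_sizes, dtype=float)
    glen = expr.gene_lengths[expr.fpkm.index].to_numpy(dtype=float)
    for c, col in enumerate(expr.fpkm.columns):
        expected = 1e9 * expr.counts[col].to_numpy() / (glen * libs[c])
        assert np.allclose(expr.fpkm[col].to_numpy(), expected)


def test_strong_coupling_orders_expression_by_promoter_acr_count(default_dataset):
    ds = default_dataset
    prom_count = {}
    for pp in ds.truth.planted_peaks.values():
        if pp.category == "promoter" and pp.host_gene:
            prom_count[pp.host_gene] = prom_count.get(pp.host_gene, 0) + 1
    fpkm = ds.expression.fpkm.mean(axis=1)
    unpatterned = [g for g in fpkm.index
                   if g not in ds.truth.gene_clusters
                   and g not in ds.truth.discordant_genes]
    med = {k: fpkm[[g for g in unpatterned if prom_count.get(g, 0) == k]].median()
           for k in (0, 1, 2)}
    assert med[2] > med[1] > med[0]


def test_zero_coupling_gives_no_acr_count_association():
    from leafatac.stats import rank_test

    hits = 0
    for seed in range(8):
        # a clean null: coupling, archetype planting and stage-specific
        # archetype coupling all off
        cfg = small_config(seed=seed, expression_coupling=0.0,
                           n_patterned_genes=0, n_discordant=0,
                           specific_cluster_coupling=0.0)
        ds = generate_dataset(cfg)
        prom = {}
        for pp in ds.truth.planted_peaks.values():
            if pp.category == "promoter" and pp.host_gene:
                prom[pp.host_gene] = prom.get(pp.host_gene, 0) + 1
        fpkm = ds.expression.fpkm.mean(axis=1)
        with0 = fpkm[[g for g in fpkm.index if prom.get(g, 0) == 0 and fpkm[g] > 0]]
        with1 = fpkm[[g for g in fpkm.index if prom.get(g, 0) >= 1 and fpkm[g] > 0]]
        if rank_test(with0.to_numpy(), with1.to_numpy()) < 0.05:
            hits += 1
    assert hits <= 2  # null: ~5% expected, allow slack at 8 seeds


def test_discordant_gene_construction(default_dataset):
    ds = default_dataset
    truth = ds.truth
    assert len(truth.discordant_genes) == ds.config.n_discordant
    lmean = truth.expression_log2_mean
    for g in truth.discordant_genes:
        pids = [pid for pid, pp in truth.planted_peaks.items()
                if pp.host_gene == g and pp.category == "promoter"
                and pid in truth.dpi_effects]
        assert pids
        eff = truth.dpi_effects[pids[0]]
        j = list(STAGES).index(eff["stage"])
        others = [k for k in range(3) if k != j]
        de = lmean.loc[g].iloc[j] - lmean.loc[g].iloc[others].mean()
        # accessibility trend and expression trend have opposite signs
        assert np.sign(de) == -np.sign(eff["log2fc"])


# ---------------------------------------------------- fragments / sequences

def test_fragment_counts_and_bounds(default_dataset):
    ds = default_dataset
    sizes = ds.annotation.chrom_sizes
    frags = ds.fragments["BBCH_11_rep1"]
    assert len(frags) >= 0.95 * ds.config.n_fragments_per_sample
    for chrom, s, e in frags[:2000]:
        assert 0 <= s < e <= sizes[chrom]


def test_motifs_planted_at_recorded_positions(default_dataset):
    from leafatac.integration import scan_motif

    ds = default_dataset
    assert ds.truth.motif_placements
    for gene, places in ds.truth.motif_placements.items():
        for rec in places:
            seq = ds.sequences[rec["chrom"]][
                rec["position"]:rec["position"] + len(rec["motif"])]
            assert scan_motif(seq, rec["motif"])


# ------------------------------------------------------------ full dataset

def test_dataset_files_round_trip(tmp_path, default_dataset):
    from leafatac.intervals import read_peaks

    paths = write_dataset(default_dataset, tmp_path)
    back = read_peaks(paths["peaks_BBCH_11_rep1"], fmt="narrowPeak")
    assert len(back) == len(default_dataset.peaks[("BBCH_11", 1)])
    ann = read_annotation(paths["gff3"], paths["chrom_sizes"])
    assert len(ann.genes) == len(default_dataset.annotation.genes)
    counts = pd.read_csv(paths["atac_counts"], sep="\t", index_col=0)
    assert counts.equals(default_dataset.atac_counts.counts)


def test_dataset_generation_is_seed_deterministic(tmp_path):
    import hashlib

    cfg = small_config()
    digests = []
    for run in (1, 2):
        out = tmp_path / f"run{run}"
        paths = write_dataset(generate_dataset(cfg), out)
        h = hashlib.sha256()
        for key in sorted(paths):
            h.update(paths[key].read_bytes())
        digests.append(h.hexdigest())
    assert digests[0] == digests[1]
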