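#!/usr/bin/env python
"""Generate the default synthetic dataset and write every artifact to disk.

Produces, under results/data/: the miniature genome (GFF3 + chrom.sizes +
FASTA), per-stage/replicate peak calls (narrowPeak + BED), Tn5 count and
FPKM/exon-count tables, per-sample fragment BEDs, and the planted-truth JSON.
Later analysis scripts regenerate the same dataset from the seed instead of
re-reading these files, so this script is about inspectability, not wiring.
"""

import sys
from pathlib import Path

from leafatac.simulate import SimConfig, generate_dataset, write_dataset

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    cfg = SimConfig(seed=SEED)
    ds = generate_dataset(cfg)
    outdir = Path("results/data")
    paths = write_dataset(ds, outdir)
    n_spec = sum(cfg.n_specific_peaks_per_stage)
    print(f"genome: {cfg.n_chromosomes} chromosomes, "
          f"{sum(cfg.chromosome_lengths):,} bp, {len(ds.annotation.genes)} genes")
    print(f"planted ACRs: {cfg.n_shared_peaks} shared + {n_spec} stage-specific; "
          f"{len(ds.truth.dpi_effects)} with differential intensity")
    print(f"expression: {len(ds.truth.gene_clusters)} archetype genes, "
          f"{len(ds.truth.discordant_genes)} discordant, "
          f"motifs planted in {len(ds.truth.motif_placements)} promoters")
    print(f"wrote {len(paths)} files to {outdir}/")


if __name__ == "__main__":
    main()
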