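#!/usr/bin/env python
"""ACR landscape: consolidation, specificity, feature enrichment, density.

Consolidates replicate peak calls into per-stage representative ACR sets,
partitions the tri-stage union into common / partial / stage-specific ACRs,
summarises feature-category placement (with a 2000-permutation random-region
null), and relates per-chromosome ACR counts to chromosome length.

Writes results/landscape/*.tsv and stage-specific/common BED files.
"""

import sys
from pathlib import Path

import pandas as pd

from leafatac import landscape
from leafatac.intervals import feature_proportions, write_bed
from leafatac.simulate import STAGES, SimConfig, generate_dataset

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    ds = generate_dataset(SimConfig(seed=SEED))
    out = Path("results/landscape")
    out.mkdir(parents=True, exist_ok=True)

    stage_sets = {
        s: landscape.consolidate_replicates(ds.peaks[(s, 1)], ds.peaks[(s, 2)],
                                            stage=s)
        for s in STAGES
    }
    for s in STAGES:
        n = len(stage_sets[s].peaks)
        frac = landscape.genome_fraction(stage_sets[s].peaks,
                                         ds.annotation.chrom_sizes)
        print(f"{s}: {n} consolidated ACRs covering "
              f"{100 * frac:.2f}% of the genome")

    part = landscape.classify_specificity(stage_sets)
    sizes = part.sizes()
    print("specificity partition:", sizes)
    for s in STAGES:
        write_bed(part.specific[s], out / f"specific_{s}.bed")
    write_bed(part.common, out / "common.bed")

    rows = []
    for s in STAGES:
        props = feature_proportions(stage_sets[s].peaks, ds.annotation)
        props["stage"] = s
        rows.append(props.reset_index())
    pd.concat(rows).to_csv(out / "feature_proportions.tsv", sep="\t",
                           index=False, float_format="%.4g")

    enr = landscape.permutation_enrichment(stage_sets[STAGES[0]].peaks,
                                           ds.annotation,
                                           n_permutations=2000, seed=SEED)
    enr.table.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.4g")
    print("fold enrichment vs random placement "
          f"({enr.n_permutations} permutations):")
    print(enr.table[["observed", "expected_mean", "fold", "p_enrich"]]
          .round(3).to_string())

    corr_rows = []
    for s in STAGES:
        table, r, r2 = landscape.chromosome_correlation(
            stage_sets[s].peaks, ds.annotation.chrom_sizes)
        corr_rows.append({"stage": s, "r": r, "r2": r2})
    corr = pd.DataFrame(corr_rows)
    corr.to_csv(out / "chromosome_density.tsv", sep="\t", index=False,
                float_format="%.4g")
    print("ACR count vs chromosome length r^2 per stage:",
          corr.set_index("stage")["r2"].round(3).to_dict())


if __name__ == "__main__":
    main()
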