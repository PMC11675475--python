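#!/usr/bin/env python
"""Promoter-ACR / expression coupling: counts, lengths, expression bins.

Assigns consolidated ACRs to promoter windows, then reproduces the coupling
analyses: expression by promoter-ACR count {0,1,2,3+}, length tertiles of
single-ACR genes (tie-balanced), and the six-expression-bin association
table (promoter / gene body / both / none).

Writes results/linkage/*.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from leafatac import landscape, linkage
from leafatac.simulate import STAGES, SimConfig, generate_dataset

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    ds = generate_dataset(SimConfig(seed=SEED))
    out = Path("results/linkage")
    out.mkdir(parents=True, exist_ok=True)

    stage_sets = {
        s: landscape.consolidate_replicates(ds.peaks[(s, 1)], ds.peaks[(s, 2)],
                                            stage=s)
        for s in STAGES
    }
    part = landscape.classify_specificity(stage_sets)
    merged = sorted(
        part.common + part.partial
        + [p for s in STAGES for p in part.specific[s]],
        key=lambda p: (p.chrom, p.start, p.end, p.peak_id))
    asn = linkage.assign_promoter_acrs(merged, ds.annotation)
    n_assigned = len(asn.genes_with_acr())
    n_single = len(asn.single_acr_genes())
    print(f"{n_assigned} genes carry a promoter ACR; "
          f"{100 * n_single / n_assigned:.1f}% of them exactly one")

    fpkm = ds.expression.fpkm.median(axis=1)  # robust per-gene summary
    comp = linkage.expression_by_acr_count(asn, fpkm)
    table = pd.DataFrame({
        "n_genes": {k: len(v) for k, v in comp.groups.items()},
        "median_fpkm": comp.medians,
    })
    table.to_csv(out / "expression_by_acr_count.tsv", sep="\t",
                 float_format="%.4g")
    print("median FPKM by promoter ACR count:",
          {k: round(v, 1) for k, v in comp.medians.items()})
    print("adjacent-group rank-sum p:",
          {f"{a}v{b}": f"{p:.2g}" for (a, b), p in comp.pairwise_p.items()})

    groups, tert = linkage.length_tertiles(asn, fpkm)
    print("length tertiles (single-ACR genes): medians",
          {k: round(v, 1) for k, v in tert.medians.items()},
          "top-vs-bottom p =",
          f"{tert.pairwise_p[('top', 'bottom')]:.2g}")
    pd.DataFrame({
        "n_genes": {k: len(v) for k, v in groups.items()},
        "median_fpkm": tert.medians,
    }).to_csv(out / "length_tertiles.tsv", sep="\t", float_format="%.4g")

    bins = linkage.acr_association_by_expression_bin(
        merged, ds.annotation, ds.expression.fpkm.mean(axis=1), asn)
    bins.to_csv(out / "association_by_expression_bin.tsv", sep="\t",
                float_format="%.4g")
    print("ACR association by expression bin (rows sum to 1):")
    print(bins.round(3).to_string())


if __name__ == "__main__":
    main()
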