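#!/usr/bin/env python
"""Genes whose expression tracks distance to the stroma niche.

Uses the niche labels from 02_deconvolve_niches.py, computes each
non-stroma spot's mean distance to the stroma spots, and reports the
Spearman correlation per gene, the binned-distance comparison for the
strongest decreasing gene, and its nonzero-expression prevalence.
"""

import argparse
from pathlib import Path

import pandas as pd

from stniche.io import load_tenx, log_normalize
from stniche.niches import NicheLabels
from stniche.stgradient import binned_comparison, gradient_test, nonzero_prevalence


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("scratch/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--reference", default="stroma")
    ap.add_argument("--bin-width-um", type=float, default=500.0)
    args = ap.parse_args()

    dataset = log_normalize(load_tenx(args.data))
    labels = NicheLabels(pd.read_csv(args.out / "niche_labels.tsv", sep="\t", index_col=0))

    table = gradient_test(dataset, labels, args.reference)
    table = table.sort_values("rho")
    table.to_csv(args.out / "stgradient.tsv", sep="\t", index=False)
    print("strongest gradients (negative rho = decays away from "
          f"{args.reference}):")
    print(table.head(8).to_string(index=False))

    top_gene = table.iloc[0]["gene"]
    bc = binned_comparison(
        dataset, labels, args.reference, top_gene, bin_width_um=args.bin_width_um
    )
    binned = pd.DataFrame(
        {
            "bin_start_um": bc.bin_edges[:-1],
            "bin_end_um": bc.bin_edges[1:],
            "median_lognorm": bc.bin_medians,
            "n_spots": bc.bin_counts,
        }
    )
    binned.to_csv(args.out / f"binned_{top_gene}.tsv", sep="\t", index=False)
    print(f"\n{top_gene} by distance bin:")
    print(binned.to_string(index=False))
    print(bc.comparisons.to_string(index=False))
    print(f"\n{top_gene} nonzero prevalence: "
          f"{nonzero_prevalence(dataset, top_gene):.3f}")


if __name__ == "__main__":
    main()
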