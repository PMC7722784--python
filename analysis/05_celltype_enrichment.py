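#!/usr/bin/env python
"""Cell-type assignment and cluster enrichment on the toy atlas.

Assigns genes to cell types by the mean-FPKM ratio criterion
(mu_type / sum(mu_others) > 2.5, progenitor categories excluded),
verifies the planted markers are recovered, and scores a planted
microglia-biased gene cluster for cell-type enrichment by hypergeometric
log-odds.
"""

import argparse
import json
from pathlib import Path

from phosflow.celltype import assign_celltypes, celltype_loe
from phosflow.io import read_celltype_atlas


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    columns = json.loads((args.data / "atlas_columns.json").read_text())
    atlas = read_celltype_atlas(args.data / "atlas.tsv", columns)
    assignment = assign_celltypes(atlas)
    ledger = json.loads((args.data / "atlas_ledger.json").read_text())
    markers = ledger["assignable_markers"]
    hits = sum(assignment.get(g) == t for g, t in markers.items())
    print(f"marker recovery: {hits}/{len(markers)} planted markers "
          f"assigned; {len(assignment.assignments)} genes assigned total")

    # cluster enrichment demonstrated on a planted "up" cluster drawn with
    # 3x odds toward microglial genes from the quantified-gene background
    import numpy as np
    rng = np.random.default_rng(args.seed)
    background = sorted(markers)
    weights = np.array([3.0 if markers[g] == "Microglia" else 1.0
                        for g in background])
    cluster = list(rng.choice(background, 30, replace=False,
                              p=weights / weights.sum()))
    frame = celltype_loe(cluster, background, assignment)
    frame["cluster"] = "up"
    top = frame["loe"].idxmax()
    print(f"planted microglia-biased cluster ({len(cluster)} genes): "
          f"top cell type {top} (LOE {frame.loc[top, 'loe']:.2f})")
    frame.to_csv(args.out / "celltype_loe.tsv", sep="\t")


if __name__ == "__main__":
    main()
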