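#!/usr/bin/env python
"""Generate the synthetic TMT phosphoproteomics experiment.

Writes a 10-plex PSM table (500 peptides, two genotype groups, spiked 2x
up- and 0.5x down-regulation, duplicate PSMs with isolation interference,
planted quality-gate failures), a kinase-substrate set collection with one
activated kinase, foreground/background motif windows with a planted +1
proline enrichment, and a toy cell-type atlas — each with its ground-truth
ledger — under results/data/.
"""

import argparse
import json
from pathlib import Path

from phosflow.io import write_gmt, write_psm_table
from phosflow.simulate import (
    SimConfig,
    simulate_celltype_atlas,
    simulate_kinase_scores,
    simulate_motif_sites,
    simulate_psm_table,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    config = SimConfig(seed=args.seed)

    records, channel_map, ledger = simulate_psm_table(config)
    write_psm_table(records, args.out / "psm.tsv")
    (args.out / "psm_ledger.json").write_text(json.dumps(ledger, indent=2))
    (args.out / "channels.json").write_text(json.dumps(
        {"labels": list(channel_map.channel_labels),
         "groups": list(channel_map.group_ids)}, indent=2))
    print(f"PSM table: {len(records)} PSMs, plex {channel_map.plex_size}, "
          f"{len(ledger['spiked_rows'])} spiked peptides")

    scores, sets, kin_ledger = simulate_kinase_scores(config)
    write_gmt(sets, args.out / "kinase_sets.gmt")
    with open(args.out / "site_scores.tsv", "w") as fh:
        fh.write("site\tscore\n")
        for site, value in sorted(scores.items()):
            fh.write(f"{site}\t{float(value)!r}\n")
    (args.out / "kinase_ledger.json").write_text(
        json.dumps(kin_ledger, indent=2))
    print(f"kinase sets: {len(sets)} sets; planted shift "
          f"{kin_ledger['plant']['shift']} on {kin_ledger['plant']['size']} "
          "sites")

    fg, bg, motif_ledger = simulate_motif_sites(config)
    (args.out / "motif_foreground.txt").write_text("\n".join(fg) + "\n")
    (args.out / "motif_background.txt").write_text("\n".join(bg) + "\n")
    (args.out / "motif_ledger.json").write_text(
        json.dumps(motif_ledger, indent=2))
    print(f"motif windows: {len(fg)} foreground / {len(bg)} background; "
          f"plant {motif_ledger['plant']}")

    atlas, atlas_ledger = simulate_celltype_atlas(config)
    atlas.values.to_csv(args.out / "atlas.tsv", sep="\t")
    (args.out / "atlas_columns.json").write_text(
        json.dumps(atlas.cell_type_columns, indent=2))
    (args.out / "atlas_ledger.json").write_text(
        json.dumps(atlas_ledger, indent=2))
    print(f"atlas: {atlas.values.shape[0]} genes x "
          f"{atlas.values.shape[1]} columns")


if __name__ == "__main__":
    main()
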