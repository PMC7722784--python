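#!/usr/bin/env python
"""Differential phosphopeptide statistics for the genotype contrast.

Computes per-peptide fold changes (disease over control, ratio of
normalized group means) with two-sided Student's t-tests, classifies
regulation (up: FC > 1.25 & p < 1e-2; down: FC < 0.8 & p < 1e-2), and
compares the recovered fold changes of the spiked peptides against the
generator ledger.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from phosflow.differential import classify_regulation, fold_change_and_test, \
    stats_to_frame
from phosflow.io import ChannelMap, read_quant_matrix


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    matrix = read_quant_matrix(args.out / "matrix.tsv")
    channels = json.loads((args.data / "channels.json").read_text())
    matrix.channel_map = ChannelMap(
        tuple(channels["labels"]), tuple(channels["labels"]),
        tuple(channels["groups"]))

    stats = fold_change_and_test(matrix, ("disease", "control"))
    parts = classify_regulation(stats)
    print("regulation: " + ", ".join(f"{len(v)} {k}"
                                     for k, v in parts.items()))

    ledger = json.loads((args.data / "psm_ledger.json").read_text())
    by_key = {s.row_key: s for s in stats if s.valid}
    for direction, pick in (("up", lambda fc: fc > 1),
                            ("down", lambda fc: fc < 1)):
        spiked = [by_key[k].fold_change
                  for k, fc in ledger["spiked_rows"].items()
                  if pick(fc) and k in by_key]
        planted = next(fc for fc in ledger["spiked_rows"].values()
                       if pick(fc))
        print(f"spiked {direction} peptides: mean recovered FC "
              f"{np.mean(spiked):.3f} (planted {planted}, "
              f"n={len(spiked)})")

    stats_to_frame(stats).to_csv(args.out / "stats.tsv", sep="\t",
                                 index=False)


if __name__ == "__main__":
    main()
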