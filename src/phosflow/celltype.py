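"""Cell-type assignment from an expression atlas and cluster enrichment.

A gene is called enriched in a cell type when its mean FPKM there exceeds
2.5x the summed means of the other displayed cell types
(mu_type / sum_{i != type} mu_i > 2.5, strict). Progenitor categories
(OPC, newly formed oligodendrocytes) are excluded from both candidacy and
denominators so pan-oligodendrocyte genes are not discarded; the displayed
"Oligodendrocyte" category is the myelinating columns only.

Up- and down-regulated peptide clusters (mapped to unique genes) are then
scored per cell type by the same signed hypergeometric log-odds used for
motif logos, against the background of all quantified genes.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from phosflow._hypergeom import log_odds_enrichment
from phosflow.io import CellTypeAtlas

DEFAULT_EXCLUDED_TYPES = ("OPC", "New Oligodendrocytes")
DEFAULT_RATIO_THRESHOLD = 2.5


@dataclasses.dataclass
class CellTypeAssignment:
    """gene -> cell type map derived from the atlas ratio criterion."""

    assignments: dict[str, str]
    ratios: dict[str, float]
    excluded_types: tuple[str, ...]

    def get(self, gene: str) -> str | None:
        return self.assignments.get(gene)

    @property
    def assigned_genes(self) -> set[str]:
        return set(self.assignments)


def assign_celltypes(
    atlas: CellTypeAtlas,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    excluded_types: Iterable[str] = DEFAULT_EXCLUDED_TYPES,
) -> CellTypeAssignment:
    """Assign each gene to at most one enriched cell type.

    For every candidate type, mu_type is the mean of the type's atlas
    columns and the criterion is mu_type / sum(mu of other candidate
    types) > ratio_threshold (strict). Excluded types never appear as
    candidates nor in denominators. A gene expressed in exactly one
    candidate type (zero denominator, positive numerator) qualifies; an
    all-zero gene is unassigned. If several types qualify the largest
    ratio wins, with ties left unassigned.
    """
    excluded = tuple(excluded_types)
    means = atlas.type_means()
    candidates = [t for t in means.columns if t not in excluded]
    if len(candidates) < 2:
        raise ValueError("need at least two candidate cell types")
    mu = means[candidates]
    total = mu.sum(axis=1)

    assignments: dict[str, str] = {}
    ratios: dict[str, float] = {}
    for gene, row in mu.iterrows():
        best_type, best_ratio, tie = None, -np.inf, False
        for t in candidates:
            other = total[gene] - row[t]
            if other > 0:
                ratio = row[t] / other
            elif row[t] > 0:
                ratio = np.inf
            else:
                continue  # all-zero gene contributes no candidate
            if ratio > best_ratio:
                best_type, best_ratio, tie = t, ratio, False
            elif ratio == best_ratio:
                tie = True
        if best_type is not None and not tie and best_ratio > ratio_threshold:
            assignments[str(gene)] = best_type
            ratios[str(gene)] = float(best_ratio)
    return CellTypeAssignment(assignments, ratios, excluded)


def celltype_loe(
    cluster: Iterable[str],
    background: Iterable[str],
    assignment: CellTypeAssignment,
) -> pd.DataFrame:
    """Signed hypergeometric log-odds per cell type for a gene cluster.

    ``cluster`` (e.g. genes of up-regulated peptides mapping to a single
    protein) must be a subset of ``background`` (all genes with at least
    one quantified PSM). Genes without a cell-type assignment are dropped
    from both numerators and totals. Returns a frame with columns
    k, K, n, N and loe per cell type; an empty assigned cluster yields
    all-zero LOE with a warning.
    """
    cluster = set(cluster)
    background = set(background)
    if not cluster <= background:
        raise ValueError("cluster must be a subset of the background")

    assigned_bg = {g: assignment.get(g) for g in background
                   if assignment.get(g) is not None}
    assigned_fg = {g: t for g, t in assigned_bg.items() if g in cluster}
    n, N = len(assigned_fg), len(assigned_bg)
    types = sorted({t for t in assignment.assignments.values()})

    rows = []
    if n == 0:
        warnings.warn("cluster contains no assigned genes; LOE is zero",
                      RuntimeWarning)
    for t in types:
        K = sum(1 for v in assigned_bg.values() if v == t)
        k = sum(1 for v in assigned_fg.values() if v == t)
        loe = log_odds_enrichment(k, K, n, N) if n > 0 else 0.0
        rows.append({"cell_type": t, "k": k, "K": K, "n": n, "N": N,
                     "loe": loe})
    return pd.DataFrame(rows).set_index("cell_type")
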