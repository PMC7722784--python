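"""Synthetic data generator for every stage of the pipeline.

Emulates the statistical structure of a multiplexed TMT phosphoproteomics
experiment at desk scale: positive reporter intensities with per-channel
loading biases and multiplicative log-normal measurement noise, duplicate
PSMs with isolation interference, quality fields with controllable failure
fractions for each filter criterion, spiked group fold changes, planted
sequence-motif enrichment, planted kinase-substrate activation, and a toy
cell-type expression atlas. Every planted truth is recorded in a ledger
returned alongside the data, so recovery tests never re-derive truth from
the outputs. Identical configurations (including the seed) reproduce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np

from phosflow.io import CellTypeAtlas, ChannelMap, PhosphoSetCollection, \
    PSMRecord
from phosflow.qcnorm import FilterThresholds

AA_FLANK = tuple("ACDEFGHIKLMNPQRSTVW")  # flank alphabet for peptides


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults model a single TMT-10 plex of 500 phosphopeptides, two
    balanced genotype groups, 10% measurement CV, spiked 2x up- and
    0.5x down-regulation on 5% of peptides each, and small fractions of
    PSMs planted to fail each quality gate.
    """

    seed: int = 0
    n_peptides: int = 500
    plex_size: int = 10
    n_disease_channels: int = 5
    channel_scale_factors: tuple[float, ...] | None = None
    noise_cv: float = 0.1
    spikes: tuple[tuple[int, float], ...] = ((25, 2.0), (25, 0.5))
    duplicate_rate: float = 0.2
    frac_fail_ion_score: float = 0.05
    frac_fail_interference: float = 0.05
    frac_fail_fdr: float = 0.05
    frac_transgenic: float = 0.02
    baseline_log10_range: tuple[float, float] = (3.0, 7.0)
    # motif simulation
    motif_n_foreground: int = 500
    motif_n_background: int = 5000
    motif_plant: tuple[int, str, float] | None = (1, "P", 4.0)
    # kinase / PSEA simulation
    kinase_n_sites: int = 500
    kinase_plant: tuple[int, float] | None = (40, 1.5)
    kinase_n_null_sets: int = 50
    kinase_null_set_size: int = 30
    # atlas simulation
    atlas_markers_per_type: int = 20
    atlas_n_housekeeping: int = 100
    atlas_marker_high: float = 100.0
    atlas_marker_low: float = 1.0

    def __post_init__(self) -> None:
        if self.plex_size < 4:
            raise ValueError("plex_size must be >= 4")
        if not 0 < self.n_disease_channels < self.plex_size:
            raise ValueError("need at least one channel per group")
        total_spiked = sum(c for c, _ in self.spikes)
        if total_spiked > self.n_peptides:
            raise ValueError("more spiked rows than peptides")
        for _, fc in self.spikes:
            if fc <= 0:
                raise ValueError("spiked fold changes must be positive")


def _group_ids(config: SimConfig) -> tuple[str, ...]:
    return tuple("disease" if i < config.n_disease_channels else "control"
                 for i in range(config.plex_size))


def _random_peptide(rng: np.random.Generator) -> tuple[str, int]:
    """Random tryptic-like peptide and the 1-based offset of its S/T/Y."""
    length = int(rng.integers(7, 16))
    chars = [AA_FLANK[i] for i in rng.integers(0, len(AA_FLANK), length)]
    site_pos = int(rng.integers(1, length))  # keep off the C-terminal K/R
    chars[site_pos - 1] = "STY"[int(rng.integers(0, 3))]
    chars[-1] = "KR"[int(rng.integers(0, 2))]
    return "".join(chars), site_pos


def simulate_psm_table(config: SimConfig
                       ) -> tuple[list[PSMRecord], ChannelMap, dict]:
    """Generate a PSM table with planted effects and a ground-truth ledger.

    Intensities follow baseline x channel scale x group effect (spiked
    rows only) x log-normal noise. A ``duplicate_rate`` fraction of
    peptides yields two PSMs with independently drawn interference. The
    ledger records channel scales, spiked fold changes per row key,
    expected retention per scan, and per-criterion planted failures.
    """
    rng = np.random.default_rng(config.seed)
    groups = _group_ids(config)
    scales = np.asarray(config.channel_scale_factors, dtype=float) \
        if config.channel_scale_factors is not None \
        else rng.uniform(0.5, 2.0, config.plex_size)
    if scales.size != config.plex_size:
        raise ValueError("channel_scale_factors length must equal plex_size")
    channel_map = ChannelMap(
        tuple(f"TMT_{i + 1}" for i in range(config.plex_size)),
        tuple(f"sample_{i + 1}" for i in range(config.plex_size)),
        groups,
    )
    disease_mask = np.array([g == "disease" for g in groups])

    # assign spiked fold changes to distinct peptides
    spiked_fc = np.ones(config.n_peptides)
    cursor = 0
    for count, fc in config.spikes:
        spiked_fc[cursor:cursor + count] = fc
        cursor += count

    sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2)) \
        if config.noise_cv > 0 else 0.0
    lo, hi = config.baseline_log10_range

    records: list[PSMRecord] = []
    ledger_rows: dict[str, dict] = {}
    per_criterion = {"ion_score": 0, "isolation_interference": 0,
                     "median_tmt": 0, "percolator_fdr": 0}
    expected_retained: list[str] = []
    thresholds = FilterThresholds()
    scan = 0
    seen_peptides: set[str] = set()
    for i in range(config.n_peptides):
        while True:
            sequence, site_pos = _random_peptide(rng)
            if sequence not in seen_peptides:
                seen_peptides.add(sequence)
                break
        residue = sequence[site_pos - 1]
        baseline = 10.0 ** rng.uniform(lo, hi)
        n_psms = 2 if rng.random() < config.duplicate_rate else 1
        gene = f"GENE{i}"
        row_key = None
        for _ in range(n_psms):
            scan += 1
            noise = np.exp(rng.normal(0.0, sigma, config.plex_size)) \
                if sigma > 0 else np.ones(config.plex_size)
            effect = np.where(disease_mask, spiked_fc[i], 1.0)
            intensities = baseline * scales * effect * noise

            fail_ion = rng.random() < config.frac_fail_ion_score
            ion_score = float(rng.uniform(1.0, 14.0)) if fail_ion \
                else float(rng.uniform(20.0, 80.0))
            fail_intf = rng.random() < config.frac_fail_interference
            interference = float(rng.uniform(31.0, 90.0)) if fail_intf \
                else float(rng.uniform(0.0, 25.0))
            transgenic = rng.random() < config.frac_transgenic
            fail_fdr = rng.random() < config.frac_fail_fdr
            fdr = float(10.0 ** rng.uniform(-1.9, -0.3)) if fail_fdr \
                else float(10.0 ** rng.uniform(-6.0, -2.1))

            rec = PSMRecord(
                scan_id=f"scan_{scan}",
                sequence=sequence,
                proteins=(f"P{i:05d}",),
                gene_symbols=(gene,),
                phospho_positions=((residue, site_pos,
                                    float(rng.uniform(0.8, 1.0))),),
                ion_score=ion_score,
                isolation_interference=interference,
                percolator_fdr=fdr,
                tmt_intensities=intensities,
                is_transgenic=transgenic,
            )
            records.append(rec)
            row_key = rec.row_key
            checks = (
                ("ion_score", ion_score > thresholds.min_ion_score),
                ("isolation_interference",
                 interference < thresholds.max_isolation_interference),
                ("median_tmt",
                 float(np.median(intensities)) > thresholds.min_median_tmt),
                ("percolator_fdr",
                 transgenic or fdr < thresholds.max_percolator_fdr),
            )
            first_fail = next((nm for nm, ok in checks if not ok), None)
            if first_fail is None:
                expected_retained.append(rec.scan_id)
            else:
                per_criterion[first_fail] += 1
        ledger_rows[row_key] = {
            "gene": gene, "fold_change": float(spiked_fc[i]),
            "baseline": baseline, "n_psms": n_psms,
        }

    ledger = {
        "seed": config.seed,
        "channel_scale_factors": [float(s) for s in scales],
        "groups": list(groups),
        "rows": ledger_rows,
        "spiked_rows": {k: v["fold_change"] for k, v in ledger_rows.items()
                        if v["fold_change"] != 1.0},
        "expected_retained_scan_ids": expected_retained,
        "per_criterion_failures": per_criterion,
    }
    return records, channel_map, ledger


def _draw_nmers(rng: np.random.Generator, n: int,
                freqs: Mapping[int, np.ndarray],
                alphabet: Sequence[str]) -> list[str]:
    out = []
    for _ in range(n):
        chars = []
        for off in range(-7, 8):
            if off == 0:
                chars.append("s")
            else:
                p = freqs[off]
                chars.append(alphabet[int(rng.choice(len(alphabet), p=p))])
        out.append("".join(chars))
    return out


def simulate_motif_sites(config: SimConfig
                         ) -> tuple[list[str], list[str], dict]:
    """Foreground and background 15-mer collections with a planted motif.

    Background windows draw flank residues i.i.d. from a uniform base
    composition; foreground windows boost the planted residue's frequency
    at the planted position by the configured multiplier. The returned
    background is the full universe (background + foreground windows), so
    the foreground is a subset of it as pLogo's model assumes.
    """
    rng = np.random.default_rng(config.seed + 1)
    alphabet = tuple("ACDEFGHIKLMNPQRSTVWY")
    base = np.full(len(alphabet), 1.0 / len(alphabet))
    bg_freqs = {off: base for off in range(-7, 8) if off != 0}

    fg_freqs = dict(bg_freqs)
    if config.motif_plant is not None:
        pos, residue, multiplier = config.motif_plant
        if pos == 0 or not -7 <= pos <= 7:
            raise ValueError("planted position must be in -7..7, nonzero")
        idx = alphabet.index(residue.upper())
        boosted = base.copy()
        boosted[idx] *= multiplier
        if boosted[idx] > 1.0:
            raise ValueError("multiplier pushes a frequency above 1")
        boosted[np.arange(len(alphabet)) != idx] *= \
            (1.0 - boosted[idx]) / (1.0 - base[idx])
        fg_freqs[pos] = boosted

    foreground = _draw_nmers(rng, config.motif_n_foreground, fg_freqs,
                             alphabet)
    background_only = _draw_nmers(rng, config.motif_n_background, bg_freqs,
                                  alphabet)
    background = background_only + foreground
    ledger = {
        "plant": {"position": config.motif_plant[0],
                  "residue": config.motif_plant[1].upper(),
                  "multiplier": config.motif_plant[2]}
        if config.motif_plant is not None else "none",
        "n_foreground": len(foreground),
        "n_background": len(background),
    }
    return foreground, background, ledger


def simulate_kinase_scores(config: SimConfig
                           ) -> tuple[dict[str, float],
                                      PhosphoSetCollection, dict]:
    """Site scores with one optionally activated kinase-substrate set.

    Null sites score i.i.d. standard normal; members of the planted set
    are shifted by the configured amount. Null sets are random draws of
    ``kinase_null_set_size`` sites.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = config.kinase_n_sites
    site_ids = [f"GENE{i}:S{10 + i}" for i in range(n)]
    scores = rng.normal(0.0, 1.0, n)

    sets: dict[str, frozenset[str]] = {}
    planted_members: list[str] = []
    if config.kinase_plant is not None:
        size, shift = config.kinase_plant
        if size > n:
            raise ValueError("planted set larger than the site universe")
        members = rng.choice(n, size=size, replace=False)
        scores[members] += shift
        planted_members = [site_ids[i] for i in members]
        sets["PLANTED_KINASE"] = frozenset(planted_members)
    for j in range(config.kinase_n_null_sets):
        members = rng.choice(n, size=config.kinase_null_set_size,
                             replace=False)
        sets[f"NULL_KINASE_{j}"] = frozenset(site_ids[i] for i in members)

    ledger = {
        "plant": {"set": "PLANTED_KINASE", "size": config.kinase_plant[0],
                  "shift": config.kinase_plant[1],
                  "members": sorted(planted_members)}
        if config.kinase_plant is not None else "none",
        "n_sites": n,
    }
    return dict(zip(site_ids, scores)), PhosphoSetCollection(sets), ledger


DEFAULT_ATLAS_TYPES = (
    "Astrocyte", "Neuron", "OPC", "New Oligodendrocytes",
    "Myelinating Oligodendrocytes", "Microglia", "Endothelia",
)


def simulate_celltype_atlas(config: SimConfig,
                            cell_types: Sequence[str] = DEFAULT_ATLAS_TYPES
                            ) -> tuple[CellTypeAtlas, dict]:
    """Toy expression atlas with planted marker genes per cell type.

    Marker genes express ``atlas_marker_high`` in their own type's columns
    and ``atlas_marker_low`` elsewhere, exceeding the 2.5 enrichment ratio
    by construction for the default candidate count; housekeeping genes
    are uniform and unassignable.
    """
    import pandas as pd
    if len(cell_types) < 2:
        raise ValueError("need at least two cell types")
    rng = np.random.default_rng(config.seed + 3)
    columns = {ct: [f"{ct} 1", f"{ct} 2"] for ct in cell_types}
    all_cols = [c for cols in columns.values() for c in cols]

    genes, rows = [], []
    markers: dict[str, str] = {}
    for ct in cell_types:
        for m in range(config.atlas_markers_per_type):
            gene = f"{ct.upper().replace(' ', '_')}_MARKER_{m}"
            genes.append(gene)
            markers[gene] = ct
            row = []
            for other in cell_types:
                value = config.atlas_marker_high if other == ct \
                    else config.atlas_marker_low
                row.extend(value * rng.uniform(0.9, 1.1, 2))
            rows.append(row)
    for h in range(config.atlas_n_housekeeping):
        gene = f"HOUSEKEEPING_{h}"
        genes.append(gene)
        markers_level = rng.uniform(4.0, 6.0)
        rows.append(list(markers_level * rng.uniform(0.95, 1.05,
                                                     len(all_cols))))

    atlas = CellTypeAtlas(
        values=pd.DataFrame(rows, index=pd.Index(genes, name="Gene"),
                            columns=all_cols),
        cell_type_columns=columns,
    )
    from phosflow.celltype import DEFAULT_EXCLUDED_TYPES
    ledger = {
        "markers": markers,
        # markers of progenitor types excluded from the enrichment
        # calculation can never be assigned; recovery tests target these
        "assignable_markers": {g: t for g, t in markers.items()
                               if t not in DEFAULT_EXCLUDED_TYPES},
        "housekeeping": [g for g in genes if g.startswith("HOUSE")],
    }
    return atlas, ledger
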