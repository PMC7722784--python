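"""Readers and writers for the pipeline's tabular formats.

The pipeline consumes documented flat TSV dialects rather than proprietary
search-engine databases:

* **PSM table** — one row per peptide-spectrum match with columns
  ``ScanID``, ``Sequence``, ``Proteins`` (semicolon-joined accessions),
  ``Genes``, ``PhosphoSites`` (e.g. ``"S5:0.99;T7:0.60"``: residue,
  1-based peptide offset, localization probability), ``IonScore``,
  ``IsolationInterference`` (percent), ``PercolatorFDR``,
  ``TMT_1..TMT_k`` reporter intensities, and ``Transgenic``.
* **Phosphosite sets** — GMT files, or PhosphoSitePlus-style
  kinase-substrate TSV (``KINASE``/``SUB_GENE``/``SUB_MOD_RSD`` columns).
* **Cell-type atlas** — wide TSV/CSV of gene x expression columns
  (mean FPKM per atlas sample), grouped into cell types by the caller.

Peptide offsets are 1-based, matching the convention of site names such
as "pY561". Parsing never silently drops rows: every input row is either
parsed or reported with its line number.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


_VALID_PHOSPHO_RESIDUES = frozenset("STY")


@dataclasses.dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match with quality metrics and TMT intensities.

    ``phospho_positions`` holds (residue, peptide_offset, localization_prob)
    triples; offsets are 1-based into ``sequence`` and must name an S/T/Y.
    """

    scan_id: str
    sequence: str
    proteins: tuple[str, ...]
    gene_symbols: tuple[str, ...]
    phospho_positions: tuple[tuple[str, int, float], ...]
    ion_score: float
    isolation_interference: float
    percolator_fdr: float
    tmt_intensities: np.ndarray
    is_transgenic: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "tmt_intensities",
            np.asarray(self.tmt_intensities, dtype=float),
        )
        for residue, offset, prob in self.phospho_positions:
            if residue not in _VALID_PHOSPHO_RESIDUES:
                raise ValueError(
                    f"phospho residue {residue!r} not one of S/T/Y"
                )
            if not 1 <= offset <= len(self.sequence):
                raise ValueError(
                    f"site offset {offset} outside peptide of length "
                    f"{len(self.sequence)}"
                )
            if self.sequence[offset - 1] != residue:
                raise ValueError(
                    f"site {residue}{offset} does not match sequence "
                    f"residue {self.sequence[offset - 1]!r}"
                )
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"localization probability {prob} not in [0,1]")

    @property
    def site_key(self) -> str:
        """Canonical localized-site assignment, e.g. ``"S5,T7"``."""
        return ",".join(
            f"{res}{off}" for res, off, _ in
            sorted(self.phospho_positions, key=lambda s: s[1])
        )

    @property
    def row_key(self) -> str:
        """Peptide identity used for duplicate grouping: sequence + sites."""
        return f"{self.sequence}|{self.site_key}"


@dataclasses.dataclass(frozen=True)
class ChannelMap:
    """Ordered TMT channel labels with their sample and group assignments."""

    channel_labels: tuple[str, ...]
    sample_ids: tuple[str, ...]
    group_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.channel_labels) == len(self.sample_ids)
                == len(self.group_ids)):
            raise ValueError("channel_labels, sample_ids and group_ids must "
                             "have equal length")

    @classmethod
    def trivial(cls, n_channels: int,
                group_ids: Sequence[str] | None = None) -> "ChannelMap":
        labels = tuple(f"TMT_{i + 1}" for i in range(n_channels))
        groups = tuple(group_ids) if group_ids is not None \
            else ("all",) * n_channels
        return cls(labels, labels, groups)

    @property
    def plex_size(self) -> int:
        return len(self.channel_labels)

    def channels_for_group(self, group: str) -> np.ndarray:
        idx = np.array([i for i, g in enumerate(self.group_ids) if g == group])
        if idx.size == 0:
            raise KeyError(f"no channels assigned to group {group!r}")
        return idx


@dataclasses.dataclass
class PhosphoSetCollection:
    """Named sets of phosphosite identifiers (``"GENE:residuePosition"``)."""

    sets: dict[str, frozenset[str]]
    n_skipped_rows: int = 0

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclasses.dataclass
class CellTypeAtlas:
    """Gene x column FPKM matrix plus the cell-type -> columns grouping."""

    values: pd.DataFrame
    cell_type_columns: dict[str, list[str]]

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("atlas expression values must be nonnegative")
        for cell_type, cols in self.cell_type_columns.items():
            if not cols:
                raise ValueError(f"cell type {cell_type!r} maps to no columns")
            missing = [c for c in cols if c not in self.values.columns]
            if missing:
                raise FormatError(
                    f"cell type {cell_type!r} references absent column(s) "
                    f"{missing}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def type_means(self) -> pd.DataFrame:
        """Mean FPKM per cell type (columns averaged within each group)."""
        return pd.DataFrame({
            ct: self.values[cols].mean(axis=1)
            for ct, cols in self.cell_type_columns.items()
        })


@dataclasses.dataclass(frozen=True)
class ParseIssue:
    line_number: int
    message: str


@dataclasses.dataclass
class PSMTable:
    """Result of parsing a PSM table: records, channel map, reported rows."""

    records: list[PSMRecord]
    channel_map: ChannelMap
    issues: list[ParseIssue]


@dataclasses.dataclass(frozen=True)
class PSMDialect:
    """Column naming of a flat PSM export."""

    scan_id: str = "ScanID"
    sequence: str = "Sequence"
    proteins: str = "Proteins"
    genes: str = "Genes"
    phospho_sites: str = "PhosphoSites"
    ion_score: str = "IonScore"
    isolation_interference: str = "IsolationInterference"
    percolator_fdr: str = "PercolatorFDR"
    tmt_prefix: str = "TMT_"
    transgenic: str = "Transgenic"
    sep: str = "\t"

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (self.scan_id, self.sequence, self.proteins, self.genes,
                self.phospho_sites, self.ion_score,
                self.isolation_interference, self.percolator_fdr,
                self.transgenic)


DEFAULT_DIALECT = PSMDialect()

_SITE_TOKEN = re.compile(r"^([STY])(\d+):([0-9.eE+-]+)$")


def _parse_sites(token: str) -> tuple[tuple[str, int, float], ...]:
    token = token.strip()
    if not token or token == "-":
        return ()
    sites = []
    for part in token.split(";"):
        m = _SITE_TOKEN.match(part.strip())
        if m is None:
            raise ValueError(f"unparseable phosphosite token {part!r}")
        sites.append((m.group(1), int(m.group(2)), float(m.group(3))))
    return tuple(sites)


def _split_list(token: str) -> tuple[str, ...]:
    token = str(token).strip()
    if not token or token == "-":
        return ()
    return tuple(p.strip() for p in token.split(";") if p.strip())


def read_psm_table(path: str | Path,
                   dialect: PSMDialect = DEFAULT_DIALECT) -> PSMTable:
    """Parse a flat PSM export into records plus an inferred channel map.

    The plex size is inferred from the ``TMT_*`` columns in the header.
    Malformed rows are collected as :class:`ParseIssue` with their 1-based
    file line numbers; they are never silently dropped.
    """
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    missing = [c for c in dialect.required_columns if c not in df.columns]
    if missing:
        raise FormatError(
            f"PSM table {path} is missing required column(s): "
            + ", ".join(missing)
        )
    tmt_cols = [c for c in df.columns if c.startswith(dialect.tmt_prefix)]
    if not tmt_cols:
        raise FormatError(
            f"PSM table {path} has no {dialect.tmt_prefix}* intensity columns"
        )
    tmt_cols.sort(key=lambda c: int(c[len(dialect.tmt_prefix):]))

    records: list[PSMRecord] = []
    issues: list[ParseIssue] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_number = i + 2  # header is line 1
        row = dict(zip(df.columns, row))
        try:
            intensities = np.array(
                [float(row[c]) for c in tmt_cols], dtype=float)
            if not np.isfinite(intensities).all() or (intensities < 0).any():
                raise ValueError("TMT intensities must be finite and >= 0")
            records.append(PSMRecord(
                scan_id=str(row[dialect.scan_id]),
                sequence=str(row[dialect.sequence]).strip().upper(),
                proteins=_split_list(row[dialect.proteins]),
                gene_symbols=_split_list(row[dialect.genes]),
                phospho_positions=_parse_sites(str(row[dialect.phospho_sites])),
                ion_score=float(row[dialect.ion_score]),
                isolation_interference=float(
                    row[dialect.isolation_interference]),
                percolator_fdr=float(row[dialect.percolator_fdr]),
                tmt_intensities=intensities,
                is_transgenic=str(row[dialect.transgenic]).strip().lower()
                in ("1", "true", "yes"),
            ))
        except (ValueError, TypeError) as exc:
            issues.append(ParseIssue(line_number, str(exc)))
    return PSMTable(records, ChannelMap.trivial(len(tmt_cols)), issues)


def write_psm_table(records: Iterable[PSMRecord], path: str | Path,
                    dialect: PSMDialect = DEFAULT_DIALECT) -> None:
    """Serialize PSM records to the flat TSV dialect (lossless round-trip)."""
    rows = []
    plex = None
    for rec in records:
        if plex is None:
            plex = rec.tmt_intensities.size
        elif rec.tmt_intensities.size != plex:
            raise ValueError("all records must share one plex size")
        row = {
            dialect.scan_id: rec.scan_id,
            dialect.sequence: rec.sequence,
            dialect.proteins: ";".join(rec.proteins),
            dialect.genes: ";".join(rec.gene_symbols),
            dialect.phospho_sites: ";".join(
                f"{r}{o}:{p!r}" for r, o, p in rec.phospho_positions),
            dialect.ion_score: repr(rec.ion_score),
            dialect.isolation_interference: repr(rec.isolation_interference),
            dialect.percolator_fdr: repr(rec.percolator_fdr),
            dialect.transgenic: int(rec.is_transgenic),
        }
        for i, v in enumerate(rec.tmt_intensities):
            row[f"{dialect.tmt_prefix}{i + 1}"] = repr(float(v))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=dialect.sep, index=False)


def read_gmt(path: str | Path) -> PhosphoSetCollection:
    """Read a GMT file (set name, description, members, tab-separated)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line has fewer than 3 fields: {line!r}")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if members:
                sets[name] = frozenset(members)
    return PhosphoSetCollection(sets)


def write_gmt(collection: PhosphoSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


_RESIDUE_POS = re.compile(r"^([A-Za-z])(\d+)(-p)?$")


def read_kinase_substrate_table(
        path: str | Path,
        species_filter: str | None = None) -> PhosphoSetCollection:
    """Read a PhosphoSitePlus-style kinase-substrate TSV into phosphosite sets.

    Expects columns ``KINASE``, ``SUB_GENE`` and ``SUB_MOD_RSD`` (residue
    letter + position, e.g. ``"Y561"``); optional ``KIN_ORGANISM`` /
    ``SUB_ORGANISM`` columns are matched against ``species_filter`` when
    given. Substrates are normalized to ``"GENE:residuePosition"``. Rows
    with unparseable residue tokens are skipped and counted in
    ``n_skipped_rows``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    required = ["KINASE", "SUB_GENE", "SUB_MOD_RSD"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            "kinase-substrate table is missing column(s): " + ", ".join(missing)
        )
    if species_filter is not None:
        for col in ("KIN_ORGANISM", "SUB_ORGANISM"):
            if col in df.columns:
                df = df[df[col].str.lower() == species_filter.lower()]

    sets: dict[str, set[str]] = {}
    skipped = 0
    for kinase, gene, rsd in zip(df["KINASE"], df["SUB_GENE"],
                                 df["SUB_MOD_RSD"]):
        m = _RESIDUE_POS.match(str(rsd).strip())
        if m is None or pd.isna(gene) or pd.isna(kinase):
            skipped += 1
            continue
        ident = f"{gene}:{m.group(1).upper()}{int(m.group(2))}"
        sets.setdefault(str(kinase), set()).add(ident)
    return PhosphoSetCollection(
        {k: frozenset(v) for k, v in sets.items()}, n_skipped_rows=skipped)


def read_celltype_atlas(path: str | Path,
                        column_groups: Mapping[str, Sequence[str]],
                        gene_column: str | None = None,
                        sep: str | None = None) -> CellTypeAtlas:
    """Read a wide gene x expression table and attach a cell-type grouping.

    Genes appearing on multiple rows are collapsed by the mean of their
    expression values. A grouping that references an absent column raises
    :class:`FormatError` naming the column.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if gene_column is None:
        gene_column = df.columns[0]
    if gene_column not in df.columns:
        raise FormatError(f"atlas has no gene column {gene_column!r}")
    df = df.set_index(gene_column)
    df = df.apply(pd.to_numeric)
    df = df.groupby(level=0).mean()
    return CellTypeAtlas(
        values=df,
        cell_type_columns={ct: list(cols)
                           for ct, cols in column_groups.items()},
    )


def read_quant_matrix(path: str | Path):
    """Read a serialized quantification matrix (TSV, channels as columns)."""
    from phosflow.qcnorm import QuantMatrix
    df = pd.read_csv(path, sep="\t", index_col=0)
    return QuantMatrix(
        row_keys=list(df.index.astype(str)),
        values=df.values.astype(float),
        channel_map=ChannelMap.trivial(df.shape[1]),
    )


def write_quant_matrix(matrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.row_keys,
                      columns=matrix.channel_map.channel_labels)
    df.to_csv(path, sep="\t", float_format="%.17g")
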