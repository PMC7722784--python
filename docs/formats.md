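# File formats

All pipeline inputs and outputs are flat, documented text tables; no
proprietary search-result databases are read.

## PSM table (TSV)

One row per peptide-spectrum match. Required columns:

| column                  | content                                              |
|-------------------------|------------------------------------------------------|
| `ScanID`                | opaque scan identifier                               |
| `Sequence`              | upper-case peptide sequence                          |
| `Proteins`              | semicolon-joined protein accessions                  |
| `Genes`                 | semicolon-joined gene symbols                        |
| `PhosphoSites`          | `S5:0.99;T7:0.60` — residue, 1-based peptide offset, localization probability |
| `IonScore`              | search-engine ion score (≥ 0)                        |
| `IsolationInterference` | percent, 0–100                                       |
| `PercolatorFDR`         | fraction, 0–1                                        |
| `TMT_1` … `TMT_k`       | reporter intensities; plex size k inferred from the header |
| `Transgenic`            | `0`/`1` — transgene-derived peptide flag             |

Offsets are 1-based and must name an S/T/Y in `Sequence` (matching the
`pY561` site-name convention). Rows that fail to parse are reported with
their line numbers, never silently dropped. Column names can be remapped
via `phosflow.io.PSMDialect`.

## Phosphosite sets

- **GMT**: `set-name <TAB> description <TAB> member1 <TAB> member2 ...`
- **Kinase-substrate TSV** (PhosphoSitePlus `Kinase_Substrate_Dataset`
  layout): requires `KINASE`, `SUB_GENE`, `SUB_MOD_RSD` (e.g. `Y561`);
  optional `KIN_ORGANISM`/`SUB_ORGANISM` for species filtering.

Substrate identifiers normalize to `GENE:residuePosition` (e.g.
`Siglecf:Y561`). Rows with unparseable residue tokens are skipped and
counted.

## Cell-type atlas (TSV/CSV)

Wide table: first (or named) column gene identifier, remaining columns
per-sample mean FPKM. The cell-type grouping (type → list of columns) is
supplied separately (CLI: YAML file). Duplicate gene rows are collapsed
by mean.

## Quantification matrix (TSV)

First column peptide row key (`SEQUENCE|S5,T7`), remaining columns one
per channel, written at full float precision so write-then-read is
value-identical.

## Stats table (TSV)

Columns `row_key`, `fc`, `log2fc`, `p`, `label`
(label ∈ {up, down, unchanged}).

## PSEA results (TSV)

Columns `set`, `overlap`, `ES`, `NES`, `p`, `q`.
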