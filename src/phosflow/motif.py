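"""pLogo-style sequence-motif enrichment on phosphosite-centered 15-mers.

Each confidently localized phosphosite (localization probability > 0.75)
contributes one 15-residue window centered on the site; a peptide with two
localized sites contributes two windows. Flanks missing from the peptide
are taken from the protein sequence when available, otherwise the window
is padded with 'A'. Identical windows arising from mis-cleaved, oxidized
or multiply-phosphorylated peptides are collapsed, combining their
quantification by the median.

Per-position, per-residue enrichment of a foreground window collection
against a background collection is the signed hypergeometric log-odds

    LOE = -log10( sf(k-1) / cdf(k) ),  X ~ Hypergeometric(N, K, n)

with k the foreground count of the residue at that position, n the number
of foreground windows, K and N the matching background counts; positive
values mark enrichment, negative depletion.

Pattern matching counts, for a window, how many of a motif's non-wildcard,
non-center positions carry a matching residue (e.g. the CaMKII pattern
[FLMVI]-[RK]-Q-.-[st]-[FLMVI] or the CDK pattern [st]-P-K-K).
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from phosflow._hypergeom import log_odds_enrichment
from phosflow.io import PSMRecord

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
WINDOW = 15
HALF = WINDOW // 2
PAD = "A"
DEFAULT_MIN_LOCALIZATION = 0.75


@dataclasses.dataclass
class NmerSet:
    """A collection of fixed-length phosphosite-centered windows.

    ``values`` optionally carries one quantification value per window
    (fold change on any consistent scale); ``combine_identical`` collapses
    duplicate windows by the median of their values.
    """

    nmers: list[str]
    values: list[float] | None = None
    weights_combined: bool = False

    def __post_init__(self) -> None:
        for nmer in self.nmers:
            if len(nmer) != WINDOW:
                raise ValueError(f"window {nmer!r} is not length {WINDOW}")
            if nmer[HALF] not in "sty":
                raise ValueError(
                    f"window {nmer!r} center must be a phosphosite (s/t/y)")
        if self.values is not None and len(self.values) != len(self.nmers):
            raise ValueError("values must align with nmers")

    def __len__(self) -> int:
        return len(self.nmers)

    def combine_identical(self) -> "NmerSet":
        """Collapse duplicate windows, median-combining their values."""
        grouped: dict[str, list[float]] = {}
        order: list[str] = []
        for i, nmer in enumerate(self.nmers):
            if nmer not in grouped:
                grouped[nmer] = []
                order.append(nmer)
            if self.values is not None:
                grouped[nmer].append(self.values[i])
        values = [median(grouped[n]) for n in order] \
            if self.values is not None else None
        return NmerSet(order, values, weights_combined=True)


@dataclasses.dataclass
class ExtractionReport:
    n_sites_seen: int = 0
    n_below_localization: int = 0
    n_rejected: int = 0
    rejections: list[str] = dataclasses.field(default_factory=list)


def _window_from(sequence: str, center_idx: int) -> str:
    """15-mer around ``center_idx`` (0-based), 'A'-padded at termini, with
    the center residue lower-cased."""
    chars = []
    for off in range(-HALF, HALF + 1):
        j = center_idx + off
        chars.append(sequence[j] if 0 <= j < len(sequence) else PAD)
    chars[HALF] = chars[HALF].lower()
    return "".join(chars)


def extract_nmers(
    psms: Iterable[PSMRecord],
    protein_sequences: Mapping[str, str] | None = None,
    min_localization: float = DEFAULT_MIN_LOCALIZATION,
    values: Sequence[float] | None = None,
) -> tuple[NmerSet, ExtractionReport]:
    """One 15-mer per confidently localized site across ``psms``.

    Sites with localization probability <= ``min_localization`` are
    excluded (ambiguous). When ``protein_sequences`` maps an accession of
    the PSM to a full sequence containing the peptide, flanks extend into
    the protein; otherwise the peptide is 'A'-padded. ``values`` aligns a
    quantification value with each PSM (propagated to its windows).
    """
    psms = list(psms)
    if values is not None and len(values) != len(psms):
        raise ValueError("values must align with psms")
    report = ExtractionReport()
    nmers: list[str] = []
    nmer_values: list[float] = []
    for i, psm in enumerate(psms):
        for residue, offset, prob in psm.phospho_positions:
            report.n_sites_seen += 1
            if not prob > min_localization:
                report.n_below_localization += 1
                continue
            context, center = _locate_context(psm, offset, protein_sequences)
            if context[center] != residue:
                report.n_rejected += 1
                report.rejections.append(
                    f"{psm.scan_id}: site {residue}{offset} does not match "
                    f"sequence residue {context[center]!r}")
                continue
            nmers.append(_window_from(context, center))
            if values is not None:
                nmer_values.append(float(values[i]))
    return NmerSet(nmers, nmer_values if values is not None else None), report


def _locate_context(psm: PSMRecord, offset: int,
                    protein_sequences: Mapping[str, str] | None
                    ) -> tuple[str, int]:
    if protein_sequences:
        for acc in (*psm.proteins, *psm.gene_symbols):
            seq = protein_sequences.get(acc)
            if seq is not None:
                pos = seq.find(psm.sequence)
                if pos >= 0:
                    return seq, pos + offset - 1
    return psm.sequence, offset - 1


@dataclasses.dataclass
class MotifLogo:
    """Position x residue log-odds enrichment with the underlying counts."""

    loe: pd.DataFrame          # index: relative position, columns: residues
    k: pd.DataFrame            # foreground counts per cell
    K: pd.DataFrame            # background counts per cell
    n: int                     # total foreground windows
    N: int                     # total background windows

    def max_cell(self) -> tuple[int, str]:
        """(position, residue) of the maximum enrichment value."""
        pos = self.loe.max(axis=1).idxmax()
        res = self.loe.loc[pos].idxmax()
        return int(pos), str(res)


def _position_counts(nmers: Sequence[str]) -> dict[int, Counter]:
    counts: dict[int, Counter] = {
        off: Counter() for off in range(-HALF, HALF + 1) if off != 0}
    for nmer in nmers:
        for off in counts:
            counts[off][nmer[HALF + off].upper()] += 1
    return counts


def plogo_loe(foreground: NmerSet | Sequence[str],
              background: NmerSet | Sequence[str]) -> MotifLogo:
    """Signed hypergeometric log-odds logo of foreground vs background.

    The foreground is assumed drawn from the background collection
    (k <= K per cell, n <= N). Residues forced by composition (K = N) and
    a foreground equal to the background both give LOE exactly 0.
    """
    fg = list(foreground.nmers if isinstance(foreground, NmerSet)
              else foreground)
    bg = list(background.nmers if isinstance(background, NmerSet)
              else background)
    n, N = len(fg), len(bg)
    positions = [off for off in range(-HALF, HALF + 1) if off != 0]
    shape = (len(positions), len(AMINO_ACIDS))
    if n == 0 or N == 0:
        warnings.warn("empty foreground or background; returning empty logo",
                      RuntimeWarning)
        zeros = pd.DataFrame(np.zeros(shape), index=positions,
                             columns=AMINO_ACIDS)
        return MotifLogo(zeros, zeros.copy(), zeros.copy(), n, N)
    if n > N:
        raise ValueError("foreground larger than background collection")

    fg_counts = _position_counts(fg)
    bg_counts = _position_counts(bg)
    loe = np.zeros(shape)
    kmat = np.zeros(shape, dtype=int)
    Kmat = np.zeros(shape, dtype=int)
    for i, off in enumerate(positions):
        for j, aa in enumerate(AMINO_ACIDS):
            k = fg_counts[off][aa]
            K = bg_counts[off][aa]
            kmat[i, j] = k
            Kmat[i, j] = K
            loe[i, j] = log_odds_enrichment(k, K, n, N)
    idx = pd.Index(positions, name="position")
    return MotifLogo(
        pd.DataFrame(loe, index=idx, columns=AMINO_ACIDS),
        pd.DataFrame(kmat, index=idx, columns=AMINO_ACIDS),
        pd.DataFrame(Kmat, index=idx, columns=AMINO_ACIDS),
        n, N,
    )


def build_foreground(stats_list, p_max: float = 0.05,
                     min_up_fc: float = 1.25,
                     max_down_fc: float = 0.8) -> set[str]:
    """Row keys of regulated peptides for the motif foreground.

    Uses the motif-analysis selection (p < 0.05 with FC > 1.25 or
    FC < 0.8), which is deliberately looser in p than the up/down cluster
    definition used for cell-type enrichment.
    """
    keys = set()
    for s in stats_list:
        if not s.valid:
            continue
        if s.p_value < p_max and (s.fold_change > min_up_fc
                                  or s.fold_change < max_down_fc):
            keys.add(s.row_key)
    return keys


_CENTER_CLASSES = {"st", "sty", "s", "t", "y"}


@dataclasses.dataclass(frozen=True)
class MotifPattern:
    """An ordered kinase-substrate motif over residue classes.

    ``classes`` holds, per position, a frozenset of residues, ``None`` for
    a wildcard, or the phospho-center (a lowercase class such as {s, t}).
    Exactly one center is required; wildcards and the center are excluded
    from match counts.
    """

    name: str
    classes: tuple[frozenset | None, ...]
    center_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.center_index < len(self.classes):
            raise ValueError("center_index out of range")

    @classmethod
    def from_string(cls, name: str, pattern: str) -> "MotifPattern":
        """Parse dash-separated position classes, e.g.
        ``"[FLMVI]-[RK]-Q-.-[st]-[FLMVI]"``. Lowercase classes mark the
        phospho-center; ``.`` is a wildcard."""
        classes: list[frozenset | None] = []
        center = None
        for token in (t.strip() for t in pattern.strip("- ").split("-")):
            if not token:
                continue
            if token == ".":
                classes.append(None)
                continue
            residues = token.strip("[]")
            if residues.lower() in _CENTER_CLASSES and residues.islower():
                if center is not None:
                    raise ValueError("pattern has multiple phospho-centers")
                center = len(classes)
                classes.append(frozenset(residues.lower()))
            else:
                classes.append(frozenset(residues.upper()))
        if center is None:
            raise ValueError("pattern has no phospho-center class")
        return cls(name, tuple(classes), center)

    @property
    def counted_positions(self) -> tuple[int, ...]:
        """Offsets (relative to center) that contribute to match counts."""
        return tuple(i - self.center_index
                     for i, c in enumerate(self.classes)
                     if c is not None and i != self.center_index)


CAMKII_MOTIF = MotifPattern.from_string(
    "CaMKII", "[FLMVI]-[RK]-Q-.-[st]-[FLMVI]")
CDK_MOTIF = MotifPattern.from_string("CDK", "[st]-P-K-K")


def count_motif_matches(nmer: str, pattern: MotifPattern) -> int:
    """Residues of ``nmer`` matching the pattern's counted positions.

    The pattern's phospho-center is aligned to the window center; the
    center itself and wildcards never contribute to the count.
    """
    if len(nmer) != WINDOW:
        raise ValueError(f"window must be length {WINDOW}")
    if len(pattern.classes) > WINDOW:
        raise ValueError("pattern longer than the n-mer window")
    count = 0
    for off in pattern.counted_positions:
        j = HALF + off
        if not 0 <= j < WINDOW:
            raise ValueError("pattern extends past the n-mer window")
        if nmer[j].upper() in pattern.classes[pattern.center_index + off]:
            count += 1
    return count


def count_peptide_motif_matches(nmers: Sequence[str],
                                pattern: MotifPattern) -> int:
    """Max match count over a peptide's site windows (multi-site rule)."""
    if not nmers:
        raise ValueError("no windows supplied")
    return max(count_motif_matches(n, pattern) for n in nmers)
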