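"""Phosphosite window parsing, position inference, and 14-3-3 motif scanning.

Phosphopeptide annotations write the phosphorylated residue in lowercase
within a short sequence window (e.g. ``QATMDFStPSVFDQQ``).  Database windows
are +/-7 residues around the site, truncated at the protein termini; tryptic
peptides from other repositories are accepted too.  When one window carries a
declared protein position it can anchor a neighbouring window by unique exact
sequence overlap, yielding the absolute position of the second site.

14-3-3 proteins bind phosphoserine/threonine in two consensus contexts:
mode I ``R S x pS/pT x P`` and mode II ``R x x x pS/pT x P``.  Only these
literal patterns are scanned; no trained site predictor is involved.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

__all__ = [
    "PhosphoWindow",
    "MotifHit",
    "parse_window",
    "infer_position",
    "count_sites",
    "scan_14_3_3_motifs",
]

MIN_OVERLAP = 8  # residues two windows must share exactly to align


@dataclasses.dataclass(frozen=True)
class PhosphoWindow:
    """A phosphopeptide annotation with exactly one lowercase phospho-residue.

    ``identified_in`` lists the extract fractions in which this study's own
    MS experiment (on the human protein) detected the site — e.g.
    ``("N", "T")`` for nuclear and total extracts — or is empty for
    database-only rows.
    """

    window: str
    declared_position: int | None = None
    species: str = ""
    source: str = ""
    identified_in: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        parse_window(self.window)  # validates the single-lowercase invariant
        if self.declared_position is not None and self.declared_position < 1:
            raise ValueError("declared_position is 1-based and must be >= 1")

    @property
    def site_offset(self) -> int:
        """1-based offset of the lowercase residue within the window."""
        return parse_window(self.window)[0]

    @property
    def residue(self) -> str:
        return parse_window(self.window)[1]


@dataclasses.dataclass(frozen=True)
class MotifHit:
    motif_id: str  # modeI | modeII
    site_position: int
    matched_span: str


def parse_window(window: str) -> tuple[int, str]:
    """Locate the single lowercase phospho-residue in a window string.

    Returns ``(offset, residue)`` with a 1-based offset and the residue
    uppercased.  The residue must be S, T or Y.
    """
    if not window or not window.isalpha():
        raise ValueError(f"window must be a non-empty letter string, got {window!r}")
    lows = [i for i, ch in enumerate(window) if ch.islower()]
    if len(lows) != 1:
        raise ValueError(
            f"window must contain exactly one lowercase residue, found {len(lows)} in {window!r}"
        )
    i = lows[0]
    residue = window[i].upper()
    if residue not in "STY":
        raise ValueError(f"phospho-residue must be S, T or Y, got {residue!r}")
    return i + 1, residue


def _window_start(anchor: PhosphoWindow) -> int:
    """Protein position of the anchor window's first residue.

    The site sits at ``declared_position`` and at ``site_offset`` within the
    window, so the window starts at ``declared_position - site_offset + 1``.
    A window truncated at the N terminus (shorter left flank) is thereby
    pinned at protein position 1 automatically.
    """
    assert anchor.declared_position is not None
    start = anchor.declared_position - anchor.site_offset + 1
    if start < 1:
        raise ValueError(
            f"window {anchor.window!r} extends before protein position 1 "
            f"(declared position {anchor.declared_position})"
        )
    return start


def infer_position(anchor: PhosphoWindow, query: PhosphoWindow, min_overlap: int = MIN_OVERLAP) -> int:
    """Infer the query site's protein position by overlap with an anchored window.

    The anchor pins a stretch of protein sequence to absolute coordinates;
    the query window is slid across it and placed where all overlapping
    residues match exactly (case-insensitive) over at least ``min_overlap``
    positions.  The placement must be unique.  Returns the 1-based protein
    position of the query's lowercase residue.
    """
    if anchor.declared_position is None:
        raise ValueError("anchor window needs a declared_position")
    a_seq = anchor.window.upper()
    q_seq = query.window.upper()
    a_start = _window_start(anchor)

    placements = []
    # slide query start across every offset giving >= min_overlap shared columns
    for shift in range(-(len(q_seq) - min_overlap), len(a_seq) - min_overlap + 1):
        lo = max(0, shift)
        hi = min(len(a_seq), shift + len(q_seq))
        if hi - lo < min_overlap:
            continue
        if a_seq[lo:hi] == q_seq[lo - shift : hi - shift]:
            placements.append(shift)
    if not placements:
        raise ValueError(
            f"query window {query.window!r} shares no exact overlap of >= "
            f"{min_overlap} residues with anchor {anchor.window!r}"
        )
    if len(placements) > 1:
        raise ValueError(
            f"ambiguous placement of {query.window!r} against {anchor.window!r}: "
            f"{len(placements)} candidate offsets"
        )
    q_start = a_start + placements[0]
    pos = q_start + query.site_offset - 1
    if pos < 1:
        raise ValueError("inferred position falls before protein position 1")
    return pos


def count_sites(rows: Iterable[PhosphoWindow], species_filter: str | None = None) -> int:
    """Count distinct declared phosphosite positions, optionally per species.

    A row matches a species filter if its species label matches, or if the
    site was experimentally identified in this study (``identified_in``
    non-empty): the study's MS was performed on the human protein, so a
    database window annotated on the mouse orthologue still counts as a
    human site once confirmed experimentally.
    """
    positions = set()
    for row in rows:
        if row.declared_position is None:
            continue
        if species_filter is not None:
            if row.species != species_filter and not row.identified_in:
                continue
        positions.add(row.declared_position)
    return len(positions)


def scan_14_3_3_motifs(sequence: str, phospho_positions: Iterable[int]) -> list[MotifHit]:
    """Scan phosphosites for the two 14-3-3 consensus binding contexts.

    mode I requires R at p-3, S at p-2 and P at p+2 around the phosphosite p;
    mode II requires R at p-4 and P at p+2 (1-based protein coordinates,
    unconstrained positions free).  A site too close to a terminus for a
    pattern cannot match it; one site may yield both hits.
    """
    seq = sequence.upper()
    n = len(seq)
    hits: list[MotifHit] = []
    for p in sorted(set(phospho_positions)):
        if not 1 <= p <= n:
            raise ValueError(f"phospho position {p} outside sequence of length {n}")
        if seq[p - 1] not in "ST":
            raise ValueError(
                f"residue at position {p} is {seq[p - 1]!r}, expected S or T"
            )
        if p - 3 >= 1 and p + 2 <= n:
            if seq[p - 4] == "R" and seq[p - 3] == "S" and seq[p + 1] == "P":
                hits.append(MotifHit("modeI", p, seq[p - 4 : p + 2]))
        if p - 4 >= 1 and p + 2 <= n:
            if seq[p - 5] == "R" and seq[p + 1] == "P":
                hits.append(MotifHit("modeII", p, seq[p - 5 : p + 2]))
    return hits
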