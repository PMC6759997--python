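"""Reading and validation of AP-MS count tables, protein lengths and designs.

The pipeline starts downstream of the database search: its exchange format is
a protein-level table of spectral counts (and optionally unique-peptide
counts) per sample, plus a FASTA file supplying protein lengths for NSAF
normalization.  A protein that was not identified in a sample has a count of
zero — absent cells are imputed as 0, never treated as missing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "SampleMeta",
    "SpectralCountTable",
    "DesignError",
    "read_count_table",
    "read_protein_lengths",
    "validate_design",
    "design_from_yaml",
    "write_count_table",
]


class DesignError(ValueError):
    """Raised when a sample design or count table violates its contract."""


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """One protein row: accession, gene symbol, length in residues."""

    accession: str
    gene_symbol: str = ""
    length_aa: int | None = None
    mw_kDa: float | None = None

    def __post_init__(self) -> None:
        if self.length_aa is not None and self.length_aa < 1:
            raise ValueError(f"length_aa must be >= 1, got {self.length_aa}")


@dataclasses.dataclass(frozen=True)
class SampleMeta:
    """Sample annotation: condition ('bait' or 'control') and replicate index."""

    sample_id: str
    condition: str
    replicate_index: int

    def __post_init__(self) -> None:
        if self.condition not in ("bait", "control"):
            raise DesignError(
                f"condition must be 'bait' or 'control', got {self.condition!r}"
            )
        if self.replicate_index < 1:
            raise DesignError("replicate_index is 1-based and must be >= 1")


@dataclasses.dataclass
class SpectralCountTable:
    """Protein x sample matrices of spectral counts and unique-peptide counts.

    Invariants: both matrices are |proteins| x |samples| non-negative
    integers, and ``unique_peptides[i, s] <= spc[i, s]`` wherever
    ``spc[i, s] > 0``.  When a source table carries no unique-peptide
    information the peptide matrix defaults to the spectral counts themselves
    (every spectrum treated as a distinct peptide — an upper bound, so the
    two-peptide gate is then only as stringent as the counts allow).
    """

    proteins: list[ProteinRecord]
    samples: list[SampleMeta]
    spc: np.ndarray
    unique_peptides: np.ndarray

    def __post_init__(self) -> None:
        n_p, n_s = len(self.proteins), len(self.samples)
        self.spc = np.asarray(self.spc)
        self.unique_peptides = np.asarray(self.unique_peptides)
        if self.spc.shape != (n_p, n_s) or self.unique_peptides.shape != (n_p, n_s):
            raise ValueError(
                f"matrix shape mismatch: expected ({n_p}, {n_s}), got "
                f"spc {self.spc.shape}, unique_peptides {self.unique_peptides.shape}"
            )
        for mat, name in ((self.spc, "spc"), (self.unique_peptides, "unique_peptides")):
            if not np.issubdtype(mat.dtype, np.integer):
                raise ValueError(f"{name} must be an integer matrix")
            if (mat < 0).any():
                raise ValueError(f"negative count in {name}")
        bad = (self.spc > 0) & (self.unique_peptides > self.spc)
        if bad.any():
            raise ValueError("unique_peptides exceeds spectral counts")
        accs = [p.accession for p in self.proteins]
        if len(set(accs)) != len(accs):
            raise ValueError("duplicate accession in protein list")

    @property
    def accessions(self) -> list[str]:
        return [p.accession for p in self.proteins]

    def sample_index(self, condition: str, replicate_index: int) -> int:
        for i, s in enumerate(self.samples):
            if s.condition == condition and s.replicate_index == replicate_index:
                return i
        raise KeyError(f"no sample ({condition}, replicate {replicate_index})")


def _read_matrix(path: str | Path, sample_ids: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    first = df.columns[0]
    df = df.set_index(first)
    # optional gene_symbol column sits between accession and the samples
    meta_cols = [c for c in df.columns if c not in sample_ids]
    for c in meta_cols:
        if c != "gene_symbol":
            raise DesignError(f"unknown sample_id {c!r} in header of {path}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate accession {dup!r} in {path}")
    return df


def read_count_table(
    path: str | Path,
    design: Sequence[SampleMeta],
    unique_peptides_path: str | Path | None = None,
) -> SpectralCountTable:
    """Read a tab-separated protein x sample count table.

    The first column is the accession, an optional ``gene_symbol`` column may
    follow, and the remaining columns must be the ``sample_id``s of *design*.
    Empty cells are imputed as zero.  Negative or non-integer counts are
    rejected.  A second table of unique-peptide counts with the same layout
    may be supplied; proteins absent from it get peptide counts equal to
    their spectral counts.
    """
    sample_ids = [s.sample_id for s in design]
    if len(set(sample_ids)) != len(sample_ids):
        raise DesignError("duplicate sample_id in design")
    df = _read_matrix(path, sample_ids)

    genes = df["gene_symbol"] if "gene_symbol" in df.columns else None
    counts = df.reindex(columns=sample_ids).fillna(0)
    arr = counts.to_numpy()
    if not np.all(arr == np.floor(arr)):
        raise ValueError(f"non-integer count in {path}")
    spc = arr.astype(np.int64)
    if (spc < 0).any():
        raise ValueError(f"negative count in {path}")

    proteins = [
        ProteinRecord(accession=str(acc), gene_symbol=str(genes[acc]) if genes is not None else "")
        for acc in df.index
    ]

    if unique_peptides_path is not None:
        pep_df = _read_matrix(unique_peptides_path, sample_ids)
        pep = (
            pep_df.reindex(index=df.index, columns=sample_ids)
            .fillna(0)
            .to_numpy()
        )
        if not np.all(pep == np.floor(pep)):
            raise ValueError(f"non-integer count in {unique_peptides_path}")
        pep = pep.astype(np.int64)
        # proteins missing from the peptide table fall back to their counts
        missing = ~df.index.isin(pep_df.index)
        pep[missing] = spc[missing]
    else:
        pep = spc.copy()

    return SpectralCountTable(proteins=proteins, samples=list(design), spc=spc, unique_peptides=pep)


def write_count_table(table: SpectralCountTable, path: str | Path) -> None:
    """Write the spectral-count matrix back to TSV (inverse of read)."""
    df = pd.DataFrame(
        table.spc,
        index=pd.Index(table.accessions, name="accession"),
        columns=[s.sample_id for s in table.samples],
    )
    df.insert(0, "gene_symbol", [p.gene_symbol for p in table.proteins])
    df.to_csv(path, sep="\t")


def _parse_accession(header_token: str) -> str:
    # UniProt "sp|ACC|NAME" / "tr|ACC|NAME" dialect; otherwise the raw token
    parts = header_token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return header_token


def read_protein_lengths(fasta: str | Path) -> dict[str, int]:
    """Map accession -> sequence length (residues) from a protein FASTA.

    Accessions come from the first whitespace-delimited header token; the
    UniProt ``sp|ACC|NAME`` dialect is unwrapped to the bare accession.
    Empty sequences are an error, as are duplicate accessions whose
    sequences differ (identical duplicates are tolerated).
    """
    lengths: dict[str, int] = {}
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta), "fasta"):
        acc = _parse_accession(record.id)
        seq = str(record.seq).strip()
        if len(seq) == 0:
            raise ValueError(f"empty sequence for {acc!r} in {fasta}")
        if acc in seqs and seqs[acc] != seq:
            raise ValueError(f"duplicate accession {acc!r} with differing sequence")
        seqs[acc] = seq
        lengths[acc] = len(seq)
    return lengths


def validate_design(table: SpectralCountTable) -> list[tuple[int, int]]:
    """Pair bait and control samples by replicate index.

    Returns a list of ``(bait_column, control_column)`` index pairs ordered
    by replicate index.  The design must be balanced — the ratio filter is a
    per-replicate comparison, so every bait replicate needs its control.
    """
    by_cond: dict[str, dict[int, int]] = {"bait": {}, "control": {}}
    for col, s in enumerate(table.samples):
        if s.replicate_index in by_cond[s.condition]:
            raise DesignError(
                f"duplicate replicate_index {s.replicate_index} for condition {s.condition!r}"
            )
        by_cond[s.condition][s.replicate_index] = col
    n_bait, n_control = len(by_cond["bait"]), len(by_cond["control"])
    if n_bait == 0 or n_control == 0:
        raise DesignError("design needs at least one bait and one control sample")
    if n_bait != n_control or set(by_cond["bait"]) != set(by_cond["control"]):
        raise DesignError(
            f"unbalanced design: {n_bait} bait vs {n_control} control replicates"
        )
    return [
        (by_cond["bait"][r], by_cond["control"][r])
        for r in sorted(by_cond["bait"])
    ]


def design_from_yaml(path: str | Path) -> list[SampleMeta]:
    """Load a sample design from YAML.

    Expected layout::

        samples:
          - {sample_id: bait_1, condition: bait, replicate_index: 1}
          - {sample_id: ctrl_1, condition: control, replicate_index: 1}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries: Iterable[Mapping] = doc["samples"] if isinstance(doc, Mapping) else doc
    design = [
        SampleMeta(
            sample_id=str(e["sample_id"]),
            condition=str(e["condition"]),
            replicate_index=int(e["replicate_index"]),
        )
        for e in entries
    ]
    key = [(s.condition, s.replicate_index) for s in design]
    if len(set(key)) != len(key):
        raise DesignError("duplicate (condition, replicate_index) in design")
    return design
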