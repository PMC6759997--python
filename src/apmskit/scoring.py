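"""Interactor selection by spectral-count enrichment and NSAF quantitation.

A protein is called a *strict* interactor when its bait/control spectral-count
ratio clears the fold threshold in every replicate pair, with at least
``min_unique`` unique peptides in each passing bait replicate; it is *relaxed*
when it does so in all but one replicate.  Relative abundance within each
sample is expressed as NSAF (normalized spectral abundance factor): spectral
counts divided by protein length, as a percent of the sample's total
length-normalized counts.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np

from .ingest import SpectralCountTable, validate_design

__all__ = [
    "RatioProfile",
    "InteractomeEntry",
    "ScoringConfig",
    "spectral_ratio",
    "classify_protein",
    "nsaf",
    "mean_nsaf",
    "build_interactome",
    "rank_by_nsaf",
]


@dataclasses.dataclass(frozen=True)
class ScoringConfig:
    """Thresholds of the enrichment filter.

    threshold : fold-change the bait/control ratio must reach (default 5).
    comparator : "ge" (ratio >= threshold, default) or "gt" (strictly >).
    min_unique : unique peptides required in each passing bait replicate.
    pseudocount : added to both counts before the ratio; 0 disables it, in
        which case a zero-control ratio is +inf for nonzero bait (a protein
        absent from every control must remain selectable).
    """

    threshold: float = 5.0
    comparator: str = "ge"
    min_unique: int = 2
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.comparator not in ("ge", "gt"):
            raise ValueError(f"comparator must be 'ge' or 'gt', got {self.comparator!r}")
        if self.threshold < 0 or self.pseudocount < 0 or self.min_unique < 0:
            raise ValueError("threshold, pseudocount and min_unique must be non-negative")

    def passes(self, ratio: float) -> bool:
        return ratio > self.threshold if self.comparator == "gt" else ratio >= self.threshold


@dataclasses.dataclass
class RatioProfile:
    """Per-replicate bait/control ratios for one protein."""

    accession: str
    ratios: tuple[float, ...]
    n_pass: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_pass <= len(self.ratios):
            raise ValueError("n_pass outside [0, n_replicates]")


@dataclasses.dataclass
class InteractomeEntry:
    """Per-protein verdict: category, ratios, mean NSAF in bait and control."""

    accession: str
    gene_symbol: str
    category: str  # strict | relaxed | none
    ratios: RatioProfile
    nsaf_bait_pct: float
    nsaf_control_pct: float
    min_unique_peptides: int


def spectral_ratio(bait_count: int, control_count: int, pseudocount: float = 0.0) -> float:
    """Bait/control spectral-count ratio.

    With ``pseudocount == 0``: plain division; a zero control gives ``inf``
    for nonzero bait and ``0.0`` for the 0/0 case.  A positive pseudocount
    ``c`` gives ``(bait + c) / (control + c)``, always finite.
    """
    if bait_count < 0 or control_count < 0 or pseudocount < 0:
        raise ValueError("counts and pseudocount must be non-negative")
    if pseudocount > 0:
        return (bait_count + pseudocount) / (control_count + pseudocount)
    if control_count == 0:
        return math.inf if bait_count > 0 else 0.0
    return bait_count / control_count


def classify_protein(
    profile: RatioProfile,
    unique_peptides_per_bait_replicate: Sequence[int],
    threshold: float = 5.0,
    min_unique: int = 2,
    comparator: str = "ge",
) -> str:
    """Assign a protein to the strict, relaxed, or none category.

    A replicate passes when its ratio clears the threshold AND the bait run
    carries at least ``min_unique`` unique peptides.  strict = all replicates
    pass; relaxed = exactly all-but-one pass; the two are disjoint by
    construction.
    """
    peptides = list(unique_peptides_per_bait_replicate)
    if len(peptides) != len(profile.ratios):
        raise ValueError(
            f"{len(profile.ratios)} ratios but {len(peptides)} peptide counts"
        )
    cfg = ScoringConfig(threshold=threshold, comparator=comparator, min_unique=min_unique)
    n = len(profile.ratios)
    n_joint = sum(
        1
        for r, p in zip(profile.ratios, peptides)
        if cfg.passes(r) and p >= min_unique
    )
    if n_joint == n:
        return "strict"
    if n >= 2 and n_joint == n - 1:
        return "relaxed"
    return "none"


def nsaf(counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """NSAF percent for one sample: 100 * (SpC_i/L_i) / sum_j (SpC_j/L_j)."""
    c = np.asarray(counts, dtype=float)
    L = np.asarray(lengths, dtype=float)
    if c.shape != L.shape:
        raise ValueError("counts and lengths differ in length")
    if (L < 1).any():
        raise ValueError("all protein lengths must be >= 1")
    if (c < 0).any():
        raise ValueError("negative count")
    saf = c / L
    total = saf.sum()
    if total == 0:
        raise ValueError("all-zero sample: NSAF undefined")
    return 100.0 * saf / total


def mean_nsaf(per_replicate_nsaf: Sequence[float]) -> float:
    """Arithmetic mean NSAF over replicates."""
    vals = np.asarray(per_replicate_nsaf, dtype=float)
    if vals.size == 0:
        raise ValueError("mean NSAF of zero replicates is undefined")
    return float(vals.mean())


def build_interactome(
    table: SpectralCountTable,
    lengths: Mapping[str, int],
    config: ScoringConfig | None = None,
) -> list[InteractomeEntry]:
    """Score every protein of a paired bait/control count table.

    Computes per-replicate ratios, the strict/relaxed/none category under
    *config*, and mean NSAF percent across bait and across control samples.
    Proteins missing from *lengths* are an error (NSAF needs the length).
    """
    cfg = config or ScoringConfig()
    pairs = validate_design(table)
    accs = table.accessions
    missing = [a for a in accs if a not in lengths]
    if missing:
        raise KeyError(f"no length for accession(s): {missing[:5]}")
    L = np.array([lengths[a] for a in accs], dtype=float)

    bait_cols = [b for b, _ in pairs]
    ctrl_cols = [c for _, c in pairs]
    nsaf_bait = np.column_stack([nsaf(table.spc[:, col], L) for col in bait_cols])
    nsaf_ctrl = np.column_stack([nsaf(table.spc[:, col], L) for col in ctrl_cols])

    entries = []
    for i, prot in enumerate(table.proteins):
        ratios = tuple(
            spectral_ratio(int(table.spc[i, b]), int(table.spc[i, c]), cfg.pseudocount)
            for b, c in pairs
        )
        peptides = [int(table.unique_peptides[i, b]) for b in bait_cols]
        profile = RatioProfile(
            accession=prot.accession,
            ratios=ratios,
            n_pass=sum(cfg.passes(r) for r in ratios),
        )
        category = classify_protein(
            profile,
            peptides,
            threshold=cfg.threshold,
            min_unique=cfg.min_unique,
            comparator=cfg.comparator,
        )
        entries.append(
            InteractomeEntry(
                accession=prot.accession,
                gene_symbol=prot.gene_symbol,
                category=category,
                ratios=profile,
                nsaf_bait_pct=float(nsaf_bait[i].mean()),
                nsaf_control_pct=float(nsaf_ctrl[i].mean()),
                min_unique_peptides=min(peptides),
            )
        )
    return entries


def rank_by_nsaf(entries: Sequence[InteractomeEntry]) -> list[InteractomeEntry]:
    """Order entries by descending mean bait NSAF; ties break by accession."""
    return sorted(entries, key=lambda e: (-e.nsaf_bait_pct, e.accession))
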