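"""End-to-end scoring pipeline and packaged reference-table fixtures.

``run_pipeline`` chains ingestion, paired-design validation, enrichment
classification, NSAF quantitation and ranking into one call that writes a
TSV report and a run log.  The two reference tables printed in the source
study — the NSAF-ranked top-22 interactor lists for total protein extracts
(TPE) and nuclear extracts (NE), and the Ser/Thr phosphosite windows — ship
as packaged TSV fixtures, checksum-guarded against silent corruption.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from importlib import resources
from pathlib import Path

import pandas as pd

from .ingest import design_from_yaml, read_count_table, read_protein_lengths, validate_design
from .phospho import PhosphoWindow
from .scoring import InteractomeEntry, ScoringConfig, build_interactome, rank_by_nsaf

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "write_interactome_tsv",
    "load_table1_fixture",
    "load_table2_fixture",
]

logger = logging.getLogger("apmskit")

_FIXTURE_SHA256 = {
    "table1_interactome.tsv": "2b20405ba5e12373efca2556c8e3e6b643e346a5e1f9b7a15de6d0d3d25ef9c1",
    "table2_phosphosites.tsv": "938ece1517ff8bea1524bfdda67fced344c97d8ebd682275dfe140e3c3f8fa66",
}


class PipelineError(RuntimeError):
    """A component failure, labelled with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclasses.dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    counts_path: str | Path
    fasta_path: str | Path
    design_path: str | Path
    out_dir: str | Path = "."
    unique_peptides_path: str | Path | None = None
    scoring: ScoringConfig = dataclasses.field(default_factory=ScoringConfig)
    log_level: str = "INFO"


def write_interactome_tsv(entries: list[InteractomeEntry], path: str | Path) -> None:
    """Write the ranked interactome report (deterministic byte-for-byte)."""
    ranked = rank_by_nsaf(entries)
    rows = []
    for rank, e in enumerate(ranked, start=1):
        row = {
            "rank": rank,
            "accession": e.accession,
            "gene_symbol": e.gene_symbol,
            "category": e.category,
            "nsaf_bait_pct": f"{e.nsaf_bait_pct:.6f}",
            "nsaf_control_pct": f"{e.nsaf_control_pct:.6f}",
            "min_unique_peptides": e.min_unique_peptides,
        }
        for i, r in enumerate(e.ratios.ratios, start=1):
            row[f"ratio_rep{i}"] = "inf" if r == float("inf") else f"{r:.4f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: RunConfig) -> list[InteractomeEntry]:
    """Ingest, score and rank; write ``interactome.tsv`` and ``run.log``.

    Returns the full entry list (all categories).  Failures are re-raised as
    :class:`PipelineError` carrying the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    try:
        try:
            design = design_from_yaml(config.design_path)
            table = read_count_table(
                config.counts_path, design, config.unique_peptides_path
            )
        except Exception as exc:
            raise PipelineError("ingest:counts", exc) from exc
        try:
            lengths = read_protein_lengths(config.fasta_path)
        except Exception as exc:
            raise PipelineError("ingest:fasta", exc) from exc
        try:
            pairs = validate_design(table)
        except Exception as exc:
            raise PipelineError("design", exc) from exc
        logger.info(
            "design: %d replicate pairs (%s)",
            len(pairs),
            ", ".join(
                f"{table.samples[b].sample_id}~{table.samples[c].sample_id}"
                for b, c in pairs
            ),
        )
        logger.info(
            "thresholds: ratio %s %s, min_unique=%d, pseudocount=%g",
            ">" if config.scoring.comparator == "gt" else ">=",
            config.scoring.threshold,
            config.scoring.min_unique,
            config.scoring.pseudocount,
        )
        try:
            entries = build_interactome(table, lengths, config.scoring)
        except Exception as exc:
            raise PipelineError("scoring", exc) from exc
        n_strict = sum(e.category == "strict" for e in entries)
        n_relaxed = sum(e.category == "relaxed" for e in entries)
        logger.info(
            "scored %d proteins: %d strict, %d relaxed", len(entries), n_strict, n_relaxed
        )
        write_interactome_tsv(entries, out_dir / "interactome.tsv")
        return entries
    finally:
        logger.removeHandler(handler)
        handler.close()


def _fixture_text(name: str) -> str:
    data = resources.files("apmskit.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise ValueError(f"fixture {name} checksum mismatch: {digest}")
    return data.decode()


def load_table1_fixture() -> pd.DataFrame:
    """The NSAF-ranked top-22 interactor tables for the TPE and NE fractions.

    Columns: fraction (TPE/NE), gene_symbol, accession, mw_kDa,
    protein_name, nsaf_bait_pct (mean NSAF % in the bait IP),
    nsaf_control_pct (mean NSAF % in the negative-control IP).
    """
    import io

    df = pd.read_csv(io.StringIO(_fixture_text("table1_interactome.tsv")), sep="\t")
    assert set(df["fraction"]) == {"TPE", "NE"}
    return df


def load_table2_fixture() -> list[PhosphoWindow]:
    """The Ser/Thr phosphosite windows with declared positions and species."""
    import io

    df = pd.read_csv(io.StringIO(_fixture_text("table2_phosphosites.tsv")), sep="\t")
    rows = []
    for _, r in df.iterrows():
        ident = () if pd.isna(r.get("identified_in")) else tuple(str(r["identified_in"]).split("/"))
        rows.append(
            PhosphoWindow(
                window=r["peptide"],
                declared_position=int(str(r["position"])[1:]),
                species=r["species"],
                source=r["source"],
                identified_in=ident,
            )
        )
    return rows
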