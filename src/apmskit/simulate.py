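"""Synthetic AP-MS, phosphosite, and colocalization data with known truth.

The count generator emulates the study design the enrichment filter targets:
a tagged bait immunoprecipitated alongside a negative-control IP, three
replicates each.  Protein-specific background abundances span orders of
magnitude (log-normal), spectral counts are overdispersed around them
(gamma-mixed Poisson, i.e. negative binomial), a planted subset of true
interactors is enriched fold-times over background in the bait, and
unique-peptide counts are a binomial thinning of the spectral counts.  The
bait protein itself is included as a high-abundance bait-only row, mimicking
the dominant bait band on the gel.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .ingest import ProteinRecord, SampleMeta, SpectralCountTable
from .scoring import InteractomeEntry
from .coloc import ROIMeasurement

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_apms",
    "evaluate_recovery",
    "simulate_coloc",
    "BAIT_ACCESSION",
]

BAIT_ACCESSION = "BAIT0001"

# log-normal sigma for protein-specific background means; spectral counts in
# an IP eluate span roughly two orders of magnitude across proteins
_BASELINE_SIGMA = 0.8
# bait-row mean spectral count per replicate (the bait dominates its own IP)
_BAIT_ROW_MEAN = 300.0


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters for a bait/control AP-MS experiment.

    n_proteins : background proteins (the bait row is added on top).
    n_true : how many of them are planted true interactors.
    fold : bait enrichment of true interactors (>= 1; 1 = null model).
    base_mean : expected control spectral count of a typical protein.
    dispersion : negative-binomial overdispersion (variance = mu + d*mu^2);
        0 degenerates to Poisson.
    n_replicates : paired bait/control replicates.
    peptide_ratio : expected unique peptides per spectrum (binomial thinning).
    seed : RNG seed; every draw derives from it.
    """

    n_proteins: int = 400
    n_true: int = 20
    fold: float = 20.0
    base_mean: float = 10.0
    dispersion: float = 0.05
    n_replicates: int = 3
    peptide_ratio: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_true <= self.n_proteins:
            raise ValueError("need 0 <= n_true <= n_proteins")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if self.base_mean <= 0 or self.dispersion < 0:
            raise ValueError("base_mean must be positive, dispersion non-negative")
        if not 0 < self.peptide_ratio <= 1:
            raise ValueError("peptide_ratio must be in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclasses.dataclass
class SimulationTruth:
    true_interactors: set[str]
    config: SimulationConfig


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-mixed Poisson draws with variance mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_apms(
    config: SimulationConfig,
) -> tuple[SpectralCountTable, SimulationTruth, dict[str, int]]:
    """Generate a paired bait/control spectral-count table with planted truth.

    Returns the count table, the set of planted interactor accessions (the
    bait row is always a true interactor), and a protein-length map for NSAF.
    Fully reproducible from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins

    accs = [f"SIM{i:04d}" for i in range(n)]
    true_idx = rng.choice(n, size=cfg.n_true, replace=False)
    is_true = np.zeros(n, dtype=bool)
    is_true[true_idx] = True

    mu = np.log(cfg.base_mean) - _BASELINE_SIGMA**2 / 2  # log-normal with mean base_mean
    baseline = rng.lognormal(mu, _BASELINE_SIGMA, size=n)
    bait_mean = np.where(is_true, baseline * cfg.fold, baseline)

    n_rep = cfg.n_replicates
    spc = np.zeros((n + 1, 2 * n_rep), dtype=np.int64)
    for r in range(n_rep):
        spc[:n, r] = _nb_counts(rng, bait_mean, cfg.dispersion)
        spc[:n, n_rep + r] = _nb_counts(rng, baseline, cfg.dispersion)
    # bait protein: abundant in its own IP, absent from the control IP
    spc[n, :n_rep] = _nb_counts(rng, np.full(n_rep, _BAIT_ROW_MEAN), cfg.dispersion)
    spc[n, n_rep:] = 0

    pep = rng.binomial(spc, cfg.peptide_ratio)
    pep = np.where(spc > 0, np.maximum(pep, 1), 0)

    all_accs = accs + [BAIT_ACCESSION]
    proteins = [ProteinRecord(accession=a, gene_symbol=a) for a in all_accs]
    samples = [
        SampleMeta(sample_id=f"bait_{r + 1}", condition="bait", replicate_index=r + 1)
        for r in range(n_rep)
    ] + [
        SampleMeta(sample_id=f"ctrl_{r + 1}", condition="control", replicate_index=r + 1)
        for r in range(n_rep)
    ]
    table = SpectralCountTable(
        proteins=proteins, samples=samples, spc=spc, unique_peptides=pep
    )
    lengths = {a: int(L) for a, L in zip(all_accs, rng.integers(100, 1501, size=n + 1))}
    truth = SimulationTruth(
        true_interactors={accs[i] for i in true_idx} | {BAIT_ACCESSION},
        config=cfg,
    )
    return table, truth, lengths


def evaluate_recovery(
    entries: Sequence[InteractomeEntry], truth: SimulationTruth
) -> tuple[float, float, float]:
    """Sensitivity, specificity and empirical FDR of the strict set vs truth.

    sensitivity = |strict ∩ truth| / |truth|;
    specificity = true negatives over non-truth proteins;
    FDR = |strict \\ truth| / max(|strict|, 1).
    """
    if not truth.true_interactors:
        raise ValueError("empty truth set: sensitivity undefined")
    strict = {e.accession for e in entries if e.category == "strict"}
    universe = {e.accession for e in entries}
    pos = truth.true_interactors & universe
    neg = universe - truth.true_interactors
    sensitivity = len(strict & pos) / len(pos)
    specificity = len(neg - strict) / len(neg) if neg else 1.0
    fdr = len(strict - pos) / max(len(strict), 1)
    return sensitivity, specificity, fdr


def simulate_coloc(
    n_roi: int, pixels: int, true_r: float, seed: int, condition: str = "sim"
) -> list[ROIMeasurement]:
    """Generate ROIs of paired Gaussian pixel intensities with correlation true_r.

    Each ROI draws ``pixels`` bivariate-normal pairs with population
    correlation ``true_r``, shifted and clipped to be non-negative (mean 100,
    sd 10, so clipping is negligible).  Per-ROI sample r converges to
    ``true_r`` as pixel count grows.
    """
    if not -1 <= true_r <= 1:
        raise ValueError("true_r must lie in [-1, 1]")
    if pixels < 3:
        raise ValueError("need at least 3 pixels per ROI")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, true_r], [true_r, 1.0]])
    rois = []
    for k in range(n_roi):
        xy = rng.multivariate_normal([0.0, 0.0], cov, size=pixels)  # svd handles |r| = 1
        intensities = np.clip(100.0 + 10.0 * xy, 0.0, None)
        rois.append(
            ROIMeasurement(
                roi_id=f"roi{k:03d}",
                condition=condition,
                ch1=intensities[:, 0],
                ch2=intensities[:, 1],
            )
        )
    return rois
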