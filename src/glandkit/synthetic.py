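"""Seeded generators for every pipeline input, with ground truth attached.

Each generator returns plain tables in the formats the analysis modules
read, plus the truth needed to verify recovery: planted subtraction-group
labels, true compound masses, true kinetic slopes, intended phenotype
strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import GROUP_HIGH_LOW, SAMPLES
from .volatiles import (ALKENE_COMPONENTS, DEFAULT_REGISTRY, MAIN_COMPONENTS,
                        Compound)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_expression_library",
    "generate_gcms_run",
    "generate_po_traces",
    "generate_phenotype_dataset",
]

S1, S2, S3, S4, S5, S6 = SAMPLES


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters for the synthetic six-sample expression library."""

    seed: int = 0
    n_background_genes: int = 1000
    group_sizes: tuple[int, ...] = (0,) * 10
    baseline_reads: float = 10.0  # mean background count
    planted_fc: float = 64.0  # fold multiplier of the planted signal
    margin: float = 2.0  # extra factor above planted_fc for robustness
    read_length: int = 38
    noise_model: str = "negative_binomial"  # or "poisson" or "fixed"
    dispersion: float = 0.3  # NB overdispersion: var = mu + dispersion*mu^2

    def __post_init__(self):
        if len(self.group_sizes) != 10:
            raise ValueError("group_sizes must have exactly 10 entries")
        if any(g < 0 for g in self.group_sizes):
            raise ValueError("group_sizes entries must be non-negative")
        if not np.isfinite(self.baseline_reads) or self.baseline_reads <= 0:
            raise ValueError("baseline_reads must be positive and finite")
        if self.planted_fc < 2.0:
            raise ValueError("planted_fc must be at least 2")
        if self.margin < 1.0:
            raise ValueError("margin must be at least 1")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be non-negative")
        if self.noise_model not in ("negative_binomial", "poisson", "fixed"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model == "negative_binomial" and self.dispersion <= 0:
            raise ValueError("negative-binomial dispersion must be positive")


@dataclass
class GroundTruth:
    """What was planted: labels, masses, slopes, strengths (as applicable)."""

    group_labels: dict[str, int | None] = field(default_factory=dict)
    compound_masses: dict[str, float] = field(default_factory=dict)
    trace_slopes: dict[str, float] = field(default_factory=dict)
    strengths: dict[str, int] = field(default_factory=dict)


def _draw_counts(rng: np.random.Generator, mean: float, size,
                 noise_model: str, dispersion: float) -> np.ndarray:
    if noise_model == "fixed":
        return np.full(size, round(mean), dtype=np.int64)
    if noise_model == "poisson":
        return rng.poisson(mean, size=size)
    # negative binomial with var = mu + dispersion*mu^2
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


# per group: samples set to the high planted level; unnamed samples stay at
# the gene's low level.  s2 follows the gland pattern for groups 1 and 2 so
# planted genes do not leak into group 10.
_PLANT_HIGH: dict[int, tuple[str, ...]] = {
    g: highs for g, (highs, _) in GROUP_HIGH_LOW.items()
}
_PLANT_HIGH[1] = (S2, S3, S4, S5, S6)
_PLANT_HIGH[2] = (S2, S3, S4)
_PLANT_HIGH[10] = (S2,)


def generate_expression_library(cfg: SimulationConfig
                                ) -> tuple[pd.DataFrame, GroundTruth]:
    """Six-sample read-count library with planted subtraction-group genes.

    Background genes draw all six counts independently from the noise model
    (exchangeable across samples).  A planted gene draws one low level
    shared by its low-side samples, and its high-side samples get
    ``(low + 1) * planted_fc * margin`` reads, which guarantees the group's
    defining inequalities under a pseudocount of one.
    """
    rng = np.random.default_rng(cfg.seed)
    rows: list[dict] = []
    truth = GroundTruth()

    for group, n_genes in enumerate(cfg.group_sizes, start=1):
        highs = _PLANT_HIGH[group]
        for i in range(n_genes):
            gene = f"G{group:02d}_{i:04d}"
            low = int(_draw_counts(rng, cfg.baseline_reads, (), cfg.noise_model,
                                   cfg.dispersion))
            high = int(np.ceil((low + 1) * cfg.planted_fc * cfg.margin))
            counts = {s: (high if s in highs else low) for s in SAMPLES}
            rows.append({"gene_id": gene,
                         "transcript_length": int(rng.integers(500, 3001)),
                         **counts})
            truth.group_labels[gene] = group

    bg = _draw_counts(rng, cfg.baseline_reads,
                      (cfg.n_background_genes, len(SAMPLES)),
                      cfg.noise_model, cfg.dispersion)
    for i in range(cfg.n_background_genes):
        gene = f"BG_{i:05d}"
        rows.append({"gene_id": gene,
                     "transcript_length": int(rng.integers(500, 3001)),
                     **{s: int(bg[i, j]) for j, s in enumerate(SAMPLES)}})
        truth.group_labels[gene] = None

    library = pd.DataFrame(rows,
                           columns=["gene_id", "transcript_length", *SAMPLES])
    return library, truth


def generate_gcms_run(true_masses: Mapping[str, float],
                      curve_params: Mapping[str, tuple[float, float]],
                      noise_sd: float = 0.0, seed: int | None = None,
                      registry: Mapping[str, Compound] = DEFAULT_REGISTRY,
                      standard_amounts: Sequence[float] = (2.0, 5.0, 10.0,
                                                           20.0, 50.0),
                      sample_id: str = "sample",
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one GC-MS run: a sample peak table plus a standard series.

    ``curve_params`` maps standard compounds to (slope, intercept) of the
    linear area response.  Each sample compound's area comes from the curve
    of its calibration surrogate, so a noiseless run round-trips exactly
    through calibration and quantification.  ``noise_sd`` is relative
    (multiplicative Gaussian).  Compounds with zero true mass emit no peak.
    """
    rng = np.random.default_rng(seed)
    if len(standard_amounts) < 2:
        raise ValueError("need at least two standard levels")

    def jitter(area: float) -> float:
        if noise_sd == 0:
            return area
        return area * (1.0 + rng.normal(0.0, noise_sd))

    std_rows = []
    for comp, (slope, intercept) in curve_params.items():
        if slope <= 0:
            raise ValueError(f"non-positive slope for standard {comp!r}")
        for amount in standard_amounts:
            std_rows.append({"compound": comp, "amount_ng": float(amount),
                             "area": jitter(slope * amount + intercept)})
    standards = pd.DataFrame(std_rows)

    peak_rows = []
    for comp, mass in true_masses.items():
        if comp not in registry:
            raise KeyError(f"unknown compound {comp!r}")
        if mass < 0:
            raise ValueError("true masses must be non-negative")
        if mass == 0:
            continue
        surrogate = registry[comp].surrogate
        if surrogate not in curve_params:
            raise KeyError(f"no curve parameters for required standard "
                           f"{surrogate!r} (surrogate of {comp!r})")
        slope, intercept = curve_params[surrogate]
        ri = registry[comp].retention_indices[0]
        peak_rows.append({"sample_id": sample_id, "compound": comp,
                          "retention_index": float(ri),
                          "area": jitter(slope * mass + intercept)})
    peaks = pd.DataFrame(peak_rows, columns=["sample_id", "compound",
                                             "retention_index", "area"])
    return peaks, standards


def generate_po_traces(true_vmax: float, lag_min: float = 0.0,
                       plateau_od: float | None = None,
                       noise_sd: float = 0.0, seed: int | None = None,
                       n_samples: int = 1, n_blanks: int = 3,
                       drift_per_min: float = 0.001,
                       group: str = "wt") -> tuple[pd.DataFrame, GroundTruth]:
    """Kinetic plate with lag/linear/plateau sample traces and paired blanks.

    Blanks carry only the substrate self-darkening drift; sample wells add a
    piecewise-linear signal of slope ``true_vmax`` starting at ``lag_min``
    and capped at ``plateau_od`` (no cap when None).  Readings every 2 min
    for 90 min (46 timepoints).
    """
    if true_vmax <= 0:
        raise ValueError("true_vmax must be positive for signal traces")
    rng = np.random.default_rng(seed)
    minutes = np.arange(0, 91, 2, dtype=float)  # 46 points
    truth = GroundTruth()

    def noise(size):
        return rng.normal(0.0, noise_sd, size) if noise_sd else np.zeros(size)

    rows = []
    for b in range(n_blanks):
        od = drift_per_min * minutes + noise(minutes.size)
        well = f"blank_{b:02d}"
        for t, v in zip(minutes, od):
            rows.append({"well": well, "group": "blank", "minute": t,
                         "od490": v, "is_blank": True})
    for i in range(n_samples):
        signal = np.clip(true_vmax * (minutes - lag_min), 0.0, None)
        if plateau_od is not None:
            signal = np.minimum(signal, plateau_od)
        od = drift_per_min * minutes + signal + noise(minutes.size)
        well = f"{group}_{i:02d}"
        truth.trace_slopes[well] = true_vmax
        for t, v in zip(minutes, od):
            rows.append({"well": well, "group": group, "minute": t,
                         "od490": v, "is_blank": False})
    return pd.DataFrame(rows), truth


# per-beetle relative-level bands used to plant each intended strength
_STRONG_BAND = (0.08, 0.20)  # 80-92% reduction: strength-2 evidence
_MODERATE_BAND = (0.35, 0.65)  # 35-65% reduction: strength-4 evidence
_QUIET_BAND = (0.92, 1.08)  # inside the 25% no-change zone


def generate_phenotype_dataset(strength_per_gene: Mapping[str, int],
                               n_beetles: int = 4, seed: int | None = None,
                               glands: Sequence[str] = ("thoracic",
                                                        "abdominal"),
                               ) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-beetle relative chemical levels planting a known strength 1-5.

    Strength 1 zeroes one component in every beetle; 2 reduces it into the
    75-95% band; 3 plants the strong effect in a strict subset of beetles
    (requires ``n_beetles`` >= 2); 4 plants a 35-65% reduction; 5 keeps all
    components inside the 25% band.  Strength 6 (uncloned/untested) has no
    data to simulate and is rejected.
    """
    if n_beetles < 2:
        raise ValueError("need at least two beetles")
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    rows = []
    target = MAIN_COMPONENTS[0]  # component carrying the planted effect

    for gene, strength in strength_per_gene.items():
        if strength not in (1, 2, 3, 4, 5):
            raise ValueError(
                f"strength {strength} cannot be simulated as data "
                "(6 means uncloned or untested)")
        truth.strengths[gene] = strength
        affected = set(range(n_beetles))
        if strength == 3:
            affected = set(range(max(1, n_beetles // 2)))  # strict subset
        for beetle in range(n_beetles):
            for gland in glands:
                for comp in MAIN_COMPONENTS:
                    level = float(rng.uniform(*_QUIET_BAND))
                    if comp == target and beetle in affected:
                        if strength == 1:
                            level = 0.0
                        elif strength in (2, 3):
                            level = float(rng.uniform(*_STRONG_BAND))
                        elif strength == 4:
                            level = float(rng.uniform(*_MODERATE_BAND))
                    rows.append({"gene": gene, "beetle": beetle,
                                 "gland": gland, "compound": comp,
                                 "relative_level": level})
    return pd.DataFrame(rows), truth
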