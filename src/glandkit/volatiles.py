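"""GC-MS volatile quantification: calibration, peak matching, masses, moles.

The compound registry carries the main gland volatiles with their molecular
weights and retention indices.  Compounds lacking an authentic standard are
quantified as equivalents through the curve of a structurally similar
surrogate (EBQ through the EHQ curve, heptadecadiene through the
heptadecene curve).

Units: standard amounts and back-calculated masses are nanograms unless
noted; :func:`molar_totals` and :func:`compositional_stats` take masses in
micrograms and report nanomoles, matching the reporting convention of the
summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import rank_sum_test, welch_ttest

__all__ = [
    "Compound",
    "CalibrationCurve",
    "DEFAULT_REGISTRY",
    "QUINONE_COMPONENTS",
    "ALKENE_COMPONENTS",
    "MAIN_COMPONENTS",
    "fit_calibration",
    "match_peak",
    "quantify",
    "sum_quinones",
    "molar_totals",
    "mbq_ebq_molar_ratio",
    "compositional_stats",
    "compare_groups",
    "compare_sexes",
]


@dataclass(frozen=True)
class Compound:
    name: str
    molecular_weight: float  # g/mol
    retention_indices: tuple[int, ...]  # one or two aliases
    calibration_surrogate: str | None = None  # standard whose curve is used
    quantified: bool = True  # part of the five-component quantification

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")

    @property
    def surrogate(self) -> str:
        return self.calibration_surrogate or self.name


def _registry(compounds: Iterable[Compound]) -> dict[str, Compound]:
    return {c.name: c for c in compounds}


#: main gland volatiles; short keys: MBQ/EBQ benzoquinones, MHQ/EHQ their
#: hydroquinone precursors, 15ene/17diene/17ene the alkenes.
DEFAULT_REGISTRY: dict[str, Compound] = _registry([
    Compound("MBQ", 122.04, (1011, 1018)),
    Compound("EBQ", 136.05, (1098, 1109), calibration_surrogate="EHQ"),
    Compound("MHQ", 124.05, (1350, 1367)),
    Compound("EHQ", 138.07, (1432,)),
    Compound("15diene", 208.38, (1477,), quantified=False),
    Compound("15ene", 210.24, (1492,)),
    Compound("DMPB", 180.12, (1552,), quantified=False),
    Compound("16ene", 224.25, (1593,), quantified=False),
    Compound("17diene", 236.25, (1663, 1672), calibration_surrogate="17ene"),
    Compound("17ene", 238.27, (1693,)),
])

#: summed-quinone components: benzoquinone plus its hydroquinone precursor;
#: the sum is converted to moles with the benzoquinone molecular weight.
QUINONE_COMPONENTS = {"MBQ_sum": ("MBQ", "MHQ"), "EBQ_sum": ("EBQ", "EHQ")}
ALKENE_COMPONENTS = ("15ene", "17diene", "17ene")
MAIN_COMPONENTS = ("MBQ_sum", "EBQ_sum") + ALKENE_COMPONENTS

#: molecular weight used for each reported component (µg -> nmol)
COMPONENT_MW = {
    "MBQ_sum": 122.04,
    "EBQ_sum": 136.05,
    "15ene": 210.24,
    "17diene": 236.25,
    "17ene": 238.27,
}


@dataclass(frozen=True)
class CalibrationCurve:
    compound: str
    slope: float  # area per ng
    intercept: float  # area
    r_squared: float
    n_points: int

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


def fit_calibration(standards: Sequence[tuple[float, float]] | pd.DataFrame,
                    compound: str = "") -> CalibrationCurve:
    """Ordinary least-squares line through (amount_ng, area) standard points."""
    if isinstance(standards, pd.DataFrame):
        pairs = standards[["amount_ng", "area"]].to_numpy(dtype=float)
    else:
        pairs = np.asarray(standards, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 2:
        raise ValueError("need at least two (amount, area) pairs")
    amounts, areas = pairs[:, 0], pairs[:, 1]
    if np.unique(amounts).size < 2:
        raise ValueError("degenerate design: all standard amounts equal")
    fit = sps.linregress(amounts, areas)
    return CalibrationCurve(compound, float(fit.slope), float(fit.intercept),
                            float(fit.rvalue) ** 2, len(pairs))


def fit_standard_series(standards: pd.DataFrame) -> dict[str, CalibrationCurve]:
    """Fit one curve per compound from a long table (compound, amount_ng, area)."""
    return {name: fit_calibration(grp, name)
            for name, grp in standards.groupby("compound", sort=False)}


def match_peak(retention_index: float,
               registry: Mapping[str, Compound] = DEFAULT_REGISTRY,
               tolerance: float = 5.0) -> str | None:
    """Nearest-alias compound match within ``tolerance`` RI units.

    Dual retention indices are aliases of one compound.  An exact tie
    between two different compounds is unresolvable and returns None.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    best: tuple[float, str] | None = None
    tied = False
    for comp in registry.values():
        d = min(abs(retention_index - ri) for ri in comp.retention_indices)
        if d > tolerance:
            continue
        if best is None or d < best[0]:
            best, tied = (d, comp.name), False
        elif d == best[0] and comp.name != best[1]:
            tied = True
    if best is None or tied:
        return None
    return best[1]


def quantify(peak_area: float, curve: CalibrationCurve) -> float:
    """Back-calculate mass (ng) from a peak area; negative masses clip to 0."""
    return max(0.0, (peak_area - curve.intercept) / curve.slope)


def quantify_peaks(peaks: pd.DataFrame,
                   curves: Mapping[str, CalibrationCurve],
                   registry: Mapping[str, Compound] = DEFAULT_REGISTRY,
                   ri_tolerance: float = 5.0) -> pd.DataFrame:
    """Turn a peak table into per-sample compound masses (ng).

    ``peaks`` needs columns ``sample_id`` and ``area`` plus either
    ``compound`` or ``retention_index``.  Unmatched peaks and compounds
    excluded from quantification are dropped.  Each quantified compound is
    resolved through its surrogate's curve; a missing surrogate curve is an
    error.
    """
    df = peaks.copy()
    if "compound" not in df.columns:
        if "retention_index" not in df.columns:
            raise ValueError("peak table needs a compound or retention_index column")
        df["compound"] = [match_peak(ri, registry, ri_tolerance)
                          for ri in df["retention_index"]]
        df = df.dropna(subset=["compound"])
    df = df[df["compound"].map(lambda c: c in registry and registry[c].quantified)]
    masses = []
    for _, row in df.iterrows():
        comp = registry[row["compound"]]
        if comp.surrogate not in curves:
            raise KeyError(f"no calibration curve for {comp.surrogate!r} "
                           f"(surrogate of {comp.name!r})")
        masses.append(quantify(row["area"], curves[comp.surrogate]))
    df = df.assign(mass_ng=masses)
    return (df.groupby(["sample_id", "compound"], sort=False)["mass_ng"]
            .sum().reset_index())


def sum_quinones(masses: Mapping[str, float]) -> dict[str, float]:
    """Collapse per-species masses to the reported five main components.

    Hydroquinones are precursors of the corresponding benzoquinones, so the
    pair is summed and reported as one secreted-quinone component.
    """
    out = {}
    for comp, parts in QUINONE_COMPONENTS.items():
        out[comp] = float(sum(masses.get(p, 0.0) for p in parts))
    for comp in ALKENE_COMPONENTS:
        out[comp] = float(masses.get(comp, 0.0))
    return out


def molar_totals(component_masses_ug: Mapping[str, float]) -> tuple[float, float]:
    """(quinones_nmol, alkenes_nmol) from main-component masses in µg."""
    missing = [c for c in MAIN_COMPONENTS if c not in component_masses_ug]
    if missing:
        raise KeyError(f"missing component masses: {missing}")
    quinones = sum(1000.0 * component_masses_ug[c] / COMPONENT_MW[c]
                   for c in QUINONE_COMPONENTS)
    alkenes = sum(1000.0 * component_masses_ug[c] / COMPONENT_MW[c]
                  for c in ALKENE_COMPONENTS)
    return float(quinones), float(alkenes)


def mbq_ebq_molar_ratio(mbq_sum_ug: float, ebq_sum_ug: float) -> float:
    """Molar ratio of summed MBQ to summed EBQ (benzoquinone MWs)."""
    if ebq_sum_ug <= 0:
        raise ValueError("EBQ mass must be positive")
    return (mbq_sum_ug / COMPONENT_MW["MBQ_sum"]) / \
        (ebq_sum_ug / COMPONENT_MW["EBQ_sum"])


def alkene_fractions(component_masses_ug: Mapping[str, float]) -> dict[str, float]:
    """Molar fraction of each alkene among all alkenes; NaN if none present."""
    nmol = {c: 1000.0 * component_masses_ug.get(c, 0.0) / COMPONENT_MW[c]
            for c in ALKENE_COMPONENTS}
    total = sum(nmol.values())
    if total == 0:
        return {c: float("nan") for c in ALKENE_COMPONENTS}
    return {c: v / total for c, v in nmol.items()}


def compositional_stats(profiles: pd.DataFrame) -> pd.DataFrame:
    """Compositional summary per sex x gland plus whole-beetle rows.

    ``profiles`` holds one row per observation with columns ``sex``,
    ``gland`` and the five main components in µg.  Statistics are computed
    on group means (whole-beetle rows sum the per-gland means).  Reported per
    row: MBQ/EBQ molar ratio, quinone/alkene molar ratio, alkene molar
    fractions, quinone weight fraction, and each gland's share of the
    whole-beetle molar totals.
    """
    for col in ("sex", "gland", *MAIN_COMPONENTS):
        if col not in profiles.columns:
            raise ValueError(f"profiles missing column {col!r}")
    if profiles.empty:
        raise ValueError("no profiles given")

    means = profiles.groupby(["sex", "gland"])[list(MAIN_COMPONENTS)].mean()
    rows = []
    for sex, per_gland in means.groupby(level="sex"):
        per_gland = per_gland.droplevel("sex")
        whole = per_gland.sum(axis=0)
        totals = {g: molar_totals(per_gland.loc[g]) for g in per_gland.index}
        whole_q, whole_a = molar_totals(whole)
        for gland, masses in per_gland.iterrows():
            q, a = totals[gland]
            rows.append(_compo_row(sex, gland, masses, q, a,
                                   q / whole_q if whole_q else np.nan,
                                   a / whole_a if whole_a else np.nan))
        rows.append(_compo_row(sex, "whole", whole, whole_q, whole_a, 1.0, 1.0))
    return pd.DataFrame(rows)


def _compo_row(sex, gland, masses, quinones_nmol, alkenes_nmol,
               quinone_share, alkene_share) -> dict:
    mbq_nmol = 1000.0 * masses["MBQ_sum"] / COMPONENT_MW["MBQ_sum"]
    ebq_nmol = 1000.0 * masses["EBQ_sum"] / COMPONENT_MW["EBQ_sum"]
    total_mass = float(sum(masses[c] for c in MAIN_COMPONENTS))
    quinone_mass = float(masses["MBQ_sum"] + masses["EBQ_sum"])
    row = {
        "sex": sex,
        "gland": gland,
        "quinones_nmol": quinones_nmol,
        "alkenes_nmol": alkenes_nmol,
        "mbq_ebq_molar_ratio": mbq_nmol / ebq_nmol if ebq_nmol else np.nan,
        "quinone_alkene_molar_ratio": (quinones_nmol / alkenes_nmol
                                       if alkenes_nmol else np.nan),
        "quinone_weight_fraction": (quinone_mass / total_mass
                                    if total_mass else np.nan),
        "quinone_share_of_beetle": quinone_share,
        "alkene_share_of_beetle": alkene_share,
    }
    row.update({f"frac_{c}": v for c, v in alkene_fractions(masses).items()})
    return row


def compare_groups(reference: pd.DataFrame, other: pd.DataFrame,
                   components: Sequence[str] = MAIN_COMPONENTS) -> pd.DataFrame:
    """Two-sided rank-sum p-value per component, reference vs other group."""
    rows = []
    for comp in components:
        res = rank_sum_test(reference[comp], other[comp])
        rows.append({"component": comp, "pvalue": res.pvalue,
                     "method": res.method})
    return pd.DataFrame(rows)


def compare_sexes(profiles: pd.DataFrame,
                  components: Sequence[str] = MAIN_COMPONENTS) -> pd.DataFrame:
    """Welch t-test p-value per component, males vs females."""
    males = profiles[profiles["sex"] == "male"]
    females = profiles[profiles["sex"] == "female"]
    rows = []
    for comp in components:
        res = welch_ttest(males[comp], females[comp])
        rows.append({"component": comp, "pvalue": res.pvalue,
                     "t": res.statistic})
    return pd.DataFrame(rows)
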