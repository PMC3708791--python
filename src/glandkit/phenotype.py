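"""RNAi phenotype-strength classification from per-beetle chemical changes.

Levels are relative: knock-down amount divided by the control mean for the
same compound and gland.  Strength scale:

    1  very strong — a compound undetectable or <=5% left in every beetle
    2  strong      — a compound reduced by >=75% (to <=25% left) or
                     increased by >75% in every beetle
    3  strong/very strong but only in a strict subset of the beetles
    4  some changes — a compound 25-75% reduced or increased in the
                     majority of beetles
    5  neglectable — every change below 25%
    6  uncloned or untested

Evidence from either gland counts; boundaries are inclusive on the strong
side (a reduction of exactly 75% is strength 2, exactly 25% is strength 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STRENGTH_LABELS",
    "component_change",
    "classify_strength",
    "cohort_summary",
]

STRENGTH_LABELS = {
    1: "very strong",
    2: "strong",
    3: "strong, occasional",
    4: "some changes",
    5: "neglectable changes",
    6: "uncloned or untested",
}

# relative-level thresholds (level = kd / control mean)
UNDETECTABLE = 0.05  # <=5% left
STRONG_LOW, STRONG_HIGH = 0.25, 1.75  # >=75% reduction / >75% increase
MODERATE_LOW, MODERATE_HIGH = 0.75, 1.25  # 25% change either way


def component_change(kd_amount: float, control_mean: float) -> float:
    """Signed relative change (kd - control) / control; -1 is undetectable."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    if kd_amount < 0:
        raise ValueError("knock-down amount must be non-negative")
    return (kd_amount - control_mean) / control_mean


def _beetle_evidence(levels: np.ndarray) -> tuple[bool, bool, bool]:
    """(very_strong, strong, moderate) evidence flags for one beetle."""
    very_strong = bool(np.any(levels <= UNDETECTABLE))
    strong = very_strong or bool(np.any(levels <= STRONG_LOW)
                                 or np.any(levels >= STRONG_HIGH))
    moderate = bool(np.any((levels <= MODERATE_LOW) & (levels > STRONG_LOW))
                    or np.any((levels >= MODERATE_HIGH) & (levels < STRONG_HIGH)))
    return very_strong, strong, moderate


def classify_strength(record: pd.DataFrame | None,
                      penetrance_threshold: float = 0.0,
                      tested: bool = True) -> int:
    """Assign a phenotype strength 1-6 to one gene.

    ``record`` holds one row per (beetle, gland, compound) with columns
    ``beetle`` and ``relative_level``; evidence from any gland or compound
    counts for a beetle.  ``penetrance_threshold`` is the minimum fraction
    of beetles with strong evidence required for strength 3 (the default
    accepts a single beetle).
    """
    if not tested or record is None:
        return 6
    if record.empty:
        raise ValueError("tested gene with no beetle measurements")
    if (record["relative_level"] < 0).any():
        raise ValueError("relative levels must be non-negative")

    very_strong, strong, moderate = [], [], []
    for _, grp in record.groupby("beetle", sort=False):
        vs, st, mo = _beetle_evidence(grp["relative_level"].to_numpy(dtype=float))
        very_strong.append(vs)
        strong.append(st)
        moderate.append(mo)

    n = len(strong)
    if all(strong):
        return 1 if all(very_strong) else 2
    n_strong = sum(strong)
    if n_strong and n_strong / n >= penetrance_threshold:
        return 3
    n_moderate = sum(m or s for m, s in zip(moderate, strong))
    if n_moderate / n >= 0.5:
        return 4
    return 5


def cohort_summary(strengths: pd.Series | dict) -> pd.DataFrame:
    """Tabulate strengths 1-6 plus the strong (1-3) and altered (1-4) totals.

    Percentages are relative to the tested genes (strengths 1-5).
    """
    s = pd.Series(strengths, dtype="Int64")
    counts = s.value_counts().reindex(range(1, 7), fill_value=0)
    n_tested = int(counts.loc[1:5].sum())

    def pct(k: int) -> float:
        return 100.0 * k / n_tested if n_tested else 0.0

    rows = [{"category": STRENGTH_LABELS[i], "strength": str(i),
             "n_genes": int(counts[i]),
             "percent_of_tested": pct(int(counts[i])) if i <= 5 else np.nan}
            for i in range(1, 7)]
    strong = int(counts.loc[1:3].sum())
    altered = int(counts.loc[1:4].sum())
    rows.append({"category": "strong (1-3)", "strength": "1-3",
                 "n_genes": strong, "percent_of_tested": pct(strong)})
    rows.append({"category": "any alteration (1-4)", "strength": "1-4",
                 "n_genes": altered, "percent_of_tested": pct(altered)})
    return pd.DataFrame(rows)
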