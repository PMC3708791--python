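"""Phenol-oxidase microplate kinetics and inhibition-zone statistics.

Kinetic plates are long tables with columns ``well``, ``group``, ``minute``,
``od490`` and ``is_blank`` (readings every 2 min for 90 min).  Substrate
self-darkening is removed by subtracting the mean blank trace; activity is
the maximum least-squares slope (Vmax, OD/min) over all contiguous windows
of a fixed width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import rank_sum_test, significance_stars, welch_ttest

__all__ = [
    "blank_correct",
    "po_vmax",
    "po_vmax_window",
    "plate_vmax",
    "po_group_stats",
    "zone_compare",
]

DEFAULT_WINDOW_POINTS = 10  # 20 minutes at 2-min readings


def blank_correct(trace: pd.DataFrame, blank: pd.DataFrame) -> pd.DataFrame:
    """Pointwise subtraction of a (mean) blank trace on the same time grid."""
    t = trace.sort_values("minute").reset_index(drop=True)
    b = blank.sort_values("minute").reset_index(drop=True)
    if len(t) != len(b) or not np.array_equal(t["minute"].to_numpy(),
                                              b["minute"].to_numpy()):
        raise ValueError("trace and blank are on different time grids")
    out = t.copy()
    out["od490"] = t["od490"].to_numpy() - b["od490"].to_numpy()
    return out


def mean_blank(plate: pd.DataFrame) -> pd.DataFrame:
    """Average all blank wells of a plate into one trace."""
    blanks = plate[plate["is_blank"]]
    if blanks.empty:
        raise ValueError("plate has no blank wells")
    return (blanks.groupby("minute", sort=True)["od490"]
            .mean().reset_index())


def po_vmax_window(minutes, od490,
                   window_points: int = DEFAULT_WINDOW_POINTS
                   ) -> tuple[float, tuple[float, float]]:
    """Best linear-phase slope and the (start, end) minutes of its window.

    Scans every contiguous window of ``window_points`` readings, fits an
    ordinary least-squares line, and returns the maximum slope clipped at 0.
    """
    t = np.asarray(minutes, dtype=float)
    y = np.asarray(od490, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("minutes and od490 must be 1-D and equally long")
    if window_points < 3:
        raise ValueError("window must span at least 3 points")
    if window_points > t.size:
        raise ValueError("window longer than trace")
    order = np.argsort(t)
    t, y = t[order], y[order]
    best_slope, best_win = -np.inf, (t[0], t[window_points - 1])
    for i in range(t.size - window_points + 1):
        tw = t[i:i + window_points]
        yw = y[i:i + window_points]
        slope = np.polyfit(tw, yw, 1)[0]
        if slope > best_slope:
            best_slope, best_win = slope, (float(tw[0]), float(tw[-1]))
    return max(0.0, float(best_slope)), best_win


def po_vmax(minutes, od490,
            window_points: int = DEFAULT_WINDOW_POINTS) -> float:
    """Vmax (OD/min) of the linear phase; see :func:`po_vmax_window`."""
    return po_vmax_window(minutes, od490, window_points)[0]


def plate_vmax(plate: pd.DataFrame,
               window_points: int = DEFAULT_WINDOW_POINTS) -> pd.DataFrame:
    """Blank-correct every sample well of a plate and estimate its Vmax."""
    blank = mean_blank(plate)
    rows = []
    for (well, group), grp in (plate[~plate["is_blank"]]
                               .groupby(["well", "group"], sort=False)):
        corrected = blank_correct(grp[["minute", "od490"]], blank)
        vmax, window = po_vmax_window(corrected["minute"],
                                      corrected["od490"], window_points)
        rows.append({"well": well, "group": group, "vmax": vmax,
                     "window_start": window[0], "window_end": window[1]})
    return pd.DataFrame(rows)


def po_group_stats(vmax_table: pd.DataFrame,
                   wild_type: str = "wt") -> pd.DataFrame:
    """Square-root transformed per-group summary and Welch t-tests vs wild-type.

    ``vmax_table`` has columns ``group`` and ``vmax``.  Groups with a single
    well are summarized but their test is skipped (p = NaN).
    """
    if wild_type not in set(vmax_table["group"]):
        raise ValueError(f"wild-type group {wild_type!r} missing")
    wt = np.sqrt(vmax_table.loc[vmax_table["group"] == wild_type,
                                "vmax"].to_numpy(dtype=float))
    rows = []
    for group, grp in vmax_table.groupby("group", sort=False):
        root = np.sqrt(grp["vmax"].to_numpy(dtype=float))
        q1, med, q3 = np.percentile(root, [25, 50, 75])
        row = {
            "group": group, "n": root.size,
            "mean_sqrt_vmax": float(root.mean()),
            "sd_sqrt_vmax": float(root.std(ddof=1)) if root.size > 1 else np.nan,
            "q1": float(q1), "median": float(med), "q3": float(q3),
            "pvalue": np.nan, "stars": "",
        }
        if group != wild_type:
            if root.size < 2 or wt.size < 2:
                row["note"] = "test skipped: fewer than 2 wells"
            else:
                res = welch_ttest(wt, root)
                row["pvalue"] = res.pvalue
                row["stars"] = significance_stars(res.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


def zone_compare(zones: pd.DataFrame, wild_type: str = "wt") -> pd.DataFrame:
    """Rank-sum test of each knock-down against the same-sex wild-type.

    ``zones`` has columns ``microbe``, ``sex``, ``group`` and ``area``
    (cm^2).  Stars follow the two-level convention (*** below 0.001, **
    below 0.01).
    """
    if (zones["area"] < 0).any():
        raise ValueError("zone areas must be non-negative")
    rows = []
    for (microbe, sex), cell in zones.groupby(["microbe", "sex"], sort=False):
        wt_areas = cell.loc[cell["group"] == wild_type, "area"]
        for group, grp in cell.groupby("group", sort=False):
            if group == wild_type:
                continue
            if wt_areas.empty:
                raise ValueError(
                    f"no wild-type measurements for {microbe}/{sex}")
            res = rank_sum_test(wt_areas, grp["area"])
            rows.append({
                "microbe": microbe, "sex": sex, "group": group,
                "n_wt": len(wt_areas), "n_kd": len(grp),
                "pvalue": res.pvalue, "method": res.method,
                "stars": significance_stars(res.pvalue, (0.001, 0.01, 0.01)),
            })
    return pd.DataFrame(rows)
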