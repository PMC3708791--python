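"""Published reference tables used as pipeline inputs.

These are transcribed printed values from the original stink-gland study:
the raw sequencing totals of the six libraries, the wild-type per-gland
volatile means, and the per-group gene counts of the subtraction screen.
Only raw quantities are stored; every derived metric (ratios, depths,
molar totals) is recomputed by the analysis modules.
"""

from __future__ import annotations

import pandas as pd

from .expression import SAMPLES

__all__ = [
    "sequencing_summary",
    "gland_volatile_means",
    "subtraction_group_sizes",
]


def sequencing_summary() -> pd.DataFrame:
    """Raw per-library sequencing totals (reads and bases), index = sample."""
    data = {
        "total_reads": [29_527_715, 29_690_989, 28_544_764,
                        29_350_110, 27_929_437, 27_786_784],
        "mapped_reads": [14_727_172, 15_773_797, 14_605_945,
                         15_590_528, 14_327_863, 16_955_288],
        "covered_total_base": [15_746_380, 13_768_019, 13_279_109,
                               12_151_610, 13_943_411, 13_272_086],
        "reference_total_base": [23_149_063] * 6,
    }
    return pd.DataFrame(data, index=pd.Index(SAMPLES, name="sample"))


def gland_volatile_means(include_whole_rows: bool = False) -> pd.DataFrame:
    """Mean wild-type volatile masses (µg) per sex and gland.

    Quinone columns are the summed secreted quinones (benzoquinone plus its
    hydroquinone precursor).  The published whole-beetle rows (gland
    "whole", the per-beetle thr+abd totals as printed, which differ from
    the sum of per-gland means at the last digit) are included only on
    request.
    """
    rows = [
        {"sex": "male", "gland": "thoracic", "MBQ_sum": 5.39,
         "EBQ_sum": 7.08, "15ene": 4.71, "17diene": 2.39, "17ene": 1.08},
        {"sex": "female", "gland": "thoracic", "MBQ_sum": 5.66,
         "EBQ_sum": 7.41, "15ene": 4.80, "17diene": 2.74, "17ene": 1.06},
        {"sex": "male", "gland": "abdominal", "MBQ_sum": 8.43,
         "EBQ_sum": 10.63, "15ene": 9.91, "17diene": 0.51, "17ene": 1.06},
        {"sex": "female", "gland": "abdominal", "MBQ_sum": 7.51,
         "EBQ_sum": 10.84, "15ene": 9.58, "17diene": 0.66, "17ene": 0.94},
    ]
    if include_whole_rows:
        rows += [
            {"sex": "male", "gland": "whole", "MBQ_sum": 13.82,
             "EBQ_sum": 17.71, "15ene": 14.62, "17diene": 2.90,
             "17ene": 2.14},
            {"sex": "female", "gland": "whole", "MBQ_sum": 13.20,
             "EBQ_sum": 18.25, "15ene": 14.31, "17diene": 3.36,
             "17ene": 1.97},
        ]
    return pd.DataFrame(rows)


def subtraction_group_sizes() -> tuple[int, ...]:
    """Published per-group gene counts of the ten-group subtraction screen."""
    return (62, 23, 40, 0, 4, 0, 299, 0, 39, 44)
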