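"""Sequencing-library metrics and the ten-group gland-specificity subtraction.

A library is a :class:`pandas.DataFrame` with one row per gene and columns

    gene_id, transcript_length, s1_ctl, s2_tthr, s3_mthr, s4_fthr,
    s5_mabd, s6_fabd

where the six sample columns hold raw mapped-read counts.  All fold changes
are computed on raw reads (library sizes of the six samples are close enough
that no normalization is applied).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SAMPLES",
    "GLAND_SAMPLES",
    "GROUP_HIGH_LOW",
    "READ_LENGTH",
    "coverage",
    "library_metrics",
    "log2_fold_change",
    "abundant_genes",
    "classify_subtraction_groups",
    "group_summary",
    "fold_change_profile",
    "read_library",
    "write_library",
]

#: canonical sample keys, in column order
SAMPLES = ("s1_ctl", "s2_tthr", "s3_mthr", "s4_fthr", "s5_mabd", "s6_fabd")
#: the four wild-type gland samples
GLAND_SAMPLES = ("s3_mthr", "s4_fthr", "s5_mabd", "s6_fabd")

READ_LENGTH = 38  # bases per sequenced read

S1, S2, S3, S4, S5, S6 = SAMPLES

#: Groups 1-9 as (high-side samples, low-side samples): every high sample
#: must exceed every low sample by the log2 fold-change cutoff.  Group 10
#: (tar-mutant deregulation, two-sided against s3 and s4) is special-cased.
GROUP_HIGH_LOW: dict[int, tuple[tuple[str, ...], tuple[str, ...]]] = {
    1: ((S3, S4, S5, S6), (S1,)),
    2: ((S3, S4), (S5, S6, S1)),
    3: ((S5, S6), (S3, S4, S1)),
    4: ((S3, S5), (S4, S6, S1)),
    5: ((S4, S6), (S3, S5)),  # no control comparison for this group
    6: ((S3,), (S4, S1)),
    7: ((S5,), (S6, S1)),
    8: ((S4,), (S3, S1)),
    9: ((S6,), (S5, S1)),
}


def coverage(reads, transcript_length, read_length: int = READ_LENGTH):
    """Sequencing depth of a transcript: reads x read_length / length."""
    length = np.asarray(transcript_length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("transcript_length must be positive")
    return np.asarray(reads, dtype=float) * read_length / length


def library_metrics(summary: pd.DataFrame, read_length: int = READ_LENGTH,
                    reference_sample: str = S1) -> pd.DataFrame:
    """Derive the per-sample library metrics from raw sequencing totals.

    Parameters
    ----------
    summary
        One row per sample (index = sample key) with columns ``total_reads``,
        ``mapped_reads``, ``covered_total_base`` and ``reference_total_base``.

    Returns a copy with the derived columns ``mapping_ratio``,
    ``total_mapped_bases``, ``covered_ratio``, ``average_depth`` and
    ``relative_total_reads`` (ratio to the control sample) added.
    """
    required = {"total_reads", "mapped_reads", "covered_total_base",
                "reference_total_base"}
    missing = required - set(summary.columns)
    if missing:
        raise ValueError(f"summary is missing columns: {sorted(missing)}")
    if reference_sample not in summary.index:
        raise ValueError(f"reference sample {reference_sample!r} not present")
    if (summary["total_reads"] <= 0).any():
        raise ValueError("total_reads must be positive")
    if (summary["reference_total_base"] <= 0).any():
        raise ValueError("reference_total_base must be positive")
    if (summary["mapped_reads"] > summary["total_reads"]).any():
        raise ValueError("mapped_reads cannot exceed total_reads")
    if (summary["covered_total_base"] > summary["reference_total_base"]).any():
        raise ValueError("covered_total_base cannot exceed reference_total_base")

    out = summary.copy()
    out["mapping_ratio"] = out["mapped_reads"] / out["total_reads"]
    out["total_mapped_bases"] = out["mapped_reads"] * read_length
    out["covered_ratio"] = out["covered_total_base"] / out["reference_total_base"]
    out["average_depth"] = out["total_mapped_bases"] / out["reference_total_base"]
    ref_total = out.loc[reference_sample, "total_reads"]
    out["relative_total_reads"] = out["total_reads"] / ref_total
    return out


def log2_fold_change(reads_a, reads_b, pseudocount: float = 1.0):
    """log2((a + pc) / (b + pc)); antisymmetric under swapping a and b."""
    a = np.asarray(reads_a, dtype=float)
    b = np.asarray(reads_b, dtype=float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and (np.any(a <= 0) or np.any(b <= 0)):
        raise ValueError("zero reads require a positive pseudocount")
    return np.log2(a + pseudocount) - np.log2(b + pseudocount)


def _validate_library(library: pd.DataFrame) -> None:
    missing = [c for c in ("gene_id", "transcript_length", *SAMPLES)
               if c not in library.columns]
    if missing:
        raise ValueError(f"library is missing columns: {missing}")
    counts = library[list(SAMPLES)].to_numpy()
    if not np.isfinite(counts).all() or (counts < 0).any():
        raise ValueError("read counts must be finite and non-negative")
    if (library["transcript_length"] <= 0).any():
        raise ValueError("transcript_length must be positive")


def abundant_genes(library: pd.DataFrame, threshold: float = 50.0,
                   scope: str = "glands",
                   read_length: int = READ_LENGTH) -> set[str]:
    """Genes with coverage strictly above ``threshold``.

    scope "glands": coverage > threshold in every one of s3-s6;
    scope "control": coverage > threshold in s1.
    """
    _validate_library(library)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if scope == "glands":
        samples: Sequence[str] = GLAND_SAMPLES
    elif scope == "control":
        samples = (S1,)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    length = library["transcript_length"]
    mask = np.ones(len(library), dtype=bool)
    for s in samples:
        mask &= coverage(library[s], length, read_length) > threshold
    return set(library.loc[mask, "gene_id"])


def _group_masks(lfc: Mapping[tuple[str, str], np.ndarray],
                 counts: Mapping[str, np.ndarray],
                 cutoff: float, min_reads: float | None) -> dict[int, np.ndarray]:
    """Boolean pass-mask per group for vectorized per-gene evaluation."""
    n = len(next(iter(counts.values())))
    masks: dict[int, np.ndarray] = {}
    for g, (highs, lows) in GROUP_HIGH_LOW.items():
        m = np.ones(n, dtype=bool)
        for h in highs:
            for lo in lows:
                m &= lfc[(h, lo)] >= cutoff
            if min_reads is not None:
                m &= counts[h] >= min_reads
        masks[g] = m
    # Group 10: two-sided deregulation of s2 against both wild-type
    # prothoracic samples.
    m10 = (np.abs(lfc[(S2, S3)]) >= cutoff) & (np.abs(lfc[(S2, S4)]) >= cutoff)
    if min_reads is not None:
        m10 &= np.maximum(counts[S2], counts[S3]) >= min_reads
        m10 &= np.maximum(counts[S2], counts[S4]) >= min_reads
    masks[10] = m10
    return masks


def classify_subtraction_groups(library: pd.DataFrame, cutoff: float = 6.0,
                                pseudocount: float = 1.0,
                                min_reads: float | None = 64.0) -> pd.DataFrame:
    """Assign each gene to at most one of the ten subtraction groups.

    Every inequality is a log2 fold change >= ``cutoff`` with the given
    pseudocount.  ``min_reads`` is an expression floor applied to the
    high-side samples of a group (pass ``None`` to disable).  A gene passing
    several condition sets is assigned the lowest-numbered group
    (first-match in group order), making the assignment non-overlapping.

    Returns a DataFrame with columns ``gene_id``, ``group`` (1-10, or
    pandas NA when unassigned) and ``passing_groups`` (tuple of all groups
    whose conditions held, diagnostic).
    """
    _validate_library(library)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    counts = {s: library[s].to_numpy(dtype=float) for s in SAMPLES}
    pairs = {(a, b) for highs, lows in GROUP_HIGH_LOW.values()
             for a in highs for b in lows}
    pairs |= {(S2, S3), (S2, S4)}
    lfc = {pair: log2_fold_change(counts[pair[0]], counts[pair[1]], pseudocount)
           for pair in pairs}
    masks = _group_masks(lfc, counts, cutoff, min_reads)

    passing = [tuple(g for g in range(1, 11) if masks[g][i])
               for i in range(len(library))]
    assigned = [p[0] if p else None for p in passing]
    return pd.DataFrame({
        "gene_id": library["gene_id"].to_numpy(),
        "group": pd.array(assigned, dtype="Int64"),
        "passing_groups": passing,
    })


def group_summary(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-group gene counts and percentages of all assigned genes."""
    assigned = assignments.dropna(subset=["group"])
    counts = assigned["group"].value_counts().reindex(range(1, 11), fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame({
        "group": counts.index,
        "n_genes": counts.to_numpy(dtype=int),
        "percent": 100.0 * counts.to_numpy() / total if total else 0.0,
    }).reset_index(drop=True)


def fold_change_profile(gene_ids: Iterable[str], library: pd.DataFrame,
                        pseudocount: float = 1.0) -> pd.DataFrame:
    """log2 fold change of each gland sample (and s2) against the control.

    One row per requested gene; columns s3-s6 and s2, each versus s1.
    """
    _validate_library(library)
    gene_ids = list(gene_ids)
    indexed = library.set_index("gene_id")
    unknown = [g for g in gene_ids if g not in indexed.index]
    if unknown:
        raise KeyError(f"unknown gene_id(s): {unknown}")
    sub = indexed.loc[gene_ids]
    data = {s: log2_fold_change(sub[s], sub[S1], pseudocount)
            for s in (S3, S4, S5, S6, S2)}
    return pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))


def read_library(path) -> pd.DataFrame:
    """Read a tab-separated library table and validate it."""
    library = pd.read_csv(path, sep="\t")
    _validate_library(library)
    return library


def write_library(library: pd.DataFrame, path) -> None:
    _validate_library(library)
    library.to_csv(path, sep="\t", index=False)
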