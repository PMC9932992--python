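"""Count normalization (median-of-ratios), TPM, and the expressed-gene filter.

Size factors follow the median-of-ratios estimator: for each gene with
strictly positive counts in every sample, compute its geometric mean across
samples; each sample's factor is the median of count/geomean ratios over
those reference genes, rescaled so the factors have geometric mean 1.
Normalized counts are raw counts divided by the sample's factor, which makes
expression comparable across libraries of different depth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["size_factors", "normalize_counts", "tpm", "filter_expressed"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (geometric mean 1)."""
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate size factors")
    values = counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; median-of-ratios "
            "reference set is empty (a pseudo-reference fallback is not applied "
            "silently — filter or supply factors explicitly)"
        )
    ref = values[all_positive]
    geomean = np.exp(np.log(ref).mean(axis=1))
    ratios = ref / geomean[:, None]
    factors = np.median(ratios, axis=0)  # even counts: midpoint average
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Return (normalized counts, size factors)."""
    factors = size_factors(counts)
    return counts / factors, factors


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized within-sample abundance.

    ``lengths`` gives each gene's length in bp; which transcript length
    defines a gene is the caller's choice and must match the quantification.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing gene lengths for: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        bad = denom.index[denom == 0].tolist()
        raise ValueError(f"zero-depth samples: {bad}")
    return rate.div(denom, axis=1) * 1e6


def filter_expressed(
    tpm_df: pd.DataFrame,
    meta: pd.DataFrame,
    threshold: float = 1.0,
    allow_list: tuple[str, ...] = (),
) -> dict[str, set[str]]:
    """Expressed-gene sets per cell type, plus their union.

    A gene counts as expressed in a cell type when its median TPM across that
    cell type's 46,XX samples or its 46,XY samples is at least ``threshold``
    (boundary inclusive).  ``allow_list`` genes are always kept (rescue of
    borderline genes supported by external expression data).  The returned
    dict maps each cell type to its gene set and ``"union"`` to the
    cross-cell-type union.
    """
    out: dict[str, set[str]] = {}
    for cell_type, sub in meta.groupby("cell_type", observed=True):
        xx = sub.index[(sub.x_count == 2) & (sub.y_count == 0) & (sub.chr21_count == 2)]
        xy = sub.index[(sub.x_count == 1) & (sub.y_count == 1) & (sub.chr21_count == 2)]
        if len(xx) == 0 or len(xy) == 0:
            raise ValueError(
                f"cell type {cell_type!r} needs both 46,XX and 46,XY samples "
                "for the expression filter"
            )
        med_xx = tpm_df[xx].median(axis=1)
        med_xy = tpm_df[xy].median(axis=1)
        keep = tpm_df.index[(med_xx >= threshold) | (med_xy >= threshold)]
        out[str(cell_type)] = set(keep) | (set(allow_list) & set(tpm_df.index))
    out["union"] = set().union(*(out[k] for k in out))
    return out
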