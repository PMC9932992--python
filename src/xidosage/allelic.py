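"""Allele-specific expression: informative-SNP filtering, XCI skew calling,
skew-adjusted allelic ratios, and the Xi-expression test.

In a two-X sample, cells form two populations according to which X is
inactivated.  The *skewing coefficient* is the fraction of cells in the major
population, estimated as the median dominant-allele read fraction over SNPs
in "Xa-only" genes (genes known to be silenced on Xi and showing no dosage
response here, so their reads come exclusively from the active X).  Samples
with a coefficient >= 0.8 are called skewed; samples with almost no
informative Xa-only SNPs but plenty elsewhere are interpreted as fully
skewed (coefficient set to 1), since complete skew leaves Xa-only genes
monoallelic and hence uninformative.

For each SNP the raw allelic ratio AR = min/max of the two allele counts.
Partial skew mixes the two populations; with minor-population fraction
t = 1 - skew, the observed ratio relates to the within-cell Xi/Xa ratio by
the two-population mixture

    AR_obs = ((1 - t) AR + t) / ((1 - t) + t AR)

whose exact algebraic inverse

    AR = (AR_obs - AR_obs t - t) / (1 - t - AR_obs t)

is applied per sample.  Adjusted ARs below zero (sampling noise around a
silent gene) are retained, not clamped, so the downstream t tests stay
unbiased.  A gene's AR is the mean over its SNPs within each skewed sample,
then over samples (>= 3 informative skewed samples required); Xi expression
is a one-sided one-sample t test of mean AR > 0, BH-adjusted across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .dosage import fdr_adjust
from .types import RunConfig

__all__ = [
    "filter_informative_snps",
    "classify_xa_only",
    "skew_coefficient",
    "call_skew",
    "null_skew_simulation",
    "forward_mixture_ar",
    "adjust_ar",
    "gene_allelic_ratio",
    "SkewCall",
]


@dataclass
class SkewCall:
    sample_id: str
    coefficient: float
    n_xa_only_snps: int
    n_total_snps: int
    highly_skewed: bool
    is_skewed: bool
    callable: bool = True


def filter_informative_snps(
    table: pd.DataFrame,
    expressed_genes: set[str],
    meta: pd.DataFrame,
    annotation: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Keep informative SNPs: expressed gene, >= min coverage total, >= min
    reads per allele; drop configured artifact genes; drop PAR SNPs in
    samples carrying a Y chromosome (their second allele may come from Y).
    """
    config = config or RunConfig()
    t = table
    total = t["count_allele1"] + t["count_allele2"]
    keep = (
        t["gene_id"].isin(expressed_genes)
        & (total >= config.min_snp_coverage)
        & (t[["count_allele1", "count_allele2"]].min(axis=1) >= config.min_reads_per_allele)
        & ~t["gene_id"].isin(set(config.artifact_snp_genes))
    )
    if len(annotation):
        par_genes = set(annotation.index[annotation["region"].isin(["PAR1", "PAR2"])])
        y_samples = set(meta.index[meta["y_count"] >= 1])
        keep &= ~(t["gene_id"].isin(par_genes) & t["sample_id"].isin(y_samples))
    return t[keep].copy()


def classify_xa_only(
    annotation: pd.DataFrame, dex: pd.DataFrame, config: RunConfig | None = None
) -> set[str]:
    """Genes expressed only from Xa: prior status Subject, ΔE_X below the
    cutoff, and clearly non-significant (FDR above the floor)."""
    config = config or RunConfig()
    joined = annotation.join(dex[["value", "fdr"]], how="inner")
    keep = (
        (joined["prior_xci_status"] == "Subject")
        & (joined["value"] < config.xa_only_dex_max)
        & (joined["fdr"] > config.xa_only_fdr_min)
    )
    return set(joined.index[keep.fillna(False)])


def skew_coefficient(
    xa_only_counts: pd.DataFrame,
    n_total_snps: int,
    sample_id: str = "",
    config: RunConfig | None = None,
) -> SkewCall:
    """Skew call for one sample.

    ``xa_only_counts`` holds that sample's SNP rows restricted to Xa-only
    genes.  Per SNP, the dominant fraction is max(c1, c2) / (c1 + c2) (exact
    50/50 ties contribute 0.5); the coefficient is the median across SNPs.
    Samples with <= 5 Xa-only SNPs but many SNPs overall are called highly
    skewed with coefficient 1.
    """
    config = config or RunConfig()
    n_xa = len(xa_only_counts)
    if n_xa > 0:
        c1 = xa_only_counts["count_allele1"].to_numpy(float)
        c2 = xa_only_counts["count_allele2"].to_numpy(float)
        dom = np.maximum(c1, c2) / (c1 + c2)
        coef = float(np.median(dom))
    else:
        coef = np.nan
    if (
        n_xa <= config.max_xa_only_snps_for_highly_skewed
        and n_total_snps >= config.t_many_snps
    ):
        return SkewCall(
            sample_id=sample_id,
            coefficient=1.0,
            n_xa_only_snps=n_xa,
            n_total_snps=n_total_snps,
            highly_skewed=True,
            is_skewed=True,
        )
    if n_xa == 0:
        return SkewCall(sample_id, np.nan, 0, n_total_snps, False, False, callable=False)
    return SkewCall(
        sample_id=sample_id,
        coefficient=coef,
        n_xa_only_snps=n_xa,
        n_total_snps=n_total_snps,
        highly_skewed=False,
        is_skewed=bool(coef >= config.skew_threshold),
    )


def call_skew(
    filtered: pd.DataFrame,
    xa_only_genes: set[str],
    meta: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Skew calls for every two-X sample with informative SNPs."""
    config = config or RunConfig()
    rows = []
    two_x = meta.index[meta["x_count"] == 2]
    by_sample = dict(tuple(filtered.groupby("sample_id")))
    for sample_id in two_x:
        sub = by_sample.get(sample_id)
        if sub is None or len(sub) == 0:
            continue
        call = skew_coefficient(
            sub[sub["gene_id"].isin(xa_only_genes)], len(sub), sample_id, config
        )
        rows.append(call.__dict__)
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "coefficient",
            "n_xa_only_snps",
            "n_total_snps",
            "highly_skewed",
            "is_skewed",
            "callable",
        ],
    ).set_index("sample_id")


def null_skew_simulation(
    n_snps: int,
    depth: int,
    reps: int,
    seed: int | np.random.Generator = 0,
    threshold: float = 0.8,
    chunk: int = 100_000,
) -> float:
    """Monte-Carlo probability that balanced biallelic expression yields a
    skew coefficient >= ``threshold`` (a false skew call).

    Each replicate draws binomial(depth, 1/2) reads at ``n_snps`` SNPs,
    computes the median dominant-allele fraction, and checks it against the
    threshold.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        k = rng.binomial(depth, 0.5, size=(m, n_snps))
        dom = np.maximum(k, depth - k) / depth
        med = np.median(dom, axis=1)
        hits += int((med >= threshold).sum())
        done += m
    return hits / reps


def forward_mixture_ar(ar_true: float, t: float):
    """Observed allelic ratio from a true within-cell ratio under partial skew.

    With minor-population fraction t, reads mix as
    ((1 - t) ar + t) / ((1 - t) + t ar).  Test oracle and the algebraic
    inverse of :func:`adjust_ar`.
    """
    ar_true = np.asarray(ar_true, dtype=float)
    t = np.asarray(t, dtype=float)
    return ((1.0 - t) * ar_true + t) / ((1.0 - t) + t * ar_true)


def adjust_ar(ar_obs: float, t: float):
    """Remove partial-skew mixing from an observed allelic ratio.

    Exact inverse of :func:`forward_mixture_ar`; for a silent gene the
    observed ratio t/(1-t) maps exactly to 0.  Results below 0 are returned
    as-is (callers flag them).
    """
    ar_obs = np.asarray(ar_obs, dtype=float)
    t = np.asarray(t, dtype=float)
    denom = 1.0 - t - ar_obs * t
    if np.any(denom <= 0):
        raise ValueError("AR adjustment denominator <= 0 (skew too extreme)")
    return (ar_obs - ar_obs * t - t) / denom


def gene_allelic_ratio(
    filtered: pd.DataFrame,
    skew_calls: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene skew-adjusted allelic ratios and the Xi-expression test.

    Only skewed samples contribute.  Returns (gene table, long per-sample
    table).  Genes with fewer than the required informative skewed samples
    are omitted from the gene table.
    """
    config = config or RunConfig()
    skewed = skew_calls[skew_calls["is_skewed"]]
    t_by_sample = (1.0 - skewed["coefficient"]).to_dict()
    sub = filtered[filtered["sample_id"].isin(skewed.index)].copy()
    if len(sub) == 0:
        empty = pd.DataFrame(
            columns=["mean_ar", "n_samples", "p_gt_zero", "fdr", "xi_expressed",
                     "any_negative_ar"]
        )
        return empty, pd.DataFrame(columns=["gene_id", "sample_id", "ar"])
    lo = sub[["count_allele1", "count_allele2"]].min(axis=1)
    hi = sub[["count_allele1", "count_allele2"]].max(axis=1)
    sub["ar_raw"] = lo / hi
    sub["t"] = sub["sample_id"].map(t_by_sample)
    sub["ar_adj"] = adjust_ar(sub["ar_raw"].to_numpy(), sub["t"].to_numpy())
    per_sample = (
        sub.groupby(["gene_id", "sample_id"], observed=True)["ar_adj"]
        .mean()
        .rename("ar")
        .reset_index()
    )
    rows = []
    for gene_id, grp in per_sample.groupby("gene_id", observed=True):
        vals = grp["ar"].to_numpy(float)
        if len(vals) < config.min_informative_samples:
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd == 0:
            p = 0.0 if mean > 0 else 1.0
        else:
            p = float(scipy.stats.ttest_1samp(vals, 0.0, alternative="greater").pvalue)
        rows.append(
            {
                "gene_id": gene_id,
                "mean_ar": mean,
                "n_samples": len(vals),
                "p_gt_zero": p,
                "any_negative_ar": bool((vals < 0).any()),
            }
        )
    genes = pd.DataFrame(rows,
                         columns=["gene_id", "mean_ar", "n_samples", "p_gt_zero",
                                  "any_negative_ar"])
    genes = genes.set_index("gene_id")
    genes["fdr"] = fdr_adjust(genes["p_gt_zero"]) if len(genes) else np.nan
    genes["xi_expressed"] = genes["fdr"] < 0.05
    return genes, per_sample
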