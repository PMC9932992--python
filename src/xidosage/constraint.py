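"""Gene-constraint percentile ranking and candidate-driver selection.

Four published metrics gauge how tightly selection constrains a gene's
expression level: LOEUF and RVIS (low = intolerant of loss of function),
pHI (high = likely haploinsufficient), and P_CT (high = conserved microRNA
targeting, i.e. intolerant of over-expression).  Each metric is converted to
a within-group percentile (high = more constrained), ranking NPX genes
separately from autosomal + PAR genes; the per-gene average over available
metrics (at least two required) is the aggregate constraint score.
Candidate drivers of Xi-copy-number phenotypes are the NPX genes with
|ΔE_X| >= 0.1 (FDR < 0.05) in either cell type, ranked by that score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .types import RunConfig

__all__ = ["percentile_ranks", "average_constraint", "candidate_drivers", "METRICS"]

# metric -> +1 when larger raw values mean more constrained, -1 otherwise
METRICS = {"loeuf": -1, "rvis": -1, "phi": +1, "pct": +1}


def percentile_ranks(
    metrics: pd.DataFrame,
    min_expected_lof: float = 10.0,
) -> pd.DataFrame:
    """Within-group percentile per metric (ties get average ranks).

    ``metrics`` columns: gene_id, group (NPX / autosomal_PAR), loeuf, rvis,
    phi, pct, ampliconic, expected_lof.  Ampliconic genes are removed before
    ranking (constraint metrics are unreliable for near-identical gene
    copies); LOEUF values from genes with fewer than ``min_expected_lof``
    expected LoF variants are blanked.  Percentile = 100 * rank / n with the
    most constrained gene at 100.
    """
    df = metrics.set_index("gene_id") if "gene_id" in metrics.columns else metrics.copy()
    unknown = [c for c in df.columns if c not in
               ("group", "ampliconic", "expected_lof", *METRICS)]
    if unknown:
        raise ValueError(f"unknown metric columns: {unknown}")
    df = df[~df["ampliconic"].astype(bool)].copy()
    if "expected_lof" in df.columns:
        low = df["expected_lof"] < min_expected_lof
        df.loc[low, "loeuf"] = np.nan
    out = df[["group"]].copy()
    for metric, sign in METRICS.items():
        if metric not in df.columns:
            continue
        col = np.full(len(df), np.nan)
        for _, grp_idx in df.groupby("group").groups.items():
            vals = df.loc[grp_idx, metric].to_numpy(float)
            ok = np.isfinite(vals)
            if not ok.any():
                continue
            ranks = scipy.stats.rankdata(sign * vals[ok], method="average")
            pct = 100.0 * ranks / ok.sum()
            sub = np.full(len(vals), np.nan)
            sub[ok] = pct
            col[df.index.get_indexer(grp_idx)] = sub
        out[f"{metric}_pctile"] = col
    pct_cols = [c for c in out.columns if c.endswith("_pctile")]
    out["n_metrics"] = out[pct_cols].notna().sum(axis=1)
    out["avg_percentile"] = average_constraint(out[pct_cols], strict=False)
    return out


def average_constraint(percentiles: pd.DataFrame, strict: bool = True) -> pd.Series:
    """Unweighted mean of available metric percentiles; needs >= 2 metrics."""
    n = percentiles.notna().sum(axis=1)
    if strict and (n < 2).any():
        bad = percentiles.index[n < 2].tolist()
        raise ValueError(f"genes with < 2 constraint metrics: {bad[:5]}")
    avg = percentiles.mean(axis=1)
    avg[n < 2] = np.nan
    return avg.rename("avg_percentile")


def candidate_drivers(
    dex_by_cell_type: dict[str, pd.DataFrame],
    constraint: pd.DataFrame,
    config: RunConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Rank candidate driver genes of Xi-copy-number phenotypes.

    NPX candidates must reach |ΔE_X| >= 0.1 with FDR < 0.05 in at least one
    cell type (union over cell types) and are ranked by average constraint
    percentile, keeping the top N (default 10).  PAR1 candidates are genes at
    or above the 50th percentile of the autosomal + PAR comparison group.
    """
    config = config or RunConfig()
    qualifies = {}
    best_abs = {}
    for cell_type, dex in dex_by_cell_type.items():
        sig = (
            (dex["fdr"] < config.fdr_threshold)
            & (dex["value"].abs() >= config.driver_abs_dex_min)
            & np.isfinite(dex["value"])
        )
        for g in dex.index[sig]:
            qualifies[g] = True
        for g in dex.index:
            v = abs(dex.loc[g, "value"])
            if np.isfinite(v):
                best_abs[g] = max(best_abs.get(g, 0.0), float(v))
    cons = constraint.dropna(subset=["avg_percentile"])
    npx = cons[cons["group"] == "NPX"]
    eligible = npx.index.intersection([g for g, q in qualifies.items() if q])
    ranked = npx.loc[eligible].sort_values("avg_percentile", ascending=False)
    top = ranked.head(config.n_driver_candidates).copy()
    top["max_abs_dex"] = [best_abs.get(g, np.nan) for g in top.index]

    par = cons[cons["group"] == "autosomal_PAR"]
    par_candidates = par[
        par["avg_percentile"] >= config.par1_driver_percentile_min
    ].sort_values("avg_percentile", ascending=False)
    return {"NPX": top, "PAR1": par_candidates}
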