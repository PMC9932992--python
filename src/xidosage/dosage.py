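"""Per-gene linear dosage-response models and the ΔE metrics.

For X-linked (NPX/PAR) genes, normalized expression E of each gene is fit by
ordinary least squares to

    E = b0 + bX * xi_count + bY * y_count + batch offsets + error

where xi_count = x_count - 1 (number of inactive X chromosomes).  The
intercept then represents a 45,X sample in the reference batch.  The relative
response per inactive X is

    ΔE_X = bX / b0_avg

with b0_avg the batch-averaged intercept (equal weight per batch level), i.e.
baseline expression from the single active X.  ΔE_X = 0 means added Xi copies
leave expression unchanged; ΔE_X = 1 means each Xi contributes as much as Xa;
negative values mean repression.  Analogous models cover Y-linked (NPY) genes
on the y >= 1 subset (ΔE_Y per Y beyond the first), chromosome-21 genes on
the euploid/trisomy-21 subset (ΔE_21 relative to one chromosome's share), and
an XIST-specific variant on the x >= 2 subset where the denominator is
b0_avg + bX (expression at one Xi).

Standard errors of ΔE propagate coefficient uncertainty through the ratio:

    Var(ΔE_X) = (bX^2 / b0^2) * (S_bX^2 / bX^2 + S_b0^2 / b0^2)

and the reported SE is the square root.  Significance of a ΔE is the
two-sided t test of its regression coefficient, BH-adjusted across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "build_design",
    "ols_fit",
    "fit_dosage",
    "delta_e",
    "dosage_analysis",
    "fdr_adjust",
    "bootstrap_delta_e",
    "sex_stratified_delta_e",
    "saturation_analysis",
]

MODEL_CLASSES = ("NPX_PAR", "NPY", "CHR21", "XIST")


@dataclass
class DesignInfo:
    """Design matrix plus bookkeeping for one model class."""

    X: np.ndarray  # n x k
    columns: list[str]
    samples: list[str]
    model_class: str
    dosage_col: int  # column index of the primary dosage predictor
    batch_cols: list[int]
    c_beta0_avg: np.ndarray  # contrast vector for the batch-averaged intercept

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]


def _batch_dummies(batch: pd.Series) -> tuple[np.ndarray, list[str], list[str]]:
    levels = sorted(batch.unique())
    ref, others = levels[0], levels[1:]
    cols = np.column_stack([(batch == b).to_numpy(float) for b in others]) if others else np.empty((len(batch), 0))
    return cols, [f"batch[{b}]" for b in others], levels


def build_design(meta: pd.DataFrame, model_class: str) -> DesignInfo:
    """Build the design matrix and sample subset for a model class.

    meta is indexed by sample_id with columns x_count, y_count, chr21_count,
    xi_count, batch (one cell type at a time).
    """
    if model_class not in MODEL_CLASSES:
        raise ValueError(f"unknown model class {model_class!r}")
    m = meta
    if model_class == "NPX_PAR":
        sub = m
        dose = sub["xi_count"].to_numpy(float)
        extra = [("y_count", sub["y_count"].to_numpy(float))]
    elif model_class == "XIST":
        sub = m[m["x_count"] >= 2]
        dose = sub["xi_count"].to_numpy(float)
        extra = [("y_count", sub["y_count"].to_numpy(float))]
    elif model_class == "NPY":
        sub = m[m["y_count"] >= 1]
        dose = sub["y_count"].to_numpy(float) - 1.0
        extra = [("xi_count", sub["xi_count"].to_numpy(float))]
    else:  # CHR21
        keep = (
            ((m["x_count"] == 2) & (m["y_count"] == 0))
            | ((m["x_count"] == 1) & (m["y_count"] == 1))
        )
        sub = m[keep]
        dose = sub["chr21_count"].to_numpy(float) - 2.0
        # sex indicator: 1 for 46,XY-like, 0 for 46,XX-like (intercept = 46,XX)
        extra = [("sex[XY]", (sub["y_count"] >= 1).to_numpy(float))]
    if len(sub) == 0:
        raise ValueError(f"model class {model_class}: empty sample subset")
    if np.unique(dose).size < 2:
        raise ValueError(
            f"model class {model_class}: fewer than 2 dosage levels in subset"
        )
    batch_mat, batch_names, _levels = _batch_dummies(sub["batch"])
    cols = [np.ones(len(sub)), dose] + [v for _, v in extra]
    names = ["intercept", {"NPX_PAR": "xi_count", "XIST": "xi_count", "NPY": "y_minus_1", "CHR21": "chr21_minus_2"}[model_class]]
    names += [n for n, _ in extra]
    X = np.column_stack(cols + ([batch_mat] if batch_mat.shape[1] else []))
    names += batch_names
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify confounded columns by leave-one-out rank
        confounded = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(
            f"model class {model_class}: rank-deficient design "
            f"(confounded columns: {confounded})"
        )
    n_batch = batch_mat.shape[1]
    batch_idx = list(range(X.shape[1] - n_batch, X.shape[1]))
    c = np.zeros(X.shape[1])
    c[0] = 1.0
    # equal weight per batch level; the reference level's offset is 0
    n_levels = n_batch + 1
    for j in batch_idx:
        c[j] = 1.0 / n_levels
    return DesignInfo(
        X=X,
        columns=names,
        samples=list(sub.index),
        model_class=model_class,
        dosage_col=1,
        batch_cols=batch_idx,
        c_beta0_avg=c,
    )


def ols_fit(X: np.ndarray, Y: np.ndarray):
    """Vectorized OLS of many responses on one design.

    Y is n x G.  Returns (beta (k x G), sigma2 (G,), XtX_inv (k x k), df).
    """
    n, k = X.shape
    if Y.shape[0] != n:
        raise ValueError("response and design row counts differ")
    if n <= k:
        raise ValueError(f"need more rows ({n}) than columns ({k})")
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    return beta, sigma2, XtX_inv, df


def fit_dosage(
    norm_counts: pd.DataFrame, meta: pd.DataFrame, model_class: str = "NPX_PAR"
) -> pd.DataFrame:
    """Fit the dosage model for every gene (rows of ``norm_counts``).

    Returns a per-gene frame with the dosage coefficient, the batch-averaged
    intercept, their SEs, the two-sided coefficient p value, and n.
    """
    info = build_design(meta, model_class)
    Y = norm_counts[info.samples].to_numpy(float).T  # n x G
    if not np.isfinite(Y).all():
        raise ValueError("non-finite expression values")
    beta, sigma2, XtX_inv, df = ols_fit(info.X, Y)
    d = info.dosage_col
    se_all = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))  # k x G
    c = info.c_beta0_avg
    beta0_avg = c @ beta
    se_beta0_avg = np.sqrt((c @ XtX_inv @ c) * sigma2)
    tstat = np.divide(
        beta[d], se_all[d], out=np.zeros_like(beta[d]), where=se_all[d] > 0
    )
    p = 2 * scipy.stats.t.sf(np.abs(tstat), df)
    p = np.where(se_all[d] > 0, p, 1.0)
    out = pd.DataFrame(
        {
            "model_class": model_class,
            "beta0": beta[0],
            "beta_dose": beta[d],
            "se_beta_dose": se_all[d],
            "beta0_avg": beta0_avg,
            "se_beta0_avg": se_beta0_avg,
            "sigma2": sigma2,
            "p_value": p,
            "n_samples": info.n,
            "df": df,
        },
        index=norm_counts.index,
    )
    # keep full coefficient tables for delta-method variants (XIST)
    out.attrs["beta"] = pd.DataFrame(beta, index=info.columns, columns=norm_counts.index)
    out.attrs["XtX_inv"] = XtX_inv
    out.attrs["design"] = info
    return out


def delta_e(fits: pd.DataFrame, kind: str = "X") -> pd.DataFrame:
    """ΔE table from a fitted model.

    kind "X" or "Y": beta / beta0_avg (beta0_avg + bX denominator for the
    XIST model class); kind "21": beta21 / (beta0_avg / 2).  Genes with a
    nonpositive batch-averaged intercept (non-XIST classes) have their value
    withheld (NaN) and are flagged.
    """
    model_class = fits["model_class"].iloc[0]
    info: DesignInfo = fits.attrs["design"]
    beta_full: pd.DataFrame = fits.attrs["beta"]
    XtX_inv: np.ndarray = fits.attrs["XtX_inv"]
    sigma2 = fits["sigma2"].to_numpy()

    names = info.columns
    if kind == "X":
        coef_name = "xi_count"
    elif kind == "Y":
        coef_name = "y_count" if "y_count" in names else "y_minus_1"
    elif kind == "21":
        coef_name = "chr21_minus_2"
    else:
        raise ValueError(f"unknown ΔE kind {kind!r}")
    if coef_name not in names:
        raise ValueError(f"model class {model_class} has no {kind} dosage term")
    j = names.index(coef_name)
    b = beta_full.to_numpy()[j]
    se_b = np.sqrt(XtX_inv[j, j] * sigma2)
    b0 = fits["beta0_avg"].to_numpy()
    se_b0 = fits["se_beta0_avg"].to_numpy()

    c = info.c_beta0_avg
    if model_class == "XIST":
        # denominator = expression at one Xi: beta0_avg + bX
        jx = names.index("xi_count")
        bx = beta_full.to_numpy()[jx]
        denom = b0 + bx
        value = np.divide(b, denom, out=np.full_like(b, np.nan), where=denom != 0)
        # exact delta method: gradient alpha*e_j + gamma*(c + e_jx)
        cx = c.copy()
        cx[jx] += 1.0
        se = _ratio_se(b, denom, 1.0, j, cx, XtX_inv, sigma2)
        se_product = se.copy()
        flagged = ~np.isfinite(value)
    else:
        denom = b0 / 2.0 if kind == "21" else b0
        bad = denom <= 0
        value = np.divide(b, denom, out=np.full_like(b, np.nan), where=~bad)
        scale = 2.0 if kind == "21" else 1.0
        se = _ratio_se(b, b0, scale, j, c, XtX_inv, sigma2)
        se = np.where(bad, np.nan, se)
        # covariance-free product form (ratio-of-independent-estimates
        # propagation), kept for comparability
        se_denom = se_b0 / 2.0 if kind == "21" else se_b0
        with np.errstate(divide="ignore", invalid="ignore"):
            var = (b**2 / denom**2) * (se_b**2 / b**2 + se_denom**2 / denom**2)
            var = np.where(b == 0, se_b**2 / denom**2, var)  # limit as b -> 0
        se_product = np.sqrt(np.where(bad, np.nan, var))
        flagged = bad
    p = fits["p_value"].to_numpy() if j == info.dosage_col else _coef_p(
        beta_full.to_numpy()[j], se_b, fits["df"].iloc[0]
    )
    out = pd.DataFrame(
        {
            "kind": kind,
            "value": value,
            "se": se,
            "se_product": se_product,
            "p_value": p,
            "n_samples": fits["n_samples"],
            "flagged": flagged | (np.abs(value) > 50),
        },
        index=fits.index,
    )
    out["fdr"] = fdr_adjust(out["p_value"])
    return out


def _ratio_se(
    b: np.ndarray,
    denom: np.ndarray,
    scale: float,
    j: int,
    c: np.ndarray,
    XtX_inv: np.ndarray,
    sigma2: np.ndarray,
) -> np.ndarray:
    """Delta-method SE of value = scale * b_j / denom, denom = c'beta.

    Uses the full coefficient covariance (sigma2 * XtX_inv), including the
    numerator/denominator covariance: gradient = alpha e_j + gamma c with
    alpha = scale/denom, gamma = -scale*b_j/denom^2.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = scale / denom
        gamma = -scale * b / denom**2
        Hjj = XtX_inv[j, j]
        Hc = XtX_inv @ c
        cHc = float(c @ Hc)
        quad = alpha**2 * Hjj + 2 * alpha * gamma * Hc[j] + gamma**2 * cHc
        return np.sqrt(np.maximum(quad, 0.0) * sigma2)


def _coef_p(b, se, df):
    t = np.divide(b, se, out=np.zeros_like(b), where=se > 0)
    p = 2 * scipy.stats.t.sf(np.abs(t), df)
    return np.where(se > 0, p, 1.0)


def dosage_analysis(
    norm_counts: pd.DataFrame,
    meta: pd.DataFrame,
    model_class: str = "NPX_PAR",
    kind: str = "X",
) -> pd.DataFrame:
    """Fit and summarize in one step: ΔE with SE, p, FDR per gene."""
    fits = fit_dosage(norm_counts, meta, model_class)
    return delta_e(fits, kind)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def bootstrap_delta_e(
    norm_counts: pd.DataFrame,
    meta: pd.DataFrame,
    model_class: str = "NPX_PAR",
    kind: str = "X",
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
    retry_cap: int = 100,
) -> pd.DataFrame:
    """Percentile bootstrap intervals for ΔE (resampling samples).

    Each resample is drawn with replacement from the cohort and redrawn (up
    to ``retry_cap`` times) until its design matrix is full rank with at
    least two dosage levels.
    """
    rng = np.random.default_rng(seed)
    point = dosage_analysis(norm_counts, meta, model_class, kind)
    n = len(meta)
    boots = np.empty((n_boot, norm_counts.shape[0]))
    for b in range(n_boot):
        for attempt in range(retry_cap + 1):
            idx = rng.integers(0, n, size=n)
            meta_b = meta.iloc[idx].copy()
            meta_b.index = [f"r{i}" for i in range(n)]
            counts_b = norm_counts.iloc[:, idx].copy()
            counts_b.columns = meta_b.index
            try:
                de = dosage_analysis(counts_b, meta_b, model_class, kind)
            except (ValueError, np.linalg.LinAlgError):
                if attempt == retry_cap:
                    raise RuntimeError(
                        f"bootstrap resample {b}: retry cap {retry_cap} exceeded"
                    )
                continue
            boots[b] = de["value"].to_numpy()
            break
    alpha = 1.0 - level
    lo = np.nanpercentile(boots, 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(boots, 100 * (1 - alpha / 2), axis=0)
    return pd.DataFrame(
        {
            "value": point["value"],
            "ci_lo": lo,
            "ci_hi": hi,
            "n_boot": n_boot,
        },
        index=norm_counts.index,
    )


def sex_stratified_delta_e(
    norm_counts: pd.DataFrame, meta: pd.DataFrame
) -> dict:
    """ΔE_X separately in zero-Y (female) and one-Y (male) subsets.

    The Y term is dropped (constant within each stratum).  Returns a dict
    with "female" and "male" ΔE tables and the Pearson correlation of each
    with the pooled estimate.
    """
    pooled = dosage_analysis(norm_counts, meta, "NPX_PAR", "X")
    out = {"pooled": pooled}
    for label, y in (("female", 0), ("male", 1)):
        sub = meta[meta["y_count"] == y]
        if len(sub) == 0 or sub["xi_count"].nunique() < 2:
            raise ValueError(
                f"{label} subset degenerate: needs >= 2 Xi levels "
                f"({len(sub)} samples)"
            )
        # no-Y model: reuse the NPX_PAR builder on a y-constant subset would
        # be rank-deficient, so fit with xi + batch only
        sub2 = sub.copy()
        info_cols = [np.ones(len(sub2)), sub2["xi_count"].to_numpy(float)]
        batch_mat, _, _ = _batch_dummies(sub2["batch"])
        X = np.column_stack(info_cols + ([batch_mat] if batch_mat.shape[1] else []))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"{label} subset design is rank-deficient")
        Y = norm_counts[sub2.index].to_numpy(float).T
        beta, sigma2, XtX_inv, df = ols_fit(X, Y)
        n_levels = batch_mat.shape[1] + 1
        c = np.zeros(X.shape[1])
        c[0] = 1.0
        c[2:] = 1.0 / n_levels
        b0 = c @ beta
        bX = beta[1]
        se_bX = np.sqrt(XtX_inv[1, 1] * sigma2)
        with np.errstate(divide="ignore", invalid="ignore"):
            value = np.where(b0 > 0, bX / b0, np.nan)
        se = _ratio_se(bX, b0, 1.0, 1, c, XtX_inv, sigma2)
        p = _coef_p(bX, se_bX, df)
        tab = pd.DataFrame(
            {
                "kind": "X",
                "value": value,
                "se": np.where(b0 > 0, se, np.nan),
                "p_value": p,
                "n_samples": len(sub2),
            },
            index=norm_counts.index,
        )
        tab["fdr"] = fdr_adjust(tab["p_value"])
        out[label] = tab
        both = np.isfinite(tab["value"]) & np.isfinite(pooled["value"])
        if both.sum() >= 2:
            out[f"correlation_{label}"] = float(
                np.corrcoef(tab["value"][both], pooled["value"][both])[0, 1]
            )
        else:
            out[f"correlation_{label}"] = np.nan
    return out


def saturation_analysis(
    norm_counts: pd.DataFrame,
    meta: pd.DataFrame,
    n_grid,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
    model_class: str = "NPX_PAR",
    kind: str = "X",
    fdr_threshold: float = 0.05,
    retry_cap: int = 100,
) -> pd.DataFrame:
    """Significant-gene counts for random subsets of increasing size.

    For each subset size n, draws ``reps`` subsamples without replacement
    (redrawing until the design is full rank) and counts genes with
    FDR < ``fdr_threshold``.  Returns one row per (n, rep).
    """
    rng = np.random.default_rng(seed)
    total = len(meta)
    rows = []
    for n in n_grid:
        if n > total:
            raise ValueError(f"subset size {n} exceeds cohort size {total}")
        for rep in range(reps):
            for attempt in range(retry_cap + 1):
                idx = rng.choice(total, size=n, replace=False)
                sub = meta.iloc[np.sort(idx)]
                try:
                    de = dosage_analysis(norm_counts[sub.index], sub, model_class, kind)
                except (ValueError, np.linalg.LinAlgError):
                    if attempt == retry_cap:
                        raise RuntimeError(f"saturation n={n}: retry cap exceeded")
                    continue
                rows.append(
                    {
                        "n": n,
                        "rep": rep,
                        "n_significant": int((de["fdr"] < fdr_threshold).sum()),
                    }
                )
                break
    return pd.DataFrame(rows)
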