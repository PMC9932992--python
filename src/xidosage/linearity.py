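"""Power-curve fits testing whether expression changes linearly per chromosome.

Expression is first normalized per gene to the single-copy reference: each
sample's count is divided by the mean count among samples carrying exactly
one chromosome of the relevant type (one X for NPX genes, 45,X for PAR genes,
one Y for NPY genes).  The normalized values y* are then fit by non-linear
least squares to

    y* = 1 + b * (copies - 1)^a

starting from (b, a) = (0.5, 1).  a ≈ 1 with b away from 0 indicates a linear
response (a fixed increment per added chromosome); a ≈ 0 or b ≈ 0 indicates
no change; other exponents indicate a non-linear response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "normalize_to_single_copy",
    "fit_power_curve",
    "classify_linearity",
    "linearity_analysis",
    "PowerFit",
]


@dataclass
class PowerFit:
    a: float
    b: float
    converged: bool
    rss: float
    n_points: int
    initial_a: float = 1.0
    initial_b: float = 0.5
    message: str = ""


def normalize_to_single_copy(
    expression: pd.Series, meta: pd.DataFrame, region: str
) -> tuple[pd.Series, pd.Series]:
    """Return (y*, copies) for a gene's per-sample expression.

    Reference sets: NPX -> samples with one X (any Y); PAR -> 45,X samples;
    NPY -> samples with one Y (any X).  Copies are the relevant chromosome
    count: x_count (NPX), x_count + y_count (PAR), y_count (NPY).
    """
    m = meta.loc[expression.index]
    if region in ("NPX",):
        ref = m["x_count"] == 1
        copies = m["x_count"]
    elif region in ("PAR1", "PAR2"):
        ref = (m["x_count"] == 1) & (m["y_count"] == 0)
        copies = m["x_count"] + m["y_count"]
    elif region == "NPY":
        ref = m["y_count"] == 1
        sub = m["y_count"] >= 1
        m = m[sub]
        expression = expression[m.index]
        ref = ref[m.index]
        copies = m["y_count"]
    else:
        raise ValueError(f"no single-copy reference defined for region {region!r}")
    if not ref.any():
        raise ValueError(f"empty single-copy reference set for region {region}")
    ref_mean = expression[ref.index[ref]].mean()
    if ref_mean == 0:
        raise ValueError("single-copy reference mean is zero")
    return expression / ref_mean, copies.astype(float)


def _safe_pow(z: np.ndarray, a: float) -> np.ndarray:
    """z**a with the conventions 0**a = 0 for a > 0 and 0**0 = 1 (z >= 0)."""
    out = np.empty_like(z, dtype=float)
    pos = z > 0
    with np.errstate(over="ignore", invalid="ignore"):
        out[pos] = np.power(z[pos], a)
    if a > 0:
        out[~pos] = 0.0
    elif a == 0:
        out[~pos] = 1.0
    else:
        out[~pos] = np.inf
    return np.nan_to_num(out, nan=1e12, posinf=1e12, neginf=-1e12)


def fit_power_curve(
    y_star: np.ndarray | pd.Series,
    copies: np.ndarray | pd.Series,
    ftol: float = 1e-12,
    max_iter: int = 1000,
) -> PowerFit:
    """Levenberg-Marquardt fit of y* = 1 + b (copies - 1)^a from (b, a) = (0.5, 1)."""
    y = np.asarray(y_star, dtype=float)
    z = np.asarray(copies, dtype=float) - 1.0
    if (z < 0).any():
        raise ValueError("chromosome copies must be >= 1")
    levels = np.unique(z)
    if levels.size < 3:
        return PowerFit(
            a=np.nan, b=np.nan, converged=False, rss=np.nan, n_points=len(y),
            message="fewer than 3 distinct copy-number levels (unidentifiable)",
        )

    def residuals(params):
        b, a = params
        return 1.0 + b * _safe_pow(z, a) - y

    x0 = np.array([0.5, 1.0])
    try:
        res = least_squares(
            residuals, x0, method="lm",
            ftol=ftol, xtol=1e-14, gtol=1e-14, max_nfev=max_iter * 3,
        )
    except Exception as exc:  # non-convergence is reported, never raised
        return PowerFit(
            a=np.nan, b=np.nan, converged=False, rss=np.nan,
            n_points=len(y), message=str(exc),
        )
    b, a = res.x
    rss = float(2 * res.cost)
    rss0 = float((residuals(x0) ** 2).sum())
    converged = bool(res.success) and np.isfinite(rss) and rss <= rss0 + 1e-12
    return PowerFit(
        a=float(a), b=float(b), converged=converged, rss=rss,
        n_points=len(y), message=res.message,
    )


def classify_linearity(
    fit: PowerFit,
    tau_a: float = 0.25,
    tau_b: float = 0.05,
    tau_a0: float = 0.1,
) -> str:
    """Classify a power fit as linear / flat / nonlinear / unidentifiable.

    flat when |b| <= tau_b or |a| <= tau_a0 (no dosage response); linear when
    |a - 1| <= tau_a with a real slope; nonlinear otherwise; unidentifiable
    when the fit did not converge.
    """
    if not fit.converged or not np.isfinite(fit.a):
        return "unidentifiable"
    if abs(fit.b) <= tau_b or abs(fit.a) <= tau_a0:
        return "flat"
    if abs(fit.a - 1.0) <= tau_a:
        return "linear"
    return "nonlinear"


def linearity_analysis(
    norm_counts: pd.DataFrame,
    meta: pd.DataFrame,
    regions: pd.Series,
    tau_a: float = 0.25,
    tau_b: float = 0.05,
    tau_a0: float = 0.1,
) -> pd.DataFrame:
    """Per-gene power fits and classes; ``regions`` maps gene_id -> region."""
    rows = []
    for gene_id in norm_counts.index:
        region = regions.get(gene_id, "NPX")
        expr = norm_counts.loc[gene_id]
        try:
            y_star, copies = normalize_to_single_copy(expr, meta, region)
        except ValueError as exc:
            rows.append(
                {"gene_id": gene_id, "a": np.nan, "b": np.nan, "rss": np.nan,
                 "converged": False, "linearity": "unidentifiable", "note": str(exc)}
            )
            continue
        fit = fit_power_curve(y_star.to_numpy(), copies.to_numpy())
        rows.append(
            {
                "gene_id": gene_id,
                "a": fit.a,
                "b": fit.b,
                "rss": fit.rss,
                "converged": fit.converged,
                "linearity": classify_linearity(fit, tau_a, tau_b, tau_a0),
                "note": "",
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
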