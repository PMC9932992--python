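"""Trans-modulation calls, XCI consensus annotation, and overlap statistics.

If Xi and Xa expression were independent and additive, a gene's allelic
ratio (AR, Xi/Xa output measured in skewed two-X samples) would match its
dosage response ΔE_X.  A significant divergence between the two means the
inactive X changes the active X's output in trans: AR ≈ 0 with ΔE_X != 0 is
pure Xa modulation with a silent Xi allele; AR > 0 with AR != ΔE_X combines
escape from silencing with modulation.  The modulated-gene set is the union
of genes whose ΔE_X contradicts the literature's XCI annotation and genes
whose AR differs significantly from ΔE_X.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .dosage import fdr_adjust
from .types import RunConfig

__all__ = [
    "test_ar_vs_dex",
    "classify_modulation",
    "consensus_xci",
    "study_level_call",
    "overlap_enrichment",
    "StudyARSummary",
    "STUDIES",
]

STUDIES = ("cotton", "tukiainen", "garieri", "sauteraud")

CATEGORIES = (
    "silent_additive",
    "escape_additive",
    "modulated_no_escape",
    "escape_and_modulated",
    "unclassified",
)


@dataclass(frozen=True)
class StudyARSummary:
    gene_id: str
    study: str
    call: str  # Escape / Subject / NotInformative
    ar: Optional[float] = None

    def __post_init__(self):
        if self.call not in ("Escape", "Subject", "NotInformative"):
            raise ValueError(f"unknown study call {self.call!r}")


def test_ar_vs_dex(
    per_sample_ar: pd.DataFrame,
    dex: pd.DataFrame,
    gene_ar: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Two-sided one-sample t tests of per-sample ARs against mu = ΔE_X.

    A gene is called ``ar_ne_dex`` when the BH-adjusted p is below the
    modulation FDR (default 0.1) AND the mean AR lies outside
    ΔE_X ± 1.96·SE(ΔE_X) AND it is not the case that both ΔE_X and AR are
    individually non-significant (FDR >= 0.05).  Genes lacking an SE are
    excluded with a reason.
    """
    config = config or RunConfig()
    rows = []
    grouped = per_sample_ar.groupby("gene_id", observed=True)
    for gene_id, grp in grouped:
        vals = grp["ar"].to_numpy(float)
        if len(vals) < config.min_informative_samples:
            continue
        if gene_id not in dex.index:
            rows.append({"gene_id": gene_id, "t_p_value": np.nan,
                         "excluded_reason": "no dosage fit"})
            continue
        mu = dex.loc[gene_id, "value"]
        se = dex.loc[gene_id, "se"]
        if not np.isfinite(mu) or not np.isfinite(se):
            rows.append({"gene_id": gene_id, "t_p_value": np.nan,
                         "excluded_reason": "missing ΔE_X or SE"})
            continue
        sd = vals.std(ddof=1)
        if sd == 0:
            p = 1.0 if np.isclose(vals.mean(), mu) else 0.0
        else:
            p = float(scipy.stats.ttest_1samp(vals, mu).pvalue)
        rows.append(
            {
                "gene_id": gene_id,
                "t_p_value": p,
                "mean_ar": float(vals.mean()),
                "n_samples": len(vals),
                "excluded_reason": "",
            }
        )
    out = pd.DataFrame(
        rows, columns=["gene_id", "t_p_value", "mean_ar", "n_samples",
                       "excluded_reason"]
    ).set_index("gene_id")
    tested = out["excluded_reason"] == ""
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = fdr_adjust(out.loc[tested, "t_p_value"])
    out["ar_ne_dex"] = False
    for gene_id in out.index[tested]:
        mu = dex.loc[gene_id, "value"]
        se = dex.loc[gene_id, "se"]
        mean_ar = out.loc[gene_id, "mean_ar"]
        inside_ci = abs(mean_ar - mu) <= 1.96 * se
        dex_nonsig = dex.loc[gene_id, "fdr"] >= 0.05
        ar_nonsig = (
            gene_ar.loc[gene_id, "fdr"] >= 0.05 if gene_id in gene_ar.index else True
        )
        out.loc[gene_id, "ar_ne_dex"] = bool(
            out.loc[gene_id, "fdr"] < config.ar_vs_dex_fdr
            and not inside_ci
            and not (dex_nonsig and ar_nonsig)
        )
    return out


def classify_modulation(
    dex: pd.DataFrame,
    gene_ar: pd.DataFrame,
    prior_status: pd.Series,
    ar_vs_dex: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene regulatory category and the modulated-gene set.

    ``discordant_with_prior``: ΔE_X significantly positive despite a prior
    "Subject" (silenced) annotation, or ΔE_X significantly negative (no
    annotation predicts repression).  The modulated set is the union of
    discordant genes and ar_ne_dex genes.
    """
    idx = dex.index
    out = pd.DataFrame(index=idx)
    dex_sig = (dex["fdr"] < fdr_threshold) & np.isfinite(dex["value"])
    out["dex_value"] = dex["value"]
    out["dex_significant"] = dex_sig
    prior = prior_status.reindex(idx).fillna("NoCall")
    out["discordant_with_prior"] = (
        (dex_sig & (dex["value"] > 0) & (prior == "Subject"))
        | (dex_sig & (dex["value"] < 0))
    )
    ar_sig = gene_ar["xi_expressed"].reindex(idx).fillna(False).astype(bool)
    has_ar = idx.isin(gene_ar.index)
    ne = ar_vs_dex["ar_ne_dex"].reindex(idx).fillna(False).astype(bool)
    out["ar_significant"] = ar_sig
    out["ar_ne_dex"] = ne
    out["modulated"] = out["discordant_with_prior"] | ne

    cats = []
    for g in idx:
        if not has_ar[idx.get_loc(g)]:
            cats.append("unclassified")
        elif ar_sig[g] and ne[g]:
            cats.append("escape_and_modulated")
        elif ar_sig[g]:
            cats.append("escape_additive")
        elif dex_sig[g]:
            cats.append("modulated_no_escape")
        else:
            cats.append("silent_additive")
    out["category"] = cats
    return out


def consensus_xci(
    summaries: Sequence[StudyARSummary],
    hybrid_xi_fraction: Optional[float] = None,
) -> str:
    """Synthesize per-study XCI calls into a consensus Escape/Subject/NoCall.

    Rule order: Subject if all informative studies say Subject, or if most
    (>50%) do and the average AR across studies is < 0.1.  Escape if most
    studies say Escape, or if a minority (but at least one) does and either
    more than one study shows escape or the average AR is >= 1 (a nearly
    vacuous bound, kept verbatim; a warning is attached when it fires).
    With no informative study, a rodent-hybrid Xi expression fraction
    decides: < 0.22 -> Subject, >= 0.22 -> Escape, absent -> NoCall.
    Informative patterns covered by none of the printed rules return NoCall.
    """
    informative = [s for s in summaries if s.call != "NotInformative"]
    if not informative:
        if hybrid_xi_fraction is None:
            return "NoCall"
        return "Subject" if hybrid_xi_fraction < 0.22 else "Escape"
    n = len(informative)
    n_subject = sum(s.call == "Subject" for s in informative)
    n_escape = sum(s.call == "Escape" for s in informative)
    ars = [s.ar for s in informative if s.ar is not None]
    avg_ar = float(np.mean(ars)) if ars else None

    if n_subject == n:
        return "Subject"
    if n_subject > n / 2 and avg_ar is not None and avg_ar < 0.1:
        return "Subject"
    if n_escape > n / 2:
        return "Escape"
    if 0 < n_escape <= n / 2:
        if n_escape > 1:
            return "Escape"
        if avg_ar is not None and avg_ar >= 1:
            import warnings

            warnings.warn(
                "consensus escape via the average-AR >= 1 clause "
                "(theoretical maximum; check inputs)",
                stacklevel=2,
            )
            return "Escape"
    return "NoCall"


def study_level_call(study: str, gene_id: str, summary: dict) -> StudyARSummary:
    """Map one study's numeric summary for a gene to Subject/Escape.

    Expected keys per study:
      cotton:     ar, ci_lower (95% CI lower bound of the AR)
      tukiainen:  sig_bulk, sig_single (bools or None), optional ar
      garieri:    xa_fractions (per-sample Xa read fractions)
      sauteraud:  padj, optional ar
    """
    if study not in STUDIES:
        raise ValueError(f"unknown study label {study!r}")
    if study == "cotton":
        ar = summary.get("ar")
        if ar is None:
            return StudyARSummary(gene_id, study, "NotInformative")
        ci_lower = summary.get("ci_lower")
        ci_includes_zero = ci_lower is not None and ci_lower <= 0
        call = "Subject" if (ci_includes_zero or ar < 0.1) else "Escape"
        return StudyARSummary(gene_id, study, call, ar=float(ar))
    if study == "tukiainen":
        sig_bulk = summary.get("sig_bulk")
        sig_single = summary.get("sig_single")
        if sig_bulk is None and sig_single is None:
            return StudyARSummary(gene_id, study, "NotInformative")
        escape = bool(sig_bulk) or bool(sig_single)
        ar = summary.get("ar")
        return StudyARSummary(
            gene_id, study, "Escape" if escape else "Subject",
            ar=float(ar) if ar is not None else None,
        )
    if study == "garieri":
        fracs = summary.get("xa_fractions") or []
        if len(fracs) < 2:
            return StudyARSummary(gene_id, study, "NotInformative")
        ars = np.array([1.0 / f - 1.0 for f in fracs])
        n_sig = int((ars > 0.0526).sum())
        mean_ar = float(ars.mean())
        call = "Subject" if (n_sig == 0 or mean_ar < 0.1) else "Escape"
        return StudyARSummary(gene_id, study, call, ar=mean_ar)
    # sauteraud
    padj = summary.get("padj")
    if padj is None:
        return StudyARSummary(gene_id, study, "NotInformative")
    ar = summary.get("ar")
    return StudyARSummary(
        gene_id, study, "Escape" if padj < 0.01 else "Subject",
        ar=float(ar) if ar is not None else None,
    )


def overlap_enrichment(
    set_a: set, set_b: set, universe: set
) -> tuple[int, float]:
    """Overlap size and upper-tail hypergeometric p of >= that overlap."""
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    overlap = len(set_a & set_b)
    p = float(
        scipy.stats.hypergeom.sf(overlap - 1, len(universe), len(set_a), len(set_b))
    )
    return overlap, p
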