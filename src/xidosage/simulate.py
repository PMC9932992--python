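"""Synthetic cohorts with known Xi-dosage ground truth.

The generator is the forward model that the analysis inverts.  For each gene
``g`` and sample ``s`` the expected raw count is

    mu = depth_s * batch_s * L_g * (1 + (f_g + m_g) * xi_s + y_g * ny_s)

where ``L_g`` is the expected normalized count from a single active X (Xa),
``f_g`` is the Xi transcription fraction (output of each inactive X as a
fraction of an unmodulated Xa), ``m_g`` is the trans-modulation of the Xa
allele per Xi, ``y_g`` the per-Y effect, ``xi_s = x_count - 1`` and ``ny_s``
the Y count.  The true dosage response is therefore ΔE_X = f + m, and a gene
silenced on Xi (f = 0) can still carry a nonzero ΔE_X through modulation.
Counts are drawn from a negative binomial with gene-level dispersion
(variance mu + disp * mu^2); dispersion 0 yields deterministic rounded means
so noiseless fixtures recover truth exactly.

Allelic reads for two-X samples mix two cell populations: a fraction ``s``
(the skew) with one X active and ``1 - s`` with the other.  Reads from the
two alleles of gene g are proportional to

    allele1:  s * (1 + m) + (1 - s) * f
    allele2:  s * f + (1 - s) * (1 + m)

so at full skew the observed minor/major ratio is the within-cell allelic
ratio f / (1 + m), and at partial skew it follows the closed-form mixture
implemented by :func:`xidosage.allelic.forward_mixture_ar`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import GeneAnnotation, SampleMeta
from .karyotype import parse_karyotype

__all__ = [
    "GeneTruth",
    "SampleTruth",
    "DEFAULT_LCL_DESIGN",
    "DEFAULT_FIBROBLAST_DESIGN",
    "generate_cohort",
    "generate_genes",
    "generate_modulation_panel",
    "generate_counts",
    "generate_allelic",
    "generate_constraint_metrics",
    "truth_frame",
    "sample_truth_frame",
]

# Study cohort designs: karyotype -> number of cultures profiled.
DEFAULT_LCL_DESIGN: dict[str, int] = {
    "45,X": 17,
    "46,XX": 22,
    "46,XY": 17,
    "47,XXX": 7,
    "47,XXY": 11,
    "47,XYY": 10,
    "48,XXXX": 1,
    "48,XXXY": 4,
    "48,XXYY": 3,
    "49,XXXXY": 12,
    "49,XYYYY": 2,
}

DEFAULT_FIBROBLAST_DESIGN: dict[str, int] = {
    "45,X": 23,
    "46,XX": 20,
    "46,XY": 14,
    "47,XXX": 4,
    "47,XXY": 30,
    "47,XYY": 5,
    "48,XXXY": 1,
    "49,XXXXY": 1,
    "49,XYYYY": 1,
}


@dataclass(frozen=True)
class GeneTruth:
    """Ground-truth generative parameters for one gene."""

    gene_id: str
    baseline_L: float
    xi_fraction_f: float = 0.0
    xa_modulation_m: float = 0.0
    y_effect: float = 0.0
    dispersion: float = 0.05
    region: str = "NPX"
    is_xist: bool = False

    def __post_init__(self):
        if self.baseline_L < 0 or (self.baseline_L == 0 and not self.is_xist):
            raise ValueError(f"{self.gene_id}: baseline_L must be > 0")
        if self.xi_fraction_f < 0:
            raise ValueError(f"{self.gene_id}: xi_fraction_f must be >= 0")
        if self.dispersion < 0:
            raise ValueError(f"{self.gene_id}: dispersion must be >= 0")

    @property
    def true_delta_ex(self) -> float:
        return self.xi_fraction_f + self.xa_modulation_m

    @property
    def true_ar(self) -> float:
        """Within-cell Xi/Xa allelic ratio implied by the generative model."""
        return self.xi_fraction_f / (1.0 + self.xa_modulation_m)


@dataclass(frozen=True)
class SampleTruth:
    """Per-sample nuisance truth: batch factor, library size, XCI skew."""

    sample_id: str
    karyotype: str
    batch_effect: float
    depth_factor: float
    skew_s: Optional[float] = None  # defined only for two-X samples

    def __post_init__(self):
        if self.batch_effect <= 0 or self.depth_factor <= 0:
            raise ValueError(f"{self.sample_id}: multiplicative factors must be > 0")
        if self.skew_s is not None and not (0.5 <= self.skew_s <= 1.0):
            raise ValueError(f"{self.sample_id}: skew_s must be in [0.5, 1]")


def generate_cohort(
    design: Mapping[str, int],
    cell_type: str = "LCL",
    n_batches: int = 4,
    seed: int | np.random.Generator = 0,
    batch_sd: float = 0.15,
    depth_sd: float = 0.3,
    skew_weights: tuple[float, float] = (0.5, 0.5),
    unskewed_range: tuple[float, float] = (0.5, 0.65),
    skewed_range: tuple[float, float] = (0.8, 1.0),
) -> tuple[list[SampleMeta], list[SampleTruth]]:
    """Draw a cohort of samples for a karyotype design.

    Batches are assigned round-robin across karyotypes (each karyotype's
    samples are spread over batches, emulating randomization of samples by
    karyotype into processing batches).  Two-X samples receive an XCI skew
    drawn from a two-component mixture of an unskewed and a skewed range.
    """
    if not design:
        raise ValueError("empty cohort design")
    rng = np.random.default_rng(seed)
    for k in design:
        parse_karyotype(k)  # validate early
    if any(v < 0 for v in design.values()):
        raise ValueError("sample counts must be >= 0")

    batch_factors = {
        f"b{i + 1}": float(np.exp(rng.normal(0.0, batch_sd))) for i in range(n_batches)
    }
    metas: list[SampleMeta] = []
    truths: list[SampleTruth] = []
    i = 0
    for karyotype in design:
        x, y, c21 = parse_karyotype(karyotype)
        for _ in range(design[karyotype]):
            batch = f"b{(i % n_batches) + 1}"
            sample_id = f"{cell_type}_{i + 1:03d}"
            metas.append(SampleMeta(sample_id, cell_type, x, y, c21, batch))
            skew = None
            if x == 2:
                if rng.random() < skew_weights[1] / (skew_weights[0] + skew_weights[1]):
                    skew = float(rng.uniform(*skewed_range))
                else:
                    skew = float(rng.uniform(*unskewed_range))
            truths.append(
                SampleTruth(
                    sample_id=sample_id,
                    karyotype=karyotype,
                    batch_effect=batch_factors[batch],
                    depth_factor=float(np.exp(rng.normal(0.0, depth_sd))),
                    skew_s=skew,
                )
            )
            i += 1
    return metas, truths


def generate_genes(
    n_genes: int = 200,
    seed: int | np.random.Generator = 0,
    delta_levels: Sequence[float] = (-0.3, 0.0, 0.25, 0.5, 1.0),
    modulated_fraction: float = 0.0,
    modulation_magnitude: float = 0.25,
    dispersion: float = 0.05,
    include_xist: bool = False,
    par1_fraction: float = 0.05,
    n_background: int = 4000,
) -> tuple[list[GeneTruth], list[GeneAnnotation]]:
    """Build a gene panel with true ΔE_X drawn from ``delta_levels``.

    For a modulated gene the total ΔE_X is split between Xi transcription f
    and Xa modulation m (m may be negative); otherwise the response is pure
    escape (f = ΔE_X, m = 0) when positive, or pure negative modulation when
    the level is negative (f must be >= 0).  Prior XCI annotations follow the
    truth: Subject when f = 0, Escape when f > 0.

    ``n_background`` dosage-inert autosomal genes are appended so that
    library-size estimation sees a transcriptome dominated by genes that do
    not respond to X copy number, as in real data; without them the
    median-of-ratios factors would absorb part of the dosage signal.
    """
    rng = np.random.default_rng(seed)
    truths: list[GeneTruth] = []
    annos: list[GeneAnnotation] = []
    for i in range(n_genes):
        gid = f"G{i + 1:04d}"
        level = float(delta_levels[i % len(delta_levels)])
        modulated = rng.random() < modulated_fraction
        if level < 0:
            # negative response is achievable only through modulation
            f, m = 0.0, level
        elif modulated:
            m = float(modulation_magnitude * rng.choice([-1.0, 1.0]))
            f = level - m
            if f < 0:
                m, f = -m, level + modulation_magnitude
        else:
            f, m = level, 0.0
        region = "PAR1" if rng.random() < par1_fraction else "NPX"
        L = float(rng.uniform(200.0, 2000.0))
        truths.append(
            GeneTruth(
                gene_id=gid,
                baseline_L=L,
                xi_fraction_f=f,
                xa_modulation_m=m,
                dispersion=dispersion,
                region=region,
            )
        )
        annos.append(
            GeneAnnotation(
                gene_id=gid,
                symbol=gid,
                chromosome="X",
                region=region,
                length_bp=int(rng.integers(500, 5000)),
                prior_xci_status="Subject" if f == 0 else "Escape",
            )
        )
    for i in range(n_background):
        gid = f"A{i + 1:04d}"
        truths.append(
            GeneTruth(
                gene_id=gid,
                baseline_L=float(rng.uniform(200.0, 2000.0)),
                dispersion=dispersion,
                region="autosome",
            )
        )
        annos.append(
            GeneAnnotation(
                gene_id=gid,
                symbol=gid,
                chromosome="1",
                region="autosome",
                length_bp=int(rng.integers(500, 5000)),
                prior_xci_status="NoCall",
            )
        )
    if include_xist:
        truths.append(
            GeneTruth(
                gene_id="XIST",
                baseline_L=0.0,
                xi_fraction_f=0.0,
                dispersion=dispersion,
                region="NPX",
                is_xist=True,
            )
        )
        annos.append(
            GeneAnnotation(
                gene_id="XIST",
                symbol="XIST",
                chromosome="X",
                region="NPX",
                length_bp=19000,
                is_xist=True,
                prior_xci_status="Escape",
            )
        )
    return truths, annos


def generate_modulation_panel(
    n_genes: int = 200,
    seed: int | np.random.Generator = 0,
    modulated_fraction: float = 0.5,
    m_range: tuple[float, float] = (0.2, 0.3),
    escape_fraction: float = 0.3,
    f_range: tuple[float, float] = (0.1, 0.5),
    dispersion: float = 0.05,
    n_background: int = 4000,
) -> tuple[list[GeneTruth], list[GeneAnnotation]]:
    """Gene panel for trans-modulation recovery studies.

    Mirrors the observed X-chromosome landscape: most genes are silenced on
    Xi (f = 0) and escape is mostly partial (f well below 1).  Half the
    genes (``modulated_fraction``) carry a trans-modulation of the Xa allele
    with |m| in ``m_range`` and random sign (constrained so expected counts
    stay positive at three inactive X copies); the rest have m = 0 and
    serve as negatives for the false-positive rate.
    """
    rng = np.random.default_rng(seed)
    truths: list[GeneTruth] = []
    annos: list[GeneAnnotation] = []
    for i in range(n_genes):
        gid = f"G{i + 1:04d}"
        escape = rng.random() < escape_fraction
        f = float(rng.uniform(*f_range)) if escape else 0.0
        if rng.random() < modulated_fraction:
            mag = float(rng.uniform(*m_range))
            m = mag if rng.random() < 0.5 else -mag
            if f + m <= -1.0 / 3.0 + 0.05:  # keep dose positive at xi = 3
                m = mag
        else:
            m = 0.0
        truths.append(
            GeneTruth(
                gene_id=gid,
                baseline_L=float(rng.uniform(200.0, 2000.0)),
                xi_fraction_f=f,
                xa_modulation_m=m,
                dispersion=dispersion,
                region="NPX",
            )
        )
        annos.append(
            GeneAnnotation(
                gene_id=gid,
                symbol=gid,
                chromosome="X",
                region="NPX",
                length_bp=int(rng.integers(500, 5000)),
                prior_xci_status="Subject" if f == 0 else "Escape",
            )
        )
    bg_truths, bg_annos = generate_genes(
        n_genes=0, seed=rng, dispersion=dispersion, n_background=n_background
    )
    return truths + bg_truths, annos + bg_annos


# Expected normalized counts per Xi for the XIST-like gene (expressed from
# inactive X copies only, proportional to Xi count).
XIST_PER_XI = 1000.0


def expected_counts(
    genes: Sequence[GeneTruth],
    metas: Sequence[SampleMeta],
    truths: Sequence[SampleTruth],
) -> pd.DataFrame:
    """Noise-free mean count matrix implied by the generative model."""
    truth_by_id = {t.sample_id: t for t in truths}
    scale = np.array(
        [truth_by_id[m.sample_id].depth_factor * truth_by_id[m.sample_id].batch_effect
         for m in metas]
    )
    xi = np.array([m.xi_count for m in metas], dtype=float)
    ny = np.array([m.y_count for m in metas], dtype=float)
    L = np.array([g.baseline_L for g in genes])
    delta = np.array([g.true_delta_ex for g in genes])
    y_eff = np.array([g.y_effect for g in genes])
    is_xist = np.array([g.is_xist for g in genes])
    dose = 1.0 + np.outer(delta, xi) + np.outer(y_eff, ny)
    bad = (dose <= 0) & ~is_xist[:, None]
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"nonpositive expected count for gene {genes[i].gene_id} in "
            f"sample {metas[j].sample_id} (dose factor {dose[i, j]:.3g})"
        )
    mu = L[:, None] * dose * scale[None, :]
    if is_xist.any():
        mu[is_xist] = XIST_PER_XI * xi[None, :] * scale[None, :]
    return pd.DataFrame(
        mu, index=[g.gene_id for g in genes], columns=[m.sample_id for m in metas]
    )


def generate_counts(
    genes: Sequence[GeneTruth],
    metas: Sequence[SampleMeta],
    truths: Sequence[SampleTruth],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample a raw count matrix from the negative-binomial forward model."""
    rng = np.random.default_rng(seed)
    mu = expected_counts(genes, metas, truths)
    out = np.empty(mu.shape, dtype=np.int64)
    disp = np.array([g.dispersion for g in genes])
    mu_v = mu.to_numpy()
    for i in range(len(genes)):
        if disp[i] == 0:
            out[i] = np.rint(mu_v[i]).astype(np.int64)
        else:
            # Gamma-Poisson mixture: var = mu + disp * mu^2
            shape = 1.0 / disp[i]
            lam = rng.gamma(shape, mu_v[i] / shape)
            out[i] = rng.poisson(lam)
    df = pd.DataFrame(out, index=mu.index, columns=mu.columns)
    df.index.name = "gene_id"
    return df


def generate_allelic(
    genes: Sequence[GeneTruth],
    metas: Sequence[SampleMeta],
    truths: Sequence[SampleTruth],
    snps_per_gene: int = 5,
    depth: int = 100,
    het_dropout: float = 0.0,
    seed: int | np.random.Generator = 0,
    escape_cv: float = 0.25,
) -> pd.DataFrame:
    """Draw SNP-level allele counts for all two-X samples.

    Every emitted SNP is heterozygous; ``het_dropout`` thins SNPs to emulate
    homozygous-site dropout in real ascertainment.  Allele 1 is the allele on
    the X that is active in the major cell population.

    XCI escape varies between individuals, so each sample's Xi output for an
    escape gene is drawn as f_s = f * LogNormal(-cv^2/2, cv) (mean f) with
    ``escape_cv`` the inter-individual coefficient of variation; 0 disables
    the variability.
    """
    if snps_per_gene < 1:
        raise ValueError("snps_per_gene must be >= 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    truth_by_id = {t.sample_id: t for t in truths}
    records = []
    for m in metas:
        if m.x_count != 2:
            continue
        s = truth_by_id[m.sample_id].skew_s
        if s is None:  # pragma: no cover - generate_cohort always sets it
            continue
        for g in genes:
            if g.is_xist or g.region not in ("NPX", "PAR1", "PAR2"):
                continue
            f = g.xi_fraction_f
            if escape_cv > 0 and f > 0:
                f = float(
                    f * np.exp(rng.normal(-0.5 * escape_cv**2, escape_cv))
                )
            xa = 1.0 + g.xa_modulation_m
            w1 = s * xa + (1.0 - s) * f
            w2 = s * f + (1.0 - s) * xa
            p1 = w1 / (w1 + w2)
            for k in range(snps_per_gene):
                if het_dropout > 0 and rng.random() < het_dropout:
                    continue
                c1 = int(rng.binomial(depth, p1))
                records.append(
                    {
                        "sample_id": m.sample_id,
                        "gene_id": g.gene_id,
                        "snp_id": f"{g.gene_id}_snp{k + 1}",
                        "position": 1000 * (k + 1) + 1,
                        "count_allele1": c1,
                        "count_allele2": depth - c1,
                    }
                )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "sample_id",
            "gene_id",
            "snp_id",
            "position",
            "count_allele1",
            "count_allele2",
        ],
    )


def generate_constraint_metrics(
    annotations: Sequence[GeneAnnotation],
    high_constraint_genes: Sequence[str] = (),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Synthetic gene-constraint metric table (LOEUF, RVIS, pHI, P_CT).

    Genes listed in ``high_constraint_genes`` are planted at the constrained
    extreme of every metric; the rest are drawn uniformly over realistic
    ranges.  Used for driver-recovery tests; real analyses consume published
    metric tables instead.
    """
    rng = np.random.default_rng(seed)
    high = set(high_constraint_genes)
    rows = []
    for g in annotations:
        constrained = g.gene_id in high
        u = rng.uniform(0.85, 1.0) if constrained else rng.uniform(0.0, 0.8)
        rows.append(
            {
                "gene_id": g.gene_id,
                "group": "NPX" if g.region in ("NPX",) else "autosomal_PAR",
                # low LOEUF / low RVIS = constrained; high pHI / high P_CT = constrained
                "loeuf": round(2.0 * (1.0 - u) + rng.normal(0, 0.02), 4),
                "rvis": round(-4.0 * u + 2.0 + rng.normal(0, 0.05), 4),
                "phi": round(np.clip(u + rng.normal(0, 0.02), 0, 1), 4),
                "pct": round(np.clip(u + rng.normal(0, 0.02), 0, 1), 4),
                "ampliconic": g.ampliconic,
                "expected_lof": float(rng.uniform(10, 50)),
            }
        )
    return pd.DataFrame(rows)


def truth_frame(genes: Sequence[GeneTruth]) -> pd.DataFrame:
    """Per-gene truth table (written beside any generated dataset)."""
    return pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "baseline_L": g.baseline_L,
                "xi_fraction_f": g.xi_fraction_f,
                "xa_modulation_m": g.xa_modulation_m,
                "y_effect": g.y_effect,
                "dispersion": g.dispersion,
                "region": g.region,
                "is_xist": g.is_xist,
                "true_delta_ex": g.true_delta_ex,
                "true_ar": g.true_ar if not g.is_xist else np.nan,
            }
            for g in genes
        ]
    ).set_index("gene_id")


def sample_truth_frame(truths: Sequence[SampleTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": t.sample_id,
                "karyotype": t.karyotype,
                "batch_effect": t.batch_effect,
                "depth_factor": t.depth_factor,
                "skew_s": t.skew_s if t.skew_s is not None else np.nan,
            }
            for t in truths
        ]
    ).set_index("sample_id")
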