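"""Core domain records: samples, genes, run configuration.

A :class:`SampleMeta` is the single authority for chromosome copy numbers
(count matrices carry no karyotype information).  ``xi_count`` is derived as
``x_count - 1``: every diploid-derived cell keeps one active X (Xa) and
inactivates the rest (the "n - 1" rule), so the number of inactive X
chromosomes is the X count minus one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .karyotype import format_karyotype, parse_karyotype

__all__ = ["SampleMeta", "GeneAnnotation", "RunConfig"]

REGIONS = ("PAR1", "PAR2", "NPX", "NPY", "autosome")
XCI_STATUSES = ("Escape", "Subject", "NoCall")
CELL_TYPES = ("LCL", "fibroblast")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    cell_type: str
    x_count: int
    y_count: int
    chr21_count: int = 2
    batch: str = "b1"

    def __post_init__(self):
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.x_count < 1:
            raise ValueError(f"sample {self.sample_id}: x_count must be >= 1")
        if self.y_count < 0:
            raise ValueError(f"sample {self.sample_id}: y_count must be >= 0")
        if self.chr21_count not in (2, 3):
            raise ValueError(f"sample {self.sample_id}: chr21_count must be 2 or 3")

    @property
    def xi_count(self) -> int:
        return self.x_count - 1

    @property
    def karyotype(self) -> str:
        return format_karyotype(self.x_count, self.y_count, self.chr21_count)

    @classmethod
    def from_karyotype(
        cls, sample_id: str, karyotype: str, cell_type: str = "LCL", batch: str = "b1"
    ) -> "SampleMeta":
        x, y, c21 = parse_karyotype(karyotype)
        return cls(sample_id, cell_type, x, y, c21, batch)


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    symbol: str
    chromosome: str
    region: str
    length_bp: int
    npy_partner: Optional[str] = None
    ampliconic: bool = False
    is_xist: bool = False
    prior_xci_status: str = "NoCall"

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"gene {self.gene_id}: unknown region {self.region!r}")
        if self.region == "NPY" and self.chromosome != "Y":
            raise ValueError(
                f"gene {self.gene_id}: region NPY requires chromosome Y, "
                f"got {self.chromosome!r}"
            )
        if self.length_bp <= 0:
            raise ValueError(f"gene {self.gene_id}: length_bp must be > 0")
        if self.prior_xci_status not in XCI_STATUSES:
            raise ValueError(
                f"gene {self.gene_id}: unknown XCI status {self.prior_xci_status!r}"
            )


def validate_annotation(genes: list[GeneAnnotation]) -> None:
    """Check whole-annotation invariants (at most one XIST gene)."""
    n_xist = sum(g.is_xist for g in genes)
    if n_xist > 1:
        raise ValueError(f"annotation flags {n_xist} genes as XIST; expected one")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in annotation")


@dataclass
class RunConfig:
    """Analysis thresholds and switches.

    Defaults follow the study design: genes count as expressed at median
    TPM >= 1; a sample is skewed when its skewing coefficient reaches 0.8;
    Xa-only genes require ΔE_X < 0.05 with FDR > 0.5; informative SNPs need
    >= 10 reads total and >= 3 per allele; per-gene allelic ratios need
    >= 3 informative skewed samples; the AR-vs-ΔE_X modulation test uses
    BH-adjusted p < 0.1; candidate drivers need |ΔE_X| >= 0.1.
    """

    tpm_threshold: float = 1.0
    skew_threshold: float = 0.8
    xa_only_dex_max: float = 0.05
    xa_only_fdr_min: float = 0.5
    min_snp_coverage: int = 10
    min_reads_per_allele: int = 3
    min_informative_samples: int = 3
    ar_vs_dex_fdr: float = 0.1
    driver_abs_dex_min: float = 0.1
    fdr_threshold: float = 0.05
    t_many_snps: int = 20
    max_xa_only_snps_for_highly_skewed: int = 5
    n_driver_candidates: int = 10
    par1_driver_percentile_min: float = 50.0
    seed: int = 0
    excluded_genes: list = field(default_factory=list)
    expressed_allow_list: list = field(default_factory=list)
    artifact_snp_genes: list = field(default_factory=list)
    linearity_tau_a: float = 0.25
    linearity_tau_b: float = 0.05
    linearity_tau_a0: float = 0.1

    def __post_init__(self):
        if not (0 <= self.tpm_threshold):
            raise ValueError("tpm_threshold must be >= 0")
        if not (0.5 <= self.skew_threshold <= 1):
            raise ValueError("skew_threshold must be in [0.5, 1]")
        for name in ("xa_only_fdr_min", "ar_vs_dex_fdr", "fdr_threshold"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.min_snp_coverage < 1 or self.min_reads_per_allele < 0:
            raise ValueError("SNP read thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
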