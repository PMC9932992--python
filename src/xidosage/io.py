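"""Tabular input/output: count matrices, sample metadata, gene annotation,
and SNP-level allelic count tables.

All tables are tab-delimited UTF-8 with a header row.  Sparse count matrices
may instead use MatrixMarket coordinate format with ``<stem>.rows.txt`` /
``<stem>.cols.txt`` sidecar files for gene and sample names.  Readers reject
malformed input (duplicates, negative or non-integer counts, unknown ids)
rather than coercing it.  Allelic-table positions are 1-based (VCF
convention).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import GeneAnnotation, SampleMeta, validate_annotation

__all__ = [
    "read_counts",
    "write_counts",
    "read_sample_meta",
    "write_sample_meta",
    "read_annotation",
    "write_annotation",
    "read_allelic_table",
    "write_allelic_table",
    "meta_frame",
]

ALLELIC_COLUMNS = [
    "sample_id",
    "gene_id",
    "snp_id",
    "position",
    "count_allele1",
    "count_allele2",
]


def _check_count_matrix(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if df.isna().any().any():
        raise ValueError("count matrix contains missing cells")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix contains non-numeric entries")
    if (values < 0).any():
        raise ValueError("count matrix contains negative counts")
    if not np.allclose(values, np.round(values)):
        raise ValueError("count matrix contains non-integer counts")
    out = df.astype(np.int64)
    out.index.name = "gene_id"
    return out


def read_counts(path, samples: list[str] | None = None) -> pd.DataFrame:
    """Read a gene × sample count matrix (TSV, or MatrixMarket + sidecars).

    If ``samples`` is given, every column must appear in it.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        gene_ids = path.with_suffix(".rows.txt").read_text().split()
        sample_ids = path.with_suffix(".cols.txt").read_text().split()
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        df = pd.DataFrame(dense, index=gene_ids, columns=sample_ids)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df = _check_count_matrix(df)
    if samples is not None:
        unknown = [s for s in df.columns if s not in set(samples)]
        if unknown:
            raise ValueError(f"sample ids absent from metadata: {unknown}")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(df.to_numpy()))
        path.with_suffix(".rows.txt").write_text("\n".join(df.index) + "\n")
        path.with_suffix(".cols.txt").write_text("\n".join(df.columns) + "\n")
    else:
        df.to_csv(path, sep="\t", index_label="gene_id")


def meta_frame(metas: list[SampleMeta]) -> pd.DataFrame:
    """Flatten SampleMeta records into a DataFrame indexed by sample_id."""
    rows = [
        {
            "sample_id": m.sample_id,
            "cell_type": m.cell_type,
            "karyotype": m.karyotype,
            "x_count": m.x_count,
            "y_count": m.y_count,
            "chr21_count": m.chr21_count,
            "xi_count": m.xi_count,
            "batch": m.batch,
        }
        for m in metas
    ]
    df = pd.DataFrame(rows)
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return df.set_index("sample_id")


def write_sample_meta(metas: list[SampleMeta], path) -> None:
    meta_frame(metas).to_csv(path, sep="\t")


def read_sample_meta(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"batch": str})
    metas = []
    for _, row in df.iterrows():
        m = SampleMeta(
            sample_id=str(row["sample_id"]),
            cell_type=row["cell_type"],
            x_count=int(row["x_count"]),
            y_count=int(row["y_count"]),
            chr21_count=int(row.get("chr21_count", 2)),
            batch=str(row["batch"]),
        )
        if "karyotype" in row and isinstance(row["karyotype"], str):
            if m.karyotype != row["karyotype"]:
                raise ValueError(
                    f"sample {m.sample_id}: karyotype {row['karyotype']!r} does not "
                    f"round-trip to copy numbers {(m.x_count, m.y_count, m.chr21_count)}"
                )
        metas.append(m)
    return metas


def write_annotation(genes: list[GeneAnnotation], path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "chromosome": g.chromosome,
                "region": g.region,
                "npy_partner": g.npy_partner or "",
                "ampliconic": int(g.ampliconic),
                "length_bp": g.length_bp,
                "is_xist": int(g.is_xist),
                "prior_xci_status": g.prior_xci_status,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_annotation(path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    genes = [
        GeneAnnotation(
            gene_id=str(r["gene_id"]),
            symbol=str(r["symbol"]),
            chromosome=str(r["chromosome"]),
            region=r["region"],
            npy_partner=str(r["npy_partner"]) or None,
            ampliconic=bool(int(r["ampliconic"])),
            length_bp=int(r["length_bp"]),
            is_xist=bool(int(r["is_xist"])),
            prior_xci_status=r["prior_xci_status"],
        )
        for _, r in df.iterrows()
    ]
    validate_annotation(genes)
    return genes


def annotation_frame(genes: list[GeneAnnotation]) -> pd.DataFrame:
    validate_annotation(genes)
    return pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "region": g.region,
                "npy_partner": g.npy_partner,
                "ampliconic": g.ampliconic,
                "length_bp": g.length_bp,
                "is_xist": g.is_xist,
                "prior_xci_status": g.prior_xci_status,
            }
            for g in genes
        ]
    ).set_index("gene_id")


def read_allelic_table(
    path, samples: list[str] | None = None, genes: list[str] | None = None
) -> pd.DataFrame:
    """Read a SNP-level allele-count table.

    Columns: sample_id, gene_id, snp_id, position (1-based), count_allele1,
    count_allele2.  Rejects negative counts, unknown sample/gene ids, and
    duplicate (sample_id, snp_id) records.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ALLELIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"allelic table missing columns: {missing}")
    df = df[ALLELIC_COLUMNS].copy()
    return validate_allelic_table(df, samples=samples, genes=genes)


def validate_allelic_table(
    df: pd.DataFrame,
    samples: list[str] | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    for col in ("count_allele1", "count_allele2"):
        if (df[col] < 0).any():
            bad = df.loc[df[col] < 0].iloc[0]
            raise ValueError(
                f"negative allele count at {bad['sample_id']}/{bad['snp_id']}"
            )
    dup = df.duplicated(subset=["sample_id", "snp_id"])
    if dup.any():
        bad = df.loc[dup, ["sample_id", "snp_id"]].iloc[0]
        raise ValueError(
            f"duplicate (sample, snp) record: ({bad['sample_id']}, {bad['snp_id']})"
        )
    if samples is not None:
        unknown = sorted(set(df["sample_id"]) - set(samples))
        if unknown:
            raise ValueError(f"allelic table has unknown sample ids: {unknown}")
    if genes is not None:
        unknown = sorted(set(df["gene_id"]) - set(genes))
        if unknown:
            raise ValueError(f"allelic table has unknown gene ids: {unknown}")
    return df


def write_allelic_table(df: pd.DataFrame, path) -> None:
    df[ALLELIC_COLUMNS].to_csv(path, sep="\t", index=False)
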