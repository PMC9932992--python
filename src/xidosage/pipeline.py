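"""End-to-end simulated analysis: simulate -> normalize -> dosage -> allelic
-> modulation -> constraint.

Mainly a convenience wrapper for smoke tests and examples; each stage is an
ordinary library call and can be run on real tables instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import allelic as al
from . import constraint as cn
from . import dosage as ds
from . import modulation as md
from . import normalize as nm
from . import simulate as sim
from .io import annotation_frame, meta_frame
from .types import RunConfig

__all__ = ["run_pipeline"]


def run_pipeline(
    seed: int = 0,
    design: dict | None = None,
    n_genes: int = 200,
    modulated_fraction: float = 0.3,
    snps_per_gene: int = 5,
    depth: int = 100,
    dispersion: float = 0.05,
    n_driver_plants: int = 5,
    config: RunConfig | None = None,
    genes: tuple | None = None,
) -> dict:
    """Simulate a cohort and run every analysis stage.

    Returns a dict with the simulated truth, intermediate tables, the
    modulation calls, and the ranked driver candidates (with the planted
    high-constraint genes for recovery checks).
    """
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    design = design or sim.DEFAULT_LCL_DESIGN
    metas, sample_truths = sim.generate_cohort(
        design, "LCL", n_batches=4, seed=rng
    )
    if genes is not None:
        gene_truths, annos = genes
    else:
        gene_truths, annos = sim.generate_genes(
            n_genes=n_genes,
            seed=rng,
            modulated_fraction=modulated_fraction,
            dispersion=dispersion,
        )
    counts = sim.generate_counts(gene_truths, metas, sample_truths, seed=rng)
    allelic_table = sim.generate_allelic(
        gene_truths, metas, sample_truths,
        snps_per_gene=snps_per_gene, depth=depth, het_dropout=0.2, seed=rng,
    )
    meta = meta_frame(metas)
    anno = annotation_frame(annos)
    truth = sim.truth_frame(gene_truths)

    norm, factors = nm.normalize_counts(counts)
    tpm_df = nm.tpm(counts, anno["length_bp"])
    expressed = nm.filter_expressed(tpm_df, meta, config.tpm_threshold)
    x_genes = set(anno.index[anno["region"].isin(["NPX", "PAR1", "PAR2"])])
    # config-listed outliers (ad hoc exclusions, e.g. error-dominated genes)
    keep = sorted((expressed["union"] & x_genes) - set(config.excluded_genes))

    dex = ds.dosage_analysis(norm.loc[keep], meta, "NPX_PAR", "X")

    filtered = al.filter_informative_snps(
        allelic_table, set(keep), meta, anno, config
    )
    xa_only = al.classify_xa_only(anno, dex, config)
    skew = al.call_skew(filtered, xa_only, meta, config)
    gene_ar, per_sample_ar = al.gene_allelic_ratio(filtered, skew, config)

    ar_vs_dex = md.test_ar_vs_dex(per_sample_ar, dex, gene_ar, config)
    calls = md.classify_modulation(
        dex, gene_ar, anno["prior_xci_status"], ar_vs_dex, config.fdr_threshold
    )

    # plant drivers: genes with strong true dosage responses get extreme
    # constraint metrics, so candidate selection should recover them
    strong = truth[(truth["true_delta_ex"].abs() >= 0.25) & ~truth["is_xist"]]
    planted = list(strong.index[:n_driver_plants])
    metrics = sim.generate_constraint_metrics(annos, planted, seed=rng)
    cons = cn.percentile_ranks(metrics)
    drivers = cn.candidate_drivers({"LCL": dex}, cons, config)

    return {
        "meta": meta,
        "annotation": anno,
        "truth": truth,
        "sample_truth": sim.sample_truth_frame(sample_truths),
        "counts": counts,
        "size_factors": factors,
        "expressed": expressed,
        "dex": dex,
        "skew": skew,
        "gene_ar": gene_ar,
        "per_sample_ar": per_sample_ar,
        "ar_vs_dex": ar_vs_dex,
        "modulation": calls,
        "constraint": cons,
        "drivers": drivers,
        "planted_drivers": planted,
    }
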