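"""Simulate a sex-chromosome-aneuploidy cohort with known ground truth.

Builds the default 106-sample LCL design (karyotypes 45,X through 49,XYYYY),
draws a negative-binomial count matrix for a 200-gene X panel plus an
autosomal background, and writes the tables next to their truth files.
"""

from pathlib import Path

from xidosage import simulate as sim
from xidosage.io import meta_frame, write_counts, write_sample_meta

out = Path("scratch/example_cohort")
out.mkdir(parents=True, exist_ok=True)

metas, sample_truths = sim.generate_cohort(sim.DEFAULT_LCL_DESIGN, seed=1)
genes, annotations = sim.generate_genes(n_genes=200, seed=1)
counts = sim.generate_counts(genes, metas, sample_truths, seed=2)
allelic = sim.generate_allelic(genes, metas, sample_truths,
                               snps_per_gene=5, depth=100, seed=3)

write_sample_meta(metas, out / "samples.tsv")
write_counts(counts, out / "counts.tsv")
allelic.to_csv(out / "allelic.tsv", sep="\t", index=False)
sim.truth_frame(genes).to_csv(out / "gene_truth.tsv", sep="\t")
sim.sample_truth_frame(sample_truths).to_csv(out / "sample_truth.tsv", sep="\t")

meta = meta_frame(metas)
print(f"cohort: {len(metas)} samples, "
      f"{meta['karyotype'].nunique()} karyotypes, "
      f"{meta['batch'].nunique()} batches")
print(meta["karyotype"].value_counts().to_string())
print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples; "
      f"allelic reads at {allelic['snp_id'].nunique()} SNPs in two-X samples")
# Each row of gene_truth.tsv records the generative Xi transcription
# fraction f and Xa trans-modulation m; the true dosage response is f + m.
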