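"""Generate a truth-annotated synthetic ATAC+RNA dataset.

Emits a small genome (FASTA), gene models (GTF), a disjoint TAD partition
(BED), per-sample peak calls with replicate jitter, NB count matrices for
both modalities, and a truth ledger recording every planted link,
differential gene, group-unique peak and motif instance.
"""

from tadlink.motif import load_builtin_pwm
from tadlink.synthetic_data import SimConfig, generate_dataset, write_dataset

config = SimConfig(seed=17)
pwm = load_builtin_pwm()
bundle = generate_dataset(config, motif_consensus=pwm.consensus)
manifest = write_dataset(bundle, "example_output/dataset")

print(f"genome: {config.n_chromosomes} x {config.chrom_length:,} bp, "
      f"{len(list(bundle.genome.tads))} TADs, {len(bundle.genome.genes)} genes")
print(f"peaks: {len(bundle.peaks.master_peaks)} master peaks across "
      f"{len(bundle.peaks.sample_peaks)} samples (2 groups x 4 replicates)")
print(f"planted: {len(bundle.truth.links)} peak-gene links, "
      f"{len(bundle.truth.de_genes)} differential genes, "
      f"{len(bundle.truth.motif_placements)} motif instances")
print(f"config hash {manifest['config_hash']} -> example_output/dataset/")
# The truth ledger is what downstream examples and tests score against:
# every planted entity exists in the emitted files.
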