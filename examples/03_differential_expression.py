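"""Negative-binomial differential testing with BH correction.

Runs the moment/Wald NB test on synthetic RNA counts with 30 planted
upregulated genes (true log2 fold change = 2), calls features at
adjusted p < 0.05 and |LFC| >= 1, and reports how many planted genes the
thresholds recover.
"""

from tadlink.counts_stats import AnalysisConfig, call_differential, nb_wald_test
from tadlink.synthetic_data import (
    SimConfig,
    generate_counts,
    generate_genome,
    generate_peaks_and_truth,
)

config = SimConfig(seed=17)
genome = generate_genome(config)
peaks = generate_peaks_and_truth(genome, config)
_, rna = generate_counts(genome, peaks, config)

records = nb_wald_test(rna)
calls = call_differential(records, AnalysisConfig(alpha_de=0.05, lfc_min=1.0))
planted = {d["gene"] for d in peaks.truth.de_genes}
recovered = planted & set(calls["up"])

print(f"tested {len(records)} genes across {rna.shape[1]} samples")
print(f"called {len(calls['up'])} up / {len(calls['down'])} down "
      f"(adjusted p < 0.05, |LFC| >= 1)")
print(f"planted upregulated genes recovered: {len(recovered)}/{len(planted)}")
top = sorted((r for r in records if r.call == "up"), key=lambda r: r.p_adj)[:3]
for r in top:
    print(f"  {r.feature_id}: LFC={r.lfc:.2f}, adj p={r.p_adj:.2e}")
# Planted genes have their group-B NB mean multiplied by 2^2; the
# recovered LFC estimates should cluster near 2.
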