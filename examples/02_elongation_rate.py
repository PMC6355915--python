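"""Elongation rates from a DRB/4sU nascent-RNA time course.

Simulates the four-timepoint design (0, 2, 8, 16 min after release
from a DRB block) at 1 kb/min, detects the transcription wave front
per gene at 2 and 8 min, and derives per-gene elongation rates as
(front_8 - front_2) / 6 min.
"""

from polpause import genomewide_rates
from polpause.simulate import SimulationConfig, simulate_drb_timecourse, simulate_genes

cfg = SimulationConfig(n_genes=200, seed=2, frac_genes_over_10kb=0.9)
genome = simulate_genes(cfg)
drb = simulate_drb_timecourse(genome)  # advances at cfg.elongation_rate

long_genes = [g for g in genome.genes if g.length > 10_000]
res = genomewide_rates(drb.tracks[2.0], drb.tracks[8.0], long_genes)

print(f"genes longer than 10 kb: {len(long_genes)}")
print(f"genes with a defined rate: {res.n_genes}")
print(f"mean elongation rate:   {res.mean_rate:7.1f} bp/min")
print(f"median elongation rate: {res.median_rate:7.1f} bp/min")
print(f"fraction flagged: {res.fraction_flagged:.2%}")
print(res.table.head(5).to_string(index=False))
print("\nThe simulation advanced at 1000 bp/min; the mean recovered rate")
print("should sit within a few percent of that truth.")
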