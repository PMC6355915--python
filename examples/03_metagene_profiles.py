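"""Metagene profiles and a TSS-centered occupancy heatmap.

Builds a scaled metagene profile (600 bp flanks, body rescaled to
100 bins), a TSS +/- 1 kb profile, and a TSS heatmap matrix sorted by
decreasing promoter occupancy, all from one simulated Pol II ChIP.
"""

import numpy as np

from polpause import (
    ratio_normalize, scaled_metagene, tss_centered_profile, tss_heatmap_matrix,
)
from polpause.simulate import SimulationConfig, simulate_chip, simulate_genes

genome = simulate_genes(SimulationConfig(n_genes=300, seed=3))
sim = simulate_chip(genome, "control")
enrichment = ratio_normalize(sim.ip, sim.input)

prof = scaled_metagene(enrichment, genome.genes)
tss_prof = tss_centered_profile(enrichment, genome.genes, halfwidth=1_000)
matrix, order, x = tss_heatmap_matrix(enrichment, genome.genes)

body = prof.mean[prof.upstream:prof.upstream + prof.n_body_bins]
print(f"scaled profile: {prof.n_genes} genes, {len(prof.x)} positions")
print(f"  mean body enrichment: {body.mean():.2f}")
peak_pos = int(tss_prof.x[np.argmax(tss_prof.mean)])
print(f"TSS profile peaks at {peak_pos:+d} bp "
      f"(enrichment {tss_prof.mean.max():.2f}, SEM {tss_prof.sem[np.argmax(tss_prof.mean)]:.3f})")
print(f"heatmap: {matrix.shape[0]} genes x {matrix.shape[1]} bins; "
      f"top gene by promoter occupancy: {order[0]}")
print("\nThe promoter peak rises above the gene-body plateau at the TSS,")
print("mirroring promoter-proximal Pol II accumulation.")
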