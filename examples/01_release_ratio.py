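"""Pol II release ratio (PRR) on a two-condition ChIP experiment.

Simulates a control and a knockdown condition that differ only in the
strength of the promoter-proximal Pol II peak (the knockdown halves
it), computes per-gene PRRs on input-normalized enrichment, and
compares the two PRR distributions with a two-sample KS test plus a
quartile breakdown of the shift.
"""

import numpy as np

from polpause import prr_compare, prr_table, quartile_stratify, ratio_normalize
from polpause.simulate import SimulationConfig, simulate_chip, simulate_genes

cfg = SimulationConfig(n_genes=500, seed=1)
genome = simulate_genes(cfg)
control = simulate_chip(genome, "control")
knockdown = simulate_chip(genome, "kd", pause_strength=cfg.pause_strength / 2)

enr_ctrl = ratio_normalize(control.ip, control.input)
enr_kd = ratio_normalize(knockdown.ip, knockdown.input)

# TSS selection always uses the control condition
tab_ctrl = prr_table(enr_ctrl, genome.genes, control_enrichment=enr_ctrl,
                     condition="control")
tab_kd = prr_table(enr_kd, genome.genes, control_enrichment=enr_ctrl,
                   condition="kd")

res = prr_compare(tab_ctrl, tab_kd)
print(f"eligible genes in both conditions: {res.n}")
print(f"median PRR control: {np.median(res.values_a):+.3f}")
print(f"median PRR knockdown: {np.median(res.values_b):+.3f}")
print(f"two-sample KS: D = {res.statistic:.3f}, p = {res.pvalue:.3g}")

ctrl = tab_ctrl[tab_ctrl.eligible].set_index("gene_id")["prr"]
kd = tab_kd[tab_kd.eligible].set_index("gene_id")["prr"]
shared = ctrl.index.intersection(kd.index)
_, summary = quartile_stratify(ctrl[shared].to_dict(),
                               (kd - ctrl)[shared].dropna().to_dict())
print("\nPRR shift by control-PRR quartile (1 = most paused):")
for row in summary.itertuples():
    print(f"  Q{row.quartile}: median delta = {row.median:+.3f} (n={row.n})")
print("\nA positive shift means Pol II is released into the gene body;")
print("the most strongly paused quartile moves the most.")
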