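"""Simulate bursty expression and check the NB moment identities.

Draws a paired treated/control smFISH-like dataset for one gene with
burst size b=5 and burst frequency f=4, with the treated condition using
the reciprocal perturbation (b*2, f/2).  Prints sample mean and Fano
against the closed forms mean = b*f and Fano = 1 + b: the treatment
leaves the mean untouched while the Fano factor rises from 6 toward 11.
"""

import numpy as np

from noisebench import GeneSpec, SimConfig, simulate_smfish

cfg = SimConfig(
    genes=(GeneSpec("demo", burst_size=5.0, burst_frequency=4.0),),
    n_cells=50_000, n_replicates=1, extrinsic_coupling=0.0,
    amplification=2.0, seed=42,
)
treated, control, truth = simulate_smfish(cfg)

for label, table, cond in (("control", control, "control"),
                           ("treated", treated, "treated")):
    x = table["count_demo"].to_numpy(dtype=float)
    row = truth.gene_row("demo", cond)
    print(f"{label}: sample mean {x.mean():6.2f} (theory {row['intrinsic_mean']:.0f}), "
          f"sample Fano {x.var(ddof=1)/x.mean():5.2f} "
          f"(theory {row['intrinsic_fano']:.0f})")
print("-> the mean is conserved while noise (Fano) nearly doubles: "
      "homeostatic noise amplification.")
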