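"""Build a functional network and measure its small-world organization.

Takes one preprocessed synthetic subject, computes the 13x13 Pearson
connectivity matrix of the dHbO channels, binarizes it at a few sparsity
levels and prints the graph indices: clustering Cp, characteristic path
length Lp, global efficiency Eg and small-worldness sigma against 100
degree-preserving rewired null networks.  sigma > 1 marks a small-world
network: clustered like a lattice, integrated like a random graph.
"""

import numpy as np

from nirsnet import (
    connectivity,
    default_config,
    preprocess_recording,
    simulate_subject,
    threshold_sweep,
)

cfg = default_config(seed=0)
recording, _ = simulate_subject(cfg, group="TD", subject_seed=0)
hemo = preprocess_recording(recording)

matrix = connectivity(hemo)
print("mean off-diagonal correlation:",
      round(float(matrix.r[np.triu_indices(13, 1)].mean()), 3))

grid = [0.2, 0.3, 0.4, 0.5]
print("\nsparsity  edges  Cp     Lp     Eg     sigma")
for m in threshold_sweep(matrix, mode="sparsity", grid=grid, n_null=100, seed=0):
    print(f"  {m.threshold:.2f}    {m.n_edges:3d}  {m.cp:.3f}  {m.lp:.3f}  "
          f"{m.eg:.3f}  {m.sigma:.3f}")
print("\nsigma > 1 at every level: the network clusters more than its "
      "degree-matched random references at comparable path length.")
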