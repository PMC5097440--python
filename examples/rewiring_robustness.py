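"""Key driver reproducibility under topological noise.

A network with a planted module is progressively rewired and wKDA is run on
the original and each rewired copy; reproducibility is the Jaccard overlap
of the significant key drivers.  The overlap should degrade with the
rewiring fraction and vanish at 100%.
"""

import numpy as np

import mergenet as mg

n = 200
names = mg.node_labels(n)
rng = np.random.default_rng(0)
hub = names[0]
members = list(rng.choice(names[1:], 30, replace=False))
net = mg.synthetic_network(n, planted_module=(hub, members), seed=0)
sets = mg.GeneSetCollection.from_dict({"MODULE": members})
params = mg.WkdaParams(nperm=500, seed=0)

print(f"{'rewired':>8} {'median Jaccard':>15}")
for fraction in (0.0, 0.25, 0.5, 0.75, 1.0):
    values = [
        mg.kd_reproducibility(
            net, mg.rewire_network(net, fraction, seed=10 + s),
            sets, params, fdr_cutoff=0.25,
        )
        for s in range(5)
    ]
    print(f"{fraction:>8.2f} {np.median(values):>15.3f}")
print("\nJaccard 1 means the same key drivers are found on both networks; "
      "0 means none are shared.  Full rewiring destroys the planted "
      "neighbourhood, so no consistent key drivers remain.")
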