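#!/usr/bin/env python
"""Phylogenetic discriminant analysis over the lambda grid.

Whitens the copy-number features by the lambda-scaled Brownian covariance
of the (ultrametricized) tree, refits the discriminant at each grid
value (0 to 0.1, step 0.01), and reports the lambda minimising training
misclassification.
"""

from _config import make_config
from dietcnv import pipeline

cfg = make_config()
tab = pipeline.run_pfda(cfg)
best = tab.loc[tab["optimal"]].iloc[0]
print("lambda grid misclassification:")
for _, r in tab.iterrows():
    mark = " <- optimal" if r["optimal"] else ""
    print(f"  lambda={r['lambda']:.2f}: {r['misclassification']:.3f}{mark}")
print(f"optimal lambda = {best['lambda']:.2f}; "
      f"table -> {cfg.outdir}/pfda.tsv")
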