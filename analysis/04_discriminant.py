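#!/usr/bin/env python
"""Herbivore/carnivore discriminant function with validation.

Fits the LDA on the significant families, reduces the feature set by
Wilks'-lambda stepwise forward selection, and validates by leave-one-out
cross-validation and by holding out whole clades (the two halves of the
root split).
"""

from _config import make_config
from dietcnv import pipeline

cfg = make_config()
report = pipeline.run_discriminant(cfg)
print(f"discriminant families: {len(report['families_full'])} -> "
      f"{len(report['families_selected'])} after stepwise selection "
      f"({', '.join(report['families_selected'])})")
print(f"Wilks' lambda: {report['wilks_full']:.3f} (full) vs "
      f"{report['wilks_selected']:.3f} (selected)")
print(f"LOOCV accuracy: {report['loocv_accuracy_full']:.1%} (full), "
      f"{report['loocv_accuracy_selected']:.1%} (selected)")
print(f"priors: { {k: round(v, 3) for k, v in report['priors'].items()} }")
print(f"model/scores/validation -> {cfg.outdir}/discriminant_*.json, "
      "df_scores.tsv, loocv.tsv, clade_holdout.tsv")
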