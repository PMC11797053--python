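#!/usr/bin/env python
"""Classify duplication modes with the 5-Mb co-location rule.

Each (family, species) with two or more chromosome-anchored copies is
called tandem (all copies within 5 Mb relations on one chromosome),
interchromosomal (no close pair), or both; fewer than two placed copies
is not determined (ND).
"""

from _config import make_config
from dietcnv import pipeline

cfg = make_config()
summary = pipeline.run_dupmode(cfg)
totals = summary.sum()
print("duplication-mode calls (all species):")
print("  " + ", ".join(f"{k}={int(v)}" for k, v in totals.items()))
print("per-species summary (first 8):")
print(summary.head(8).to_string())
print(f"tables -> {cfg.outdir}/dup_calls.tsv, dup_summary.tsv")
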