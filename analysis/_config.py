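"""Shared configuration for the numbered analysis scripts.

All scripts analyse one synthetic dataset generated by 01_simulate.py
under ``results/synthetic_data/`` and write their tables to
``results/``. The seed fixes everything.
"""

from pathlib import Path

from dietcnv import pipeline

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "synthetic_data"
OUT = ROOT / "results"
SEED = 20250930


def make_config() -> pipeline.PipelineConfig:
    return pipeline.PipelineConfig(
        ortholog_tsv=str(DATA / "orthologs.tsv"),
        newick=str(DATA / "tree.nwk"),
        trophic_csv=str(DATA / "trophic.csv"),
        locus_tsv=str(DATA / "loci.tsv"),
        diet_csv=str(DATA / "diet.csv"),
        simulate=True,
        n_species=32,
        n_families=100,
        n_planted=10,
        outdir=str(OUT),
        seed=SEED,
    )
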