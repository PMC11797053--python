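"""Readers and alignment for the pipeline's tabular inputs.

Parses ortholog-group tables (one row per gene family, comma-separated
protein IDs per species) into the species x family copy-number matrix,
trophic metadata CSVs, BED-like locus tables, and aligns everything with
the phylogeny onto one common, consistently ordered species set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CATEGORIES
from .trees import PhyloTree, PhyloCov, prune_to_species, vcv_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologDialect",
    "ProteinRecord",
    "read_ortholog_groups",
    "select_longest_isoform",
    "read_trophic_table",
    "apply_relabel",
    "read_locus_table",
    "read_diet_table",
    "align_dataset",
]


@dataclass(frozen=True)
class OrthologDialect:
    sep: str = "\t"
    id_sep: str = ","
    empty: str = "*"
    family_column: str = "family"


@dataclass(frozen=True)
class ProteinRecord:
    """One annotated protein; ``complete`` mirrors the presence of both a
    protein id and a translation in the source annotation."""

    species: str
    gene_id: str
    protein_id: str
    length: int
    complete: bool = True

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("protein length must be >= 1")


def read_ortholog_groups(
    path, dialect: OrthologDialect = OrthologDialect()
) -> pd.DataFrame:
    """Ortholog-group TSV -> copy-number matrix (species rows, family cols).

    A cell's count is its number of protein IDs; the empty marker (default
    ``*``) or a blank cell counts 0.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(dialect.sep)
        if header[0] != dialect.family_column:
            raise ValueError(
                f"first header field must be {dialect.family_column!r}, "
                f"got {header[0]!r}")
        species = header[1:]
        if len(set(species)) != len(species):
            raise ValueError("duplicate species in header")
        families, counts = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split(dialect.sep)
            if len(fields) != len(header):
                raise ValueError(
                    f"line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}")
            families.append(fields[0])
            counts.append([
                0 if cell in ("", dialect.empty)
                else len(cell.split(dialect.id_sep))
                for cell in fields[1:]
            ])
    if len(set(families)) != len(families):
        dupes = sorted({f for f in families if families.count(f) > 1})
        raise ValueError(f"duplicate family ids: {dupes}")
    return pd.DataFrame(
        np.asarray(counts, dtype=int).T,
        index=pd.Index(species, name="species"),
        columns=families,
    )


def select_longest_isoform(records: list[ProteinRecord]) -> list[ProteinRecord]:
    """One protein per (species, gene): the longest annotated isoform.

    Records flagged incomplete (missing protein id / translation in the
    annotation) are dropped first. Length ties break to the
    lexicographically smallest protein id, for determinism.
    """
    if not records:
        raise ValueError("no records")
    best: dict[tuple[str, str], ProteinRecord] = {}
    for rec in records:
        if not rec.complete:
            continue
        key = (rec.species, rec.gene_id)
        cur = best.get(key)
        if (cur is None or rec.length > cur.length
                or (rec.length == cur.length
                    and rec.protein_id < cur.protein_id)):
            best[key] = rec
    return list(best.values())


def read_trophic_table(path) -> pd.DataFrame:
    """Species metadata CSV with columns ``species``, ``category`` and an
    optional quantitative ``trophic_level``."""
    df = pd.read_csv(path)
    if not {"species", "category"} <= set(df.columns):
        raise ValueError("trophic CSV needs 'species' and 'category' columns")
    bad = df.loc[~df["category"].isin(CATEGORIES)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"unknown trophic category {row['category']!r} for species "
            f"{row['species']!r} (allowed: {', '.join(CATEGORIES)})")
    if df["species"].duplicated().any():
        raise ValueError("duplicate species in trophic table")
    return df.reset_index(drop=True)


def apply_relabel(table: pd.DataFrame, relabel: pd.DataFrame) -> pd.DataFrame:
    """Overlay category changes (species, category) on a base table.

    This is how alternative classifications of borderline species (e.g. a
    panda recoded from herbivore to omnivore) are expressed without
    editing the base metadata.
    """
    bad = relabel.loc[~relabel["category"].isin(CATEGORIES)]
    if not bad.empty:
        raise ValueError(
            f"unknown category in relabel table: {bad.iloc[0]['category']!r}")
    unknown = set(relabel["species"]) - set(table["species"])
    if unknown:
        raise ValueError(f"relabel names unknown species: {sorted(unknown)}")
    out = table.copy()
    mapping = relabel.set_index("species")["category"]
    mask = out["species"].isin(mapping.index)
    out.loc[mask, "category"] = out.loc[mask, "species"].map(mapping)
    return out


def read_locus_table(path) -> pd.DataFrame:
    """BED-like locus TSV: family, species, chrom (or UNPLACED), start, end."""
    df = pd.read_csv(
        path, sep="\t",
        names=["family", "species", "chrom", "start", "end"],
        header=0,
    )
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValueError("locus table must satisfy 0 <= start < end")
    return df


def read_diet_table(path) -> pd.DataFrame:
    """Diet-composition CSV: species, prey_class, proportion."""
    df = pd.read_csv(path)
    need = {"species", "prey_class", "proportion"}
    if not need <= set(df.columns):
        raise ValueError(f"diet CSV needs columns {sorted(need)}")
    if (df["proportion"] < 0).any():
        raise ValueError("proportions must be >= 0")
    return df


def align_dataset(
    matrix: pd.DataFrame, table: pd.DataFrame, tree: PhyloTree
) -> tuple[pd.DataFrame, pd.DataFrame, PhyloCov]:
    """Restrict matrix, metadata and tree to their common species.

    All three outputs share one species order (the pruned tree's tip
    order). Dropped species are logged, never silently discarded.
    """
    common = (set(matrix.index) & set(table["species"])
              & set(tree.tip_labels))
    if len(common) < 4:
        raise ValueError(
            f"only {len(common)} species shared by matrix, metadata and "
            "tree; need >= 4")
    for name, have in (("matrix", set(matrix.index)),
                       ("trophic table", set(table["species"])),
                       ("tree", set(tree.tip_labels))):
        dropped = sorted(have - common)
        if dropped:
            logger.warning("align_dataset: dropping %d species from %s: %s",
                           len(dropped), name, ", ".join(dropped))
    pruned = (tree if common == set(tree.tip_labels)
              else prune_to_species(tree, common))
    cov = vcv_matrix(pruned)
    order = cov.species
    return (
        matrix.loc[order],
        table.set_index("species").loc[order].reset_index(),
        cov,
    )
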