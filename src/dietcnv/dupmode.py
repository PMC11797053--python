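"""Tandem vs interchromosomal duplication calls from gene coordinates.

Two copies of a family in one species are a *tandem* pair when they lie on
the same chromosome within a 5-Mb window (start-to-start, inclusive);
otherwise their relation is interchromosomal. A family in a species is
called ``tandem`` when every placed copy participates only in tandem
relations, ``interchromosomal`` when no tandem pair exists, ``both`` when
a tandem pair coexists with a copy whose relations are all non-tandem, and
``ND`` (not determined) with fewer than two placed copies — copies on
unanchored contigs (chromosome ``UNPLACED``) do not count as placed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DupCall", "classify_duplication", "classify_all",
           "summarize_dup_calls", "UNPLACED", "WINDOW"]

UNPLACED = "UNPLACED"
WINDOW = 5_000_000
CALLS = ("tandem", "interchromosomal", "both", "ND")


@dataclass(frozen=True)
class DupCall:
    family: str
    species: str
    call: str
    n_copies: int  # placed copies
    pair_distances: tuple  # same-chromosome start distances


def classify_duplication(
    loci: pd.DataFrame, window: int = WINDOW, distance: str = "start"
) -> DupCall:
    """Classify the duplication mode of one (family, species).

    ``distance='start'`` measures |start_a - start_b|; ``'gap'`` measures
    the gap between intervals (0 if they overlap). The threshold is
    inclusive.
    """
    fams = loci["family"].unique()
    sps = loci["species"].unique()
    if len(fams) != 1 or len(sps) != 1:
        raise ValueError("loci must cover exactly one family and species")
    family, species = fams[0], sps[0]
    placed = loci.loc[loci["chrom"] != UNPLACED].reset_index(drop=True)
    k = len(placed)
    if k < 2:
        return DupCall(family, species, "ND", k, ())
    chrom = placed["chrom"].to_numpy()
    start = placed["start"].to_numpy()
    end = placed["end"].to_numpy()
    tandem_with = np.zeros(k, dtype=bool)
    any_tandem = False
    dists = []
    for i in range(k):
        for j in range(i + 1, k):
            if chrom[i] != chrom[j]:
                continue
            if distance == "start":
                d = abs(int(start[i]) - int(start[j]))
            elif distance == "gap":
                d = max(0, max(start[i], start[j]) - min(end[i], end[j]))
            else:
                raise ValueError(f"unknown distance rule {distance!r}")
            dists.append(int(d))
            if d <= window:
                tandem_with[i] = tandem_with[j] = True
                any_tandem = True
    if not any_tandem:
        call = "interchromosomal"
    elif tandem_with.all():
        call = "tandem"
    else:
        call = "both"
    return DupCall(family, species, call, k, tuple(dists))


def classify_all(
    loci: pd.DataFrame, window: int = WINDOW, distance: str = "start"
) -> list[DupCall]:
    """Classify every (family, species) present in the locus table."""
    return [
        classify_duplication(group, window=window, distance=distance)
        for _, group in loci.groupby(["family", "species"], sort=True)
    ]


def summarize_dup_calls(calls) -> pd.DataFrame:
    """Per-species counts of tandem / interchromosomal / both / ND calls."""
    rows = pd.DataFrame(
        [(c.species, c.call) for c in calls], columns=["species", "call"]
    )
    if rows.empty:
        return pd.DataFrame(columns=list(CALLS))
    table = (rows.value_counts().unstack(fill_value=0)
             .reindex(columns=CALLS, fill_value=0))
    table.columns.name = None
    return table.sort_index()
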