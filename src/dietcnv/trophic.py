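"""Quantitative trophic levels from diet compositions.

A consumer's trophic level is one plus the proportion-weighted mean of its
prey's trophic levels:

    TL_i = 1 + (sum_j DC_ij * TL_j) / (sum_j DC_ij)

with conventional prey levels: primary producers 1, herbivorous prey 2,
omnivorous prey 2.5, carnivorous prey 3. A pure primary-producer diet thus
gives TL = 2, the herbivore level; proportions need not be normalized.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["PREY_TL", "trophic_level", "trophic_levels_from_table"]

PREY_TL = {
    "primary_producer": 1.0,
    "herbivorous_prey": 2.0,
    "omnivorous_prey": 2.5,
    "carnivorous_prey": 3.0,
}


def trophic_level(proportions: dict[str, float],
                  prey_tl: dict[str, float] | None = None) -> float:
    """TL of one consumer from its prey-class proportions.

    Keys are prey classes; unknown classes require an explicit ``prey_tl``
    entry. Proportions may be unnormalized (only ratios matter).
    """
    tl_map = dict(PREY_TL)
    if prey_tl:
        tl_map.update(prey_tl)
    total = 0.0
    weighted = 0.0
    for prey, dc in proportions.items():
        if dc < 0:
            raise ValueError(f"negative proportion for {prey!r}")
        if prey not in tl_map:
            raise ValueError(f"no trophic level known for prey {prey!r}")
        total += dc
        weighted += dc * tl_map[prey]
    if total <= 0:
        raise ValueError("diet proportions sum to zero")
    return 1.0 + weighted / total


def trophic_levels_from_table(diet: pd.DataFrame,
                              prey_tl: dict[str, float] | None = None
                              ) -> pd.Series:
    """Per-consumer TL from a long table (species, prey_class, proportion)."""
    out = {
        sp: trophic_level(
            dict(zip(grp["prey_class"], grp["proportion"])), prey_tl)
        for sp, grp in diet.groupby("species", sort=True)
    }
    return pd.Series(out, name="trophic_level").rename_axis("species")
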