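"""Three-criterion convergence screen for diet-associated gene families.

A family is nominated for a trophic category (the "in-group") when
  (i)   median copy number in-group / median out-group >= ratio_min (2),
  (ii)  at least 90% of in-group species carry >= 1 copy, and
  (iii) at least 70% of out-group species carry <= 2 copies.

The screen is deliberately a filter, not a test: it nominates families
showing strikingly convergent copy-number elevation for one diet, which
are then examined with phylogenetically corrected models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CATEGORIES

__all__ = ["ScreeningCriteria", "ScreeningResult", "screen_families",
           "screen_all_categories", "results_frame"]


@dataclass(frozen=True)
class ScreeningCriteria:
    ratio_min: float = 2.0
    presence_fraction: float = 0.90
    presence_min_copies: int = 1
    background_fraction: float = 0.70
    background_max_copies: int = 2

    def __post_init__(self) -> None:
        for f in (self.presence_fraction, self.background_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.ratio_min, self.presence_min_copies,
               self.background_max_copies) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class ScreeningResult:
    family: str
    median_in: float
    median_out: float
    ratio: float  # may be +inf when median_out == 0 < median_in
    presence_in: float
    background_out: float
    pass_ratio: bool
    pass_presence: bool
    pass_background: bool

    @property
    def passed(self) -> bool:
        return self.pass_ratio and self.pass_presence and self.pass_background


def _median_ratio(med_in: float, med_out: float) -> float:
    # limits of the written inequality: 0/0 and x/0 with x>0
    if med_out == 0:
        return math.inf if med_in > 0 else 0.0
    return med_in / med_out


def screen_families(
    matrix: pd.DataFrame,
    in_group,
    criteria: ScreeningCriteria = ScreeningCriteria(),
) -> list[ScreeningResult]:
    """Apply the three criteria to every family column of the matrix."""
    in_group = set(in_group)
    species = set(matrix.index)
    if not in_group:
        raise ValueError("in-group is empty")
    unknown = in_group - species
    if unknown:
        raise ValueError(f"in-group species not in matrix: {sorted(unknown)}")
    out_group = species - in_group
    if not out_group:
        raise ValueError("out-group is empty (in-group covers all species)")
    in_mask = matrix.index.isin(in_group)
    X = matrix.to_numpy()
    Xin, Xout = X[in_mask], X[~in_mask]
    med_in = np.median(Xin, axis=0)
    med_out = np.median(Xout, axis=0)
    presence = (Xin >= criteria.presence_min_copies).mean(axis=0)
    background = (Xout <= criteria.background_max_copies).mean(axis=0)
    results = []
    for j, family in enumerate(matrix.columns):
        ratio = _median_ratio(float(med_in[j]), float(med_out[j]))
        results.append(ScreeningResult(
            family=family,
            median_in=float(med_in[j]),
            median_out=float(med_out[j]),
            ratio=ratio,
            presence_in=float(presence[j]),
            background_out=float(background[j]),
            pass_ratio=ratio >= criteria.ratio_min,
            pass_presence=presence[j] >= criteria.presence_fraction,
            pass_background=background[j] >= criteria.background_fraction,
        ))
    return results


def screen_all_categories(
    matrix: pd.DataFrame,
    table: pd.DataFrame,
    criteria: ScreeningCriteria = ScreeningCriteria(),
) -> dict[str, list[ScreeningResult]]:
    """Run the screen once per trophic category (in-group vs the rest)."""
    by_cat = table.groupby("category")["species"].apply(set).to_dict()
    missing = [c for c in CATEGORIES if not by_cat.get(c)]
    if missing:
        raise ValueError(f"no species in categories: {missing}")
    return {
        cat: screen_families(matrix, by_cat[cat] & set(matrix.index),
                             criteria)
        for cat in CATEGORIES
    }


def results_frame(results_by_cat: dict[str, list[ScreeningResult]]
                  ) -> pd.DataFrame:
    """Flatten the per-category results into a diagnostics table."""
    rows = []
    for cat, results in results_by_cat.items():
        for r in results:
            rows.append({
                "category": cat, "family": r.family,
                "median_in": r.median_in, "median_out": r.median_out,
                "ratio": r.ratio, "presence_in": r.presence_in,
                "background_out": r.background_out,
                "pass_ratio": r.pass_ratio,
                "pass_presence": r.pass_presence,
                "pass_background": r.pass_background,
                "passed": r.passed,
            })
    return pd.DataFrame(rows)
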