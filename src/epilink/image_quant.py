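"""Epithelial tissue proportion from segmentation label masks.

The proportion is epithelial pixel area over epithelial-plus-stromal area;
background pixels never enter numerator or denominator. Samples with a
proportion >= the cutoff (default 0.5, inclusive) are 'high', else 'low'.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, NoTissueError
from .io import MASK_BACKGROUND, MASK_EPITHELIAL, MASK_STROMAL, read_mask_png

EPITHELIAL_CUTOFF = 0.5


def epithelial_proportion(mask: np.ndarray) -> float:
    """Area_epi / (Area_epi + Area_stro) for a {0,1,2} label mask."""
    mask = np.asarray(mask)
    unknown = np.setdiff1d(np.unique(mask), [MASK_BACKGROUND, MASK_EPITHELIAL, MASK_STROMAL])
    if unknown.size:
        raise InvalidArgumentError(f"unknown label values: {unknown.tolist()}")
    epi = int(np.count_nonzero(mask == MASK_EPITHELIAL))
    stro = int(np.count_nonzero(mask == MASK_STROMAL))
    if epi + stro == 0:
        raise NoTissueError("mask contains no epithelial or stromal pixels")
    return epi / (epi + stro)


def classify_group(proportion: float, cutoff: float = EPITHELIAL_CUTOFF) -> str:
    """'high' iff proportion >= cutoff (boundary inclusive), else 'low'."""
    if not 0.0 <= proportion <= 1.0:
        raise InvalidArgumentError(f"proportion must be in [0, 1], got {proportion}")
    return "high" if proportion >= cutoff else "low"


def build_cohort(proportions: pd.DataFrame, cutoff: float = EPITHELIAL_CUTOFF) -> pd.DataFrame:
    """Attach the high/low group to a (sample_id, proportion) table."""
    cohort = proportions[["sample_id", "proportion"]].copy()
    cohort["group"] = [classify_group(p, cutoff) for p in cohort["proportion"]]
    return cohort


def cohort_from_masks(mask_paths: dict[str, str | Path],
                      cutoff: float = EPITHELIAL_CUTOFF) -> pd.DataFrame:
    """Compute the cohort table from per-sample label-mask PNGs."""
    rows = []
    for sample_id in sorted(mask_paths):
        prop = epithelial_proportion(read_mask_png(mask_paths[sample_id]))
        rows.append((sample_id, prop))
    return build_cohort(pd.DataFrame(rows, columns=["sample_id", "proportion"]), cutoff)


def cohort_summary(cohort: pd.DataFrame) -> tuple[int, int, float]:
    """(n_low, n_high, low_fraction) of a cohort table."""
    if len(cohort) == 0:
        raise InvalidArgumentError("empty cohort")
    n_high = int((cohort["group"] == "high").sum())
    n_low = int((cohort["group"] == "low").sum())
    if n_low + n_high != len(cohort):
        raise InvalidArgumentError("cohort group labels must be 'high' or 'low'")
    return n_low, n_high, n_low / len(cohort)
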