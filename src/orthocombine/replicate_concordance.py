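"""Cross-run reproducibility of confidence categories.

Two classified runs of the same individual are cross-tabulated: each
variant key observed in either run gets a (run-1 category, run-2 category)
cell, with NOT_CALLED on the side that lacks the variant.  Matching is by
canonical variant identity and ignores zygosity, so a zygosity flip between
runs shows up as a category change rather than as two unrelated variants.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import pandas as pd

from .combinator import Category, CombinedCallSet
from .platform_io import IntervalSet
from .variant_model import CanonicalVariant

logger = logging.getLogger(__name__)

NOT_CALLED = "not_called"

CROSSTAB_ORDER = [c.value for c in Category] + [NOT_CALLED]

__all__ = ["crosstab_categories", "repeat_rate", "NOT_CALLED", "CROSSTAB_ORDER"]


def _category_map(run: CombinedCallSet, regions: Optional[IntervalSet]) -> dict[CanonicalVariant, str]:
    out: dict[CanonicalVariant, str] = {}
    dups = 0
    for call in run.calls:
        v = call.variant
        if regions is not None and not regions.contains(v.chrom, v.pos):
            continue
        if v in out:
            dups += 1
            continue
        out[v] = call.category.value
    if dups:
        logger.warning("crosstab: %d duplicate variant keys within one run (first kept)", dups)
    return out


def crosstab_categories(
    run1: CombinedCallSet,
    run2: CombinedCallSet,
    regions: Optional[IntervalSet] = None,
) -> pd.DataFrame:
    """5x5 category cross-tabulation (rows = run 1, columns = run 2).

    The (NOT_CALLED, NOT_CALLED) cell is structurally zero: a variant
    absent from both runs is unobservable.  The sum of all cells equals the
    number of distinct variant keys seen in either run (within ``regions``,
    when given).
    """
    m1 = _category_map(run1, regions)
    m2 = _category_map(run2, regions)
    tab = pd.DataFrame(0, index=CROSSTAB_ORDER, columns=CROSSTAB_ORDER, dtype=int)
    for v in set(m1) | set(m2):
        tab.loc[m1.get(v, NOT_CALLED), m2.get(v, NOT_CALLED)] += 1
    return tab


def repeat_rate(tab: pd.DataFrame, category: Union[Category, str]) -> Optional[float]:
    """Fraction of run-1 calls of a category that received the same category
    in run 2 (diagonal cell over row sum); None for an empty row."""
    key = category.value if isinstance(category, Category) else category
    row_sum = int(tab.loc[key].sum())
    if row_sum == 0:
        return None
    return int(tab.loc[key, key]) / row_sum
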