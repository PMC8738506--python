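"""Pollen percentages and cumulative anthropogenic indicator curves.

Percentages are taken with respect to the terrestrial reference sum (trees,
shrubs, upland herbs and terrestrial fern spores).  Indicator curves sum the
percentages of all indicator types in each capacity category (PRIMARY,
ADVENTIVE, APOPHYTE) per sample, the quantity plotted against time to read a
land-use signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .harmonization import CapacityMap
from .records import REFERENCE_GROUPS, PercentageRecord, PollenRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "IndicatorCurveSet",
    "compute_percentages",
    "build_indicator_curves",
    "total_indicator_curve",
]

#: Curve categories in decreasing indicative strength.
CATEGORIES = ("PRIMARY", "ADVENTIVE", "APOPHYTE")


@dataclass
class IndicatorCurveSet:
    """Summed indicator percentages per capacity category at one HL level."""

    level: str
    curves: pd.DataFrame  # index: age_calBP (youngest first), columns: CATEGORIES

    @property
    def ages(self) -> np.ndarray:
        return np.asarray(self.curves.index, dtype=float)

    def __getitem__(self, category: str) -> pd.Series:
        return self.curves[category]

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (age, level, category, value) table."""
        out = self.curves.reset_index().melt(
            id_vars="age_calBP", var_name="category", value_name="value"
        )
        out.insert(1, "level", self.level)
        return out


def compute_percentages(
    record: PollenRecord, drop_empty_samples: bool = False
) -> PercentageRecord:
    """Percentages of the terrestrial reference sum, per sample.

    The denominator is the summed count of TREE, SHRUB, UPLAND_HERB and
    TERRESTRIAL_FERN types; EXCLUDED types (aquatics etc.) are expressed
    relative to the same denominator but never contribute to it, so their
    percentages may exceed 100.  Samples with an empty reference sum raise by
    default; ``drop_empty_samples=True`` removes them with a warning.
    """
    if record.groups is None:
        raise ValueError("record has no ecological groups; harmonize it first")
    in_sum = [t for t in record.taxa if record.groups[t] in REFERENCE_GROUPS]
    ref = record.counts[in_sum].sum(axis=1)
    empty = ref == 0
    if empty.any():
        bad = list(record.counts.index[empty])
        if not drop_empty_samples:
            raise ValueError(
                f"zero reference sum in samples at ages {bad} of {record.site_name!r}"
            )
        logger.warning("dropping %d samples with zero reference sum: %s", len(bad), bad)
        record = PollenRecord(
            record.site_name, record.counts.loc[~empty], record.groups
        )
        ref = ref.loc[~empty]
    values = 100.0 * record.counts.div(ref, axis=0)
    return PercentageRecord(
        site_name=record.site_name,
        values=values,
        reference_sum=ref.astype(int),
        groups=record.groups,
    )


def build_indicator_curves(
    pct: PercentageRecord, capacities: CapacityMap
) -> IndicatorCurveSet:
    """Sum indicator percentages per capacity category at each sample age.

    PRIMARY pools introduced and native primary indicators (they are kept
    distinct in the capacity map but plotted as one category).  Categories
    with no taxa yield all-zero curves.  EXCLUDED types never enter a curve.
    """
    curves = pd.DataFrame(
        0.0, index=pct.values.index, columns=list(CATEGORIES)
    )
    curves.index.name = "age_calBP"
    for taxon in pct.taxa:
        cap = capacities.get(taxon)
        if not cap.is_indicator:
            continue
        if pct.groups is not None and pct.groups[taxon].value == "EXCLUDED":
            continue
        curves[cap.category] += pct.values[taxon]
    return IndicatorCurveSet(level=capacities.level, curves=curves)


def total_indicator_curve(curves: IndicatorCurveSet) -> pd.Series:
    """Cumulative curve of all anthropogenic types: PRIMARY + ADVENTIVE + APOPHYTE."""
    total = curves.curves[list(CATEGORIES)].sum(axis=1)
    total.name = "TOTAL"
    return total
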