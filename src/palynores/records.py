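"""Core containers for stratigraphic pollen data.

A :class:`PollenRecord` holds raw pollen counts per sample (rows ordered
youngest-first by calibrated age) together with the ecological group of each
pollen type, once known.  A :class:`PercentageRecord` holds the same layout
expressed as percentages of the terrestrial reference sum (pollen of trees,
shrubs and upland herbs plus terrestrial fern spores).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "EcologicalGroup",
    "REFERENCE_GROUPS",
    "PollenRecord",
    "PercentageRecord",
    "read_counts",
    "write_counts",
]


class EcologicalGroup(str, Enum):
    """Ecological group of a pollen/spore type, controlling the reference sum."""

    TREE = "TREE"
    SHRUB = "SHRUB"
    UPLAND_HERB = "UPLAND_HERB"
    TERRESTRIAL_FERN = "TERRESTRIAL_FERN"
    EXCLUDED = "EXCLUDED"


#: Groups whose counts enter the percentage denominator.  Aquatics and other
#: EXCLUDED types are expressed relative to this sum but never contribute to it.
REFERENCE_GROUPS = frozenset(
    {
        EcologicalGroup.TREE,
        EcologicalGroup.SHRUB,
        EcologicalGroup.UPLAND_HERB,
        EcologicalGroup.TERRESTRIAL_FERN,
    }
)


def _as_group_series(
    groups: Optional[Union[pd.Series, Mapping[str, EcologicalGroup]]],
    taxa: Sequence[str],
) -> Optional[pd.Series]:
    if groups is None:
        return None
    s = pd.Series({t: EcologicalGroup(groups[t]) for t in taxa}, dtype=object)
    return s.reindex(taxa)


@dataclass
class PollenRecord:
    """Site pollen counts: samples (ages, cal yr BP) x pollen types.

    Parameters
    ----------
    site_name : str
        Free-text site label.
    counts : pandas.DataFrame
        Non-negative integer counts, one row per sample.  The index is the
        calibrated age in cal yr BP.  Rows are stored youngest-first
        (strictly increasing age); input in the opposite order is flipped.
    groups : pandas.Series, optional
        Ecological group per pollen type.  ``None`` until a harmonization
        table has been applied.
    """

    site_name: str
    counts: pd.DataFrame
    groups: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.counts.shape[0] < 1 or self.counts.shape[1] < 1:
            raise ValueError("record needs at least 1 sample and 1 pollen type")
        ages = np.asarray(self.counts.index, dtype=float)
        if np.any(np.diff(ages) == 0):
            raise ValueError("sample ages must be strictly monotone")
        if ages[0] > ages[-1]:  # oldest-first input: store youngest-first
            self.counts = self.counts.iloc[::-1]
            ages = ages[::-1]
        if np.any(np.diff(ages) <= 0):
            raise ValueError("sample ages must be strictly monotone")
        self.counts.index = pd.Index(ages, name="age_calBP")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("pollen counts must be non-negative")
        self.groups = _as_group_series(self.groups, list(self.counts.columns))

    @property
    def ages(self) -> np.ndarray:
        """Sample ages in cal yr BP, youngest first."""
        return np.asarray(self.counts.index, dtype=float)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def filter_window(self, oldest: float, youngest: float = -np.inf) -> "PollenRecord":
        """Restrict to samples with ``youngest <= age <= oldest`` (cal yr BP)."""
        mask = (self.ages <= oldest) & (self.ages >= youngest)
        if not mask.any():
            raise ValueError(
                f"no samples of {self.site_name!r} fall in "
                f"[{youngest}, {oldest}] cal yr BP"
            )
        return replace(self, counts=self.counts.loc[mask])

    def restrict(self, taxa: Sequence[str]) -> "PollenRecord":
        """Keep only the given pollen types (order preserved)."""
        groups = None if self.groups is None else self.groups.loc[list(taxa)]
        return replace(self, counts=self.counts.loc[:, list(taxa)], groups=groups)


@dataclass
class PercentageRecord:
    """Pollen percentages of the terrestrial reference sum, same layout as counts."""

    site_name: str
    values: pd.DataFrame
    reference_sum: pd.Series
    groups: pd.Series = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.groups = _as_group_series(self.groups, list(self.values.columns))

    @property
    def ages(self) -> np.ndarray:
        return np.asarray(self.values.index, dtype=float)

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)

    def restrict(self, taxa: Sequence[str]) -> "PercentageRecord":
        return PercentageRecord(
            site_name=self.site_name,
            values=self.values.loc[:, list(taxa)],
            reference_sum=self.reference_sum,
            groups=self.groups.loc[list(taxa)] if self.groups is not None else None,
        )


def read_counts(path: Union[str, Path], site_name: Optional[str] = None) -> PollenRecord:
    """Read a counts table: first column ``age_calBP``, remaining columns taxa.

    A leading comment line ``# site: NAME`` supplies the site name.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    header_site = None
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.lower().startswith("site:"):
                header_site = stripped[5:].strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an age column plus at least one taxon")
    age_col = df.columns[0]
    df = df.set_index(age_col)
    name = site_name or header_site or path.stem
    return PollenRecord(site_name=name, counts=df)


def write_counts(record: PollenRecord, path: Union[str, Path]) -> None:
    """Write a counts table readable by :func:`read_counts`."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# site: {record.site_name}\n")
        record.counts.to_csv(fh, lineterminator="\n")
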