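"""Hierarchical taxonomic harmonization of pollen types (HL0 -> HL1 -> HL2).

HL0 is the finest resolution attainable by light microscopy; HL1 merges
morphologically similar types; HL2 keeps only coarse, readily identifiable
groups (often genus or family).  Each HL0 type carries a synanthropic status
(its *indicative capacity* for human land use) and an ecological group.  When
types are merged at a coarser level the capacity of the merged type is
downgraded whenever the merge mixes indicator and non-indicator plants:
e.g. adventive Plantago lanceolata-type merged with wild Plantago species
becomes a mere apophyte signal, and Cerealia-type absorbed into Poaceae loses
its primary-indicator value entirely.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .records import EcologicalGroup, PollenRecord

logger = logging.getLogger(__name__)

__all__ = [
    "IndicativeCapacity",
    "LEVELS",
    "HarmonizationEntry",
    "HarmonizationTable",
    "CapacityMap",
    "load_harmonization_table",
    "harmonize_counts",
    "derive_capacity_map",
    "select_indicator_types",
    "default_downgrade",
]

#: Recognised harmonization level identifiers, finest first.
LEVELS = ("HL0", "HL1", "HL2")


class IndicativeCapacity(IntEnum):
    """Strength of evidence for human land use carried by a pollen type.

    Ordered: introduced primary indicators (crops brought with farming) are
    strongest, then native crops, then adventive weeds (non-native, introduced
    with agriculture), then apophytes (native plants merely favoured by land
    use); NONE marks pollen types with no synanthropic value.
    """

    NONE = 0
    APOPHYTE = 1
    ADVENTIVE = 2
    PRIMARY_NATIVE = 3
    PRIMARY_INTRODUCED = 4

    @property
    def is_indicator(self) -> bool:
        return self is not IndicativeCapacity.NONE

    @property
    def category(self) -> str:
        """Curve category: both primary capacities plot as ``PRIMARY``."""
        if self in (IndicativeCapacity.PRIMARY_INTRODUCED, IndicativeCapacity.PRIMARY_NATIVE):
            return "PRIMARY"
        return self.name


@dataclass(frozen=True)
class HarmonizationEntry:
    """One HL0 pollen type with its coarser-level parents and base status."""

    hl0_name: str
    hl1_name: str
    hl2_name: str
    base_capacity: IndicativeCapacity
    ecological_group: EcologicalGroup

    def name_at(self, level: str) -> str:
        return {"HL0": self.hl0_name, "HL1": self.hl1_name, "HL2": self.hl2_name}[level]


class HarmonizationTable:
    """Validated many-to-one mapping HL0 -> HL1 -> HL2 with per-type status."""

    def __init__(self, entries: Iterable[HarmonizationEntry]):
        entries = list(entries)
        names = [e.hl0_name for e in entries]
        dupes = sorted({n for n, c in Counter(names).items() if c > 1})
        if dupes:
            raise ValueError(f"duplicate hl0 names in harmonization table: {dupes}")
        parents: dict[str, str] = {}
        for e in entries:
            prev = parents.setdefault(e.hl1_name, e.hl2_name)
            if prev != e.hl2_name:
                raise ValueError(
                    f"conflicting parent mapping: hl1 {e.hl1_name!r} maps to "
                    f"both hl2 {prev!r} and {e.hl2_name!r}"
                )
        self._entries = {e.hl0_name: e for e in entries}

    @property
    def entries(self) -> list[HarmonizationEntry]:
        return list(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, hl0_name: str) -> bool:
        return hl0_name in self._entries

    def __getitem__(self, hl0_name: str) -> HarmonizationEntry:
        return self._entries[hl0_name]

    def names(self, level: str) -> list[str]:
        """Distinct type names at a level, in order of first appearance."""
        _check_level(level)
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.name_at(level), None)
        return list(seen)

    def constituents(self, level: str) -> dict[str, list[HarmonizationEntry]]:
        """Merged-name -> the HL0 entries it absorbs at ``level``."""
        _check_level(level)
        out: dict[str, list[HarmonizationEntry]] = {}
        for e in self.entries:
            out.setdefault(e.name_at(level), []).append(e)
        return out

    def with_entries(self, extra: Iterable[HarmonizationEntry]) -> "HarmonizationTable":
        return HarmonizationTable(self.entries + list(extra))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hl0": [e.hl0_name for e in self.entries],
                "hl1": [e.hl1_name for e in self.entries],
                "hl2": [e.hl2_name for e in self.entries],
                "status": [e.base_capacity.name for e in self.entries],
                "group": [e.ecological_group.value for e in self.entries],
            }
        )

    def write(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


@dataclass(frozen=True)
class CapacityMap:
    """Indicative capacity of every pollen type name at one level."""

    level: str
    assignments: Mapping[str, IndicativeCapacity]

    def __getitem__(self, name: str) -> IndicativeCapacity:
        return self.assignments[name]

    def get(self, name: str, default: IndicativeCapacity = IndicativeCapacity.NONE):
        return self.assignments.get(name, default)

    def indicators(self) -> list[str]:
        return [n for n, c in self.assignments.items() if c.is_indicator]


def _check_level(level: str) -> None:
    if level not in LEVELS:
        raise ValueError(f"unknown harmonization level {level!r}; expected one of {LEVELS}")


_COLUMNS = ("hl0", "hl1", "hl2", "status", "group")


def load_harmonization_table(path: Union[str, Path]) -> HarmonizationTable:
    """Load a delimited (comma or tab, auto-detected) harmonization table.

    Expected header: ``hl0,hl1,hl2,status,group`` with status tokens from
    :class:`IndicativeCapacity` and group tokens from :class:`EcologicalGroup`.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    first_line = text.splitlines()[0] if text.splitlines() else ""
    delim = "\t" if first_line.count("\t") >= first_line.count(",") and "\t" in first_line else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != list(_COLUMNS):
        raise ValueError(
            f"{path}: expected header columns {','.join(_COLUMNS)}, "
            f"got {reader.fieldnames}"
        )
    entries = []
    for i, row in enumerate(reader, start=2):
        vals = {k: (row[k] or "").strip() for k in _COLUMNS}
        if any(not vals[k] for k in ("hl0", "hl1", "hl2")):
            raise ValueError(f"{path}:{i}: empty pollen-type label")
        try:
            status = IndicativeCapacity[vals["status"]]
        except KeyError:
            raise ValueError(f"{path}:{i}: unknown status token {vals['status']!r}") from None
        try:
            group = EcologicalGroup(vals["group"])
        except ValueError:
            raise ValueError(f"{path}:{i}: unknown group token {vals['group']!r}") from None
        entries.append(
            HarmonizationEntry(vals["hl0"], vals["hl1"], vals["hl2"], status, group)
        )
    return HarmonizationTable(entries)


def _merged_group(constituents: Sequence[HarmonizationEntry]) -> EcologicalGroup:
    # Majority group of the constituent HL0 types; ties resolved to UPLAND_HERB.
    counts = Counter(e.ecological_group for e in constituents)
    top = counts.most_common()
    if len(top) > 1:
        best, runner = top[0][1], top[1][1]
        if best == runner:
            logger.warning(
                "ecological-group tie among %s; using UPLAND_HERB",
                [e.hl0_name for e in constituents],
            )
            return EcologicalGroup.UPLAND_HERB
        logger.warning(
            "merging across ecological groups %s for %s",
            dict(counts), [e.hl0_name for e in constituents],
        )
    return top[0][0]


def _complete_table(
    record: PollenRecord, table: HarmonizationTable, strict: bool
) -> HarmonizationTable:
    """Pass unmatched record taxa through as NONE/UPLAND_HERB (lenient mode)."""
    missing = [t for t in record.taxa if t not in table]
    if not missing:
        return table
    if strict:
        raise ValueError(
            f"taxa absent from harmonization table: {missing} (strict mode)"
        )
    logger.warning(
        "%d taxa absent from harmonization table, passed through with no "
        "indicative capacity: %s", len(missing), missing,
    )
    extra = [
        HarmonizationEntry(t, t, t, IndicativeCapacity.NONE, EcologicalGroup.UPLAND_HERB)
        for t in missing
    ]
    return table.with_entries(extra)


def harmonize_counts(
    record: PollenRecord,
    table: HarmonizationTable,
    level: str,
    strict: bool = False,
) -> PollenRecord:
    """Merge counts of HL0 types sharing a name at ``level``; sums are conserved.

    Taxa missing from the table are passed through unchanged with capacity
    NONE (lenient default) or rejected (``strict=True``).  Ecological groups
    of merged types follow the majority of their constituents.
    """
    _check_level(level)
    table = _complete_table(record, table, strict)
    name_of = {t: table[t].name_at(level) for t in record.taxa}
    merged = record.counts.T.groupby(
        [name_of[t] for t in record.taxa], sort=False
    ).sum().T
    present = {name_of[t] for t in record.taxa}
    groups = {
        name: _merged_group([e for e in cons if e.hl0_name in record.taxa])
        for name, cons in table.constituents(level).items()
        if name in present
    }
    return PollenRecord(
        site_name=record.site_name,
        counts=merged,
        groups=pd.Series({n: groups[n] for n in merged.columns}),
    )


def default_downgrade(capacities: Sequence[IndicativeCapacity]) -> IndicativeCapacity:
    """Capacity of a merged type from the multiset of its constituents' capacities.

    Uniform constituents keep their capacity.  Any mixture that dilutes an
    indicator with apophytes or plain wild taxa drops to APOPHYTE (the merged
    morphotype can no longer separate human influence from natural abundance).
    A mixture of primary/adventive indicators only keeps the weakest of them.
    """
    caps = set(capacities)
    if not caps:
        raise ValueError("empty constituent set")
    if len(caps) == 1:
        return next(iter(caps))
    if IndicativeCapacity.NONE in caps or IndicativeCapacity.APOPHYTE in caps:
        return IndicativeCapacity.APOPHYTE
    return min(caps)


DowngradePolicy = Callable[[Sequence[IndicativeCapacity]], IndicativeCapacity]


def derive_capacity_map(
    table: HarmonizationTable,
    level: str,
    policy: DowngradePolicy = default_downgrade,
) -> CapacityMap:
    """Indicative capacity of every type name at ``level`` under the downgrade policy."""
    _check_level(level)
    assignments = {
        name: policy([e.base_capacity for e in cons])
        for name, cons in table.constituents(level).items()
    }
    return CapacityMap(level=level, assignments=assignments)


def select_indicator_types(record, capacities: CapacityMap):
    """Restrict a (harmonized) record to anthropogenic indicator types.

    Works on :class:`PollenRecord` and :class:`PercentageRecord` alike.
    Returns ``(restricted_record, capacity_labels)`` where the labels are a
    Series mapping each retained taxon to its :class:`IndicativeCapacity`.
    An all-NONE record yields an empty selection (zero columns are not
    representable, so the restricted record is ``None`` in that case).
    """
    kept = [t for t in record.taxa if capacities.get(t).is_indicator]
    labels = pd.Series({t: capacities[t] for t in kept}, dtype=object)
    if not kept:
        return None, labels
    return record.restrict(kept), labels
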