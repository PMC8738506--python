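"""Synthetic postglacial pollen records with a known land-use history.

The generator emulates a multi-millennial lake record from a mid-elevation
European site: a stable arboreal background, an agriculture onset (default
7,500 cal yr BP) after which crop (Cerealia-type) and weed (Plantago
lanceolata-type, Sinapis-type) pollen appear with smooth logistic ramps, a
later land-use intensification (default 3,500 cal yr BP) introducing an
orchard tree (Castanea-type), and "confuser" wild taxa that share coarse
harmonized groups with the indicators — wild grasses merging with
Cerealia-type into Poaceae, wild Plantago species merging with
P. lanceolata-type into Plantago.  Counts are drawn multinomially with a
fixed pollen sum per sample, matching how pollen counts are produced
(counting grains to a target sum).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .harmonization import HarmonizationEntry, HarmonizationTable, IndicativeCapacity
from .records import EcologicalGroup, PollenRecord

__all__ = ["TaxonSpec", "SyntheticConfig", "generate_record", "generate_harmonization_table"]


@dataclass(frozen=True)
class TaxonSpec:
    """One simulated pollen type.

    ``pre`` and ``post`` are relative abundances (arbitrary positive units,
    normalized per sample) before and after the taxon's transition age;
    ``ramp_years`` is the 10-90% width of the logistic ramp between them.
    ``change`` selects which event the ramp is centred on.
    """

    name: str
    group: EcologicalGroup
    capacity: IndicativeCapacity
    pre: float
    post: float
    ramp_years: float = 300.0
    change: str = "onset"  # "onset" or "intensification"
    hl1: Optional[str] = None
    hl2: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pre < 0 or self.post < 0:
            raise ValueError(f"{self.name}: relative abundances must be >= 0")
        if self.change not in ("onset", "intensification"):
            raise ValueError(f"{self.name}: unknown change event {self.change!r}")

    @property
    def hl1_name(self) -> str:
        return self.hl1 or self.name

    @property
    def hl2_name(self) -> str:
        return self.hl2 or self.hl1 or self.name


def default_taxa() -> tuple[TaxonSpec, ...]:
    """The default simulated flora (see module docstring for the scenario)."""
    G, C = EcologicalGroup, IndicativeCapacity
    return (
        TaxonSpec("Quercus", G.TREE, C.NONE, 0.34, 0.26),
        TaxonSpec("Pinus", G.TREE, C.NONE, 0.25, 0.20),
        TaxonSpec("Poaceae wild", G.UPLAND_HERB, C.NONE, 0.24, 0.26,
                  hl1="Poaceae", hl2="Poaceae"),
        TaxonSpec("Cerealia-type", G.UPLAND_HERB, C.PRIMARY_INTRODUCED, 0.0, 0.04,
                  hl2="Poaceae"),
        TaxonSpec("Castanea-type", G.TREE, C.PRIMARY_NATIVE, 0.0, 0.02,
                  change="intensification"),
        TaxonSpec("Plantago lanceolata-type", G.UPLAND_HERB, C.ADVENTIVE, 0.0, 0.03,
                  hl2="Plantago"),
        TaxonSpec("Plantago maritima-type", G.UPLAND_HERB, C.NONE, 0.02, 0.02,
                  hl2="Plantago"),
        TaxonSpec("Artemisia", G.UPLAND_HERB, C.APOPHYTE, 0.02, 0.05),
        TaxonSpec("Sinapis arvensis-type", G.UPLAND_HERB, C.ADVENTIVE, 0.0, 0.015,
                  hl1="Brassicaceae", hl2="Brassicaceae"),
        TaxonSpec("Brassicaceae undiff.", G.UPLAND_HERB, C.NONE, 0.015, 0.015,
                  hl1="Brassicaceae", hl2="Brassicaceae"),
        TaxonSpec("Pteridium", G.TERRESTRIAL_FERN, C.APOPHYTE, 0.005, 0.02),
        TaxonSpec("Nymphaea", G.EXCLUDED, C.NONE, 0.05, 0.05),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic record.

    Defaults: a 12,000-year record sampled every 100 years (the youngest
    sample at -50 cal yr BP, i.e. post-1950), 500 grains counted per sample,
    agriculture onset at 7,500 and intensification at 3,500 cal yr BP.
    """

    duration_years: float = 12_000.0
    sample_step_years: float = 100.0
    pollen_sum_per_sample: int = 500
    onset_age_calbp: float = 7_500.0
    intensification_age_calbp: float = 3_500.0
    taxa: tuple[TaxonSpec, ...] = field(default_factory=default_taxa)
    seed: int = 0
    site_name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.onset_age_calbp >= self.duration_years:
            raise ValueError("onset must lie within the record duration")
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            raise ValueError("taxa names must be unique")

    @property
    def ages(self) -> np.ndarray:
        """Sample ages, youngest first, starting at -50 cal yr BP."""
        n = int(round(self.duration_years / self.sample_step_years)) + 1
        return -50.0 + self.sample_step_years * np.arange(n)

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        taxa_raw = raw.pop("taxa", None)
        kwargs = dict(raw)
        if taxa_raw is not None:
            kwargs["taxa"] = tuple(
                TaxonSpec(
                    name=t["name"],
                    group=EcologicalGroup(t["group"]),
                    capacity=IndicativeCapacity[t["capacity"]],
                    pre=float(t["pre"]),
                    post=float(t["post"]),
                    ramp_years=float(t.get("ramp_years", 300.0)),
                    change=t.get("change", "onset"),
                    hl1=t.get("hl1"),
                    hl2=t.get("hl2"),
                )
                for t in taxa_raw
            )
        return cls(**kwargs)


def expected_proportions(config: SyntheticConfig) -> pd.DataFrame:
    """Expected per-sample taxon proportions (rows sum to 1), youngest first."""
    ages = config.ages
    cols = {}
    # 10-90% logistic transition spans ~4.394 * scale.
    for t in config.taxa:
        centre = (
            config.onset_age_calbp
            if t.change == "onset"
            else config.intensification_age_calbp
        )
        scale = max(t.ramp_years, 1e-9) / 4.394
        s = 1.0 / (1.0 + np.exp((ages - centre) / scale))  # 0 pre, 1 post
        cols[t.name] = t.pre + (t.post - t.pre) * s
    props = pd.DataFrame(cols, index=pd.Index(ages, name="age_calBP"))
    totals = props.sum(axis=1)
    if (totals <= 0).any():
        bad = list(props.index[totals <= 0])
        raise ValueError(f"all-zero expected proportions at ages {bad}")
    return props.div(totals, axis=0)


def generate_record(config: SyntheticConfig) -> PollenRecord:
    """Draw one synthetic pollen record (multinomial counts, fixed pollen sum)."""
    props = expected_proportions(config)
    rng = np.random.default_rng(config.seed)
    counts = np.vstack(
        [
            rng.multinomial(config.pollen_sum_per_sample, p)
            for p in props.to_numpy()
        ]
    )
    df = pd.DataFrame(counts, index=props.index, columns=props.columns)
    groups = pd.Series({t.name: t.group for t in config.taxa})
    return PollenRecord(site_name=config.site_name, counts=df, groups=groups)


def generate_harmonization_table(config: SyntheticConfig) -> HarmonizationTable:
    """Harmonization table matching the simulated flora.

    Cerealia-type and wild Poaceae share HL2 "Poaceae"; the Plantago types
    share HL2 "Plantago"; Sinapis-type and undifferentiated Brassicaceae
    already merge at HL1; everything else maps to itself.
    """
    return HarmonizationTable(
        HarmonizationEntry(t.name, t.hl1_name, t.hl2_name, t.capacity, t.group)
        for t in config.taxa
    )
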