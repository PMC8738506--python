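"""End-to-end per-site analysis across harmonization levels.

For each level HL0-HL2 the pipeline harmonizes the counts, derives indicative
capacities, computes percentages of the terrestrial reference sum, builds the
indicator curves, and then compares levels: sequence-slotting psi for every
level pair, leave-one-bin-out psi drops for one pair (HL0-HL1 by default),
change points on each level's total indicator curve, and paired Wilcoxon
tests per category and level pair.  All tabular outputs are written at the
end of a successful run, so a failed stage leaves no partial files.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .abundance import (
    CATEGORIES,
    IndicatorCurveSet,
    build_indicator_curves,
    compute_percentages,
    total_indicator_curve,
)
from .changepoint import BinarySegmentation, ChangePointResult
from .harmonization import (
    LEVELS,
    HarmonizationTable,
    derive_capacity_map,
    harmonize_counts,
    load_harmonization_table,
    select_indicator_types,
)
from .records import PollenRecord, read_counts
from .slotting import (
    DropResult,
    MultivariateSeries,
    align_variables,
    bin_time_intervals,
    drop_analysis,
    psi,
)
from .stats import paired_wilcoxon

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "SiteAnalysisReport", "PipelineError", "analyze_record", "run_site"]

SCHEMA_VERSION = 1
#: Marker used in place of a p-value when a category has no taxa at a level.
NO_DATA = "no data"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a remediation hint."""

    def __init__(self, stage: str, cause: Exception, hint: str):
        super().__init__(f"stage {stage!r} failed: {cause} (hint: {hint})")
        self.stage = stage
        self.hint = hint


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the per-site analysis."""

    levels: tuple[str, ...] = LEVELS
    window_oldest: float = 12_000.0  # cal yr BP
    window_youngest: float = -100.0
    bin_width: float = 500.0
    diagonals: bool = True
    max_cp: int = 4
    penalty: Optional[float] = None
    cp_model: str = "meanvar"
    drop_pair: tuple[str, str] = ("HL0", "HL1")
    strict: bool = False

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "levels" in raw:
            raw["levels"] = tuple(raw["levels"])
        if "drop_pair" in raw:
            raw["drop_pair"] = tuple(raw["drop_pair"])
        return cls(**raw)


@dataclass
class SiteAnalysisReport:
    """Everything the per-site analysis computes, from one table and window."""

    site_name: str
    config: AnalysisConfig
    taxon_counts: dict[str, int]
    curve_sets: dict[str, IndicatorCurveSet]
    totals: dict[str, pd.Series]
    psi_values: dict[str, Optional[float]]
    drops: Optional[DropResult]
    drops_note: str
    changepoints: dict[str, Optional[ChangePointResult]]
    comparisons: list[dict]
    status: str = "ok"


def _pair_key(la: str, lb: str) -> str:
    return f"{la}-{lb}"


def indicator_percent_series(
    record: PollenRecord,
    table: HarmonizationTable,
    level: str,
    strict: bool = False,
) -> Optional[MultivariateSeries]:
    """Indicator-type percentage series at one level (ages x indicator taxa).

    Convenience composition of harmonize -> percentages -> indicator
    selection; returns ``None`` when the level has no indicator taxa.
    """
    harm = harmonize_counts(record, table, level, strict=strict)
    caps = derive_capacity_map(table, level)
    sel, _ = select_indicator_types(compute_percentages(harm), caps)
    if sel is None:
        return None
    return MultivariateSeries(level, sel.values)


def _stage(name: str, hint: str):
    """Decorator-free stage wrapper: run fn() and re-raise as PipelineError."""
    class _Ctx:
        def __init__(self):
            self.name = name

        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc, hint) from exc
            return False

    return _Ctx()


def analyze_record(
    record: PollenRecord, table: HarmonizationTable, config: AnalysisConfig = AnalysisConfig()
) -> SiteAnalysisReport:
    """Run the full analysis on an in-memory record; deterministic."""
    with _stage("window", "check the analysis window against the record's age range"):
        rec = record.filter_window(config.window_oldest, config.window_youngest)

    per_level: dict[str, dict] = {}
    for level in config.levels:
        with _stage(f"harmonize[{level}]", "check the harmonization table covers the record"):
            harm = harmonize_counts(rec, table, level, strict=config.strict)
            caps = derive_capacity_map(table, level)
        with _stage(f"percentages[{level}]", "samples need a non-empty terrestrial sum"):
            pct = compute_percentages(harm)
        with _stage(f"curves[{level}]", "indicator curve construction"):
            curves = build_indicator_curves(pct, caps)
            total = total_indicator_curve(curves)
        sel, labels = select_indicator_types(pct, caps)
        per_level[level] = {
            "pct": pct,
            "caps": caps,
            "curves": curves,
            "total": total,
            "sel": sel,
            "labels": labels,
        }

    taxon_counts = {lv: int(len(per_level[lv]["labels"])) for lv in config.levels}

    # --- psi between every level pair (union-aligned indicator assemblages)
    psi_values: dict[str, Optional[float]] = {}
    for la, lb in itertools.combinations(config.levels, 2):
        key = _pair_key(la, lb)
        sa, sb = per_level[la]["sel"], per_level[lb]["sel"]
        if sa is None or sb is None:
            psi_values[key] = None
            continue
        with _stage(f"psi[{key}]", "sequences must vary (AB_within > 0)"):
            ma = MultivariateSeries(la, sa.values)
            mb = MultivariateSeries(lb, sb.values)
            ma, mb = align_variables(ma, mb)
            try:
                psi_values[key] = psi(ma, mb, diagonals=config.diagonals).psi
            except ValueError as err:
                logger.warning("psi %s skipped: %s", key, err)
                psi_values[key] = None

    # --- leave-one-bin-out drops for the configured pair (default HL0-HL1)
    drops: Optional[DropResult] = None
    drops_note = ""
    la, lb = config.drop_pair
    sa, sb = per_level[la]["sel"], per_level[lb]["sel"]
    if sa is None or sb is None:
        drops_note = NO_DATA
    else:
        with _stage(f"drops[{_pair_key(la, lb)}]", "drop attribution needs psi > 0"):
            key_a = _coarser_key(table, sa.taxa, la, lb)
            ta = bin_time_intervals(sa, width=config.bin_width, order_key=key_a, name=la)
            tb = bin_time_intervals(sb, width=config.bin_width, name=lb)
            try:
                drops = drop_analysis(ta, tb, diagonals=config.diagonals)
            except ValueError as err:
                drops_note = str(err)
                logger.warning("drop analysis skipped: %s", err)

    # --- change points on each level's total indicator curve
    changepoints: dict[str, Optional[ChangePointResult]] = {}
    for level in config.levels:
        total = per_level[level]["total"]
        if total.size < 4:
            changepoints[level] = None
            continue
        with _stage(f"changepoints[{level}]", "series must have >= 4 samples"):
            model = BinarySegmentation(
                total.to_numpy(),
                ages=np.asarray(total.index, float),
                model=config.cp_model,
                max_cp=config.max_cp,
                penalty=config.penalty,
            )
            changepoints[level] = model.fit()

    # --- paired Wilcoxon per category and level pair
    comparisons: list[dict] = []
    for la, lb in itertools.combinations(config.levels, 2):
        for category in (*CATEGORIES, "TOTAL"):
            comparisons.append(
                _compare(per_level, la, lb, category)
            )

    any_indicators = any(per_level[lv]["sel"] is not None for lv in config.levels)
    return SiteAnalysisReport(
        site_name=record.site_name,
        config=config,
        taxon_counts=taxon_counts,
        curve_sets={lv: per_level[lv]["curves"] for lv in config.levels},
        totals={lv: per_level[lv]["total"] for lv in config.levels},
        psi_values=psi_values,
        drops=drops,
        drops_note=drops_note,
        changepoints=changepoints,
        comparisons=comparisons,
        status="ok" if any_indicators else NO_DATA,
    )


def _coarser_key(table: HarmonizationTable, taxa, level_fine: str, level_coarse: str) -> dict:
    """Map each type name at the finer level to its coarser-level parent."""
    mapping: dict[str, str] = {}
    for e in table.entries:
        mapping[e.name_at(level_fine)] = e.name_at(level_coarse)
    return {t: mapping.get(t, t) for t in taxa}


def _category_taxa(info: dict, category: str) -> list[str]:
    labels = info["labels"]
    if category == "TOTAL":
        return list(labels.index)
    return [t for t, c in labels.items() if c.category == category]


def _compare(per_level: dict, la: str, lb: str, category: str) -> dict:
    row = {"level_pair": _pair_key(la, lb), "category": category}
    ta, tb = _category_taxa(per_level[la], category), _category_taxa(per_level[lb], category)
    if not ta or not tb:  # one side without taxa in the category: explicit marker
        row.update(statistic=None, n_effective=None, p_value=None, stars=NO_DATA)
        return row
    if category == "TOTAL":
        a = per_level[la]["total"]
        b = per_level[lb]["total"]
    else:
        a = per_level[la]["curves"][category]
        b = per_level[lb]["curves"][category]
    cmp_res = paired_wilcoxon(a.to_numpy(), b.to_numpy(), la, lb, category)
    row.update(
        statistic=cmp_res.statistic,
        n_effective=cmp_res.n_effective,
        p_value=cmp_res.p_value,
        stars=cmp_res.significance,
    )
    return row


# --- output writing --------------------------------------------------------

_FLOAT_FMT = "%.6g"


def _sig(x, digits: int = 6):
    if x is None:
        return None
    if isinstance(x, (int, np.integer)):
        return int(x)
    return float(f"{float(x):.{digits}g}")


def _write_outputs(report: SiteAnalysisReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    site = report.site_name

    tidy = pd.concat([cs.to_tidy() for cs in report.curve_sets.values()], ignore_index=True)
    tidy.insert(0, "site", site)
    tidy.to_csv(outdir / "curves.csv", index=False, float_format=_FLOAT_FMT, lineterminator="\n")

    psi_row = {"site": site, **{k: v for k, v in report.psi_values.items()}}
    pd.DataFrame([psi_row]).to_csv(
        outdir / "psi.csv", index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )

    if report.drops is not None:
        drops_df = pd.DataFrame(
            {
                "site": site,
                "bin_start": [b - report.config.bin_width for b in report.drops.bins],
                "bin_end": list(report.drops.bins),
                "drop_percent": report.drops.drop_percent.to_numpy(),
            }
        )
    else:
        drops_df = pd.DataFrame(columns=["site", "bin_start", "bin_end", "drop_percent"])
    drops_df.to_csv(outdir / "drops.csv", index=False, float_format=_FLOAT_FMT, lineterminator="\n")

    cp_rows = []
    for level, res in report.changepoints.items():
        if res is None:
            continue
        for i, (t, age) in enumerate(zip(res.tau, res.ages)):
            seg_before = res.segments[res.segments["end"] == t].iloc[0]
            seg_after = res.segments[res.segments["start"] == t + 1].iloc[0]
            cp_rows.append(
                {
                    "site": site,
                    "level": level,
                    "cp_index": t,
                    "cp_age_calBP": age,
                    "segment_mean_before": seg_before["mean"],
                    "segment_mean_after": seg_after["mean"],
                }
            )
    pd.DataFrame(
        cp_rows,
        columns=[
            "site", "level", "cp_index", "cp_age_calBP",
            "segment_mean_before", "segment_mean_after",
        ],
    ).to_csv(outdir / "changepoints.csv", index=False, float_format=_FLOAT_FMT, lineterminator="\n")

    wx = pd.DataFrame(report.comparisons)
    wx.insert(0, "site", site)
    wx.to_csv(outdir / "wilcoxon.csv", index=False, float_format=_FLOAT_FMT, lineterminator="\n")

    payload = {
        "schema_version": SCHEMA_VERSION,
        "site": site,
        "status": report.status,
        "window_cal_bp": [report.config.window_youngest, report.config.window_oldest],
        "taxon_counts": report.taxon_counts,
        "psi": {k: _sig(v) for k, v in report.psi_values.items()},
        "drops_note": report.drops_note,
        "changepoint_ages": {
            lv: ([_sig(a) for a in res.ages] if res is not None else None)
            for lv, res in report.changepoints.items()
        },
        "wilcoxon": [
            {k: (_sig(v) if isinstance(v, float) else v) for k, v in row.items()}
            for row in report.comparisons
        ],
    }
    (outdir / "report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def run_site(
    counts_path: Union[str, Path],
    table_path: Union[str, Path],
    config: AnalysisConfig = AnalysisConfig(),
    outdir: Optional[Union[str, Path]] = None,
) -> SiteAnalysisReport:
    """Load inputs, run :func:`analyze_record`, optionally write all outputs.

    Outputs (curves.csv, psi.csv, drops.csv, changepoints.csv, wilcoxon.csv,
    report.json) are written only after every stage succeeded.
    """
    with _stage("load", "check the counts and table file paths and formats"):
        record = read_counts(counts_path)
        table = load_harmonization_table(table_path)
    report = analyze_record(record, table, config)
    if outdir is not None:
        with _stage("write", "check the output directory is writable"):
            _write_outputs(report, Path(outdir))
    return report
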