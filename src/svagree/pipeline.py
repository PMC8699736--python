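"""End-to-end orchestration: simulate or load, then agreement, trend and
error-grid analysis per device and strand, with deterministic CSV/JSON
outputs."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import BlandAltman
from .errorgrid import (
    DEFAULT_PCT_THRESHOLDS,
    HarmGrid,
    ZoneSet,
    classify_points,
    derive_zones,
    zone_summary,
)
from .simulate import (
    DEFAULT_GRID_STEPS,
    SSD_LIKE,
    STRANDS,
    TEB_LIKE,
    DeviceModel,
    ProtocolConfig,
    cohort_to_frame,
    frame_to_cohort,
    frame_to_questionnaire,
    questionnaire_to_frame,
    simulate_cohort,
    simulate_questionnaire,
)
from .trend import DEFAULT_EXCLUSION_PCT, FourQuadrant, compute_deltas

__all__ = ["RunConfig", "RunReport", "run"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one full analysis run.

    ``mode="simulate"`` generates the cohort and questionnaire from
    ``protocol``/``n_respondents`` under ``seed``; ``mode="load"`` reads the
    cohort CSV (and questionnaire CSV, unless a zones file is supplied).
    """

    mode: str = "simulate"
    out_dir: str | Path = "svagree_out"
    seed: int = 0
    devices: list[DeviceModel] = field(default_factory=lambda: [TEB_LIKE, SSD_LIKE])
    strands: tuple[str, ...] = STRANDS
    protocol: ProtocolConfig | None = None  # template; strand/seed overridden per strand
    n_respondents: int = 15
    grid_steps: tuple[float, ...] = DEFAULT_GRID_STEPS
    rating_noise: float = 0.1
    cohort_path: str | Path | None = None
    questionnaire_path: str | Path | None = None
    zones_path: str | Path | None = None
    exclusion_threshold: float = DEFAULT_EXCLUSION_PCT
    pct_thresholds: tuple[float, float, float] = DEFAULT_PCT_THRESHOLDS
    slope_p_threshold: float = 0.05
    ba_method: str = "repeated_varying"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")
        if self.mode == "load" and self.cohort_path is None:
            raise ValueError("mode='load' requires cohort_path")
        if not self.devices:
            raise ValueError("at least one device required")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "devices" in raw:
            raw["devices"] = [DeviceModel(**d) for d in raw["devices"]]
        if "protocol" in raw and raw["protocol"] is not None:
            proto = dict(raw["protocol"])
            if "step_targets" in proto:
                proto["step_targets"] = tuple(proto["step_targets"])
            if "step_labels" in proto and proto["step_labels"] is not None:
                proto["step_labels"] = tuple(proto["step_labels"])
            if "target_bands" in proto:
                proto["target_bands"] = {
                    int(k): tuple(v) for k, v in proto["target_bands"].items()
                }
            raw["protocol"] = ProtocolConfig(**proto)
        for key in ("strands", "grid_steps", "pct_thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        for key in ("cohort_path", "questionnaire_path", "zones_path"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d


@dataclass
class RunReport:
    """Structured results per device x strand plus provenance."""

    results: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {"results": self.results, "provenance": self.provenance}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _strand_seeds(seed: int, strands) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(strands) + 1)
    return {
        strand: int(children[i].generate_state(1)[0] % (2**31))
        for i, strand in enumerate(strands)
    }


def _questionnaire_seed(seed: int) -> int:
    return int(np.random.SeedSequence(seed).spawn(8)[-1].generate_state(1)[0] % (2**31))


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all artefacts under ``out_dir``.

    Per device x strand: repeated-measures Bland-Altman (with proportional-
    bias suppression), four-quadrant concordance, and error-grid zone
    classification; severe-harm rates are pooled across strands per device.
    Stage failures are isolated and reported per device/strand.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ---- inputs ----------------------------------------------------------
    if config.mode == "simulate":
        proto = config.protocol or ProtocolConfig()
        seeds = _strand_seeds(config.seed, config.strands)
        cohort_frames = []
        for strand in config.strands:
            cfg = dataclasses.replace(proto, strand=strand, seed=seeds[strand])
            cohort_frames.append(cohort_to_frame(simulate_cohort(cfg, config.devices)))
        cohort = pd.concat(cohort_frames, ignore_index=True)
    else:
        cohort = pd.read_csv(config.cohort_path)
    _write_csv(cohort, out_dir / "cohort.csv")

    device_names = [d.name for d in config.devices]
    present = [n for n in device_names if f"sv_{n}" in cohort.columns]

    if config.zones_path is not None:
        zones = ZoneSet.from_json(config.zones_path)
        grid = None
    else:
        if config.mode == "simulate" or config.questionnaire_path is None:
            returns = simulate_questionnaire(
                config.n_respondents,
                grid_steps=config.grid_steps,
                profiles_seed=_questionnaire_seed(config.seed),
                rating_noise=config.rating_noise,
            )
        else:
            returns = frame_to_questionnaire(pd.read_csv(config.questionnaire_path))
        _write_csv(questionnaire_to_frame(returns), out_dir / "questionnaire.csv")
        grid = HarmGrid.from_returns(returns)
        grid.to_frame("pct").to_csv(out_dir / "harm_grid_pct.csv")
        grid.to_frame("raw").to_csv(out_dir / "harm_grid_raw.csv")
        zones = derive_zones(grid, config.pct_thresholds)
    zones.to_json(out_dir / "zones.json")

    # ---- per device x strand --------------------------------------------
    results: dict = {}
    agreement_rows = []
    trend_rows = []
    zone_rows = []
    for name in device_names:
        results[name] = {}
        severe_by_strand: dict[str, tuple[int, int]] = {}
        for strand in config.strands:
            sub = cohort[cohort["strand"] == strand]
            if name not in present or sub.empty:
                results[name][strand] = {"failed": "no data for device/strand"}
                continue
            try:
                results[name][strand] = _analyse_one(
                    sub, name, strand, config, zones, out_dir,
                    agreement_rows, trend_rows, zone_rows, severe_by_strand,
                )
            except Exception as exc:  # isolate per-stage failures
                logger.exception("stage failed for %s/%s", name, strand)
                results[name][strand] = {"failed": str(exc)}
        ok = [s for s in severe_by_strand.values()]
        if len(ok) >= 2:
            severe = sum(s for s, _ in ok)
            total = sum(n for _, n in ok)
            results[name]["combined_severe_pct"] = round(100.0 * severe / total, 1)

    for rows, fname in [
        (agreement_rows, "agreement_summary.csv"),
        (trend_rows, "trend_summary.csv"),
        (zone_rows, "zone_summary.csv"),
    ]:
        if rows:
            _write_csv(pd.DataFrame(rows), out_dir / fname)

    report = RunReport(
        results=results,
        provenance={
            "seed": config.seed,
            "version": __version__,
            "config": config.config_dict(),
        },
    )
    (out_dir / "report.json").write_text(report.to_json() + "\n")
    (out_dir / "report.txt").write_text(_text_report(report) + "\n")
    return report


def _analyse_one(
    sub, name, strand, config, zones, out_dir,
    agreement_rows, trend_rows, zone_rows, severe_by_strand,
) -> dict:
    entry: dict = {}

    ba = BlandAltman.from_dataframe(sub, name).fit(method=config.ba_method)
    ba = ba.suppress_if_proportional(config.slope_p_threshold)
    s = ba.as_summary()
    entry["agreement"] = dataclasses.asdict(s)
    agreement_rows.append({"device": name, "strand": strand, **dataclasses.asdict(s)})
    _write_csv(
        ba.plot_data(), out_dir / f"bland_altman_points_{name}_{strand}.csv"
    )

    deltas = compute_deltas(frame_to_cohort(sub), name)
    fq = FourQuadrant(deltas, config.exclusion_threshold).fit()
    c = fq.as_summary()
    entry["trend"] = dataclasses.asdict(c)
    trend_rows.append({"device": name, "strand": strand, **dataclasses.asdict(c)})
    _write_csv(fq.plot_data(), out_dir / f"four_quadrant_points_{name}_{strand}.csv")

    classified = classify_points(deltas, zones)
    zs = zone_summary(classified)
    entry["errorgrid"] = {
        "n_points": zs.n_points,
        "counts": zs.counts,
        "percentages": zs.percentages,
    }
    zone_rows.append(
        {"device": name, "strand": strand, "n_points": zs.n_points,
         **{f"n_{k}": v for k, v in zs.counts.items()},
         **{f"pct_{k}": v for k, v in zs.percentages.items()}}
    )
    _write_csv(
        pd.DataFrame(
            {
                "subject_id": [d.subject_id for d, _ in classified],
                "delta_ref": [d.delta_ref for d, _ in classified],
                "delta_dev": [d.delta_dev for d, _ in classified],
                "zone": [z for _, z in classified],
            }
        ),
        out_dir / f"errorgrid_points_{name}_{strand}.csv",
    )
    severe_by_strand[strand] = (zs.counts["severe"], zs.n_points)
    return entry


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def _text_report(report: RunReport) -> str:
    lines = [f"svagree run (seed {report.provenance['seed']})", ""]
    for device, strands in report.results.items():
        lines.append(f"device: {device}")
        for strand, entry in strands.items():
            if strand == "combined_severe_pct":
                lines.append(f"  combined severe-harm rate: {entry}%")
                continue
            lines.append(f"  strand: {strand}")
            if "failed" in entry:
                lines.append(f"    FAILED: {entry['failed']}")
                continue
            a = entry["agreement"]
            loa = (
                "suppressed (proportional bias)"
                if a["loa_low"] is None
                else f"{a['loa_low']:.1f} to {a['loa_high']:.1f} ml"
            )
            pe = (
                "suppressed"
                if a["percentage_error"] is None
                else f"{a['percentage_error']:.1f}%"
            )
            lines.append(
                f"    bias {a['bias']:.1f} ml (n={a['n_pairs']}), LoA {loa}, PE {pe}"
            )
            t = entry["trend"]
            rate = (
                "undefined"
                if t["concordance_rate"] is None
                else f"{t['concordance_rate']:.0f}%"
            )
            r = "n/a" if t["pearson_r"] is None else f"{t['pearson_r']:.2f}"
            lines.append(
                f"    concordance {rate} ({t['n_total']} pairs, "
                f"{t['n_excluded']} excluded), r = {r}"
            )
            e = entry["errorgrid"]
            zones_txt = ", ".join(
                f"{k} {e['counts'][k]} ({e['percentages'][k]}%)" for k in e["counts"]
            )
            lines.append(f"    error grid: {zones_txt}")
        lines.append("")
    return "\n".join(lines)
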