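"""Orchestration: simulate -> preprocess -> detect -> dyads -> fit -> report.

``run_pipeline`` executes the stages in order on in-memory tables and
returns a :class:`RunReport` whose summary tables mirror the study's result
tables: per-trip association counts by colony and stage, percentage of birds
associating, the AICc model ranking, the model-averaged coefficients, the
prediction curve, and re-association percentages by temporal scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association_core as ac
from . import dyad_inference as di
from . import synthetic_data as sd
from . import track_preprocess as tp
from .__init__ import __version__

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    preprocess: tp.PreprocessConfig = field(default_factory=tp.PreprocessConfig)
    criteria: ac.AssociationCriteria = field(default_factory=ac.AssociationCriteria)
    threshold: float = 0.95
    averaging: str = "conditional"
    observation_unit: str = "dyad_day"
    fit_models: bool = True


@dataclass
class RunReport:
    config: RunConfig
    stage_counts: dict
    tables: dict
    warnings: list
    version: str = __version__


def _label_trips(trips: pd.DataFrame, deployments: pd.DataFrame,
                 labels: pd.DataFrame) -> pd.DataFrame:
    out = trips.copy()
    out["day"] = (out["t_start"] // sd.DAY_SECONDS).astype(int)
    out = out.merge(labels, on="day", how="left")
    out = out.merge(deployments[["bird_id", "colony_id"]], on="bird_id",
                    how="left")
    return out


def analyse_study(
    deployments: pd.DataFrame,
    gps: pd.DataFrame,
    tdr: pd.DataFrame,
    day_labels: pd.DataFrame,
    run: RunConfig | None = None,
) -> RunReport:
    """Run preprocessing, detection and inference on one study's tables."""
    run = run or RunConfig()
    counts = {"deployments": len(deployments), "gps_fixes": len(gps),
              "tdr_samples": len(tdr)}
    warnings: list[str] = []

    trips, tracks, dives = tp.preprocess_study(gps, tdr, deployments,
                                               run.preprocess)
    counts["trips"] = len(trips)
    counts["track_points"] = len(tracks)
    counts["dives"] = len(dives)

    events = ac.detect_all_associations(tracks, run.criteria,
                                        dt=run.preprocess.interp_dt)
    counts["association_events"] = len(events)

    labelled = _label_trips(trips, deployments, day_labels)
    per_trip = ac.associations_per_trip(events, labelled)
    tables = {
        "trips": labelled,
        "events": events,
        "per_trip": per_trip,
        "per_trip_summary": ac.summarize_per_trip(per_trip),
    }

    pct_rows = []
    for (colony, stage), grp in labelled.groupby(["colony_id", "stage"]):
        birds = set(grp["bird_id"])
        ev = []
        for _, trip in grp.iterrows():
            ev.append(ac._events_in_trip(events, trip["bird_id"],
                                         trip["t_start"], trip["t_end"]))
        stage_events = (pd.concat(ev).drop_duplicates()
                        if ev else events.iloc[:0])
        pct = ac.percent_individuals_associating(stage_events, birds)
        pct_rows.append({"colony_id": colony, "stage": stage,
                         "n_birds": len(birds),
                         "percent_associating": pct})
    tables["percent_associating"] = pd.DataFrame(pct_rows)
    tables["reassociation"] = ac.reassociation_rates(events, labelled)

    dyads = di.build_dyad_table(labelled, events, deployments,
                                unit=run.observation_unit)
    counts["dyad_observations"] = len(dyads)
    counts["distinct_pairs"] = (
        len(dyads.groupby(["bird_a", "bird_b"])) if len(dyads) else 0)
    tables["dyads"] = dyads

    if run.fit_models and len(dyads) and dyads["associated"].nunique() > 1:
        fits, model_table = di.rank_models(dyads)
        n_dropped = len(di.enumerate_models()) - len(fits)
        if n_dropped:
            warnings.append(f"{n_dropped} model(s) did not converge")
        averaged = di.model_average(fits, model_table["weight"].to_numpy(),
                                    threshold=run.threshold,
                                    mode=run.averaging)
        curve = di.predict_probability(averaged, np.arange(0.0, 181.0, 5.0))
        tables["model_table"] = model_table
        tables["averaged_coefficients"] = averaged
        tables["prediction_curve"] = curve
    return RunReport(config=run, stage_counts=counts, tables=tables,
                     warnings=warnings)


def run_pipeline(run: RunConfig | None = None) -> RunReport:
    """Simulate a study under the run's sim config and analyse it."""
    run = run or RunConfig()
    deployments, gps, tdr, truth, truth_windows = sd.simulate_study(run.sim)
    report = analyse_study(deployments, gps, tdr, sd.day_labels(run.sim), run)
    report.tables["truth"] = truth
    report.tables["truth_windows"] = truth_windows
    return report


def render_report(report: RunReport, fmt: str = "markdown") -> str:
    """Render the report; ``fmt`` in {"markdown", "csv"}."""
    order = ["per_trip_summary", "percent_associating", "model_table",
             "averaged_coefficients", "reassociation"]
    present = [k for k in order if k in report.tables]
    if fmt == "markdown":
        parts = [f"# Foraging association run report (atsea {report.version})",
                 "", "## Stage counts", ""]
        for k, v in report.stage_counts.items():
            parts.append(f"- {k}: {v}")
        for key in present:
            parts += ["", f"## {key}", "",
                      report.tables[key].to_markdown(index=False,
                                                     floatfmt=".3f")]
        if report.warnings:
            parts += ["", "## Warnings", ""]
            parts += [f"- {w}" for w in report.warnings]
        return "\n".join(parts) + "\n"
    if fmt == "csv":
        parts = []
        for key in present:
            parts.append(f"# {key}")
            parts.append(report.tables[key].to_csv(index=False,
                                                   lineterminator="\n"))
        return "\n".join(parts)
    raise ValueError(f"unknown report format {fmt!r}")


def write_outputs(report: RunReport, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, table in report.tables.items():
        table.to_csv(out / f"{key}.csv", index=False, lineterminator="\n")
    (out / "report.md").write_text(render_report(report, "markdown"))
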