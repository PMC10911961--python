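"""End-to-end analysis orchestration.

``run_group_analysis`` takes raw tracks, applies the inclusion filters,
derives observations, fits the requested model variants per colony x
species x period group, validates each against the observed behaviours,
selects the optimal model by log-loss and runs the foraging-event coverage
analysis on it.  ``run_proxy_assessment`` reconstructs the animal's track
from observer bearing/range records, fits the same models to both track
sets and cross-tabulates their decoded states (the FF/FN/NF/NN comparison).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ForagingHMM, FitError, ModelSpecError
from .tracks import (GeoTrack, filter_tracks, track_to_steps,
                     reconstruct_animal_track, TrackTooShortError)
from .validation import (select_model, event_coverage_multi,
                         confusion, ConfusionCounts)

logger = logging.getLogger("ternhmm")

__all__ = ["RunConfig", "GroupResult", "RunReport",
           "run_group_analysis", "run_proxy_assessment"]


@dataclass
class RunConfig:
    """Options for a full pipeline run."""

    model_ids: tuple = (0, 1, 2, 3, 4, 5, 6)
    seed: int = 1
    n_restarts: int = 25
    min_duration_s: float = 60.0
    select_by: str = "logloss"       # "aic" available for comparison studies
    decode_kind: str = "smoothed"    # posterior flavour for log-loss
    standardize_covariate: bool = True
    outdir: Path | None = None

    def __post_init__(self) -> None:
        if not self.model_ids:
            raise ValueError("at least one model id is required")


@dataclass
class GroupResult:
    """Fitted-model table and optimal-model outputs for one data group."""

    group: tuple                      # (colony, species, period)
    table: pd.DataFrame
    best_model_id: int
    best_results: object
    decoded: pd.DataFrame
    coverage: object
    dropped: list


@dataclass
class RunReport:
    groups: list
    dropped: list

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for g in self.groups:
            t = g.table.copy()
            t.insert(0, "colony", g.group[0])
            t.insert(1, "species", g.group[1])
            t.insert(2, "period", g.group[2])
            t["optimal"] = t["model_id"] == g.best_model_id
            frames.append(t)
        return pd.concat(frames, ignore_index=True)


def _fit_models(series, model_ids, config: RunConfig):
    """Fit each requested variant, tolerating individual failures."""
    results = []
    for mid in model_ids:
        try:
            model = ForagingHMM(series, mid,
                                standardize_covariate=config.standardize_covariate)
            results.append(model.fit(n_restarts=config.n_restarts,
                                     seed=config.seed + mid))
        except (FitError, ModelSpecError) as exc:
            logger.warning("model %s failed: %s", mid, exc)
    return results


def run_group_analysis(tracks, config: RunConfig) -> RunReport:
    """Filter, fit, validate and select models for every data group."""
    kept, dropped = filter_tracks(tracks, config.min_duration_s)
    for tid, reason in dropped:
        logger.info("dropped track %s: %s", tid, reason)
    groups: dict[tuple, list[GeoTrack]] = {}
    for tr in kept:
        groups.setdefault((tr.colony, tr.species, tr.period), []).append(tr)

    group_results = []
    for key, group_tracks in groups.items():
        series = []
        for tr in group_tracks:
            try:
                series.append(track_to_steps(tr))
            except TrackTooShortError as exc:
                logger.info("skipping %s: %s", tr.track_id, exc)
        if not series or any(s.behaviour is None for s in series):
            logger.warning("group %s skipped: no usable labelled tracks", key)
            continue
        results = _fit_models(series, config.model_ids, config)
        if not results:
            logger.warning("group %s skipped: no model converged", key)
            continue
        observed = [s.behaviour for s in series]
        selection = select_model(results, observed, criterion=config.select_by)
        best = results[selection.best_index]
        coverage = event_coverage_multi(
            observed, best.decoded_foraging(),
            cadence_s=series[0].cadence_s,
            track_ids=[s.track_id for s in series])
        group_results.append(GroupResult(
            group=key, table=selection.table,
            best_model_id=selection.best_model_id,
            best_results=best, decoded=best.decode(),
            coverage=coverage, dropped=dropped))

    report = RunReport(groups=group_results, dropped=dropped)
    if config.outdir is not None:
        _write_report(report, config)
    return report


def _write_report(report: RunReport, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if report.groups:
        report.to_frame().to_csv(outdir / "model_table.csv", index=False,
                                 float_format="%.6f")
    summary = {"dropped": report.dropped, "groups": []}
    for g in report.groups:
        tag = "_".join(str(x) for x in g.group)
        g.decoded.to_csv(outdir / f"decoded_{tag}.csv", index=False,
                         float_format="%.6f")
        g.coverage.to_frame().to_csv(outdir / f"events_{tag}.csv", index=False,
                                     float_format="%.6f")
        g.best_results.save(outdir / f"fit_{tag}_model{g.best_model_id}.json")
        summary["groups"].append({
            "group": list(g.group),
            "optimal_model": g.best_model_id,
            "missed_events": g.coverage.missed_count,
            "median_missed_duration_s": g.coverage.median_missed_duration_s,
            "n_events": len(g.coverage.events),
        })
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)


@dataclass
class ProxyAssessment:
    """Boat-vs-animal decoded-state comparison for one model variant."""

    model_id: int
    counts: ConfusionCounts           # FF / FN / NF / NN cross-tabulation
    agreement: float                  # (FF + NN) / n
    boat_summary: pd.DataFrame
    animal_summary: pd.DataFrame


def _distribution_summary(series_list) -> pd.DataFrame:
    steps = np.concatenate([s.step for s in series_list])
    angles = np.concatenate([s.angle[~np.isnan(s.angle)] for s in series_list])
    return pd.DataFrame({
        "quantity": ["step_km", "angle_rad"],
        "mean": [steps.mean(), angles.mean()],
        "sd": [steps.std(), angles.std()],
        "q05": [np.quantile(steps, 0.05), np.quantile(angles, 0.05)],
        "q95": [np.quantile(steps, 0.95), np.quantile(angles, 0.95)],
    })


def run_proxy_assessment(boat_tracks, config: RunConfig,
                         model_ids=None) -> list[ProxyAssessment]:
    """Assess observer-platform tracks as proxies for the animal's own track.

    For each requested model variant: reconstruct the animal tracks from the
    boats' bearing/range records, fit the variant independently to boat and
    animal observations, map each fit's states to foraging / not-foraging
    (short-step state = foraging, so label permutations cancel), and
    cross-tabulate the two Viterbi decodings.
    """
    for tr in boat_tracks:
        if tr.bearing is None or tr.distance is None:
            raise ValueError(
                f"track {tr.track_id!r} lacks bearing/distance records; "
                "cannot reconstruct the animal's positions")
    animal_tracks = [reconstruct_animal_track(tr) for tr in boat_tracks]
    boat_series = [track_to_steps(tr) for tr in boat_tracks]
    animal_series = [track_to_steps(tr) for tr in animal_tracks]

    out = []
    for mid in (model_ids if model_ids is not None else config.model_ids):
        try:
            # same seed on both sides: identical inputs then give identical fits
            boat_fit = ForagingHMM(boat_series, mid).fit(
                n_restarts=config.n_restarts, seed=config.seed + mid)
            animal_fit = ForagingHMM(animal_series, mid).fit(
                n_restarts=config.n_restarts, seed=config.seed + mid)
        except (FitError, ModelSpecError) as exc:
            logger.warning("proxy assessment, model %s failed: %s", mid, exc)
            continue
        counts = ConfusionCounts(0, 0, 0, 0)
        for animal_dec, boat_dec in zip(animal_fit.decoded_foraging(),
                                        boat_fit.decoded_foraging()):
            # animal decoding is the reference, boat decoding the prediction
            counts = counts + confusion(animal_dec, boat_dec)
        out.append(ProxyAssessment(
            model_id=mid, counts=counts,
            agreement=(counts.tp + counts.tn) / counts.total,
            boat_summary=_distribution_summary(boat_series),
            animal_summary=_distribution_summary(animal_series)))
    return out
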