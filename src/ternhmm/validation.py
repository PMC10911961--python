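"""Validation of decoded behavioural states against observed behaviours.

The positive class is foraging throughout.  Point metrics (PPV, TPR, NPV,
F1) are computed from pooled confusion counts; probabilistic calibration
uses the logarithmic loss of the smoothed foraging posteriors; and a bout-
level analysis measures, for every observed foraging event (maximal run of
observed foraging), the proportion of its time points the model decodes as
foraging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts", "confusion", "ppv", "tpr", "npv", "f1", "log_loss",
    "ForagingEvent", "extract_foraging_events", "EventCoverage",
    "event_coverage", "validation_metrics", "select_model", "ValidationMetrics",
]

LOGLOSS_CLIP = 1e-12

#: coverage histogram bins; boundaries at exactly 25/50/75% go to the upper bin,
#: "missed" is exactly zero.
COVERAGE_BIN_LABELS = ("missed", "(0,25%)", "[25,50%)", "[50,75%)", "[75,100%]")


class AlignmentError(ValueError):
    """Observed and decoded sequences differ in length."""


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with foraging as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def _as_binary(seq) -> np.ndarray:
    arr = np.asarray(seq)
    if arr.dtype.kind in "UO":
        arr = np.array([1 if str(v) == "foraging" else 0 for v in arr])
    return arr.astype(int)


def confusion(observed, decoded) -> ConfusionCounts:
    """Cross-tabulate aligned binary sequences (1 = foraging)."""
    obs = _as_binary(observed)
    dec = _as_binary(decoded)
    if len(obs) != len(dec):
        raise AlignmentError(f"length mismatch: observed {len(obs)} vs decoded {len(dec)}")
    return ConfusionCounts(
        tp=int(np.sum((obs == 1) & (dec == 1))),
        fp=int(np.sum((obs == 0) & (dec == 1))),
        fn=int(np.sum((obs == 1) & (dec == 0))),
        tn=int(np.sum((obs == 0) & (dec == 0))),
    )


def ppv(counts: ConfusionCounts) -> float:
    """Positive predictive value tp/(tp+fp); NaN when nothing was predicted positive."""
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else float("nan")


def tpr(counts: ConfusionCounts) -> float:
    """True positive rate tp/(tp+fn); NaN when no positives were observed."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else float("nan")


def npv(counts: ConfusionCounts) -> float:
    """Negative predictive value tn/(tn+fn); NaN when nothing was predicted negative."""
    denom = counts.tn + counts.fn
    return counts.tn / denom if denom else float("nan")


def f1(ppv_value: float, tpr_value: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if np.isnan(ppv_value) or np.isnan(tpr_value):
        return float("nan")
    if ppv_value + tpr_value == 0:
        return 0.0
    return 2.0 * ppv_value * tpr_value / (ppv_value + tpr_value)


def log_loss(observed, prob_foraging, clip: float = LOGLOSS_CLIP) -> float:
    """Mean negative log-likelihood of binary labels under predicted probabilities."""
    y = _as_binary(observed)
    q = np.asarray(prob_foraging, dtype=float)
    if len(y) != len(q):
        raise AlignmentError(f"length mismatch: observed {len(y)} vs probabilities {len(q)}")
    q = np.clip(q, clip, 1.0 - clip)
    return float(-np.mean(y * np.log(q) + (1 - y) * np.log(1.0 - q)))


@dataclass(frozen=True)
class ForagingEvent:
    """Maximal contiguous run of observed foraging within one track."""

    track_id: str
    start_index: int
    end_index: int            # inclusive
    duration_s: float

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1


def extract_foraging_events(observed, cadence_s: float = 1.0,
                            track_id: str = "") -> list[ForagingEvent]:
    """Run-length extraction of observed foraging bouts from one sequence."""
    obs = _as_binary(observed)
    padded = np.concatenate([[0], obs, [0]])
    diff = np.diff(padded)
    starts = np.where(diff == 1)[0]
    ends = np.where(diff == -1)[0] - 1
    return [ForagingEvent(track_id, int(a), int(b), float((b - a + 1) * cadence_s))
            for a, b in zip(starts, ends)]


def coverage_bin(proportion: float) -> str:
    """Histogram bin of a per-event decoded-foraging proportion."""
    if proportion == 0.0:
        return COVERAGE_BIN_LABELS[0]
    if proportion < 0.25:
        return COVERAGE_BIN_LABELS[1]
    if proportion < 0.50:
        return COVERAGE_BIN_LABELS[2]
    if proportion < 0.75:
        return COVERAGE_BIN_LABELS[3]
    return COVERAGE_BIN_LABELS[4]


@dataclass
class EventCoverage:
    """Per-event decoded-foraging proportions and their histogram."""

    events: list[ForagingEvent]
    proportions: list[float]
    bins: dict[str, int]
    missed_count: int
    missed_durations_s: list[float]

    @property
    def median_missed_duration_s(self) -> float:
        return float(np.median(self.missed_durations_s)) if self.missed_durations_s else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "track_id": [e.track_id for e in self.events],
            "event_start": [e.start_index for e in self.events],
            "event_len_s": [e.duration_s for e in self.events],
            "prop_correct": self.proportions,
            "bin": [coverage_bin(p) for p in self.proportions],
        })


def event_coverage(events: Sequence[ForagingEvent], decoded) -> EventCoverage:
    """Proportion of each observed foraging event decoded as foraging.

    ``decoded`` is the aligned binary decoding of the same sequence the
    events were extracted from.  An event is "missed" when the model infers
    foraging at exactly 0% of its time points; missed events' durations are
    collected for the median-missed-duration summary.
    """
    dec = _as_binary(decoded)
    proportions = []
    bins = {lab: 0 for lab in COVERAGE_BIN_LABELS}
    missed_durations: list[float] = []
    for ev in events:
        window = dec[ev.start_index: ev.end_index + 1]
        p = float(np.mean(window == 1))
        proportions.append(p)
        bins[coverage_bin(p)] += 1
        if p == 0.0:
            missed_durations.append(ev.duration_s)
    return EventCoverage(list(events), proportions, bins,
                         missed_count=len(missed_durations),
                         missed_durations_s=missed_durations)


def event_coverage_multi(observed_by_track: Sequence, decoded_by_track: Sequence,
                         cadence_s: float = 1.0,
                         track_ids: Sequence[str] | None = None) -> EventCoverage:
    """Event coverage pooled over several aligned track sequences."""
    all_events: list[ForagingEvent] = []
    proportions: list[float] = []
    bins = {lab: 0 for lab in COVERAGE_BIN_LABELS}
    missed: list[float] = []
    ids = track_ids or [str(i) for i in range(len(observed_by_track))]
    for tid, obs, dec in zip(ids, observed_by_track, decoded_by_track):
        events = extract_foraging_events(obs, cadence_s, tid)
        cov = event_coverage(events, dec)
        all_events += cov.events
        proportions += cov.proportions
        for lab in COVERAGE_BIN_LABELS:
            bins[lab] += cov.bins[lab]
        missed += cov.missed_durations_s
    return EventCoverage(all_events, proportions, bins, len(missed), missed)


@dataclass(frozen=True)
class ValidationMetrics:
    """Pooled point and probabilistic validation metrics for one fit."""

    counts: ConfusionCounts
    ppv: float
    tpr: float
    npv: float
    f1: float
    logloss: float
    aic: float = float("nan")

    def as_row(self) -> dict:
        return {"ppv": self.ppv, "tpr": self.tpr, "npv": self.npv,
                "f1": self.f1, "logloss": self.logloss, "aic": self.aic,
                "tp": self.counts.tp, "fp": self.counts.fp,
                "fn": self.counts.fn, "tn": self.counts.tn}


def validation_metrics(observed_by_track, decoded_by_track, prob_by_track,
                       aic: float = float("nan")) -> ValidationMetrics:
    """Pool time points across tracks and compute all validation metrics."""
    counts = ConfusionCounts(0, 0, 0, 0)
    for obs, dec in zip(observed_by_track, decoded_by_track):
        counts = counts + confusion(obs, dec)
    y = np.concatenate([_as_binary(o) for o in observed_by_track])
    q = np.concatenate([np.asarray(p, dtype=float) for p in prob_by_track])
    p_, t_ = ppv(counts), tpr(counts)
    return ValidationMetrics(counts, p_, t_, npv(counts), f1(p_, t_),
                             log_loss(y, q), aic)


@dataclass
class ModelSelection:
    """Ranking of candidate fits by validation log-loss."""

    table: pd.DataFrame          # one row per model, ascending log-loss
    best_index: int              # positional index into the input sequence
    best_model_id: int


def select_model(results_list, observed_by_track,
                 criterion: str = "logloss") -> ModelSelection:
    """Rank fitted models by log-loss (default) and return the minimiser.

    Each entry of ``results_list`` is a fitted results object sharing the
    same data and alignment as ``observed_by_track``.  Ties are broken by
    fewer parameters.  ``criterion="aic"`` is available for comparison
    studies only.
    """
    if not results_list:
        raise ValueError("no fitted models to select from")
    rows = []
    for i, res in enumerate(results_list):
        metrics = validation_metrics(
            observed_by_track, res.decoded_foraging(), res.prob_foraging(),
            aic=res.aic)
        row = metrics.as_row()
        row.update({"index": i, "model_id": res.spec.model_id,
                    "model_description": res.spec.description,
                    "n_params": res.n_params, "loglik": res.llf})
        rows.append(row)
    table = pd.DataFrame(rows)
    key = "logloss" if criterion == "logloss" else "aic"
    table = table.sort_values([key, "n_params"], kind="stable").reset_index(drop=True)
    best = table.iloc[0]
    return ModelSelection(table=table, best_index=int(best["index"]),
                          best_model_id=int(best["model_id"]))
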