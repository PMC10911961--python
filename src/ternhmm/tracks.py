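"""Track containers and the conversion from GPS fixes to HMM observations.

A :class:`GeoTrack` holds the raw 1 Hz fixes for one tracked individual
(or for the observer boat following it).  :func:`track_to_steps` turns a
track into the bivariate observation series the HMM consumes: great-circle
step lengths (km), signed turning angles (radians, first one undefined),
a distance-to-colony covariate and the per-step observed behaviour label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .geometry import (
    great_circle_km,
    initial_bearing,
    destination_point,
    wrap_angle,
)

FORAGING = "foraging"
NOT_FORAGING = "not_foraging"

#: Observer ethogram -> binary behaviour. Active search is erratic,
#: food-searching flight and is scored as foraging; transit search and
#: direct flight are scored as not-foraging.
ETHOGRAM = {
    "active_search": FORAGING,
    "transit_search": NOT_FORAGING,
    "direct_flight": NOT_FORAGING,
    FORAGING: FORAGING,
    NOT_FORAGING: NOT_FORAGING,
}

ZERO_STEP_EPSILON_KM = 1e-6


class EthogramError(KeyError):
    """Raised for a behaviour label outside the known ethogram."""


class TrackTooShortError(ValueError):
    """Raised when a track has too few fixes for the requested operation."""


def map_ethogram(label: str) -> str:
    """Map an observed ethogram label to binary foraging / not_foraging."""
    try:
        return ETHOGRAM[label]
    except KeyError:
        raise EthogramError(f"unknown behaviour label: {label!r}") from None


@dataclass
class GeoTrack:
    """Time-ordered GPS fixes for one individual (animal or observer boat).

    ``bearing`` (radians, [0, 2*pi)) and ``distance`` (km) are the recorded
    bearing/range from the observer platform to the animal, present only for
    boat tracks that logged them.
    """

    track_id: str
    colony_lon: float
    colony_lat: float
    time: np.ndarray          # seconds since track start
    lon: np.ndarray           # degrees
    lat: np.ndarray           # degrees
    behaviour: np.ndarray | None = None
    bearing: np.ndarray | None = None
    distance: np.ndarray | None = None
    period: str = "chick_rearing"
    colony: str = "synthetic"
    species: str = "synthetic"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        n = len(self.time)
        if n < 2:
            raise TrackTooShortError(f"track {self.track_id!r} has {n} fixes; need >= 2")
        if not (len(self.lon) == len(self.lat) == n):
            raise ValueError(f"track {self.track_id!r}: ragged fix columns")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError(f"track {self.track_id!r}: times must strictly increase")
        if np.any(np.abs(self.lat) > 90.0) or np.any(np.abs(self.lon) > 180.0):
            raise ValueError(f"track {self.track_id!r}: lon/lat out of bounds")
        for name in ("behaviour", "bearing", "distance"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if len(arr) != n:
                    raise ValueError(f"track {self.track_id!r}: {name} length mismatch")
                setattr(self, name, arr)

    @property
    def n_fixes(self) -> int:
        return len(self.time)

    @property
    def duration_s(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def cadence_s(self) -> float:
        """Modal gap between consecutive fixes, in seconds."""
        gaps = np.diff(self.time)
        vals, counts = np.unique(gaps, return_counts=True)
        return float(vals[np.argmax(counts)])


@dataclass
class StepAngleSeries:
    """Per-interval HMM observations derived from one track.

    ``step[t]`` is the km between fixes t and t+1; ``angle[t]`` is the signed
    change of heading into step t (NaN at t=0, where no previous heading
    exists); ``dist_colony[t]`` and ``behaviour[t]`` are taken from the
    step's starting fix.  ``behaviour`` is 1 = foraging, 0 = not-foraging,
    or None when the track carried no labels.
    """

    track_id: str
    step: np.ndarray
    angle: np.ndarray
    dist_colony: np.ndarray
    behaviour: np.ndarray | None = None
    cadence_s: float = 1.0
    n_zero_steps: int = 0
    colony: str = "synthetic"
    species: str = "synthetic"
    period: str = "chick_rearing"

    def __post_init__(self) -> None:
        self.step = np.asarray(self.step, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if len(self.angle) != len(self.step) or len(self.dist_colony) != len(self.step):
            raise ValueError("step/angle/dist_colony must be equal length")
        if np.any(self.step <= 0):
            raise ValueError("steps must be strictly positive (epsilon-substituted)")
        if self.behaviour is not None:
            self.behaviour = np.asarray(self.behaviour, dtype=int)

    def __len__(self) -> int:
        return len(self.step)


def track_to_steps(
    track: GeoTrack,
    zero_step_epsilon: float = ZERO_STEP_EPSILON_KM,
) -> StepAngleSeries:
    """Convert a track of >= 3 fixes to step lengths and turning angles.

    Exactly-zero steps (repeated fixes) are replaced by ``zero_step_epsilon``
    km so the strictly-positive gamma support applies, and counted in
    ``n_zero_steps``.  The heading over a zero step is carried forward from
    the last moving step so turning angles stay defined.
    """
    if track.n_fixes < 3:
        raise TrackTooShortError(
            f"track {track.track_id!r}: need >= 3 fixes for turning angles"
        )
    lon, lat = track.lon, track.lat
    step = great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    moving = step > 0
    n_zero = int(np.sum(~moving))

    headings = np.full(len(step), np.nan)
    if np.any(moving):
        headings[moving] = initial_bearing(
            lon[:-1][moving], lat[:-1][moving], lon[1:][moving], lat[1:][moving]
        )
        # forward-fill headings across stationary intervals, backfill the lead
        idx = np.where(moving, np.arange(len(step)), -1)
        idx = np.maximum.accumulate(idx)
        first = np.argmax(moving)
        idx[idx < 0] = first
        headings = headings[idx]
    else:
        headings[:] = 0.0

    angle = np.empty(len(step))
    angle[0] = np.nan
    # bearings are clockwise from north, so a counter-clockwise (left) turn
    # decreases the bearing; negate to make left turns positive
    angle[1:] = wrap_angle(-np.diff(headings))

    step = np.where(moving, step, zero_step_epsilon)
    dist_colony = great_circle_km(lon[:-1], lat[:-1], track.colony_lon, track.colony_lat)

    behaviour = None
    if track.behaviour is not None:
        behaviour = np.array(
            [1 if map_ethogram(str(b)) == FORAGING else 0 for b in track.behaviour[:-1]]
        )
    return StepAngleSeries(
        track_id=track.track_id,
        step=step,
        angle=angle,
        dist_colony=dist_colony,
        behaviour=behaviour,
        cadence_s=track.cadence_s,
        n_zero_steps=n_zero,
        colony=track.colony,
        species=track.species,
        period=track.period,
    )


def filter_tracks(
    tracks: Iterable[GeoTrack],
    min_duration_s: float = 60.0,
) -> tuple[list[GeoTrack], list[tuple[str, str]]]:
    """Apply the visual-track inclusion rules.

    Tracks whose total duration does not exceed ``min_duration_s`` are
    dropped (reason ``"too_short"``), as are tracks on which a single
    observed behaviour was recorded throughout (reason ``"single_behaviour"``,
    judged on the raw ethogram labels).  Returns (kept, [(track_id, reason)]).
    """
    kept: list[GeoTrack] = []
    dropped: list[tuple[str, str]] = []
    for track in tracks:
        if track.duration_s <= min_duration_s:
            dropped.append((track.track_id, "too_short"))
        elif track.behaviour is not None and len(set(map(str, track.behaviour))) == 1:
            dropped.append((track.track_id, "single_behaviour"))
        else:
            kept.append(track)
    return kept, dropped


def segment_track(track: GeoTrack, cadence_tol_s: float = 0.5) -> list[GeoTrack]:
    """Split a track at gaps larger than its modal cadence +- tolerance.

    Each resulting segment is treated downstream as an independent sequence.
    Segments of fewer than 2 fixes are discarded.
    """
    gaps = np.diff(track.time)
    cadence = track.cadence_s
    breaks = np.where(np.abs(gaps - cadence) > cadence_tol_s)[0]
    if len(breaks) == 0:
        return [track]
    bounds = [0, *list(breaks + 1), track.n_fixes]
    segments = []
    for k, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        if b - a < 2:
            continue
        segments.append(
            replace(
                track,
                track_id=f"{track.track_id}#{k}",
                time=track.time[a:b],
                lon=track.lon[a:b],
                lat=track.lat[a:b],
                behaviour=None if track.behaviour is None else track.behaviour[a:b],
                bearing=None if track.bearing is None else track.bearing[a:b],
                distance=None if track.distance is None else track.distance[a:b],
            )
        )
    return segments


def reconstruct_animal_track(boat_track: GeoTrack) -> GeoTrack:
    """Reconstruct the animal's track from a boat track with bearing/range.

    Each animal fix is the destination point reached from the simultaneous
    boat fix along the recorded bearing for the recorded distance.
    """
    if boat_track.bearing is None or boat_track.distance is None:
        raise ValueError(
            f"track {boat_track.track_id!r}: bearing/distance required to "
            "reconstruct the animal's position"
        )
    lon, lat = destination_point(
        boat_track.lon,
        boat_track.lat,
        np.asarray(boat_track.bearing, dtype=float),
        np.asarray(boat_track.distance, dtype=float),
    )
    return replace(
        boat_track,
        track_id=f"{boat_track.track_id}:animal",
        lon=np.asarray(lon),
        lat=np.asarray(lat),
        bearing=None,
        distance=None,
    )
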