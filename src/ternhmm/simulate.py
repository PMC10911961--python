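"""Synthetic visual-tracking data with the structure the analysis assumes.

The generator produces (i) 1 Hz tern tracks from a two-state switching
step-and-turn model on the sphere — short tortuous steps in the foraging
state, long directionally persistent steps otherwise; (ii) an observer-boat
track that pursues each tern with smoothed heading, kept roughly 50-200 m
away, logging the true bearing and range to the bird at every fix; (iii)
per-fix observed behaviour labels (the true states, optionally flipped at a
label-noise rate); and (iv) a distance-to-colony covariate that can drive
the state transition probabilities.

Default regime (overridable): mean steps 5 m / 20 m per second (plausible
tern flight speeds), angle concentrations 1 / 20, symmetric switching at
0.05 per second (about 20 s dwell times), colony at Coquet Island.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import special

from .geometry import destination_point, initial_bearing, great_circle_km
from .tracks import GeoTrack, FORAGING, NOT_FORAGING

__all__ = [
    "SimulationConfig", "SyntheticDataset", "simulate_tern_track",
    "simulate_boat_follow", "simulate_labels", "make_dataset",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults are the study conditions."""

    n_tracks: int = 10
    track_length_s: int = 2000          # steps per track (fixes = steps + 1)
    cadence_s: float = 1.0

    # state-dependent movement: index 0 = foraging, 1 = not-foraging
    mu: tuple = (0.005, 0.020)          # mean step, km
    sigma: tuple = (0.003, 0.008)       # sd step, km
    rho: tuple = (0.0, 0.0)             # von Mises mean turn, rad
    kappa: tuple = (1.0, 20.0)          # von Mises concentration
    delta: tuple = (0.5, 0.5)           # initial state distribution
    gamma_offdiag: tuple = (0.05, 0.05)  # (gamma_12, gamma_21) baseline switch rates

    # optional covariate effect on switching (logit scale, standardised distance)
    covariate_on_state: bool = False
    state_beta1: tuple = (0.0, 0.0)     # slopes for (1->2, 2->1)
    covariate_center_km: float = 3.0
    covariate_scale_km: float = 2.0

    # geography
    colony_lon: float = -1.533          # Coquet Island
    colony_lat: float = 55.333
    start_distance_km: float = 1.0

    # boat pursuit
    boat_target_km: float = 0.1         # kept c. 50-200 m from the bird
    boat_band_km: tuple = (0.05, 0.2)
    heading_smoothing: float = 0.7      # weight on the boat's previous heading
    speed_smoothing: float = 0.5        # inertia weight on the boat's previous speed
    pursuit_gain: float = 1.0           # speed demanded per km of range error, 1/s
    boat_speed_cap_kms: float = 0.04
    boat_idle_kms: float = 0.001        # slow drift while station-keeping
    boat_speed_noise_kms: float = 0.0005  # per-second throttle/GPS noise
    boat_jitter_sd_km: float = 0.0

    label_noise: float = 0.0            # observers treated as ground truth
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if not (0 <= self.heading_smoothing < 1):
            raise ValueError("heading_smoothing must be in [0, 1)")
        if not (self.mu[0] < self.mu[1]):
            raise ValueError("foraging mean step must be below not-foraging mean step")
        if any(v <= 0 for v in (*self.mu, *self.sigma)) or any(k < 0 for k in self.kappa):
            raise ValueError("movement parameters must be positive")
        if not np.isclose(sum(self.delta), 1.0):
            raise ValueError("delta must sum to 1")

    @property
    def trans_beta0(self) -> np.ndarray:
        """Logit intercepts implied by the baseline off-diagonal rates."""
        return special.logit(np.asarray(self.gamma_offdiag, dtype=float))


@dataclass
class SyntheticDataset:
    """A full synthetic study: tern tracks, boat proxies, labels, truth."""

    tern_tracks: list
    boat_tracks: list
    true_states: list                   # per track, per step (0/1), len = n steps
    config: SimulationConfig
    seed: int


def _gamma_step(rng, mu, sigma, size=None):
    shape = (mu / sigma) ** 2
    scale = sigma**2 / mu
    return rng.gamma(shape, scale, size=size)


def _switch_prob(config: SimulationConfig, state: int, dist_km: float) -> float:
    """P(leave current state) at the current distance to colony."""
    eta = config.trans_beta0[state]
    if config.covariate_on_state:
        c = (dist_km - config.covariate_center_km) / config.covariate_scale_km
        eta = eta + config.state_beta1[state] * c
    return float(special.expit(eta))


def simulate_tern_track(config: SimulationConfig, seed: int,
                        track_id: str = "tern") -> tuple[GeoTrack, np.ndarray]:
    """Simulate one tern track; returns (track, true per-step states).

    Positions advance on the sphere: each second the heading turns by a von
    Mises draw of the current state and the bird moves a gamma step.  The
    track starts ``start_distance_km`` from the colony on a random bearing;
    the first heading is uniform.  When the covariate effect is enabled the
    switching probabilities are recomputed each second from the current
    distance to the colony.
    """
    rng = np.random.default_rng(seed)
    T = config.track_length_s
    lon = np.empty(T + 1)
    lat = np.empty(T + 1)
    lon[0], lat[0] = destination_point(
        config.colony_lon, config.colony_lat,
        rng.uniform(0, 2 * np.pi), config.start_distance_km)
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(len(config.delta), p=np.asarray(config.delta))
    heading = rng.uniform(0, 2 * np.pi)
    for t in range(T):
        if t > 0:
            dist = great_circle_km(lon[t], lat[t], config.colony_lon, config.colony_lat)
            p_switch = _switch_prob(config, states[t - 1], dist)
            states[t] = 1 - states[t - 1] if rng.random() < p_switch else states[t - 1]
            k = config.kappa[states[t]]
            # kappa above 1e12 is treated as the deterministic limit psi = rho
            turn = (config.rho[states[t]] if k >= 1e12
                    else rng.vonmises(config.rho[states[t]], k))
            # turning angles are counter-clockwise positive; bearings clockwise
            heading = float(np.mod(heading - turn, 2 * np.pi))
        step = _gamma_step(rng, config.mu[states[t]], config.sigma[states[t]])
        lon[t + 1], lat[t + 1] = destination_point(lon[t], lat[t], heading, step)
    behaviour = np.array([FORAGING if s == 0 else NOT_FORAGING
                          for s in np.append(states, states[-1])], dtype=object)
    track = GeoTrack(
        track_id=track_id, colony_lon=config.colony_lon, colony_lat=config.colony_lat,
        time=np.arange(T + 1, dtype=float) * config.cadence_s,
        lon=lon, lat=lat, behaviour=behaviour,
        colony="synthetic", species="synthetic", period="chick_rearing",
    )
    return track, states


def simulate_boat_follow(tern_track: GeoTrack, config: SimulationConfig,
                         seed: int) -> GeoTrack:
    """Simulate the observer boat pursuing a tern track.

    The boat starts at the target range on a random bearing from the bird.
    Each second it blends its previous heading with the bearing to the
    bird's current position (circular weighted mean, weight
    ``heading_smoothing`` on the old heading) and smooths its speed toward
    the range error (weight ``speed_smoothing`` on the old speed, capped,
    never below a slow station-keeping drift).  Heading and speed inertia
    keep the boat near the target range while giving it smoother turning
    and steadier speed than the bird — the qualitative signature of a real
    pursuit platform.  The returned track carries the exact bearing and
    range from the boat to the bird at every fix, so the bird's position
    can be reconstructed.
    """
    rng = np.random.default_rng(seed)
    T = tern_track.n_fixes
    blon = np.empty(T)
    blat = np.empty(T)
    blon[0], blat[0] = destination_point(
        tern_track.lon[0], tern_track.lat[0],
        rng.uniform(0, 2 * np.pi), config.boat_target_km)
    w = config.heading_smoothing
    ws = config.speed_smoothing
    heading = initial_bearing(blon[0], blat[0], tern_track.lon[1], tern_track.lat[1])
    speed = config.boat_idle_kms
    band_min = config.boat_band_km[0]
    for t in range(1, T):
        dist = great_circle_km(blon[t - 1], blat[t - 1],
                               tern_track.lon[t], tern_track.lat[t])
        to_bird = initial_bearing(blon[t - 1], blat[t - 1],
                                  tern_track.lon[t], tern_track.lat[t])
        heading = float(np.mod(np.arctan2(
            w * np.sin(heading) + (1 - w) * np.sin(to_bird),
            w * np.cos(heading) + (1 - w) * np.cos(to_bird)), 2 * np.pi))
        desired = float(np.clip(
            config.pursuit_gain * (dist - config.boat_target_km),
            -config.boat_speed_cap_kms, config.boat_speed_cap_kms))
        speed = ws * speed + (1 - ws) * desired
        if config.boat_idle_kms > 0:
            # default regime: always drift forward, never reverse
            speed = max(speed, config.boat_idle_kms)
        move = speed + rng.normal(0.0, config.boat_speed_noise_kms)
        if config.boat_idle_kms > 0:
            move = max(move, 1e-4)
            # the platform never closes inside the inner band edge by itself;
            # the bird can still transiently overfly the boat
            move = min(move, max(dist - band_min, 1e-4))
        if move >= 0:
            blon[t], blat[t] = destination_point(blon[t - 1], blat[t - 1],
                                                 heading, move)
        else:
            blon[t], blat[t] = destination_point(
                blon[t - 1], blat[t - 1], np.mod(heading + np.pi, 2 * np.pi), -move)
        if config.boat_jitter_sd_km > 0:
            blon[t], blat[t] = destination_point(
                blon[t], blat[t], rng.uniform(0, 2 * np.pi),
                abs(rng.normal(0, config.boat_jitter_sd_km)))
    bearing = initial_bearing(blon, blat, tern_track.lon, tern_track.lat)
    distance = great_circle_km(blon, blat, tern_track.lon, tern_track.lat)
    return GeoTrack(
        track_id=f"{tern_track.track_id}:boat",
        colony_lon=tern_track.colony_lon, colony_lat=tern_track.colony_lat,
        time=tern_track.time.copy(), lon=blon, lat=blat,
        behaviour=None if tern_track.behaviour is None else tern_track.behaviour.copy(),
        bearing=bearing, distance=distance,
        colony=tern_track.colony, species=tern_track.species, period=tern_track.period,
    )


def simulate_labels(true_states: np.ndarray, noise_rate: float,
                    seed: int) -> np.ndarray:
    """Observed binary labels: true states flipped independently at ``noise_rate``."""
    if not (0 <= noise_rate < 0.5):
        raise ValueError("noise_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    states = np.asarray(true_states, dtype=int)
    flips = rng.random(len(states)) < noise_rate
    return np.where(flips, 1 - states, states)


def make_dataset(config: SimulationConfig | None = None,
                 seed: int | None = None) -> SyntheticDataset:
    """End-to-end generation of a synthetic visual-tracking study.

    Child seeds for each track, its boat and its labels are derived
    deterministically from the master seed, so the dataset is fully
    reproducible and individual components can be regenerated in isolation.
    """
    config = config or SimulationConfig()
    master = config.seed if seed is None else seed
    tern_tracks, boat_tracks, true_states = [], [], []
    for i in range(config.n_tracks):
        base = (master * 100003 + i * 1009) % (2**31 - 1)
        tern, states = simulate_tern_track(config, base, track_id=f"tern{i:02d}")
        labels = simulate_labels(states, config.label_noise, base + 1)
        # state 0 is foraging in the generator; last fix repeats the last step's label
        lab_full = np.array([FORAGING if s == 0 else NOT_FORAGING
                             for s in np.append(labels, labels[-1])], dtype=object)
        tern.behaviour = lab_full
        boat = simulate_boat_follow(tern, config, base + 2)
        boat.behaviour = lab_full.copy()
        tern_tracks.append(tern)
        boat_tracks.append(boat)
        true_states.append(states)
    return SyntheticDataset(tern_tracks, boat_tracks, true_states, config, master)


# --------------------------------------------------------------------------- #
# writers

def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write tern/boat track CSVs plus a manifest JSON; returns the paths."""
    from .io import write_tracks_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tern_path = outdir / "tern_tracks.csv"
    boat_path = outdir / "boat_tracks.csv"
    write_tracks_csv(dataset.tern_tracks, tern_path)
    write_tracks_csv(dataset.boat_tracks, boat_path)
    manifest = {
        "seed": dataset.seed,
        "n_tracks": dataset.config.n_tracks,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(dataset.config).items()},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"tern": tern_path, "boat": boat_path, "manifest": manifest_path}
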