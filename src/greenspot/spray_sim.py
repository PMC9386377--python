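"""Closed-loop spot-sprayer simulation: trigger, delay compensation, valve windows, scoring.

The world model is one-dimensional along the travel axis. A camera line
(region-of-interest threshold) leads the nozzle by the camera-nozzle distance
L_cn; a target is triggered the first frame its front edge crosses that line.
The controller compensates the four system delays -- identification t1,
communication t2, valve response t3, droplet fall t4 -- by scheduling the
valve on encoder distance: the command latches the encoder reading d0 at
receipt and the valve is open while the reading lies in
(d0 + open_offset, d0 + close_offset). Encoder skid is modeled as a
multiplicative slip factor plus optional zero-mean jitter per valve window.

Outcome scoring follows the field protocol: D_open = plant_front -
deposit_start and D_close = deposit_end - plant_rear (positive = margin);
a spray is invalid when either shortfall exceeds the invalid threshold
(default 70 mm, the "-7 cm" rule), missed when no deposit touches the plant
or the commanded open time is below the valve response time, else effective.
The theoretical pesticide saving rate per target is
epsilon = (L_sp - s) / L_sp * 100 with s the deposit length and L_sp the
plant spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import round_half_up

__all__ = [
    "SprayerConfig",
    "Plant",
    "FieldScenario",
    "SprayEvent",
    "SprayStats",
    "pixel_to_ground",
    "detect_crossing",
    "delay_time",
    "valve_window",
    "in_window",
    "merge_windows",
    "simulate_pass",
    "score_event",
    "saving_rate",
    "aggregate",
    "pass_dosage",
    "continuous_dosage",
    "dosage_compare",
]

#: default ground scale: 1.5 m field of view across 1280 image columns
MM_PER_PX = 1500.0 / 1280.0


def pixel_to_ground(px: float, mm_per_px: float = MM_PER_PX) -> float:
    """Image pixels -> millimetres on the ground (same scale on both axes)."""
    return px * mm_per_px


def detect_crossing(y_n: float, y_prev: float, y_threshold: float) -> bool:
    """Crossing trigger: current row past the threshold, previous row not yet.

    Rows increase toward the nozzle side, so the condition fires exactly once
    per target as it sweeps through the region of interest.
    """
    return y_n > y_threshold and y_prev <= y_threshold


@dataclass
class SprayerConfig:
    """Sprayer geometry, delays and error injection.

    Delays (seconds): t1 identification, t2 communication, t3 valve
    response, t4 droplet fall. ``camera_nozzle_distance_m`` is the ground
    distance between the ROI threshold line and the nozzle. Presets are the
    intended spray margins ahead of and behind each plant.
    """

    speed: float = 0.52                    # m/s
    t1: float = 0.038
    t2: float = 0.00082
    t3: float = 0.020
    t4: float = 0.035
    camera_nozzle_distance_m: float = 0.7
    advance_mm: float = 30.0
    lag_mm: float = 30.0
    frame_rate: float = 28.0               # Hz
    mm_per_px: float = MM_PER_PX
    invalid_threshold_mm: float = 70.0
    flow_rate_l_s: float = 0.03            # per nozzle
    # error injection (all off by default = ideal sprayer)
    slip_factor: float = 1.0               # encoder reads slip * true distance
    slip_jitter_mm: float = 0.0            # SD of per-window encoder error
    miss_prob: float = 0.0                 # P(target not identified at all)
    partial_prob: float = 0.0              # P(only part of the target detected)
    partial_frac: float = 0.3              # detected extent lost when partial

    @property
    def total_delay(self) -> float:
        return self.t1 + self.t2 + self.t3 + self.t4

    @classmethod
    def field_preset(cls, speed: float, **overrides) -> "SprayerConfig":
        """Config with realistic field error injection at a given speed.

        Wheel skid and encoder jitter grow with speed; identification misses
        (small/occluded plants) and partial detections (local reflection
        cutting off part of a canopy) occur at speed-independent rates.
        """
        base = dict(
            speed=speed,
            slip_factor=1.0 + 0.012 * max(speed - 0.5, 0.0) / 0.4,
            slip_jitter_mm=8.0 + 30.0 * max(speed - 0.5, 0.0) / 0.4,
            miss_prob=0.045,
            partial_prob=0.025,
            partial_frac=0.7,
        )
        base.update(overrides)
        return cls(**base)

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if min(self.t1, self.t2, self.t3, self.t4) < 0:
            raise ValueError("delays must be non-negative")
        if self.camera_nozzle_distance_m < self.total_delay * self.speed:
            raise ValueError(
                "sprayer too fast for geometry: camera-nozzle distance "
                f"{self.camera_nozzle_distance_m} m < total delay travel "
                f"{self.total_delay * self.speed:.4f} m")


def delay_time(cfg: SprayerConfig) -> float:
    """System delay setting T = L_cn / v - (t1 + t2 + t3 + t4), seconds."""
    T = cfg.camera_nozzle_distance_m / cfg.speed - cfg.total_delay
    if T < 0:
        raise ValueError("negative delay time: sprayer too fast for geometry")
    return T


@dataclass
class Plant:
    position_mm: float        # front edge along the travel axis
    length_mm: float
    species: str = "cabbage"

    @property
    def front(self) -> float:
        return self.position_mm

    @property
    def rear(self) -> float:
        return self.position_mm + self.length_mm

    @property
    def center(self) -> float:
        return self.position_mm + self.length_mm / 2.0


@dataclass
class FieldScenario:
    """One crop row: plants along the travel axis of a ridge."""

    plants: list[Plant]
    ridge_length_m: float = 70.0
    spacing_mm: float = 400.0
    void_rate: float = 0.0

    def __post_init__(self) -> None:
        ordered = sorted(self.plants, key=lambda p: p.position_mm)
        for a, b in zip(ordered, ordered[1:]):
            if b.front < a.rear:
                raise ValueError("plants overlap within the row")
        self.plants = ordered


def valve_window(d0: float, open_offset: float, close_offset: float
                 ) -> tuple[float, float]:
    """Valve window in encoder coordinates, anchored at the latched reading d0."""
    if close_offset <= open_offset:
        raise ValueError("close offset must exceed open offset")
    return (d0 + open_offset, d0 + close_offset)


def in_window(window: tuple[float, float], distance: float) -> bool:
    lo, hi = window
    return lo < distance < hi


def merge_windows(windows: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of open intervals; overlapping/adjacent windows fuse into one span."""
    if not windows:
        return []
    ordered = sorted(windows)
    merged = [list(ordered[0])]
    for lo, hi in ordered[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


@dataclass
class SprayEvent:
    target_id: int
    species: str
    plant_front: float
    plant_rear: float
    deposit_start: float | None
    deposit_end: float | None
    d_open: float | None
    d_close: float | None
    spray_length: float
    centroid_offset: float | None
    outcome: str                      # "effective" | "invalid" | "missed"


def score_event(deposit: tuple[float, float] | None,
                plant: tuple[float, float],
                invalid_threshold_mm: float = 70.0,
                target_id: int = 0, species: str = "cabbage",
                valve_open_ok: bool = True) -> SprayEvent:
    """Classify one target's spray outcome from its deposit interval."""
    front, rear = plant
    if rear <= front:
        raise ValueError("invalid plant interval")
    touches = (deposit is not None and deposit[1] > front and deposit[0] < rear)
    if not touches or not valve_open_ok:
        return SprayEvent(target_id=target_id, species=species,
                          plant_front=front, plant_rear=rear,
                          deposit_start=None, deposit_end=None,
                          d_open=None, d_close=None, spray_length=0.0,
                          centroid_offset=None, outcome="missed")
    start, end = deposit
    d_open = front - start
    d_close = end - rear
    outcome = ("invalid"
               if d_open < -invalid_threshold_mm or d_close < -invalid_threshold_mm
               else "effective")
    return SprayEvent(target_id=target_id, species=species,
                      plant_front=front, plant_rear=rear,
                      deposit_start=start, deposit_end=end,
                      d_open=d_open, d_close=d_close,
                      spray_length=end - start,
                      centroid_offset=abs((start + end) / 2 - (front + rear) / 2),
                      outcome=outcome)


def _simulate(scenario: FieldScenario, cfg: SprayerConfig, seed: int
              ) -> tuple[list[SprayEvent], list[tuple[float, float]]]:
    delay_time(cfg)  # validates geometry
    rng = np.random.default_rng(seed)
    v = cfg.speed * 1000.0            # mm/s
    dt = 1.0 / cfg.frame_rate
    L_cn = cfg.camera_nozzle_distance_m * 1000.0
    slip = cfg.slip_factor

    commands: list[tuple[float, float]] = []   # encoder-frame windows
    dropped: list[bool] = []                   # command below valve response time
    identified: list[bool] = []
    for plant in scenario.plants:
        missed_id = rng.random() < cfg.miss_prob
        partial = rng.random() < cfg.partial_prob
        lose_front = rng.random() < 0.5
        identified.append(not missed_id)
        if missed_id:
            dropped.append(True)
            commands.append((0.0, 0.0))
            continue
        meas_front, meas_rear = plant.front, plant.rear
        if partial:
            lost = cfg.partial_frac * plant.length_mm
            if lose_front:
                meas_front += lost
            else:
                meas_rear -= lost
        # first frame whose threshold line has passed the (measured) front edge
        k = math.floor(meas_front / (v * dt)) + 1
        t_id = k * dt
        t_rx = t_id + cfg.t1 + cfg.t2
        d0 = slip * v * t_rx                       # latched encoder reading
        img_offset = v * t_id - meas_front         # how far past the line, mm
        # controller works in encoder units and assumes no slip
        e_front = (d0 - v * (cfg.t1 + cfg.t2)) + (L_cn - img_offset)
        e_open = e_front - cfg.advance_mm - v * (cfg.t3 + cfg.t4)
        e_close = e_front + (meas_rear - meas_front) + cfg.lag_mm - v * (cfg.t3 + cfg.t4)
        open_time = (e_close - e_open) / (slip * v)
        if open_time < cfg.t3:
            dropped.append(True)
            commands.append((0.0, 0.0))
        else:
            dropped.append(False)
            commands.append((e_open, e_close))

    live = [w for w, skip in zip(commands, dropped) if not skip]
    merged = merge_windows(live)

    deposits: list[tuple[float, float]] = []
    for lo, hi in merged:
        jitter = rng.normal(0.0, cfg.slip_jitter_mm) if cfg.slip_jitter_mm > 0 else 0.0
        # ground position of the nozzle when the encoder reading crosses the
        # window edge, plus the valve/droplet travel; encoder frame leads the
        # ground frame by L_cn
        start = (lo - jitter) / slip - L_cn + v * (cfg.t3 + cfg.t4)
        end = (hi - jitter) / slip - L_cn + v * (cfg.t3 + cfg.t4)
        deposits.append((start, end))

    events = []
    for i, plant in enumerate(scenario.plants):
        best, overlap = None, 0.0
        for dep in deposits:
            ov = min(dep[1], plant.rear) - max(dep[0], plant.front)
            if ov > overlap:
                best, overlap = dep, ov
        events.append(score_event(best, (plant.front, plant.rear),
                                  invalid_threshold_mm=cfg.invalid_threshold_mm,
                                  target_id=i, species=plant.species))
    return events, deposits


def simulate_pass(scenario: FieldScenario, cfg: SprayerConfig, seed: int = 0,
                  with_deposits: bool = False):
    """Simulate one sprayer pass over a row; reproducible given the seed.

    Returns the per-target event list, or (events, deposit intervals) when
    ``with_deposits`` is set.
    """
    events, deposits = _simulate(scenario, cfg, seed)
    return (events, deposits) if with_deposits else events


def saving_rate(L_sp: float, spray_length: float) -> float:
    """Theoretical pesticide saving epsilon = (L_sp - s) / L_sp * 100, percent."""
    if L_sp <= 0:
        raise ValueError("plant spacing must be positive")
    if spray_length < 0:
        raise ValueError("spray length must be non-negative")
    if spray_length > L_sp:
        import warnings
        warnings.warn("spray length exceeds plant spacing; saving clamped to 0")
        return 0.0
    return (L_sp - spray_length) / L_sp * 100.0


@dataclass
class SprayStats:
    n_targets: int
    n_effective: int
    n_invalid: int
    n_missed: int
    effective_rate: float      # percent, 1 dp
    invalid_rate: float
    missed_rate: float
    mean_spray_length: float | None = None    # over effective events, mm
    mean_abs_d_open: float | None = None
    std_abs_d_open: float | None = None
    mean_abs_d_close: float | None = None
    std_abs_d_close: float | None = None
    mean_d_open: float | None = None          # signed means, for reference
    mean_d_close: float | None = None
    mean_centroid_offset: float | None = None
    mean_saving_rate: float | None = None     # percent
    spacing_mm: float | None = None


def aggregate(events: list[SprayEvent], spacing_mm: float | None = None) -> SprayStats:
    """Outcome counts/rates plus effective-event statistics.

    Rates are count/total * 100 rounded half-up to 1 decimal. Distance
    statistics (means and SDs of |D_open|, |D_close|, spray length, centroid
    offset) are over effective events only; the mean saving rate needs the
    plant spacing.
    """
    if not events:
        raise ValueError("no events to aggregate")
    n = len(events)
    eff = [e for e in events if e.outcome == "effective"]
    inv = [e for e in events if e.outcome == "invalid"]
    mis = [e for e in events if e.outcome == "missed"]
    stats = SprayStats(
        n_targets=n, n_effective=len(eff), n_invalid=len(inv), n_missed=len(mis),
        effective_rate=round_half_up(len(eff) / n * 100, 1),
        invalid_rate=round_half_up(len(inv) / n * 100, 1),
        missed_rate=round_half_up(len(mis) / n * 100, 1),
        spacing_mm=spacing_mm,
    )
    if eff:
        d_open = np.array([e.d_open for e in eff])
        d_close = np.array([e.d_close for e in eff])
        lengths = np.array([e.spray_length for e in eff])
        stats = replace(
            stats,
            mean_spray_length=float(lengths.mean()),
            mean_abs_d_open=float(np.abs(d_open).mean()),
            std_abs_d_open=float(np.abs(d_open).std(ddof=1)) if len(eff) > 1 else 0.0,
            mean_abs_d_close=float(np.abs(d_close).mean()),
            std_abs_d_close=float(np.abs(d_close).std(ddof=1)) if len(eff) > 1 else 0.0,
            mean_d_open=float(d_open.mean()),
            mean_d_close=float(d_close.mean()),
            mean_centroid_offset=float(np.mean([e.centroid_offset for e in eff])),
        )
        if spacing_mm is not None:
            stats = replace(stats, mean_saving_rate=float(
                np.mean([saving_rate(spacing_mm, min(e.spray_length, spacing_mm))
                         for e in eff])))
    return stats


def pass_dosage(deposits: list[tuple[float, float]], cfg: SprayerConfig) -> float:
    """Litres dispensed over a targeted pass: total open time x flow rate."""
    total_mm = sum(hi - lo for lo, hi in deposits)
    return total_mm / (cfg.speed * 1000.0) * cfg.flow_rate_l_s


def continuous_dosage(scenario: FieldScenario, cfg: SprayerConfig) -> float:
    """Litres dispensed spraying the whole ridge without interruption."""
    return scenario.ridge_length_m / cfg.speed * cfg.flow_rate_l_s


def dosage_compare(target_dosage: float, continuous_dosage: float
                   ) -> tuple[float, float]:
    """Saved litres and saving percentage of targeted vs. continuous spraying."""
    if target_dosage < 0 or continuous_dosage <= 0:
        raise ValueError("dosages must be positive")
    saved = continuous_dosage - target_dosage
    return saved, saved / continuous_dosage * 100.0
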