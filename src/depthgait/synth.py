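"""Synthetic locomotor-trial generator with known ground truth.

Emulates the data streams of a water-depth-gradient locomotion experiment on an
elongate amphibious fish: a traveling-wave body midline digitized at 500 frames
per second, 3-D landmark trajectories (nose, tail tip, back of skull, left and
right pectoral-fin lobe tips), pectoral-fin angle cycles with controllable
left-right phasing, and multi-channel EMG sampled at 10 kHz arranged as an
anterior-to-posterior activation wave with left/right alternation.

The body is modelled as an inextensible midline of length BL carrying a lateral
traveling wave

    y(s, t) = BL * A(s) * sin(2*pi*(f*t - s/lambda)),   s in [0, 1],

where ``s`` is arc length in body lengths (nose = 0, tail = 1), ``A(s)`` the
amplitude envelope in BL, ``f`` the wave frequency and ``lambda`` the body
wavelength in BL.  The longitudinal coordinate is obtained by integrating
``dx = sqrt(ds^2 - dy^2)`` so that arc length is conserved exactly: the
nose-tail chord can never exceed BL and the 100 output points are equally
spaced in arc length by construction.  The whole body translates forward at a
constant speed (BL/s).

EMG channels are zero-mean Gaussian noise whose standard deviation is modulated
by a raised-cosine (Hann) envelope inside each burst and a constant baseline
outside, which makes the top-5% "theoretical maximum" normalization
analytically approximable.

Every generative parameter, burst interval and stroke-event time is recorded in
:class:`GroundTruth`, so downstream estimators can be validated exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from .emg import EMGChannel
from .midline import LandmarkTrajectory, MidlineSequence

__all__ = [
    "TrialSpec",
    "GroundTruth",
    "Trial",
    "TrialSet",
    "DepthMapping",
    "make_envelope",
    "generate_trial",
    "generate_depth_sweep",
    "write_trial",
    "write_trial_set",
]

#: default electrode layout: five sites spaced along the left axial red muscle
#: (percent BL, side), plus contralateral electrodes at positions 2 and 4.
DEFAULT_EMG_SITES: tuple[tuple[float, str], ...] = (
    (19.8, "left"),
    (33.1, "left"),
    (42.8, "left"),
    (57.4, "left"),
    (67.4, "left"),
    (33.1, "right"),
    (57.4, "right"),
)

_S_GRID = np.linspace(0.0, 1.0, 1001)  # fine arc-length grid, body lengths


def make_envelope(head: float = 0.01, tail: float = 0.08, power: float = 2.0,
                  scale: float = 1.0) -> Callable[[np.ndarray], np.ndarray]:
    """Amplitude envelope A(s) in BL, growing from head to tail.

    ``A(s) = scale * (head + (tail - head) * s**power)`` — the standard
    head-to-tail amplitude growth of an undulatory swimmer.
    """
    def env(s):
        return scale * (head + (tail - head) * np.asarray(s, float) ** power)
    return env


@dataclass
class TrialSpec:
    """Generative parameters for one locomotor trial.

    Defaults describe a steady trial: 100 mm fish at 1 BL/s, a 2 Hz body wave
    of one body-length wavelength, 1.5 Hz in-phase pectoral fins with a 60 deg
    range of motion, and a 40%-duty EMG wave advancing 30 deg of the tailbeat
    cycle per electrode site.
    """

    body_length: float = 100.0            # mm
    body_depth_treatment: float = 3.0     # water depth, body depths (BD)
    frame_rate: float = 500.0             # frames / s
    emg_rate: float = 10000.0             # samples / s
    duration: float = 3.0                 # s
    speed_bl_s: float = 1.0               # forward speed, BL / s
    wave_frequency: float = 2.0           # body-wave cycles / s
    wavelength_bl: float = 1.0            # body wavelength, BL
    wave_amplitude_envelope: Callable[[np.ndarray], np.ndarray] | None = None
    fin_frequency: float = 1.5            # pectoral-fin cycles / s
    fin_mean_angle_deg: float = 90.0      # nose-skull-fin angle midpoint
    fin_amplitude_deg: float = 30.0       # half range of motion
    fin_phase_offset: float = 0.0         # left fin phase, deg (0 in, 180 out)
    fin_phase_kappa: float = math.inf     # von Mises jitter concentration
    fin_phase_mixed: bool = False         # alternate 0/180 deg per cycle
    nose_elevation_bl: float = 0.1        # per-cycle nose lift, BL
    emg_sites: tuple[tuple[float, str], ...] = DEFAULT_EMG_SITES
    burst_duty: float = 0.4               # fraction of tailbeat cycle
    burst_gain: float | dict[tuple[float, str], float] = 1.0
    burst_onset_phase_deg: float = 0.0    # most-anterior onset phase
    onset_lag_per_site_deg: float = 30.0  # anterior-to-posterior lag
    emg_baseline_sd: float = 0.05         # baseline noise SD, signal units
    noise_sd: float = 0.0                 # landmark/midline jitter, BL
    fish_id: str = "synthfish"
    seed: int = 0

    def envelope(self) -> Callable[[np.ndarray], np.ndarray]:
        return self.wave_amplitude_envelope or make_envelope()

    def site_gain(self, site: tuple[float, str]) -> float:
        if isinstance(self.burst_gain, dict):
            return float(self.burst_gain[site])
        return float(self.burst_gain)

    def validate(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if not self.emg_rate > 0:
            raise ValueError("emg_rate must be > 0")
        if not 0 < self.burst_duty < 1:
            raise ValueError("burst_duty must lie in (0, 1)")
        if not self.body_length > 0:
            raise ValueError("body_length must be > 0")
        if self.wave_frequency < 0:
            raise ValueError("wave_frequency must be >= 0")
        if not self.wavelength_bl > 0:
            raise ValueError("wavelength_bl must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        env = np.asarray(self.envelope()(_S_GRID), float)
        if np.any(env < 0):
            raise ValueError("wave_amplitude_envelope must be non-negative")
        # the wave must stay geometrically realizable: |dy/ds| < 1
        slope = np.max(np.abs(np.gradient(env, _S_GRID))) + \
            np.max(env) * 2 * np.pi / self.wavelength_bl
        if slope >= 0.95:
            raise ValueError(
                "wave_amplitude_envelope too steep for an inextensible body")
        for pos, side in self.emg_sites:
            if not 0 <= pos <= 100:
                raise ValueError("emg_sites positions must lie in [0, 100] %BL")
            if side not in ("left", "right"):
                raise ValueError("emg_sites side must be 'left' or 'right'")


@dataclass
class GroundTruth:
    """Book-keeping record of every generative parameter and event time."""

    spec: dict
    depth_bd: float
    speed_bl_s: float
    wave_frequency: float
    fin_frequency: float
    fin_rom_deg: float
    fin_phase_offset_deg: float
    nose_elevation_bl: float
    nose_elevation_phase_deg: float
    lateral_amplitude_bl: dict[int, float]           # %BL site -> A(s) in BL
    swing_distance_bl: dict[int, float]              # %BL site -> BL
    tail_swing_right_starts: list[float]
    tail_swing_left_starts: list[float]
    fin_adduction_starts: dict[str, list[float]]     # side -> times (s)
    fin_abduction_starts: dict[str, list[float]]
    left_fin_phase_deg: list[float]                  # per-cycle ground truth
    emg_bursts: dict[str, list[tuple[float, float]]]  # channel -> (on, off)
    emg_onset_phase_deg: dict[str, float]            # channel -> deg of cycle
    mapping: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return str(o)
        return json.dumps(dataclasses.asdict(self), default=default, indent=1)


@dataclass
class Trial:
    spec: TrialSpec
    landmarks: LandmarkTrajectory
    midlines: MidlineSequence
    emg: list[EMGChannel]
    ground_truth: GroundTruth

    @property
    def depth_bd(self) -> float:
        return self.spec.body_depth_treatment


@dataclass
class TrialSet:
    trials: list[Trial]
    mapping: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.trials)

    def __len__(self):
        return len(self.trials)


# ---------------------------------------------------------------------------
# midline geometry
# ---------------------------------------------------------------------------

def _body_shape(spec: TrialSpec, times: np.ndarray,
                s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free body coordinates in BL units.

    Returns (x, y), each shaped (len(times), len(s)), for arc positions ``s``
    (subset of the fine grid).  The inextensibility integral is evaluated on
    the fine grid and interpolated to ``s``.
    """
    f, lam = spec.wave_frequency, spec.wavelength_bl
    env = np.asarray(spec.envelope()(_S_GRID), float)
    phase = 2 * np.pi * (f * times[:, None] - _S_GRID[None, :] / lam)
    y = env[None, :] * np.sin(phase)
    dyds = np.gradient(y, _S_GRID, axis=1)
    dxds = np.sqrt(np.clip(1.0 - dyds ** 2, 1e-12, None))
    # x decreases tailward; nose advances at the forward speed
    x_rel = -_cumtrapz(dxds, _S_GRID)
    x = spec.speed_bl_s * times[:, None] + x_rel
    xi = _interp_cols(s, _S_GRID, x)
    yi = _interp_cols(s, _S_GRID, y)
    return xi, yi


def _cumtrapz(v: np.ndarray, x: np.ndarray) -> np.ndarray:
    dx = np.diff(x)
    out = np.zeros_like(v)
    out[..., 1:] = np.cumsum(0.5 * (v[..., 1:] + v[..., :-1]) * dx, axis=-1)
    return out


def _interp_cols(s: np.ndarray, grid: np.ndarray, vals: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(grid, s) - 1, 0, len(grid) - 2)
    w = (s - grid[idx]) / (grid[idx + 1] - grid[idx])
    return vals[:, idx] * (1 - w) + vals[:, idx + 1] * w


def _nose_z(spec: TrialSpec, times: np.ndarray) -> np.ndarray:
    """Nose height in BL: one lift per fin cycle peaking at mid-cycle."""
    return spec.nose_elevation_bl * 0.5 * (
        1.0 - np.cos(2 * np.pi * spec.fin_frequency * times))


# ---------------------------------------------------------------------------
# pectoral fins
# ---------------------------------------------------------------------------

def _left_fin_phases(spec: TrialSpec, n_cycles: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-cycle phase of left adduction within the right-fin cycle, deg."""
    if spec.fin_phase_mixed:
        base = np.where(np.arange(n_cycles) % 2 == 0, 0.0, 180.0)
    else:
        base = np.full(n_cycles, spec.fin_phase_offset, float)
    if math.isinf(spec.fin_phase_kappa):
        jitter = np.zeros(n_cycles)
    else:
        jitter = np.degrees(
            rng.vonmises(0.0, spec.fin_phase_kappa, size=n_cycles))
    return base + jitter


def _fin_angles(spec: TrialSpec, times: np.ndarray,
                rng: np.random.Generator):
    """Fin angle series plus ground-truth stroke events for both sides."""
    f = spec.fin_frequency
    T = 1.0 / f
    n_cycles = int(math.floor(spec.duration * f)) + 3
    ks = np.arange(-1, n_cycles - 1)

    theta_r = spec.fin_mean_angle_deg + spec.fin_amplitude_deg * np.cos(
        2 * np.pi * f * times)
    right_add = ks * T
    right_abd = (ks + 0.5) * T

    phases = _left_fin_phases(spec, len(ks), rng)
    left_add = (ks + phases / 360.0) * T
    if np.any(np.diff(left_add) <= 0):
        raise ValueError(
            "fin_phase_kappa too small: left-fin cycle order not preserved")
    # monotone cycle-phase function psi with psi(left_add[k]) = k
    psi = np.interp(times, left_add, ks.astype(float))
    # linear extrapolation beyond the tabulated adduction times
    lo, hi = times < left_add[0], times > left_add[-1]
    psi[lo] = ks[0] + (times[lo] - left_add[0]) / T
    psi[hi] = ks[-1] + (times[hi] - left_add[-1]) / T
    theta_l = spec.fin_mean_angle_deg + spec.fin_amplitude_deg * np.cos(
        2 * np.pi * psi)
    left_abd = left_add + 0.5 * T

    in_trial = lambda ts: [float(t) for t in ts if 0 <= t <= spec.duration]
    events = {
        "adduction": {"left": in_trial(left_add), "right": in_trial(right_add)},
        "abduction": {"left": in_trial(left_abd), "right": in_trial(right_abd)},
    }
    keep = (right_add >= 0) & (right_add <= spec.duration - T)
    truth_phases = np.mod(phases[keep], 360.0)
    return theta_l, theta_r, events, list(map(float, truth_phases))


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def _tail_cycle_starts(spec: TrialSpec, margin: float = 0.0) -> np.ndarray:
    """Times at which the tail starts swinging right (maximum-left tail)."""
    f, lam = spec.wave_frequency, spec.wavelength_bl
    t0 = (0.25 + 1.0 / lam) / f
    k = np.arange(-math.ceil((t0 + margin) * f) - 1,
                  math.ceil(spec.duration * f) + 2)
    return t0 + k / f


def _emg_channels(spec: TrialSpec, rng: np.random.Generator):
    """Gaussian-noise channels with Hann-envelope bursts on a tail-cycle grid."""
    n = int(round(spec.duration * spec.emg_rate))
    t = np.arange(n) / spec.emg_rate
    Tw = 1.0 / spec.wave_frequency
    starts = _tail_cycle_starts(spec, margin=Tw)

    positions = sorted({pos for pos, _ in spec.emg_sites})
    rank = {pos: i for i, pos in enumerate(positions)}

    channels, bursts_out, phase_out = [], {}, {}
    for pos, side in spec.emg_sites:
        phase = spec.burst_onset_phase_deg + \
            spec.onset_lag_per_site_deg * rank[pos]
        if side == "right":
            phase += 180.0
        onsets = starts + (phase / 360.0) * Tw
        offsets = onsets + spec.burst_duty * Tw
        keep = (offsets > 0) & (onsets < spec.duration)
        onsets, offsets = onsets[keep], offsets[keep]

        gain = spec.site_gain((pos, side))
        sd = np.full(n, spec.emg_baseline_sd)
        for on, off in zip(onsets, offsets):
            i0, i1 = np.searchsorted(t, [on, off])
            if i1 > i0:
                u = (t[i0:i1] - on) / (off - on)
                sd[i0:i1] += gain * 0.5 * (1 - np.cos(2 * np.pi * u))
        samples = rng.normal(0.0, 1.0, n) * sd

        name = f"{side}_{pos:g}"
        channels.append(EMGChannel(samples=samples, rate=spec.emg_rate,
                                   muscle="axial_red", side=side,
                                   position_percent_bl=pos,
                                   fish_id=spec.fish_id, name=name))
        bursts_out[name] = [(float(a), float(b))
                            for a, b in zip(onsets, offsets)]
        phase_out[name] = float(np.mod(phase, 360.0))
    return channels, bursts_out, phase_out


# ---------------------------------------------------------------------------
# ground-truth swing distance
# ---------------------------------------------------------------------------

def _true_swing_distance(spec: TrialSpec, site_percent: float) -> float:
    """Mean path length (BL) between successive lateral extrema at a site."""
    f, lam = spec.wave_frequency, spec.wavelength_bl
    s = site_percent / 100.0
    # lateral extrema of sin(2*pi*(f t - s/lam)) at quarter-cycle offsets
    t_ext = (np.arange(0.25, spec.duration * f - 0.25, 0.5) + s / lam) / f
    t_ext = t_ext[(t_ext >= 0) & (t_ext <= spec.duration)]
    if len(t_ext) < 2:
        return float("nan")
    lengths = []
    for a, b in zip(t_ext[:-1], t_ext[1:]):
        tt = np.linspace(a, b, 400)
        x, y = _body_shape(spec, tt, np.array([s]))
        lengths.append(np.sum(np.hypot(np.diff(x[:, 0]), np.diff(y[:, 0]))))
    return float(np.mean(lengths))


# ---------------------------------------------------------------------------
# trial assembly
# ---------------------------------------------------------------------------

def generate_trial(spec: TrialSpec) -> Trial:
    """Generate one synthetic trial; bit-reproducible for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    BL = spec.body_length
    nf = int(round(spec.duration * spec.frame_rate))
    times = np.arange(nf) / spec.frame_rate

    s100 = np.linspace(0.0, 1.0, 100)
    x, y = _body_shape(spec, times, s100)       # BL units
    mid = np.stack([x, y], axis=-1) * BL        # (T, 100, 2) calibrated

    s_skull = 0.12
    xs, ys = _body_shape(spec, times, np.array([0.0, s_skull, 1.0]))
    nose = np.column_stack([xs[:, 0] * BL, ys[:, 0] * BL,
                            _nose_z(spec, times) * BL])
    skull = np.column_stack([xs[:, 1] * BL, ys[:, 1] * BL, np.zeros(nf)])
    tail = np.column_stack([xs[:, 2] * BL, ys[:, 2] * BL, np.zeros(nf)])

    theta_l, theta_r, fin_events, left_phases = _fin_angles(spec, times, rng)
    d = nose[:, :2] - skull[:, :2]
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    fin_len = 0.15 * BL

    def fin_tip(theta_deg, sign):
        a = np.radians(theta_deg) * sign
        rot = np.stack([np.cos(a) * d[:, 0] - np.sin(a) * d[:, 1],
                        np.sin(a) * d[:, 0] + np.cos(a) * d[:, 1]], axis=1)
        return np.column_stack([skull[:, :2] + fin_len * rot, np.zeros(nf)])

    points = {
        "nose": nose, "tail": tail, "skull": skull,
        "fin_left": fin_tip(theta_l, +1.0),   # +y side is the fish's left
        "fin_right": fin_tip(theta_r, -1.0),
    }

    if spec.noise_sd > 0:
        jit = spec.noise_sd * BL
        mid = mid + rng.normal(0.0, jit, mid.shape)
        for k in points:
            points[k] = points[k] + rng.normal(0.0, jit, points[k].shape)

    landmarks = LandmarkTrajectory(time_s=times, points=points,
                                   frame_rate=spec.frame_rate, body_length=BL)
    midlines = MidlineSequence(points=mid, body_length=BL,
                               frame_rate=spec.frame_rate)

    channels, bursts, onset_phases = _emg_channels(spec, rng)

    env = spec.envelope()
    f, lam = spec.wave_frequency, spec.wavelength_bl
    tail_r = [(k + 0.25 + 1 / lam) / f
              for k in range(-2, int(spec.duration * f) + 1)]
    tail_l = [t + 0.5 / f for t in tail_r]
    inside = lambda ts: [t for t in ts if 0 <= t <= spec.duration]

    sites = (40, 60, 80)
    truth = GroundTruth(
        spec=_spec_dict(spec),
        depth_bd=spec.body_depth_treatment,
        speed_bl_s=spec.speed_bl_s,
        wave_frequency=spec.wave_frequency,
        fin_frequency=spec.fin_frequency,
        fin_rom_deg=2 * spec.fin_amplitude_deg,
        fin_phase_offset_deg=spec.fin_phase_offset,
        nose_elevation_bl=spec.nose_elevation_bl,
        nose_elevation_phase_deg=180.0,
        lateral_amplitude_bl={p: float(env(p / 100.0)) for p in sites},
        swing_distance_bl={p: _true_swing_distance(spec, p) for p in sites},
        tail_swing_right_starts=inside(tail_r),
        tail_swing_left_starts=inside(tail_l),
        fin_adduction_starts=fin_events["adduction"],
        fin_abduction_starts=fin_events["abduction"],
        left_fin_phase_deg=left_phases,
        emg_bursts=bursts,
        emg_onset_phase_deg=onset_phases,
    )
    return Trial(spec=spec, landmarks=landmarks, midlines=midlines,
                 emg=channels, ground_truth=truth)


def _spec_dict(spec: TrialSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["wave_amplitude_envelope"] = None if spec.wave_amplitude_envelope is None \
        else "custom"
    if isinstance(d.get("burst_gain"), dict):
        d["burst_gain"] = {f"{k[1]}_{k[0]:g}": v
                           for k, v in d["burst_gain"].items()}
    return d


# ---------------------------------------------------------------------------
# depth sweep
# ---------------------------------------------------------------------------

@dataclass
class DepthMapping:
    """Documented depth-to-parameter mapping for the synthetic study design.

    All mappings are monotone in water depth and are configuration, not
    hard-coded science: as the water drops below ``reference_depth`` BD the
    body-wave amplitude envelope scales up, anterior axial-muscle burst gain
    rises, and below ``fin_switch_depth`` the pectoral fins switch from
    in-phase (0 deg) to out-of-phase (180 deg).
    """

    fin_switch_depth: float = 0.8     # BD below which fins go out-of-phase
    reference_depth: float = 1.0      # BD at which scaling begins
    amplitude_slope: float = 0.6      # envelope scale per BD below reference
    anterior_gain_slope: float = 1.5  # burst-gain increase per BD below ref
    anterior_cutoff_percent: float = 40.0  # sites counted as anterior

    def amplitude_scale(self, depth: float) -> float:
        return 1.0 + self.amplitude_slope * max(0.0, self.reference_depth - depth)

    def gain(self, depth: float, position_percent: float, base: float) -> float:
        if position_percent < self.anterior_cutoff_percent:
            return base * (1.0 + self.anterior_gain_slope *
                           max(0.0, self.reference_depth - depth))
        return base

    def fin_phase_offset(self, depth: float) -> float:
        return 0.0 if depth >= self.fin_switch_depth else 180.0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def generate_depth_sweep(base: TrialSpec, depths: Sequence[float],
                         trials_per_depth: int = 1,
                         mapping: DepthMapping | None = None) -> TrialSet:
    """Generate trials across water-depth treatments under a documented mapping."""
    if len(depths) == 0:
        raise ValueError("depths must be non-empty")
    if len(set(depths)) != len(depths):
        raise ValueError("duplicate depths")
    if trials_per_depth < 1:
        raise ValueError("trials_per_depth must be >= 1")
    mapping = mapping or DepthMapping()

    base_env = base.wave_amplitude_envelope or make_envelope()
    trials = []
    for di, depth in enumerate(depths):
        scale = mapping.amplitude_scale(depth)
        env = (lambda sc: (lambda s: sc * np.asarray(base_env(s), float)))(scale)
        gains = {site: mapping.gain(depth, site[0], base.site_gain(site))
                 for site in base.emg_sites}
        for ti in range(trials_per_depth):
            spec = dataclasses.replace(
                base,
                body_depth_treatment=depth,
                wave_amplitude_envelope=env,
                fin_phase_offset=mapping.fin_phase_offset(depth),
                burst_gain=gains,
                seed=base.seed + 1009 * di + ti,
            )
            trial = generate_trial(spec)
            trial.ground_truth.mapping = mapping.as_dict()
            trials.append(trial)
    return TrialSet(trials=trials, mapping=mapping.as_dict())


# ---------------------------------------------------------------------------
# writers (plain-text external formats)
# ---------------------------------------------------------------------------

def write_trial(trial: Trial, outdir: str | Path) -> Path:
    """Write one trial as landmark/midline/EMG CSVs plus ground-truth JSON."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    lm = trial.landmarks
    rows = []
    for name, arr in lm.points.items():
        for i, t in enumerate(lm.time_s):
            rows.append((i, t, name, arr[i, 0], arr[i, 1], arr[i, 2]))
    pd.DataFrame(rows, columns=["frame", "time_s", "landmark", "x", "y", "z"]) \
        .to_csv(outdir / "landmarks.csv", index=False)

    T, n, _ = trial.midlines.points.shape
    frames = np.repeat(np.arange(T), n)
    idx = np.tile(np.arange(n), T)
    flat = trial.midlines.points.reshape(-1, 2)
    pd.DataFrame({"frame": frames, "point_index": idx,
                  "x": flat[:, 0], "y": flat[:, 1]}) \
        .to_csv(outdir / "midline.csv", index=False)

    for ch in trial.emg:
        stem = outdir / f"emg_{ch.name}"
        pd.DataFrame({"sample": np.arange(len(ch.samples)),
                      "value": ch.samples}).to_csv(f"{stem}.csv", index=False)
        meta = {"side": ch.side, "percent_BL": ch.position_percent_bl,
                "rate": ch.rate, "muscle": ch.muscle, "fish_id": ch.fish_id}
        Path(f"{stem}.yaml").write_text(yaml.safe_dump(meta))

    (outdir / "ground_truth.json").write_text(trial.ground_truth.to_json())
    return outdir


def write_trial_set(ts: TrialSet, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    for i, trial in enumerate(ts.trials):
        write_trial(trial, outdir / f"depth_{trial.depth_bd:g}_trial_{i:03d}")
    (outdir / "mapping.json").write_text(json.dumps(ts.mapping, indent=1))
    return outdir
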