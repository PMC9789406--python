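"""Trial-level body kinematics: speed, curvature, swing distance, wave timing.

All magnitudes are standardized to body length (BL) so individuals can be
compared.  The variables follow the standard conventions for undulatory
locomotion across a water-depth gradient:

* **locomotion speed** — net straight-line nose displacement in the x-y plane
  over the trial, in BL/s;
* **curvature coefficient** — ``1 - min_t d(t)`` where ``d(t)`` is the
  straight-line nose-tail distance standardized to BL, minimized over a
  locomotor cycle: 0 is a perfectly straight fish, 1 is nose touching tail;
* **swing distance** — path length a body point travels in the x-y plane
  between maximum-left and maximum-right lateral amplitude, in BL;
* **wave frequency** — mean of 1/period between successive same-sign lateral
  amplitude peaks, cycles/s;
* **nose elevation** — per-cycle maximum nose height above the trial baseline,
  in BL, with the timing of each maximum expressed in degrees of the
  corresponding pectoral-fin cycle;
* **maximum-amplitude phase** — timing of maximum left/right lateral amplitude
  at 40/60/80% BL, in degrees of the tail stroke.

Digitized trajectories carry frame-to-frame jitter, so position series are
low-pass filtered (zero-phase Butterworth) before extremum and path-length
operations; path length in particular is unboundedly inflated by unfiltered
noise.  Cutoffs default to several times the highest locomotor frequency and
are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .fin import (DEFAULT_CUTOFF_HZ, StrokeSegmentation, StrokeError, lowpass,
                  phase_in_cycle, smooth_series)
from .midline import LandmarkTrajectory, MidlineSequence

__all__ = [
    "KinematicSummary",
    "curvature_coefficient",
    "locomotion_speed",
    "swing_distance",
    "wave_frequency",
    "nose_elevation",
    "max_amplitude_phase",
    "lowpass",
    "alternating_extrema",
]

@dataclass
class KinematicSummary:
    """Per-trial kinematic variables (trial means; the unit of analysis)."""

    speed_bl_s: float
    curvature_coefficient: float
    swing_distance_bl: dict[float, float]        # %BL site -> BL
    wave_frequency_hz: float
    fin_frequency_hz: float | None
    fin_rom_deg: float | None
    nose_elevation_bl: float | None

    def __post_init__(self):
        if not 0.0 <= self.curvature_coefficient <= 1.0:
            raise ValueError("curvature_coefficient must lie in [0, 1]")
        if self.wave_frequency_hz < 0:
            raise ValueError("wave_frequency must be >= 0")


# ---------------------------------------------------------------------------
# filtering and extrema helpers
# ---------------------------------------------------------------------------

def alternating_extrema(y: np.ndarray, smooth_window: int = 5,
                        prominence_fraction: float = 0.1,
                        min_excursion_fraction: float = 0.5
                        ) -> list[tuple[int, int]]:
    """Alternating (sign, frame index) extrema of a lightly smoothed signal.

    sign +1 marks a local maximum, -1 a local minimum.  Runs of same-sign
    extrema keep only the most extreme member, so the output alternates.
    Extremum pairs whose excursion falls below ``min_excursion_fraction`` of
    the median excursion are pruned: they are jitter or filter-edge artifacts,
    not genuine half-strokes.
    """
    ys = smooth_series(y, smooth_window)
    rng = float(np.ptp(ys))
    if rng <= 1e-9 * max(1.0, float(np.max(np.abs(ys)))):
        raise StrokeError("no detectable amplitude extrema (constant signal)")
    prom = prominence_fraction * rng
    hi, _ = sps.find_peaks(ys, prominence=prom)
    lo, _ = sps.find_peaks(-ys, prominence=prom)
    ext = sorted([(+1, int(i)) for i in hi] + [(-1, int(i)) for i in lo],
                 key=lambda e: e[1])
    if not ext:
        raise StrokeError("no detectable amplitude extrema")

    def dedupe(seq):
        out = [seq[0]]
        for sign, i in seq[1:]:
            if sign == out[-1][0]:
                keep = i if sign * ys[i] > sign * ys[out[-1][1]] else out[-1][1]
                out[-1] = (sign, keep)
            else:
                out.append((sign, i))
        return out

    out = dedupe(ext)
    while len(out) >= 3:
        exc = np.array([abs(ys[b] - ys[a])
                        for (_, a), (_, b) in zip(out, out[1:])])
        k = int(np.argmin(exc))
        if exc[k] >= min_excursion_fraction * np.median(exc):
            break
        out = dedupe(out[:k] + out[k + 2:])
    return out


# ---------------------------------------------------------------------------
# trial variables
# ---------------------------------------------------------------------------

def curvature_coefficient(midlines: MidlineSequence,
                          cycle: tuple[float, float] | None = None) -> float:
    """1 minus the minimum nose-tail distance over the cycle, in BL.

    ``cycle`` is a (start_s, end_s) window; the whole trial is used when
    omitted.  A nose-tail distance exceeding BL by more than 2% in any frame
    indicates inconsistent calibration and raises an error.
    """
    t = midlines.times
    if cycle is None:
        sel = np.ones(len(t), bool)
    else:
        sel = (t >= cycle[0]) & (t <= cycle[1])
    if sel.sum() < 2:
        raise ValueError("cycle must span at least 2 frames")
    pts = midlines.points[sel]
    d = np.hypot(*(pts[:, 0, :] - pts[:, -1, :]).T) / midlines.body_length
    if np.any(d > 1.02):
        raise ValueError(
            "nose-tail distance exceeds body length by more than 2%: "
            "inconsistent calibration")
    return float(1.0 - np.clip(d.min(), 0.0, 1.0))


def locomotion_speed(landmarks: LandmarkTrajectory,
                     body_length: float | None = None) -> float:
    """Net straight-line nose displacement in the x-y plane, BL/s."""
    landmarks.require("nose")
    bl = body_length or landmarks.body_length
    duration = landmarks.time_s[-1] - landmarks.time_s[0]
    if duration <= 0:
        raise ValueError("trial duration must be > 0")
    nose = landmarks.points["nose"][:, :2]
    return float(np.hypot(*(nose[-1] - nose[0])) / duration / bl)


def swing_distance(site_xy: np.ndarray, lateral: np.ndarray,
                   frame_rate: float, body_length: float,
                   cutoff: float = DEFAULT_CUTOFF_HZ) -> float:
    """Mean path length between successive lateral extrema at a site, BL.

    ``site_xy`` is the (T, 2) trajectory of the body point; ``lateral`` its
    signed body-frame displacement used to locate maximum-left/right frames.
    Both are low-pass filtered before measurement.
    """
    xy = lowpass(np.asarray(site_xy, float), frame_rate, cutoff)
    lat = lowpass(np.asarray(lateral, float), frame_rate, cutoff)
    ext = alternating_extrema(lat)
    if len(ext) < 2:
        raise StrokeError("need at least one complete left-right excursion")
    lengths = []
    for (_, i0), (_, i1) in zip(ext[:-1], ext[1:]):
        seg = xy[i0:i1 + 1]
        lengths.append(np.sum(np.hypot(*np.diff(seg, axis=0).T)))
    return float(np.mean(lengths) / body_length)


def wave_frequency(lateral: np.ndarray, frame_rate: float,
                   cutoff: float = DEFAULT_CUTOFF_HZ) -> float:
    """Mean of 1/period over successive same-sign lateral peaks, cycles/s."""
    lat = lowpass(np.asarray(lateral, float), frame_rate, cutoff)
    ext = alternating_extrema(lat)
    maxima = np.array([i for s, i in ext if s == +1], float)
    if len(maxima) < 2:
        raise StrokeError("need at least 2 same-sign peaks")
    periods = np.diff(maxima) / frame_rate
    return float(np.mean(1.0 / periods))


def nose_elevation(landmarks: LandmarkTrajectory,
                   fin_stroke: StrokeSegmentation,
                   body_length: float | None = None,
                   cutoff: float = 5.0,
                   baseline_percentile: float = 1.0
                   ) -> tuple[float, np.ndarray]:
    """Per-cycle maximum nose height above baseline, BL, and its fin phase.

    The baseline is a low percentile of the filtered nose height (a robust
    stand-in for the trial minimum, since the substrate height is not recorded
    separately).  Each cycle's maximum is timed in degrees of the enclosing
    pectoral-fin cycle (0 deg = start of adduction).  Returns the trial-mean
    magnitude and the per-cycle phase samples.
    """
    landmarks.require("nose")
    bl = body_length or landmarks.body_length
    z = landmarks.points["nose"][:, 2]
    if not np.any(np.isfinite(z)):
        raise ValueError("missing z coordinate for nose")
    zf = lowpass(z, landmarks.frame_rate, cutoff)
    baseline = np.percentile(zf, baseline_percentile)

    mags, phases = [], []
    t = landmarks.time_s
    for a, m, b in fin_stroke.cycles:
        sel = (t >= a) & (t <= b)
        if not sel.any():
            continue
        i = np.flatnonzero(sel)[np.argmax(zf[sel])]
        mags.append((zf[i] - baseline) / bl)
        phases.append(phase_in_cycle(t[i], (a, m, b)))
    if not mags:
        raise StrokeError("no fin cycles overlap the trial")
    return float(np.mean(mags)), np.asarray(phases, float)


def max_amplitude_phase(lateral: np.ndarray, frame_rate: float,
                        tail_stroke: StrokeSegmentation,
                        sites: Sequence[float] = (40.0, 60.0, 80.0),
                        cutoff: float = DEFAULT_CUTOFF_HZ
                        ) -> dict[tuple[float, str], np.ndarray]:
    """Phase of maximum left/right amplitude at body sites, deg of tail stroke.

    ``lateral`` is the (T, n_points) body-frame displacement (left positive).
    For every cycle, the frames of maximum-left (+) and maximum-right (-)
    amplitude at each site are mapped to degrees of the tail stroke
    (0 deg = start of tail swing right).  Returns
    {(site_percent, 'left'|'right'): phases}.
    """
    lateral = np.asarray(lateral, float)
    n = lateral.shape[1]
    out: dict[tuple[float, str], np.ndarray] = {}
    for site in sites:
        if not 0 <= site <= 100:
            raise ValueError(f"site {site} outside 0-100% BL")
        col = int(round(site / 100.0 * (n - 1)))
        lat = lowpass(lateral[:, col], frame_rate, cutoff)
        ext = alternating_extrema(lat)
        left, right = [], []
        for sign, i in ext:
            loc = tail_stroke.locate(i / frame_rate)
            if loc is None:
                continue
            ph = phase_in_cycle(i / frame_rate, loc[1])
            (left if sign > 0 else right).append(ph)
        out[(site, "left")] = np.asarray(left, float)
        out[(site, "right")] = np.asarray(right, float)
    return out
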