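"""Pectoral-fin and tail stroke segmentation, fin angle and phase timing.

Two stroke clocks are used throughout the pipeline:

* the **pectoral fin stroke**, defined by right-fin motion — start of adduction
  is stroke start (0 deg) and start of abduction is mid-stroke (180 deg);
* the **tail stroke** — start of tail swing to the right is stroke start
  (0 deg) and start of tail swing to the left is mid-stroke (180 deg).

Because both 0 and 180 deg are anchored to named events, phases are mapped
piecewise-linearly over the two half-cycles (a single linear map cannot honor
both anchors when half-cycles are asymmetric).

Fin angle is the interior angle at the back of the skull between rays to the
nose and to the fin-lobe tip, computed in the top-view x-y projection by
default (a 3-D option is provided).  Events may be detected automatically from
signal extrema or supplied verbatim from a manual annotation table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .midline import LandmarkTrajectory

__all__ = [
    "StrokeSegmentation",
    "StrokeError",
    "fin_angle",
    "segment_strokes",
    "fin_frequency",
    "fin_rom",
    "trial_fin_rom",
    "left_fin_phase",
    "phase_in_cycle",
    "read_stroke_annotations",
    "smooth_series",
]

logger = logging.getLogger(__name__)

#: default zero-phase low-pass corner for digitized series at 500 frames/s;
#: several times the highest locomotor frequency, far below it for noise
DEFAULT_CUTOFF_HZ = 10.0

_START_EVENT = {"fin": "adduction_start", "tail": "tail_swing_right_start"}
_MID_EVENT = {"fin": "abduction_start", "tail": "tail_swing_left_start"}


class StrokeError(ValueError):
    """Raised when a stroke cycle structure cannot be established."""


@dataclass
class StrokeSegmentation:
    """Alternating stroke events and the cycles they delimit."""

    stroke_kind: str                        # "fin" | "tail"
    events: list[tuple[str, float]]         # (event_type, time_s), ordered

    def __post_init__(self):
        if self.stroke_kind not in ("fin", "tail"):
            raise ValueError("stroke_kind must be 'fin' or 'tail'")
        times = [t for _, t in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise StrokeError("events must be strictly increasing in time")
        kinds = [k for k, _ in self.events]
        if any(a == b for a, b in zip(kinds, kinds[1:])):
            raise StrokeError(f"event types must alternate; got {kinds}")

    @property
    def cycles(self) -> list[tuple[float, float, float]]:
        """(start, mid, end) triples delimited by consecutive start events."""
        start_type = _START_EVENT[self.stroke_kind]
        out = []
        for (k0, t0), (k1, t1), (k2, t2) in zip(
                self.events, self.events[1:], self.events[2:]):
            if k0 == start_type:
                out.append((t0, t1, t2))
        return out

    def locate(self, t: float) -> tuple[int, tuple[float, float, float]] | None:
        """Cycle id and (start, mid, end) of the cycle containing time ``t``."""
        for i, (a, m, b) in enumerate(self.cycles):
            if a <= t < b:
                return i, (a, m, b)
        return None

    def shift(self, dt: float) -> "StrokeSegmentation":
        return StrokeSegmentation(
            self.stroke_kind, [(k, t + dt) for k, t in self.events])


def phase_in_cycle(t: float, cycle: tuple[float, float, float]) -> float:
    """Map a time to degrees within a (start, mid, end) cycle.

    The first half-cycle spans 0-180 deg and the second 180-360 deg
    (piecewise linear), so both named anchor events land exactly on 0 and 180.
    """
    a, m, b = cycle
    if not a < m < b:
        raise StrokeError("cycle mid must lie strictly between start and end")
    if t < a or t > b:
        raise StrokeError("time outside cycle")
    if t <= m:
        return 180.0 * (t - a) / (m - a)
    return (180.0 + 180.0 * (t - m) / (b - m)) % 360.0


# ---------------------------------------------------------------------------
# fin angle
# ---------------------------------------------------------------------------

def fin_angle(landmarks: LandmarkTrajectory, side: str,
              use_3d: bool = False) -> np.ndarray:
    """Interior nose-skull-fin angle per frame, degrees in (0, 180].

    Frames with coincident landmarks are flagged as NaN rather than
    fabricated.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    landmarks.require("nose", "skull", f"fin_{side}")
    dims = slice(None) if use_3d else slice(0, 2)
    a = landmarks.points["nose"][:, dims] - landmarks.points["skull"][:, dims]
    b = landmarks.points[f"fin_{side}"][:, dims] - \
        landmarks.points["skull"][:, dims]
    na, nb = np.linalg.norm(a, axis=1), np.linalg.norm(b, axis=1)
    ok = (na > 0) & (nb > 0)
    ang = np.full(len(na), np.nan)
    cosang = np.einsum("ij,ij->i", a[ok], b[ok]) / (na[ok] * nb[ok])
    ang[ok] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return ang


def lowpass(x: np.ndarray, fs: float, cutoff: float = DEFAULT_CUTOFF_HZ,
            order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the first axis.

    NaN frames (flagged-missing landmarks) are linearly interpolated before
    filtering.  A non-positive or super-Nyquist cutoff disables filtering.
    """
    x = np.asarray(x, float)
    if x.ndim == 1:
        bad = ~np.isfinite(x)
        if bad.any() and not bad.all():
            idx = np.arange(len(x))
            x = x.copy()
            x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    if cutoff <= 0 or cutoff >= fs / 2:
        return x
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def smooth_series(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average; NaNs are linearly interpolated first."""
    x = np.asarray(x, float).copy()
    bad = ~np.isfinite(x)
    if bad.all():
        raise ValueError("all-NaN series")
    if bad.any():
        idx = np.arange(len(x))
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    if window <= 1:
        return x
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, np.ones(window) / window, mode="same")[pad:len(x) + pad]


# ---------------------------------------------------------------------------
# stroke segmentation
# ---------------------------------------------------------------------------

def segment_strokes(sig: np.ndarray, frame_rate: float, kind: str,
                    smooth_window: int = 5,
                    prominence_fraction: float = 0.1,
                    cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> StrokeSegmentation:
    """Detect alternating stroke events from signal extrema.

    * ``kind='fin'``: the signal is a fin-angle series; adduction starts at
      each local maximum and abduction at each local minimum.
    * ``kind='tail'``: the signal is tail lateral displacement (left
      positive); swing right starts at each local maximum (zero crossing of
      lateral velocity from the left extreme) and swing left at each minimum.

    Extrema are detected on a lightly smoothed copy with a minimum prominence
    of ``prominence_fraction`` of the signal range.
    """
    if kind not in ("fin", "tail"):
        raise ValueError("kind must be 'fin' or 'tail'")
    y = smooth_series(lowpass(sig, frame_rate, cutoff_hz), smooth_window)
    rng = float(np.ptp(y))
    if rng <= 1e-9 * max(1.0, float(np.max(np.abs(y)))):
        raise StrokeError("constant signal: no stroke events")
    prom = prominence_fraction * rng
    hi, _ = sps.find_peaks(y, prominence=prom)
    lo, _ = sps.find_peaks(-y, prominence=prom)
    if len(hi) == 0 or len(lo) == 0:
        raise StrokeError("signal spans less than one stroke cycle")

    hi_name = _START_EVENT[kind]       # maxima: adduction / swing-right start
    lo_name = _MID_EVENT[kind]
    events = sorted([(hi_name, i) for i in hi] + [(lo_name, i) for i in lo],
                    key=lambda e: e[1])
    kinds = [k for k, _ in events]
    if any(a == b for a, b in zip(kinds, kinds[1:])):
        raise StrokeError(f"events do not alternate: {events}")
    return StrokeSegmentation(
        stroke_kind=kind,
        events=[(k, i / frame_rate) for k, i in events])


# ---------------------------------------------------------------------------
# fin metrics
# ---------------------------------------------------------------------------

def fin_frequency(seg: StrokeSegmentation) -> float:
    """Mean of 1/duration over complete stroke cycles, cycles/s."""
    cycles = seg.cycles
    if len(cycles) < 2:
        raise StrokeError("need at least 2 complete cycles")
    durations = np.array([b - a for a, _, b in cycles])
    return float(np.mean(1.0 / durations))


def fin_rom(angle: np.ndarray, seg: StrokeSegmentation,
            frame_rate: float, smooth_window: int = 5,
            cutoff_hz: float = 6.0) -> float:
    """Per-cycle (max - min) fin angle, averaged over cycles, degrees.

    The angle series is low-pass filtered first: a per-cycle extreme of an
    unfiltered digitized series is biased upward by frame-to-frame jitter.
    The default corner (~4x the fin-beat frequency) keeps the stroke waveform
    while suppressing that bias.
    """
    cycles = seg.cycles
    if not cycles:
        raise StrokeError("no complete cycles")
    y = smooth_series(lowpass(angle, frame_rate, cutoff_hz), smooth_window)
    roms = []
    for a, _, b in cycles:
        i0, i1 = int(round(a * frame_rate)), int(round(b * frame_rate))
        chunk = y[i0:i1 + 1]
        if chunk.size == 0:
            raise StrokeError("empty cycle")
        roms.append(np.ptp(chunk))
    return float(np.mean(roms))


def trial_fin_rom(left_rom: float, right_rom: float) -> float:
    """Trial value: mean of the left- and right-side range of motion."""
    return 0.5 * (left_rom + right_rom)


def left_fin_phase(left_seg: StrokeSegmentation,
                   right_seg: StrokeSegmentation) -> np.ndarray:
    """Phase (deg) of each left adduction start within the right-fin cycle.

    Left events falling outside every right-fin cycle are skipped with a log
    entry.
    """
    phases = []
    for kind, t in left_seg.events:
        if kind != "adduction_start":
            continue
        loc = right_seg.locate(t)
        if loc is None:
            logger.info("left adduction at %.4f s outside right-fin cycles; "
                        "skipped", t)
            continue
        phases.append(phase_in_cycle(t, loc[1]))
    return np.asarray(phases, float)


# ---------------------------------------------------------------------------
# manual annotations
# ---------------------------------------------------------------------------

def read_stroke_annotations(path: str | Path, trial: str, side: str,
                            kind: str = "fin") -> StrokeSegmentation:
    """Build a segmentation from a manual event table.

    CSV schema: trial, side, event_type, time_s.  Events are supplied
    verbatim, preserving the original manual-scoring workflow.
    """
    import pandas as pd

    df = pd.read_csv(path)
    sub = df[(df["trial"].astype(str) == str(trial)) & (df["side"] == side)] \
        .sort_values("time_s")
    events = [(str(r.event_type), float(r.time_s))
              for r in sub.itertuples(index=False)]
    if not events:
        raise StrokeError(f"no events for trial {trial!r} side {side!r}")
    return StrokeSegmentation(stroke_kind=kind, events=events)
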