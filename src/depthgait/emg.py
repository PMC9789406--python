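"""EMG conditioning and burst-level metrics.

Signals are conditioned the way locomotor EMG is routinely processed: a
zero-phase 60 Hz notch (mains interference) followed by a zero-phase 40-4000 Hz
band-pass.  Burst metrics follow the standard comparative-physiology
definitions:

* duty factor — burst duration as a percentage of the tailbeat cycle that
  contains the burst onset;
* RIA — rectified integrated area: the sum of rectified amplitudes within a
  burst, expressed as a percentage of a *theoretical maximum* (the mean of the
  top 5% of rectified amplitudes pooled per electrode and fish, times the burst
  duration).  Using sample counts for duration makes the gain cancel exactly,
  so RIA is invariant to uniform channel rescaling;
* onset/offset phase — burst edges mapped to degrees of the tailbeat cycle;
* contralateral co-activation — interval overlap of left and right bursts at
  the same axial position.

Burst boundaries may come from a threshold detector (below) or from a manual
annotation table, which always takes precedence when supplied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .fin import StrokeSegmentation, phase_in_cycle

__all__ = [
    "EMGChannel",
    "EMGBurst",
    "condition_signal",
    "detect_bursts",
    "duty_factor",
    "theoretical_max_rate",
    "ria",
    "burst_phase",
    "coactivation_count",
    "read_burst_annotations",
]

logger = logging.getLogger(__name__)


@dataclass
class EMGChannel:
    """A single electrode recording with its metadata."""

    samples: np.ndarray
    rate: float                      # samples / s
    muscle: str                      # "adductor" | "axial_red"
    side: str                        # "left" | "right"
    position_percent_bl: float
    fish_id: str = ""
    name: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if not 0 <= self.position_percent_bl <= 100:
            raise ValueError("position_percent_bl must lie in [0, 100]")
        if not self.name:
            self.name = f"{self.side}_{self.position_percent_bl:g}"

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate


@dataclass
class EMGBurst:
    """One annotated burst with its cycle-level metrics."""

    onset_s: float
    offset_s: float
    duty_factor: float | None = None   # % of tailbeat cycle
    ria: float | None = None           # % of theoretical maximum
    cycle_id: int | None = None
    onset_deg: float | None = None
    offset_deg: float | None = None
    wrapped: bool = False
    exceeds_cycle: bool = False

    def __post_init__(self):
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must exceed onset")


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def condition_signal(ch: EMGChannel, notch_hz: float = 60.0,
                     notch_q: float = 30.0,
                     band_hz: tuple[float, float] = (40.0, 4000.0)) -> EMGChannel:
    """Zero-phase 60 Hz notch followed by a zero-phase band-pass.

    The high cutoff is clipped just below Nyquist (with a warning) when the
    sampling rate is too low for the nominal 4000 Hz corner.  Output length
    equals input length.
    """
    x = ch.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in EMG channel")
    nyq = ch.rate / 2.0
    b, a = sps.iirnotch(notch_hz, notch_q, fs=ch.rate)
    y = sps.filtfilt(b, a, x)
    lo, hi = band_hz
    if hi >= nyq:
        warnings.warn(
            f"band-pass high cutoff {hi} Hz clipped to {0.99 * nyq:.0f} Hz "
            f"(Nyquist {nyq:.0f} Hz)")
        hi = 0.99 * nyq
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=ch.rate, output="sos")
    y = sps.sosfiltfilt(sos, y)
    out = EMGChannel(samples=y, rate=ch.rate, muscle=ch.muscle, side=ch.side,
                     position_percent_bl=ch.position_percent_bl,
                     fish_id=ch.fish_id, name=ch.name)
    return out


# ---------------------------------------------------------------------------
# burst detection (automatic helper; annotations override)
# ---------------------------------------------------------------------------

def detect_bursts(ch: EMGChannel, threshold_k: float = 3.0,
                  edge_k: float = 0.5, merge_gap_s: float = 0.025,
                  min_duration_s: float = 0.020, smooth_s: float = 0.010,
                  edge_clamp_s: float = 0.012) -> list[tuple[float, float]]:
    """Hysteresis threshold on the smoothed rectified envelope.

    The envelope is a moving average of the rectified signal.  Baseline mean
    is taken from the quieter half of the envelope and baseline variability
    from the rectified signal in that region.  A burst must cross the
    detection threshold (baseline mean + ``threshold_k`` SD); its edges are
    first extended out to the lower edge threshold (+ ``edge_k`` SD) and then
    refined by extrapolating the local envelope slope back to baseline
    (bounded by ``edge_clamp_s``), which counters the systematic lateness of
    threshold crossings on gradually rising bursts.  Bursts separated by less
    than ``merge_gap_s`` are merged; bursts shorter than ``min_duration_s``
    are dropped.
    """
    x = np.abs(ch.samples)
    if not x.any():
        return []
    w = max(1, int(round(smooth_s * ch.rate)))
    env = np.convolve(x, np.ones(w) / w, mode="same")
    quiet = env <= np.median(env)
    m = env[quiet].mean()
    s = x[quiet].std()
    thr_hi = m + threshold_k * s
    thr_lo = m + edge_k * s

    padded = np.concatenate([[False], env > thr_lo, [False]])
    d = np.diff(padded.astype(int))
    runs = [(a, b) for a, b in zip(np.flatnonzero(d == 1),
                                   np.flatnonzero(d == -1))
            if np.max(env[a:b]) >= thr_hi]

    clamp = edge_clamp_s * ch.rate
    refined = []
    for a, b in runs:
        on, off = float(a), float(b)
        i_hi = a + int(np.argmax(env[a:b] >= thr_hi))
        k = max(3, (i_hi - a) // 4)
        if a + k < len(env) and env[a + k] > env[a]:
            on = a - min((env[a] - m) * k / (env[a + k] - env[a]), clamp)
        j_hi = b - 1 - int(np.argmax(env[a:b][::-1] >= thr_hi))
        k2 = max(3, (b - 1 - j_hi) // 4)
        if b - 1 - k2 >= 0 and env[b - 1 - k2] > env[b - 1]:
            off = (b - 1) + min(
                (env[b - 1] - m) * k2 / (env[b - 1 - k2] - env[b - 1]), clamp)
        refined.append([max(on, 0.0) / ch.rate,
                        min(off, len(env) - 1) / ch.rate])

    merged: list[list[float]] = []
    for on, off in refined:
        if merged and on - merged[-1][1] < merge_gap_s:
            merged[-1][1] = off
        else:
            merged.append([on, off])
    return [(on, off) for on, off in merged if off - on >= min_duration_s]


# ---------------------------------------------------------------------------
# burst metrics
# ---------------------------------------------------------------------------

def duty_factor(burst: tuple[float, float], cycle: tuple[float, float]) -> float:
    """Burst duration as a percentage of the tailbeat cycle duration."""
    on, off = burst
    start, end = cycle
    if off <= on:
        raise ValueError("burst offset must exceed onset")
    if end <= start:
        raise ValueError("cycle duration must be > 0")
    return 100.0 * (off - on) / (end - start)


def theoretical_max_rate(pooled: "np.ndarray | list[np.ndarray]") -> float:
    """Mean of the top 5% of rectified amplitudes pooled per electrode/fish."""
    if isinstance(pooled, (list, tuple)):
        pooled = np.concatenate([np.asarray(p, float).ravel() for p in pooled]) \
            if pooled else np.array([])
    pooled = np.abs(np.asarray(pooled, float).ravel())
    if pooled.size == 0:
        raise ValueError("empty sample pool")
    if pooled.size < 20:
        raise ValueError("need at least 20 samples to estimate the top 5%")
    k = max(1, int(np.ceil(0.05 * pooled.size)))
    top = np.partition(pooled, -k)[-k:]
    return float(top.mean())


def ria(burst_samples: np.ndarray, max_rate: float) -> float:
    """Rectified integrated area as % of the theoretical maximum.

    ``100 * sum(|v|) / (max_rate * n)`` — the theoretical maximum shares the
    burst's own time base (sample count), so units and gain cancel.
    """
    v = np.abs(np.asarray(burst_samples, float))
    if v.size == 0:
        raise ValueError("empty burst")
    if max_rate <= 0:
        raise ValueError("max_rate must be > 0")
    return float(100.0 * v.sum() / (max_rate * v.size))


def burst_phase(bursts: list[tuple[float, float]],
                tail_stroke: StrokeSegmentation) -> list[EMGBurst]:
    """Map burst onsets/offsets to degrees of the enclosing tailbeat cycle.

    A burst is assigned to the cycle containing its onset; bursts starting
    outside every cycle are skipped with a log entry.  When the offset maps to
    a smaller angle than the onset (the burst crosses the cycle boundary) the
    result is flagged ``wrapped``.
    """
    out = []
    for on, off in bursts:
        loc = tail_stroke.locate(on)
        if loc is None:
            logger.info("burst at %.4f s outside all tail cycles; skipped", on)
            continue
        cid, cycle = loc
        onset_deg = phase_in_cycle(on, cycle)
        off_loc = tail_stroke.locate(off)
        offset_deg = phase_in_cycle(off, off_loc[1]) if off_loc else \
            phase_in_cycle(min(off, np.nextafter(cycle[2], cycle[0])), cycle)
        wrapped = offset_deg < onset_deg
        out.append(EMGBurst(onset_s=on, offset_s=off, cycle_id=cid,
                            onset_deg=onset_deg, offset_deg=offset_deg,
                            wrapped=wrapped,
                            exceeds_cycle=(off - on) > (cycle[2] - cycle[0])))
    return out


def coactivation_count(left_bursts: list[tuple[float, float]],
                       right_bursts: list[tuple[float, float]],
                       min_overlap_s: float = 0.0) -> tuple[int, int]:
    """Count left-side bursts overlapping any right-side burst.

    A left burst is co-active when its interval overlaps a right burst by more
    than ``min_overlap_s`` seconds.  Returns (n_coactive, n_total_left).
    """
    n_co = 0
    for lon, loff in left_bursts:
        for ron, roff in right_bursts:
            if min(loff, roff) - max(lon, ron) > min_overlap_s:
                n_co += 1
                break
    return n_co, len(left_bursts)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_burst_annotations(path: str | Path):
    """Read a manual burst table (trial, channel, onset_s, offset_s).

    Returns a dict mapping (trial, channel) -> list of (onset, offset).
    """
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault((str(row.trial), str(row.channel)), []).append(
            (float(row.onset_s), float(row.offset_s)))
    return {k: sorted(v) for k, v in out.items()}
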