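"""Body-midline extraction, arc-length resampling and body-frame coordinates.

Top-view silhouettes of an elongate fish are reduced to an ordered nose-to-tail
centreline: the binarized mask is skeletonized, the skeleton's main path is
extracted (spurs pruned), and the path is resampled to a fixed number of points
equally spaced in arc length.  Lateral (body-frame) displacement is measured
perpendicular to the travel axis, defined as the principal direction of nose
motion over the trial, and standardized to body length (BL).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import networkx as nx
import numpy as np
from skimage.morphology import skeletonize

__all__ = [
    "LandmarkTrajectory",
    "MidlineSequence",
    "MidlineError",
    "midline_from_mask",
    "resample_midline",
    "body_frame",
    "travel_axis",
    "read_landmarks_csv",
    "read_midline_csv",
]


class MidlineError(ValueError):
    """Raised for degenerate masks, branched skeletons or undefined axes."""


@dataclass
class LandmarkTrajectory:
    """Time-indexed named 3-D points for one trial (calibrated units)."""

    time_s: np.ndarray                 # (T,)
    points: dict[str, np.ndarray]      # name -> (T, 3)
    frame_rate: float
    body_length: float

    def __post_init__(self):
        T = len(self.time_s)
        for name, arr in self.points.items():
            if arr.shape != (T, 3):
                raise ValueError(f"landmark {name!r} must be (T, 3)")

    def require(self, *names: str) -> None:
        for n in names:
            if n not in self.points:
                raise KeyError(f"missing landmark {n!r}")


@dataclass
class MidlineSequence:
    """Per-frame ordered arc-length-resampled midlines, nose first."""

    points: np.ndarray        # (T, n, 2), point 0 = nose in every frame
    body_length: float
    frame_rate: float

    def __post_init__(self):
        if self.points.ndim != 3 or self.points.shape[-1] != 2:
            raise ValueError("points must be (T, n, 2)")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def nose(self) -> np.ndarray:
        return self.points[:, 0, :]


# ---------------------------------------------------------------------------
# mask -> ordered centreline path
# ---------------------------------------------------------------------------

_STEPS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def midline_from_mask(mask: np.ndarray, head_hint: tuple[float, float],
                      prune_fraction: float = 0.05) -> np.ndarray:
    """Ordered (x, y) centreline of the largest component of a binary mask.

    The skeleton's main path is the longest geodesic between skeleton
    endpoints; side branches shorter than ``prune_fraction`` of that path are
    pruned as spurs.  The path is returned from the endpoint nearest
    ``head_hint`` (x, y) to the far endpoint.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise MidlineError("empty mask: no foreground pixels")

    from scipy import ndimage
    labels, n_lab = ndimage.label(mask)
    if n_lab > 1:
        sizes = ndimage.sum(mask, labels, index=np.arange(1, n_lab + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    if mask.sum() < 100:
        raise MidlineError("largest component has fewer than 100 pixels")

    skel = skeletonize(mask)
    g = _skeleton_graph(skel)
    ends = [n for n in g if g.degree(n) == 1]
    if len(ends) < 2:
        raise MidlineError("skeleton has no two endpoints (closed or point-like)")

    # main path: longest weighted geodesic over endpoint pairs
    best = (None, -1.0)
    for i, a in enumerate(ends):
        dist, paths = nx.single_source_dijkstra(g, a, weight="weight")
        for b in ends[i + 1:]:
            if b in dist and dist[b] > best[1]:
                best = (paths[b], dist[b])
    path, main_len = best
    if path is None:
        raise MidlineError("disconnected skeleton")

    extra = [e for e in ends if e not in (path[0], path[-1])]
    if extra:
        # measure each spur as distance from its endpoint to the main path
        dist_to_main = nx.multi_source_dijkstra_path_length(
            g, set(path), weight="weight")
        lengths = [dist_to_main.get(e, np.inf) for e in extra]
        bad = [L for L in lengths if L > prune_fraction * main_len]
        if bad:
            raise MidlineError(
                f"skeleton has {len(ends)} endpoints; "
                f"{len(bad)} branch(es) exceed the pruning threshold")

    rc = np.asarray(path, float)                 # (N, 2) as (row, col)
    xy = rc[:, ::-1].copy()                      # (x=col, y=row)
    xy = _smooth_path(xy)                        # deflate pixel staircase
    d0 = np.hypot(*(xy[0] - np.asarray(head_hint, float)))
    d1 = np.hypot(*(xy[-1] - np.asarray(head_hint, float)))
    if d1 < d0:
        xy = xy[::-1]
    return xy


def _smooth_path(xy: np.ndarray, window: int = 7) -> np.ndarray:
    """Moving-average smoothing of a pixel chain, endpoints preserved.

    An 8-connected skeleton path zigzags between pixel centres and
    overestimates the true centreline arc length; a short moving average
    removes the staircase without distorting curvature at fish scale.
    """
    if len(xy) <= window:
        return xy
    kern = np.ones(window) / window
    sm = np.column_stack([
        np.convolve(np.pad(xy[:, k], window // 2, mode="edge"), kern,
                    mode="same")[window // 2:window // 2 + len(xy)]
        for k in range(2)])
    sm[0], sm[-1] = xy[0], xy[-1]
    return sm


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pix = set(zip(rows.tolist(), cols.tolist()))
    for r, c in pix:
        for dr, dc in _STEPS:
            nb = (r + dr, c + dc)
            if nb in pix:
                g.add_edge((r, c), nb, weight=np.hypot(dr, dc))
    if not g and pix:
        g.add_nodes_from(pix)
    return g


# ---------------------------------------------------------------------------
# arc-length resampling
# ---------------------------------------------------------------------------

def resample_midline(path: np.ndarray, n: int = 100) -> np.ndarray:
    """Resample an ordered polyline to ``n`` points equally spaced in arc length.

    Endpoints are preserved exactly; interior points are placed on the linear
    interpolant of the input path.
    """
    path = np.asarray(path, float)
    if path.ndim != 2 or len(path) < 2:
        raise MidlineError("path must contain at least 2 points")
    if n < 2:
        raise MidlineError("n must be >= 2")
    seg = np.hypot(*np.diff(path, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= 0:
        raise MidlineError("zero-length path")
    targets = np.linspace(0.0, arc[-1], n)
    out = np.column_stack([np.interp(targets, arc, path[:, k])
                           for k in range(path.shape[1])])
    out[0], out[-1] = path[0], path[-1]
    return out


# ---------------------------------------------------------------------------
# body-frame lateral displacement
# ---------------------------------------------------------------------------

def travel_axis(midlines: MidlineSequence) -> tuple[np.ndarray, np.ndarray]:
    """Travel axis (unit vector, origin) from PCA of nose displacement.

    The axis direction is the first principal component of the per-frame nose
    positions, oriented along the net nose displacement.
    """
    nose = midlines.nose()
    if len(nose) < 2:
        raise MidlineError("need at least 2 frames")
    centred = nose - nose.mean(axis=0)
    cov = centred.T @ centred
    net = nose[-1] - nose[0]
    if np.allclose(cov, 0) or (np.hypot(*net) == 0 and
                               np.trace(cov) < 1e-12):
        raise MidlineError("no definable travel axis: fish did not move")
    w, v = np.linalg.eigh(cov)
    u = v[:, np.argmax(w)]
    if np.dot(u, net) < 0:
        u = -u
    return u, nose.mean(axis=0)


def body_frame(midlines: MidlineSequence) -> np.ndarray:
    """Signed lateral displacement (left positive) of each point, in BL.

    Returns an array shaped (T, n): the perpendicular distance of each midline
    point from the travel axis, positive toward the fish's left (90 deg
    counter-clockwise from the direction of travel), standardized to BL.
    """
    u, origin = travel_axis(midlines)
    nvec = np.array([-u[1], u[0]])          # +90 deg CCW: the fish's left
    rel = midlines.points - origin[None, None, :]
    return (rel @ nvec) / midlines.body_length


# ---------------------------------------------------------------------------
# CSV readers (schemas shared with the synthetic generator)
# ---------------------------------------------------------------------------

def read_landmarks_csv(path: str | Path, frame_rate: float,
                       body_length: float) -> LandmarkTrajectory:
    import pandas as pd

    df = pd.read_csv(path)
    names = df["landmark"].unique()
    frames = np.sort(df["frame"].unique())
    points = {}
    for name in names:
        sub = df[df["landmark"] == name].sort_values("frame")
        points[name] = sub[["x", "y", "z"]].to_numpy(float)
    time_s = df.drop_duplicates("frame").sort_values("frame")["time_s"] \
        .to_numpy(float)
    if len(time_s) != len(frames):
        raise ValueError("inconsistent frame/time columns")
    return LandmarkTrajectory(time_s=time_s, points=points,
                              frame_rate=frame_rate, body_length=body_length)


def read_midline_csv(path: str | Path, frame_rate: float,
                     body_length: float) -> MidlineSequence:
    import pandas as pd

    df = pd.read_csv(path).sort_values(["frame", "point_index"])
    n = df["point_index"].nunique()
    pts = df[["x", "y"]].to_numpy(float).reshape(-1, n, 2)
    return MidlineSequence(points=pts, body_length=body_length,
                           frame_rate=frame_rate)
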