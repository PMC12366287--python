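"""Feature-point detection and Brownian trajectory linking for labeled cells.

Implements the classic intensity-moment particle tracking scheme used for
fluorescent spots: image restoration (background subtraction + low-pass),
percentile-thresholded local-maximum detection with sub-pixel centroid
refinement and intensity moments (m0, m2), a non-particle discrimination
step, and frame-to-frame linking by optimal bipartite assignment with gap
closing across up to ``link_range`` frames.

Default parameters follow the standard plugin settings for this assay:
radius 10 px, percentile 0.6 %, cutoff 0, link range 4 frames, maximum
displacement 5 px per step, Brownian dynamics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

__all__ = [
    "TrackerParams",
    "ParticleDetection",
    "CellTrack",
    "restore_image",
    "detect_particles",
    "discriminate",
    "link_tracks",
    "track_stack",
    "tracks_to_dataframe",
]

_BIG = 1e12  # forbidden link
_SKIP = 1e6  # cost of leaving a track or detection unmatched


@dataclass(frozen=True)
class TrackerParams:
    """Detection and linking parameters.

    ``percentile`` selects candidate maxima from the upper tail of the
    restored-intensity distribution (percent mode, the plugin default);
    set ``percentile_mode="absolute"`` to use it as an absolute intensity
    threshold instead.  ``min_track_length`` is the persistence (in linked
    detections) a track needs before it counts toward droplet occupancy.
    """

    radius: int = 10
    percentile: float = 0.6
    percentile_mode: str = "percent"
    cutoff: float = 0.0
    link_range: int = 4
    max_displacement: float = 5.0
    dynamics: str = "Brownian"
    min_track_length: int = 5

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.percentile_mode == "percent" and not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")
        if self.percentile_mode not in ("percent", "absolute"):
            raise ValueError("percentile_mode must be 'percent' or 'absolute'")
        if self.link_range < 1:
            raise ValueError("link_range must be >= 1")
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be > 0")
        if self.min_track_length < 1:
            raise ValueError("min_track_length must be >= 1")


@dataclass(frozen=True)
class ParticleDetection:
    """One detected spot: refined sub-pixel centroid plus intensity moments."""

    frame: int
    x: float
    y: float
    m0: float
    m2: float
    peak: float = 0.0


@dataclass
class CellTrack:
    """A linked trajectory of detections in one label channel."""

    track_id: int
    channel: str | None = None
    detections: list[ParticleDetection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def frames(self):
        return np.array([d.frame for d in self.detections])

    @property
    def xs(self):
        return np.array([d.x for d in self.detections])

    @property
    def ys(self):
        return np.array([d.y for d in self.detections])

    @property
    def m0s(self):
        return np.array([d.m0 for d in self.detections])

    @property
    def median_position(self) -> tuple[float, float]:
        return float(np.median(self.xs)), float(np.median(self.ys))


def restore_image(image, radius: int):
    """Background-subtract and low-pass filter a raw frame.

    The local background is estimated with a (2*radius+1) boxcar mean and
    subtracted from the Gaussian-smoothed signal, flattening slowly varying
    backgrounds while preserving spot-scale structure.  A constant image
    restores to (numerically) all zeros.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("restore_image expects a 2-D grayscale image")
    if 2 * radius + 1 > min(image.shape):
        raise ValueError("radius too large for the image")
    background = ndimage.uniform_filter(image, size=2 * radius + 1, mode="reflect")
    smoothed = ndimage.gaussian_filter(image, sigma=1.0, mode="reflect")
    restored = smoothed - background
    # filter arithmetic leaves O(eps)·scale ripple on flat regions, which a
    # percentile threshold on an otherwise empty image would pick up as
    # maxima; snap residuals far below the image scale to exactly zero
    atol = 1e-9 * max(float(np.abs(image).max()), 1.0)
    restored[np.abs(restored) < atol] = 0.0
    return restored


def detect_particles(image, params: TrackerParams, frame: int = 0) -> list[ParticleDetection]:
    """Detect spot candidates in a restored image.

    Local maxima within ``radius`` whose restored intensity lies in the
    upper ``percentile`` of the intensity distribution are kept; centroids
    are refined by the intensity-weighted mean over the radius
    neighborhood, where the zeroth (m0) and second (m2) intensity moments
    are also computed.  Detections closer than ``radius`` are merged,
    keeping the brighter.  An empty image yields an empty list.
    """
    image = np.asarray(image, dtype=float)
    r = params.radius
    if params.percentile_mode == "percent":
        thr = float(np.percentile(image, 100.0 - params.percentile))
    else:
        thr = float(params.percentile)
    thr = max(thr, 0.0)
    local_max = ndimage.maximum_filter(image, size=2 * r + 1, mode="reflect")
    cand = np.argwhere((image >= local_max) & (image > thr))
    if cand.size == 0:
        return []
    peaks = image[cand[:, 0], cand[:, 1]]
    order = np.argsort(-peaks, kind="stable")
    cand, peaks = cand[order], peaks[order]

    # greedy merge: keep the brighter of any pair closer than radius
    kept: list[int] = []
    for i in range(len(cand)):
        ok = True
        for j in kept:
            if np.hypot(*(cand[i] - cand[j])) < r:
                ok = False
                break
        if ok:
            kept.append(i)

    h, w = image.shape
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (xx**2 + yy**2) <= r**2
    out: list[ParticleDetection] = []
    for i in kept:
        py, px = int(cand[i, 0]), int(cand[i, 1])
        y0, y1 = max(py - r, 0), min(py + r + 1, h)
        x0, x1 = max(px - r, 0), min(px + r + 1, w)
        patch = np.clip(image[y0:y1, x0:x1], 0, None)
        sub = disk[(y0 - py + r) : (y1 - py + r), (x0 - px + r) : (x1 - px + r)]
        weights = patch * sub
        m0 = float(weights.sum())
        if m0 <= 0:
            continue
        ys_loc, xs_loc = np.mgrid[y0:y1, x0:x1]
        cy = float((weights * ys_loc).sum() / m0)
        cx = float((weights * xs_loc).sum() / m0)
        m2 = float((weights * ((xs_loc - cx) ** 2 + (ys_loc - cy) ** 2)).sum() / m0)
        out.append(ParticleDetection(frame=frame, x=cx, y=cy, m0=m0, m2=m2, peak=float(peaks[i])))
    return out


def discriminate(detections: list[ParticleDetection], cutoff: float) -> list[ParticleDetection]:
    """Drop detections whose (m0, m2) discrimination score falls below ``cutoff``.

    The score is a non-negative kernel density of each detection's
    standardized moment pair within the detection ensemble, so genuine
    particles (which cluster in moment space) score high and isolated
    outliers score low.  With the default ``cutoff = 0`` every detection
    passes.
    """
    if cutoff <= 0 or not detections:
        return list(detections)
    m0 = np.array([d.m0 for d in detections])
    m2 = np.array([d.m2 for d in detections])
    s0 = m0.std() or 1.0
    s2 = m2.std() or 1.0
    z = np.column_stack([(m0 - m0.mean()) / s0, (m2 - m2.mean()) / s2])
    d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
    score = np.exp(-d2 / 2.0).mean(axis=1)
    return [d for d, s in zip(detections, score) if s >= cutoff]


def _moment_scales(frames: list[list[ParticleDetection]]) -> tuple[float, float]:
    m0 = np.array([d.m0 for dets in frames for d in dets])
    m2 = np.array([d.m2 for dets in frames for d in dets])
    s0 = float(m0.std()) if m0.size else 1.0
    s2 = float(m2.std()) if m2.size else 1.0
    return (s0 or 1.0), (s2 or 1.0)


def link_tracks(
    frames: list[list[ParticleDetection]],
    params: TrackerParams,
    channel: str | None = None,
) -> list[CellTrack]:
    """Link per-frame detections into trajectories.

    Per frame, an optimal bipartite assignment between active tracks and
    new detections minimizes squared displacement plus squared differences
    of the standardized intensity moments; links are forbidden beyond
    ``max_displacement`` per elapsed frame.  Tracks may bridge gaps of up
    to ``link_range - 1`` missing frames; unlinkable detections start new
    tracks, so every detection belongs to exactly one track.
    """
    s0, s2 = _moment_scales(frames)
    tracks: list[CellTrack] = []
    active: list[CellTrack] = []
    for f, dets in enumerate(frames):
        active = [t for t in active if f - t.detections[-1].frame <= params.link_range]
        assigned = set()
        if active and dets:
            nt, nd = len(active), len(dets)
            cost = np.full((nt + nd, nd + nt), _BIG)
            cost[nt:, nd:] = 0.0
            for i, t in enumerate(active):
                last = t.detections[-1]
                gap = f - last.frame
                limit = params.max_displacement * gap
                cost[i, nd + i] = _SKIP
                for j, d in enumerate(dets):
                    dist = np.hypot(d.x - last.x, d.y - last.y)
                    if dist <= limit:
                        cost[i, j] = (
                            dist**2
                            + ((d.m0 - last.m0) / s0) ** 2
                            + ((d.m2 - last.m2) / s2) ** 2
                        )
            for j in range(nd):
                cost[nt + j, j] = _SKIP
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if i < nt and j < nd and cost[i, j] < _SKIP:
                    active[i].detections.append(dets[j])
                    assigned.add(j)
        for j, d in enumerate(dets):
            if j not in assigned:
                t = CellTrack(track_id=len(tracks), channel=channel, detections=[d])
                tracks.append(t)
                active.append(t)
    return tracks


def track_stack(stack, params: TrackerParams, channel: str | None = None) -> list[CellTrack]:
    """Restore, detect, discriminate and link across a (T, H, W) image stack."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("track_stack expects a (T, H, W) stack")
    frames = []
    for f in range(stack.shape[0]):
        restored = restore_image(stack[f], params.radius)
        dets = detect_particles(restored, params, frame=f)
        frames.append(discriminate(dets, params.cutoff))
    return link_tracks(frames, params, channel=channel)


def tracks_to_dataframe(tracks: list[CellTrack]) -> pd.DataFrame:
    """Long-format table (channel, track_id, frame, x, y, m0, m2, intensity).

    Coordinates are 0-based pixel centers, x = column, y = row, origin at
    the top-left; ``intensity`` is the zeroth moment m0.
    """
    rows = []
    for t in tracks:
        for d in t.detections:
            rows.append(
                {
                    "channel": t.channel,
                    "track_id": t.track_id,
                    "frame": d.frame,
                    "x": d.x,
                    "y": d.y,
                    "m0": d.m0,
                    "m2": d.m2,
                    "intensity": d.m0,
                }
            )
    cols = ["channel", "track_id", "frame", "x", "y", "m0", "m2", "intensity"]
    return pd.DataFrame(rows, columns=cols)
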