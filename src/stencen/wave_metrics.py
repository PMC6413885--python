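"""Quantification of cortical-wave movies.

These are the analysis algorithms applied identically to simulated readouts
and microscopy-like image stacks: biosensor peak-distance along a line scan
(19-pixel moving-average smoothing, argmax offset), wave-front segmentation
and frame-to-frame edge-displacement speed with low/high displacement
gates, the fraction-of-fastest-pixels statistic, patch counts and areas,
puncta detection/linking with lifetimes, and kymograph extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure, segmentation

__all__ = [
    "WaveMovie",
    "SpeedReport",
    "PeakDistanceResult",
    "smooth_profile",
    "peak_distance",
    "segment_wavefronts",
    "wave_speed",
    "before_after_report",
    "puncta_lifetime",
    "patch_stats",
    "kymograph",
]


@dataclass
class WaveMovie:
    """Image stack(s) with physical metadata.

    ``channels`` maps a label to a (T, Y, X) pixel array (a (T, N) array is
    accepted for 1D line movies).  ``pixel_size`` is length/pixel and
    ``frame_interval`` time/frame.
    """

    channels: Dict[str, np.ndarray]
    pixel_size: float
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite pixels")
            self.channels[name] = arr

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    def channel(self, name: Optional[str] = None) -> np.ndarray:
        if name is None:
            if len(self.channels) != 1:
                raise ValueError(
                    f"movie has channels {list(self.channels)}; specify one")
            return next(iter(self.channels.values()))
        return self.channels[name]


@dataclass
class PeakDistanceResult:
    """Signed peak offset: positive = first channel's peak precedes the
    reference channel's peak along the propagation direction."""

    distance: float
    index_a: int
    index_b: int


@dataclass
class SpeedReport:
    """Edge-displacement wave-speed summary of one movie (or window)."""

    per_frame_speed: np.ndarray      # length/time, NaN where no accepted pixels
    mean_speed: float                # video average over accepted displacements
    fraction_fastest: float
    patch_count: np.ndarray          # per frame
    mean_patch_area: float           # length^2, NaN if no patches
    accepted_count: int

    def __post_init__(self):
        if not (0.0 <= self.fraction_fastest <= 1.0):
            raise ValueError("fraction_fastest must lie in [0, 1]")


def smooth_profile(signal: Sequence[float], window: int = 19) -> np.ndarray:
    """Centered moving average; edges use symmetrically shrinking windows."""
    x = np.asarray(signal, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(x):
        raise ValueError(f"window {window} exceeds signal length {len(x)}")
    if window == 1:
        return x.copy()
    half = window // 2
    c = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half, n - 1)
    # shrink symmetrically so the window stays centered
    reach = np.minimum(i - lo, hi - i)
    lo, hi = i - reach, i + reach
    return (c[hi + 1] - c[lo]) / (hi - lo + 1)


def peak_distance(ch_a: Sequence[float], ch_b: Sequence[float],
                  pixel_size: float, direction: int = 1,
                  window: int = 19) -> PeakDistanceResult:
    """Distance between smoothed intensity maxima of two line profiles.

    Both profiles are moving-average filtered (window 19 pixels); the
    result is ``direction * (argmax_a - argmax_b) * pixel_size``.  Ties
    break toward the first index.
    """
    a = np.asarray(ch_a, float)
    b = np.asarray(ch_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be equal-length 1D arrays")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    sa = smooth_profile(a, window)
    sb = smooth_profile(b, window)
    for name, s in (("a", sa), ("b", sb)):
        if np.ptp(s) < 1e-12:
            warnings.warn(f"profile {name} is flat after smoothing; "
                          "argmax tie broken toward the first index")
    ia, ib = int(np.argmax(sa)), int(np.argmax(sb))
    return PeakDistanceResult(
        distance=float(direction * (ia - ib) * pixel_size),
        index_a=ia, index_b=ib)


def segment_wavefronts(frame: np.ndarray, k: float = 1.0,
                       min_size: int = 9, smooth_sigma: float = 0.0) -> np.ndarray:
    """Label wave fronts: threshold at mean + k*sd, drop objects < min_size,
    8-connected components.  Returns an integer label image (0 = background).

    ``smooth_sigma`` applies a Gaussian blur before thresholding; useful for
    noisy frames where single-pixel speckle would fragment the fronts.
    """
    f = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("frame contains non-finite pixels")
    if smooth_sigma > 0:
        f = ndimage.gaussian_filter(f, smooth_sigma)
    mask = f > f.mean() + k * f.std()
    lab = measure.label(mask, connectivity=2)
    if min_size > 1 and lab.max() > 0:
        sizes = np.bincount(lab.ravel())
        small = np.where(sizes < min_size)[0]
        mask &= ~np.isin(lab, small[small > 0])
    return measure.label(mask, connectivity=2)


def _edge_pixels(mask: np.ndarray) -> np.ndarray:
    """Inner boundary pixels of a binary mask."""
    return segmentation.find_boundaries(mask, mode="inner", connectivity=2) & mask


def _frame_displacements(prev_mask: np.ndarray, next_mask: np.ndarray,
                         pixel_size: float) -> np.ndarray:
    """Distance (length units) from each edge pixel of the next frame to the
    nearest edge pixel of the previous frame."""
    prev_edge = _edge_pixels(prev_mask)
    next_edge = _edge_pixels(next_mask)
    if not prev_edge.any() or not next_edge.any():
        return np.empty(0)
    dist = ndimage.distance_transform_edt(~prev_edge) * pixel_size
    return dist[next_edge]


def wave_speed(movie: WaveMovie, channel: Optional[str] = None,
               low: float = 0.1, high: float = 5.0, k: float = 1.0,
               min_size: int = 9, smooth_sigma: float = 0.0) -> SpeedReport:
    """Edge-displacement wave speed.

    For every boundary pixel of a wave front in frame n+1 the distance to
    the closest wave edge in frame n is computed; displacements outside
    [low, high] (length units) are rejected as not belonging to the same
    front.  Per-frame mean displacement / frame_interval gives speed; the
    fraction of fastest pixels is the fraction of accepted displacements at
    least one standard deviation above the video-wide mean.
    """
    stack = movie.channel(channel)
    if stack.ndim != 3:
        raise ValueError("wave_speed needs a (T, Y, X) stack")
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    labels = [segment_wavefronts(fr, k=k, min_size=min_size,
                             smooth_sigma=smooth_sigma) for fr in stack]
    masks = [lb > 0 for lb in labels]

    per_frame = []
    all_disp: List[np.ndarray] = []
    for i in range(1, len(masks)):
        disp = _frame_displacements(masks[i - 1], masks[i], movie.pixel_size)
        kept = disp[(disp >= low) & (disp <= high)]
        all_disp.append(kept)
        per_frame.append(kept.mean() / movie.frame_interval if kept.size else np.nan)
    flat = np.concatenate(all_disp) if all_disp else np.empty(0)

    if flat.size:
        mean_speed = float(flat.mean() / movie.frame_interval)
        mu, sd = flat.mean(), flat.std()
        fraction = float(np.mean(flat >= mu + sd)) if sd > 0 else 0.0
    else:
        mean_speed, fraction = 0.0, 0.0

    counts, mean_area = patch_stats(labels)
    return SpeedReport(
        per_frame_speed=np.asarray(per_frame),
        mean_speed=mean_speed,
        fraction_fastest=fraction,
        patch_count=counts,
        mean_patch_area=mean_area * movie.pixel_size ** 2 if np.isfinite(mean_area) else np.nan,
        accepted_count=int(flat.size),
    )


def before_after_report(movie: WaveMovie, event_frame: int,
                        n_window: int = 30, n_gap: int = 30,
                        **kwargs) -> Tuple[SpeedReport, SpeedReport]:
    """Paired speed reports around a recruitment event.

    Before: the ``n_window`` frames preceding the event.  After: ``n_gap``
    frames are allowed to elapse for the perturbation to take effect, then
    the next ``n_window`` frames are measured.
    """
    T = movie.n_frames
    if event_frame < n_window or T < event_frame + n_gap + n_window:
        raise ValueError(
            f"insufficient frames: need {n_window} before frame {event_frame} "
            f"and {n_gap}+{n_window} after (movie has {T})")

    def window(lo, hi):
        return WaveMovie(
            channels={k_: v[lo:hi] for k_, v in movie.channels.items()},
            pixel_size=movie.pixel_size, frame_interval=movie.frame_interval,
            meta=dict(movie.meta))

    before = wave_speed(window(event_frame - n_window, event_frame), **kwargs)
    after = wave_speed(window(event_frame + n_gap, event_frame + n_gap + n_window),
                       **kwargs)
    return before, after


def puncta_lifetime(movie: WaveMovie, channel: Optional[str] = None,
                    k: float = 1.0, min_area: int = 4, max_area: int = 100,
                    link_radius: float = 2.0,
                    drop_censored: bool = True) -> List[float]:
    """Lifetimes of small transient bright objects (puncta).

    Objects with segmented area in [min_area, max_area] pixels are linked
    across consecutive frames by nearest-centroid matching within
    ``link_radius`` pixels; a single missed detection frame is tolerated
    (transient overlaps split tracks otherwise).  A punctum's lifetime is
    ``(last_frame - first_frame + 1) * frame_interval``.  Tracks touching
    the first or last frame are right/left-censored and are dropped by
    default.
    """
    stack = movie.channel(channel)
    if stack.ndim != 3:
        raise ValueError("puncta_lifetime needs a (T, Y, X) stack")
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 frames")

    tracks: List[dict] = []   # {centroid, first, last}
    active: List[dict] = []
    for t, frame in enumerate(stack):
        lab = segment_wavefronts(frame, k=k, min_size=1)
        centroids = []
        for rp in measure.regionprops(lab):
            if min_area <= rp.area <= max_area:
                centroids.append(np.array(rp.centroid))
        new_active: List[dict] = []
        used = set()
        for tr in active:
            best, best_d = None, link_radius
            for j, c in enumerate(centroids):
                if j in used:
                    continue
                d = float(np.linalg.norm(c - tr["centroid"]))
                if d <= best_d:
                    best, best_d = j, d
            if best is not None:
                used.add(best)
                tr["centroid"] = centroids[best]
                tr["last"] = t
                tr["misses"] = 0
                new_active.append(tr)
            elif tr.get("misses", 0) < 1:
                tr["misses"] = tr.get("misses", 0) + 1
                new_active.append(tr)
            else:
                tracks.append(tr)
        for j, c in enumerate(centroids):
            if j not in used:
                new_active.append({"centroid": c, "first": t, "last": t,
                                   "misses": 0})
        active = new_active
    tracks.extend(active)
    last_frame = stack.shape[0] - 1
    if drop_censored:
        tracks = [tr for tr in tracks
                  if tr["first"] > 0 and tr["last"] < last_frame]
    return [(tr["last"] - tr["first"] + 1) * movie.frame_interval
            for tr in tracks]


def patch_stats(masks: Sequence[np.ndarray]) -> Tuple[np.ndarray, float]:
    """Per-frame patch counts and the video-mean patch area (pixels).

    ``masks`` are labeled images.  Mean area is NaN when no patches exist.
    """
    counts = []
    areas: List[float] = []
    for lab in masks:
        lab = np.asarray(lab)
        ids, cnts = np.unique(lab[lab > 0], return_counts=True)
        counts.append(len(ids))
        areas.extend(cnts.tolist())
    mean_area = float(np.mean(areas)) if areas else np.nan
    return np.asarray(counts, dtype=int), mean_area


def kymograph(movie: WaveMovie, line: Tuple[Tuple[float, float], Tuple[float, float]],
              channel: Optional[str] = None,
              n_samples: Optional[int] = None) -> np.ndarray:
    """Space-x-time matrix sampled bilinearly along a line, one row per
    spatial sample, one column per frame."""
    stack = movie.channel(channel)
    if stack.ndim == 2:          # (T, N) line movie: the kymograph itself
        return stack.T.copy()
    (r0, c0), (r1, c1) = line
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= stack.shape[1] - 1 and 0 <= c <= stack.shape[2] - 1):
            raise ValueError(f"line endpoint ({r}, {c}) outside frame")
    if n_samples is None:
        n_samples = int(np.hypot(r1 - r0, c1 - c0)) + 1
    rows = np.linspace(r0, r1, n_samples)
    cols = np.linspace(c0, c1, n_samples)
    out = np.empty((n_samples, stack.shape[0]))
    for t in range(stack.shape[0]):
        out[:, t] = ndimage.map_coordinates(stack[t], [rows, cols], order=1)
    return out
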