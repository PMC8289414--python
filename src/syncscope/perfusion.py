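"""Glucose-analog bolus arrival kinetics near and far from vessels.

The arrival frame is the first frame whose whole-image mean rises by
more than 5 intensity units over the previous frame.  Circular ROIs of
5 um diameter are classified *near* (within 10 um of the nearest vessel
pixel, boundary inclusive) or *far*; each ROI trace is min-max
normalised (F/F_max) over the window from 5 s before to 10 s after
arrival and summarised by its trapezoidal AUC and by the spread across
ROIs at the +3 s time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import InputError, NoArrivalError
from .movie import IsletMovie

ARRIVAL_JUMP = 5.0  # intensity units
NEAR_CUT_UM = 10.0
ROI_DIAMETER_UM = 5.0
WINDOW_BEFORE_S = 5.0
WINDOW_AFTER_S = 10.0
DISPERSION_T_S = 3.0


@dataclass
class PerfusionROISet:
    """ROI table: centres, distance classes and (normalised) window traces."""

    centers_px: np.ndarray  # (n, 2) (y, x)
    distance_um: np.ndarray  # (n,) distance to the nearest vessel pixel
    distance_class: np.ndarray  # (n,) "near" | "far"
    window_traces: np.ndarray  # (n, W) raw mean intensity over the window
    normalized: np.ndarray  # (n, W) F/F_max traces
    arrival_frame: int
    frame_interval_s: float

    @property
    def window_times_s(self) -> np.ndarray:
        w = self.window_traces.shape[1]
        return -WINDOW_BEFORE_S + np.arange(w) * self.frame_interval_s

    def of_class(self, cls: str) -> np.ndarray:
        return self.normalized[self.distance_class == cls]


def detect_arrival_frame(movie: IsletMovie) -> int:
    """First frame with a whole-image mean increase > 5 units (strict)."""
    series = movie.data.mean(axis=(1, 2, 3))
    jumps = np.diff(series)
    hits = np.nonzero(jumps > ARRIVAL_JUMP)[0]
    if len(hits) == 0:
        raise NoArrivalError("no frame-to-frame image-mean increase above 5 units")
    return int(hits[0] + 1)


def classify_rois(
    centers_px: np.ndarray, vessel_mask: np.ndarray, pixel_size_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Distance of each ROI centre to the nearest vessel pixel, and its class.

    Distance is the Euclidean distance transform of the vessel mask
    evaluated at the ROI centre; 10 um exactly counts as near.
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if not vessel_mask.any():
        raise InputError("vessel mask is empty")
    dist_um = ndimage.distance_transform_edt(~vessel_mask) * pixel_size_um
    centers = np.asarray(centers_px)
    d = dist_um[centers[:, 0].astype(int), centers[:, 1].astype(int)]
    cls = np.where(d <= NEAR_CUT_UM, "near", "far")
    return d, cls


def roi_trace(movie: IsletMovie, center_px: tuple[float, float]) -> np.ndarray:
    """Mean intensity over a 5 um disc at ``center_px``, first z-plane."""
    r_px = (ROI_DIAMETER_UM / 2.0) / movie.pixel_size_um
    cy, cx = center_px
    _, _, ny, nx = movie.data.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= max(r_px, 1.0) ** 2
    return movie.data[:, 0, disc].mean(axis=1)


def normalize_fmax(trace: np.ndarray) -> np.ndarray:
    """Min-max (F/F_max) normalisation of a window trace to [0, 1]."""
    trace = np.asarray(trace, dtype=float)
    lo, hi = trace.min(), trace.max()
    if hi <= lo:
        raise InputError("constant trace cannot be F/F_max normalised")
    return (trace - lo) / (hi - lo)


def auc_window(normalized: np.ndarray, dt_s: float = 1.0) -> float:
    """Trapezoidal integral of a normalised window trace (seconds x F/F_max)."""
    return float(np.trapezoid(np.asarray(normalized, dtype=float), dx=dt_s))


def dispersion_at(
    normalized_traces: np.ndarray,
    t_s: float = DISPERSION_T_S,
    frame_interval_s: float = 1.0,
) -> float:
    """Sample SD across ROIs of the normalised value at ``t_s`` after arrival."""
    arr = np.asarray(normalized_traces, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise InputError("need at least 2 ROI traces")
    idx = int(round((t_s + WINDOW_BEFORE_S) / frame_interval_s))
    if not 0 <= idx < arr.shape[1]:
        raise InputError("time point outside the normalisation window")
    return float(arr[:, idx].std(ddof=1))


def place_rois(
    vessel_mask: np.ndarray,
    islet_mask: np.ndarray,
    pixel_size_um: float,
    n_per_class: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random ROI centres stratified by distance class within the islet."""
    dist_um = ndimage.distance_transform_edt(~np.asarray(vessel_mask, bool))
    dist_um = dist_um * pixel_size_um
    inside = np.asarray(islet_mask, bool) & ~np.asarray(vessel_mask, bool)
    centers = []
    for cls_mask in (dist_um <= NEAR_CUT_UM, dist_um > NEAR_CUT_UM):
        ys, xs = np.nonzero(inside & cls_mask)
        if len(ys) == 0:
            raise InputError("a distance class has no candidate pixels")
        pick = rng.choice(len(ys), size=min(n_per_class, len(ys)), replace=False)
        centers.extend(zip(ys[pick], xs[pick]))
    return np.asarray(centers)


def extract_roi_set(
    movie: IsletMovie,
    vessel_mask: np.ndarray,
    centers_px: np.ndarray,
) -> PerfusionROISet:
    """Window, normalise and classify a set of ROIs around bolus arrival."""
    arrival = detect_arrival_frame(movie)
    dt = movie.frame_interval_s
    before = int(round(WINDOW_BEFORE_S / dt))
    after = int(round(WINDOW_AFTER_S / dt))
    lo, hi = arrival - before, arrival + after
    if lo < 0 or hi >= movie.n_frames:
        raise InputError("movie too short for the -5..+10 s arrival window")
    dist, cls = classify_rois(centers_px, vessel_mask, movie.pixel_size_um)
    raw = np.array([roi_trace(movie, c)[lo : hi + 1] for c in centers_px])
    norm = np.array([normalize_fmax(tr) for tr in raw])
    return PerfusionROISet(
        centers_px=np.asarray(centers_px),
        distance_um=dist,
        distance_class=cls,
        window_traces=raw,
        normalized=norm,
        arrival_frame=arrival,
        frame_interval_s=dt,
    )


def analyze_perfusion(
    movie: IsletMovie,
    vessel_mask: np.ndarray,
    islet_mask: Optional[np.ndarray] = None,
    n_per_class: int = 15,
    seed: int = 0,
) -> tuple[PerfusionROISet, dict[str, float]]:
    """ROI placement + windowing + the per-islet perfusion summary.

    The summary holds, for each distance class, the AUC of the mean
    normalised trace and the across-ROI SD at +3 s.
    """
    if islet_mask is None:
        islet_mask = np.ones(movie.data.shape[2:], dtype=bool)
    rng = np.random.default_rng(seed)
    centers = place_rois(
        vessel_mask, islet_mask, movie.pixel_size_um, n_per_class, rng
    )
    rois = extract_roi_set(movie, vessel_mask, centers)
    summary: dict[str, float] = {"arrival_frame": float(rois.arrival_frame)}
    for cls in ("near", "far"):
        traces = rois.of_class(cls)
        if len(traces) == 0:
            continue
        mean_trace = traces.mean(axis=0)
        summary[f"auc_{cls}"] = auc_window(mean_trace, dt_s=movie.frame_interval_s)
        if len(traces) >= 2:
            summary[f"sd_at_3s_{cls}"] = dispersion_at(
                traces, frame_interval_s=movie.frame_interval_s
            )
    return rois, summary
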