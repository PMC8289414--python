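"""Movie conditioning applied before activity/coordination analysis.

The sequence mirrors the analysis the metrics assume: a 5x5 spatial
averaging filter per frame, removal of pixels without significant
fluorescence and of saturated pixels, per-pixel linear detrending to
correct mild photobleaching, and a motion gate that trims a recording at
the first frame whose rigid displacement from frame 0 exceeds half a
cell width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .errors import InputError
from .movie import IsletMovie

SMOOTH_KERNEL = 5

# PixelMask reason codes
REASON_KEPT = 0
REASON_LOW_FLUORESCENCE = 1
REASON_SATURATED = 2
REASON_NAMES = {0: "kept", 1: "low_fluorescence", 2: "saturated"}


@dataclass
class PixelMask:
    """Per-pixel inclusion mask over the (Z, Y, X) volume."""

    included: np.ndarray  # (Z, Y, X) bool
    reason: np.ndarray  # (Z, Y, X) int, see REASON_* codes

    @property
    def n_kept(self) -> int:
        return int(self.included.sum())

    def summary(self) -> dict[str, float]:
        total = self.included.size
        return {
            "kept_fraction": float(self.included.sum() / total),
            "low_fluorescence_fraction": float(
                (self.reason == REASON_LOW_FLUORESCENCE).sum() / total
            ),
            "saturated_fraction": float((self.reason == REASON_SATURATED).sum() / total),
        }


@dataclass
class MotionResult:
    """Outcome of the motion gate: pass, trim(t_end) or reject."""

    status: str  # "pass" | "trim" | "reject"
    t_end: Optional[int]  # last usable frame index when status == "trim"
    displacement_um: np.ndarray  # per-frame displacement vs frame 0


def smooth_movie(movie: IsletMovie, kernel: int = SMOOTH_KERNEL) -> IsletMovie:
    """Uniform ``kernel x kernel`` spatial average per frame and z-plane.

    Borders use reflect padding; the time axis is untouched.
    """
    _, _, ny, nx = movie.data.shape
    if ny < kernel or nx < kernel:
        raise InputError(f"frame smaller than the {kernel}x{kernel} smoothing kernel")
    out = ndimage.uniform_filter(
        movie.data, size=(1, 1, kernel, kernel), mode="reflect"
    )
    return movie.with_data(out)


def mask_islet(
    movie: IsletMovie, min_mean_intensity: Optional[float] = None
) -> PixelMask:
    """Exclude saturated pixels and pixels without significant fluorescence.

    A pixel is *saturated* if its trace ever reaches the movie's
    saturation value, and *low fluorescence* if its temporal mean falls
    below ``min_mean_intensity``.  When the threshold is not given it is
    derived by Otsu's method on the temporal-mean image, which separates
    islet from background without a free parameter.
    """
    if min_mean_intensity is not None and min_mean_intensity < 0:
        raise InputError("min_mean_intensity must be >= 0")
    mean_img = movie.data.mean(axis=0)  # (Z, Y, X)
    if min_mean_intensity is None:
        min_mean_intensity = float(threshold_otsu(mean_img))
    saturated = (movie.data >= movie.saturation_value).any(axis=0)
    low = mean_img < min_mean_intensity
    reason = np.zeros(mean_img.shape, dtype=int)
    reason[low] = REASON_LOW_FLUORESCENCE
    reason[saturated] = REASON_SATURATED  # saturation takes precedence
    included = reason == REASON_KEPT
    return PixelMask(included=included, reason=reason)


def detrend_linear(x: np.ndarray) -> np.ndarray:
    """Remove the per-trace least-squares line, preserving the mean.

    Works on a 1-D trace or any array whose first axis is time.
    """
    x = np.asarray(x, dtype=float)
    t_len = x.shape[0]
    if t_len < 3:
        raise InputError("detrending needs at least 3 time points")
    t = np.arange(t_len, dtype=float)
    tc = t - t.mean()
    denom = (tc**2).sum()
    flat = x.reshape(t_len, -1)
    slope = tc @ flat / denom
    detrended = flat - tc[:, None] * slope[None, :]
    return detrended.reshape(x.shape)


def detrend_movie(movie: IsletMovie) -> IsletMovie:
    """Per-pixel linear detrend of a movie (mean-preserving)."""
    return movie.with_data(detrend_linear(movie.data))


def assess_motion(
    movie: IsletMovie,
    cell_width_um: float,
    min_frames: int = 10,
    upsample: int = 10,
) -> MotionResult:
    """Gate a recording on rigid tissue motion.

    Displacement of every frame relative to frame 0 is estimated by
    phase cross-correlation on the z-maximum projection (a stand-in for
    a structural channel).  The first frame displaced by at least half a
    cell width triggers a trim at the preceding frame; a trim leaving
    fewer than ``min_frames`` frames rejects the movie.
    """
    if cell_width_um <= 0:
        raise InputError("cell_width_um must be > 0")
    ref = movie.data[0].max(axis=0)
    threshold_um = 0.5 * cell_width_um
    disp = np.zeros(movie.n_frames)
    bad = None
    for t in range(1, movie.n_frames):
        frame = movie.data[t].max(axis=0)
        shift = phase_cross_correlation(ref, frame, upsample_factor=upsample)[0]
        disp[t] = float(np.hypot(*shift)) * movie.pixel_size_um
        if disp[t] >= threshold_um and bad is None:
            bad = t
    if bad is None:
        return MotionResult(status="pass", t_end=None, displacement_um=disp)
    t_end = bad - 1
    if t_end + 1 < min_frames:
        return MotionResult(status="reject", t_end=None, displacement_um=disp)
    return MotionResult(status="trim", t_end=t_end, displacement_um=disp)
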