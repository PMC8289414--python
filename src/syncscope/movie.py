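"""In-memory container for time-lapse fluorescence recordings.

A movie is a real-valued array ordered (T, Z, Y, X): time, axial plane,
image row, image column.  Physical calibration travels with the array:
the frame interval in seconds, the lateral pixel size in micrometres and
the detector saturation value (pixels that ever reach it are treated as
clipped by the masking step).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError


@dataclass
class IsletMovie:
    """4-D fluorescence recording with acquisition metadata.

    Parameters
    ----------
    data
        Array of shape ``(T, Z, Y, X)``.  A 3-D ``(T, Y, X)`` array is
        accepted and promoted to a single z-plane.
    frame_interval_s
        Time between consecutive frames, seconds.
    pixel_size_um
        Lateral pixel size, micrometres.
    saturation_value
        Intensity at which the detector clips.  ``inf`` disables
        saturation handling.
    z_spacing_um
        Axial spacing between planes, micrometres (8 um is typical for
        intravital z-stacks).
    """

    data: np.ndarray
    frame_interval_s: float
    pixel_size_um: float
    saturation_value: float = np.inf
    z_spacing_um: float = 8.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 3:
            arr = arr[:, None, :, :]
        if arr.ndim != 4:
            raise InputError(f"movie data must be (T, Z, Y, X); got shape {arr.shape}")
        if arr.shape[0] < 2:
            raise InputError("movie needs at least 2 frames")
        if self.frame_interval_s <= 0:
            raise InputError("frame_interval_s must be > 0")
        if self.pixel_size_um <= 0:
            raise InputError("pixel_size_um must be > 0")
        self.data = arr

    # -- convenience ----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        """(Z, Y, X) shape."""
        return self.data.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def fs_hz(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.frame_interval_s

    def with_data(self, data: np.ndarray) -> "IsletMovie":
        """Copy of this movie with the array replaced, metadata kept."""
        return replace(self, data=data)

    def trimmed(self, t_end: int) -> "IsletMovie":
        """Movie restricted to frames ``0..t_end`` inclusive."""
        if t_end < 1:
            raise InputError("trim must keep at least 2 frames")
        return self.with_data(self.data[: t_end + 1])
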