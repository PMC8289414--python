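"""Activity classification and coordinated-area segmentation.

The masked movie is tiled into 5x5-pixel blocks per z-plane; a block is
*active* when its detrended trace carries peaks whose amplitude exceeds
1.5x the background noise scale, and active blocks whose pairwise
Pearson correlation exceeds 0.7 are merged (transitively) into
coordinated regions.  The two headline statistics are the active
fraction (active pixels / kept pixels, across all z) and the largest
coordinated fraction (pixels of the largest region / active pixels).

Region membership does not require spatial contiguity by default: two
well-separated patches oscillating in phase belong to one region, which
is what false-colour synchronization maps display.  Pass
``require_contiguity=True`` to additionally split regions into spatially
connected components of adjacent tiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import InputError, UndefinedResultError
from .movie import IsletMovie
from .preprocess import PixelMask, detrend_linear

BLOCK = 5
MIN_BLOCK_PIXELS = 13  # majority of a 5x5 tile
R_MIN_DEFAULT = 0.7
ACTIVITY_FACTOR = 1.5
PEAK_PROMINENCE_FACTOR = 2.0
PEAK_MIN_SEPARATION = 2  # frames
BASELINE_PERCENTILE = 10.0


@dataclass
class BlockTraceSet:
    """Per-block normalized time courses with tile geometry.

    Traces are block means over kept pixels, divided by their temporal
    mean and linearly detrended.  ``centroids_px`` are (y, x) tile
    centres; ``n_pixels`` the kept-pixel count per tile.
    """

    traces: np.ndarray  # (n_blocks, T)
    centroids_px: np.ndarray  # (n_blocks, 2) (y, x)
    z: np.ndarray  # (n_blocks,)
    n_pixels: np.ndarray  # (n_blocks,)
    tile_index: np.ndarray  # (n_blocks, 2) (row, col) tile coordinates

    @property
    def n_blocks(self) -> int:
        return len(self.traces)


@dataclass
class CoordinationMap:
    """Region labelling of active blocks plus the derived fractions.

    ``region_label`` is 0 for inactive blocks; coordinated regions are
    numbered 1, 2, ... in decreasing order of pixel count.
    """

    region_label: np.ndarray  # (n_blocks,) int
    active_blocks: np.ndarray  # (n_blocks,) bool
    region_pixel_counts: np.ndarray  # pixel count per region, descending
    n_kept_pixels: int
    blocks: BlockTraceSet = field(repr=False)

    @property
    def n_regions(self) -> int:
        return len(self.region_pixel_counts)

    @property
    def n_active_pixels(self) -> int:
        return int(self.blocks.n_pixels[self.active_blocks].sum())

    def regions_holding_at_least(self, fraction: float) -> int:
        """Number of regions holding at least ``fraction`` of the active area."""
        active = self.n_active_pixels
        if active == 0:
            return 0
        return int((self.region_pixel_counts >= fraction * active).sum())


def extract_blocks(movie: IsletMovie, mask: PixelMask) -> BlockTraceSet:
    """Tile the masked movie into 5x5 blocks and build their traces."""
    data = movie.data
    n_t, n_z, ny, nx = data.shape
    traces, cents, zs, npx, tiles = [], [], [], [], []
    for z in range(n_z):
        inc = mask.included[z]
        for r0 in range(0, ny - BLOCK + 1, BLOCK):
            for c0 in range(0, nx - BLOCK + 1, BLOCK):
                tile = inc[r0 : r0 + BLOCK, c0 : c0 + BLOCK]
                kept = int(tile.sum())
                if kept < MIN_BLOCK_PIXELS:
                    continue
                ys, xs = np.nonzero(tile)
                block = data[:, z, r0 : r0 + BLOCK, c0 : c0 + BLOCK]
                trace = block[:, ys, xs].mean(axis=1)
                mean = trace.mean()
                if mean > 0:
                    trace = trace / mean
                traces.append(detrend_linear(trace))
                cents.append((r0 + (BLOCK - 1) / 2.0, c0 + (BLOCK - 1) / 2.0))
                zs.append(z)
                npx.append(kept)
                tiles.append((r0 // BLOCK, c0 // BLOCK))
    if not traces:
        raise UndefinedResultError("no usable blocks: mask kept too few pixels")
    return BlockTraceSet(
        traces=np.asarray(traces),
        centroids_px=np.asarray(cents, dtype=float),
        z=np.asarray(zs),
        n_pixels=np.asarray(npx),
        tile_index=np.asarray(tiles),
    )


#: lower-quartile of |centered first difference| -> sigma for Gaussian noise:
#: quantile q of |Z| is Phi^-1((1+q)/2), and differencing scales sigma by sqrt(2)
_NOISE_QUANTILE = 0.25
_NOISE_QUANTILE_FACTOR = 0.31864  # Phi^-1(0.625)


def noise_scale(trace: np.ndarray) -> float:
    """Robust per-sample noise sd estimated from first differences.

    Uses the lower quartile of the centred absolute first difference
    rather than the median, so intermittent fast oscillatory content
    (aliased fast components riding on a slow wave) does not inflate
    the estimate: at least half the frames sit on the quiet phase of
    the slow cycle and dominate the lower quartile.
    """
    d = np.diff(np.asarray(trace, dtype=float))
    q = np.quantile(np.abs(d - np.median(d)), _NOISE_QUANTILE)
    return float(q / (_NOISE_QUANTILE_FACTOR * np.sqrt(2.0)))


def noise_background(trace: np.ndarray) -> float:
    """Amplitude a pure-noise trace of this length would show.

    Peak amplitude is measured as maximum minus the 10th percentile, so
    for Gaussian noise of sd sigma over T frames its expectation is
    roughly ``sigma * (sqrt(2 ln T) + 1.28)`` (expected maximum plus the
    baseline offset).  Activity must beat 1.5x this, which makes the
    rule reject noise-only traces regardless of their sd.
    """
    trace = np.asarray(trace, dtype=float)
    sigma = noise_scale(trace)
    t_len = trace.shape[0]
    return float(sigma * (np.sqrt(2.0 * np.log(t_len)) + 1.2816))


def detect_peaks(
    trace: np.ndarray, frame_interval_s: float | None = None
) -> list[tuple[int, float]]:
    """Local maxima with prominence above twice the noise scale.

    Returns ``(time_index, amplitude)`` pairs where amplitude is the
    peak value minus the trace's 10th-percentile baseline.  Peaks closer
    than 2 frames are merged (the larger one kept).  A constant trace
    yields no peaks.
    """
    trace = np.asarray(trace, dtype=float)
    if np.ptp(trace) == 0:
        return []
    scale = noise_scale(trace)
    prominence = max(PEAK_PROMINENCE_FACTOR * scale, 1e-12 * np.ptp(trace))
    idx, _ = signal.find_peaks(trace, prominence=prominence, distance=PEAK_MIN_SEPARATION)
    baseline = np.percentile(trace, BASELINE_PERCENTILE)
    return [(int(i), float(trace[i] - baseline)) for i in idx]


def classify_active(peaks: Sequence[tuple[int, float]], background: float) -> bool:
    """Active iff the maximum peak amplitude exceeds 1.5x background (strict)."""
    if background <= 0:
        raise InputError("background must be > 0")
    if not peaks:
        return False
    return max(a for _, a in peaks) > ACTIVITY_FACTOR * background


def classify_blocks_active(blocks: BlockTraceSet) -> np.ndarray:
    """Apply the peak/amplitude activity rule to every block trace."""
    active = np.zeros(blocks.n_blocks, dtype=bool)
    for i, trace in enumerate(blocks.traces):
        peaks = detect_peaks(trace)
        bg = noise_background(trace)
        if bg <= 0:
            # noiseless trace: any genuine peak counts as activity
            active[i] = bool(peaks) and max(a for _, a in peaks) > 0
        else:
            active[i] = classify_active(peaks, bg)
    return active


def peak_coincidence(
    peaks_a: Sequence[tuple[int, float]],
    peaks_b: Sequence[tuple[int, float]],
    tolerance: int = 1,
) -> float:
    """Fraction of peaks in the sparser train matched within ``tolerance`` frames."""
    if not peaks_a or not peaks_b:
        return 0.0
    ta = np.array([i for i, _ in peaks_a])
    tb = np.array([i for i, _ in peaks_b])
    ref, other = (ta, tb) if len(ta) <= len(tb) else (tb, ta)
    hits = sum(np.min(np.abs(other - t)) <= tolerance for t in ref)
    return hits / len(ref)


def merge_coordinated(
    blocks: BlockTraceSet,
    r_min: float = R_MIN_DEFAULT,
    n_kept_pixels: Optional[int] = None,
    active: Optional[np.ndarray] = None,
    require_contiguity: bool = False,
) -> CoordinationMap:
    """Merge active blocks into coordinated regions.

    Candidate regions are seeded by coincident peak timing, but because
    blocks whose peaks align also correlate above the threshold, the
    final partition is exactly the set of connected components of the
    strict ``R > r_min`` Pearson-correlation graph over active blocks,
    which is also how it is computed here.  Labels are ordered by region
    pixel count, largest first; ties go to the component containing the
    lowest block index.
    """
    if active is None:
        active = classify_blocks_active(blocks)
    active = np.asarray(active, dtype=bool)
    if n_kept_pixels is None:
        n_kept_pixels = int(blocks.n_pixels.sum())
    n_active = int(active.sum())
    labels = np.zeros(blocks.n_blocks, dtype=int)
    if n_active < 2:
        if n_active == 1:
            warnings.warn("fewer than 2 active blocks; single trivial region")
            labels[active] = 1
            counts = np.array([int(blocks.n_pixels[active].sum())])
        else:
            warnings.warn("no active blocks; empty coordination map")
            counts = np.array([], dtype=int)
        return CoordinationMap(labels, active, counts, n_kept_pixels, blocks)

    act_idx = np.nonzero(active)[0]
    sub = blocks.traces[act_idx]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=-1.0)
    adj = corr > r_min
    np.fill_diagonal(adj, True)
    if require_contiguity:
        same_z = blocks.z[act_idx][:, None] == blocks.z[act_idx][None, :]
        tiles = blocks.tile_index[act_idx]
        dist = np.abs(tiles[:, None, :] - tiles[None, :, :]).max(axis=2)
        adj &= same_z & (dist <= 1)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)

    sizes = np.zeros(n_comp, dtype=int)
    for c in range(n_comp):
        sizes[c] = int(blocks.n_pixels[act_idx[comp == c]].sum())
    # order: size descending, then lowest member block index for ties
    first_member = np.array([act_idx[comp == c].min() for c in range(n_comp)])
    order = np.lexsort((first_member, -sizes))
    rank = np.empty(n_comp, dtype=int)
    rank[order] = np.arange(1, n_comp + 1)
    labels[act_idx] = rank[comp]
    counts = sizes[order]
    return CoordinationMap(labels, active, counts, n_kept_pixels, blocks)


def active_fraction(cmap: CoordinationMap) -> float:
    """Active pixels / kept pixels, pooled across z-planes."""
    if cmap.n_kept_pixels == 0:
        raise UndefinedResultError("no kept pixels")
    return cmap.n_active_pixels / cmap.n_kept_pixels


def largest_coordinated_fraction(cmap: CoordinationMap) -> float:
    """Pixels of the largest coordinated region / active pixels."""
    active = cmap.n_active_pixels
    if active == 0:
        raise UndefinedResultError("no active pixels")
    return float(cmap.region_pixel_counts[0]) / active


def analyze_coordination(
    movie: IsletMovie,
    mask: PixelMask,
    r_min: float = R_MIN_DEFAULT,
    require_contiguity: bool = False,
) -> tuple[CoordinationMap, BlockTraceSet]:
    """Blocks -> activity -> coordinated regions, in one call."""
    blocks = extract_blocks(movie, mask)
    cmap = merge_coordinated(
        blocks,
        r_min=r_min,
        n_kept_pixels=mask.n_kept,
        require_contiguity=require_contiguity,
    )
    return cmap, blocks
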