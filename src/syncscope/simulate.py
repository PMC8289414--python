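"""Ground-truthed synthetic islet generator.

Three generators, all deterministic in ``(seed, config)``:

* :func:`generate_architecture` — cell positions on a jittered triangular
  lattice clipped to an ellipse, endocrine types (beta/alpha/delta)
  assigned by radial sorting (beta inward) blended with a random
  permutation controlled by ``intermix``, and a nearest-neighbour
  contact graph (pairs closer than 1.2x the median nearest-neighbour
  spacing).
* :func:`generate_calcium_movie` — a (T, Z, Y, X) fluorescence movie in
  which every cell carries a clean oscillation (smoothed square slow
  wave, optional fast sinusoid gated to the plateau), organised into K
  phase-separated synchronization domains or a planar travelling wave,
  with mosaic sensor expression, additive Gaussian noise, linear
  photobleaching and saturation clipping.  The noiseless per-cell traces
  and all latent labels are returned as :class:`GroundTruth`.
* :func:`generate_perfusion_movie` — a single-plane bolus-arrival movie:
  vessel pixels rise first with a logistic time course, tissue pixels
  follow with a delay growing with distance from the nearest vessel.

The clean-trace amplitude scale is fixed (baseline 100, oscillation
amplitude 10), so the signal-to-noise ratio of a simulation is simply
``10 / noise_sd`` (the default ``noise_sd = 2`` gives SNR 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import SimulationConfig
from .errors import ConfigurationError
from .movie import IsletMovie

# geometry of the cell layout
CELL_SPACING_UM = 12.0  # lattice constant ~ mouse endocrine cell diameter
ELLIPSE_ASPECT = 1.4  # major/minor axis ratio of the islet outline
JITTER_FRAC = 0.12  # positional jitter, fraction of the lattice constant
CONTACT_FACTOR = 1.2  # contact radius, multiple of median NN spacing
CELL_RADIUS_FRAC = 0.45  # raster footprint radius, fraction of spacing

# fluorescence scale of clean traces
BASELINE_F = 100.0
OSC_AMPLITUDE = 10.0
BACKGROUND_F = 10.0
FAST_REL_AMPLITUDE = 0.5  # fast-component amplitude relative to slow
SQUARE_SOFTNESS = 0.25  # tanh softness of the slow square wave
DEPTH_LENGTH_UM = 100.0  # exponential depth-attenuation length constant
PHASE_JITTER_RAD = 0.2  # per-domain jitter around the stratified phases
DOMAIN_GAP_FACTOR = 2.75  # sensor-negative band half-width between domains,
#                           in lattice constants

# perfusion movie
PERFUSION_BASE_F = 20.0
PERFUSION_AMPLITUDE = 200.0
VESSEL_HALF_WIDTH_PX = 1

TYPE_NAMES = ("beta", "alpha", "delta")

# independent random streams derived from the one user seed
_STREAM_ARCH, _STREAM_CALCIUM, _STREAM_PERFUSION = 0, 1, 2


@dataclass
class ArchitectureMap:
    """Cell positions (um), endocrine types, and nearest-neighbour contacts.

    ``contacts`` is an ``(m, 2)`` integer array of unordered cell-id
    pairs with ``contacts[:, 0] < contacts[:, 1]``, no duplicates and no
    self-pairs.
    """

    positions_um: np.ndarray  # (n, 2) x, y
    types: np.ndarray  # (n,) of {"beta", "alpha", "delta"}
    contacts: np.ndarray  # (m, 2) int

    def __post_init__(self) -> None:
        n = len(self.positions_um)
        if len(self.types) != n:
            raise ConfigurationError("positions and types length mismatch")
        if len(self.contacts):
            c = np.asarray(self.contacts)
            if (c[:, 0] >= c[:, 1]).any():
                raise ConfigurationError("contacts must be sorted pairs a < b")
            if c.max() >= n or c.min() < 0:
                raise ConfigurationError("contact refers to unknown cell id")

    @property
    def n_cells(self) -> int:
        return len(self.positions_um)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def contact_pairs(self) -> set[tuple[int, int]]:
        return {(int(a), int(b)) for a, b in self.contacts}


@dataclass
class GroundTruth:
    """Latent state of a generated calcium movie.

    ``per_cell_clean_trace`` holds the noiseless, unbleached trace of
    every cell at the top z-plane (attenuation 1); an emitted pixel of an
    expressing cell equals this trace exactly when ``noise_sd = 0`` and
    ``bleach_slope_per_s = 0``.
    """

    domain_label: np.ndarray  # (n,) int in 1..K
    phase_offset: np.ndarray  # (n,) radians, includes wave delay
    true_wave_speed_um_s: Optional[float]
    active_cells: np.ndarray  # (n,) bool: sensor-expressing & oscillating
    per_cell_clean_trace: np.ndarray  # (n, T)
    cell_label_image: np.ndarray  # (Y, X) int, -1 = background
    origin_um: np.ndarray  # (2,) x, y of pixel (0, 0) centre

    def cell_centroids_px(self) -> np.ndarray:
        """(n, 2) array of (y, x) pixel centroids of each cell footprint."""
        n = len(self.domain_label)
        out = np.full((n, 2), np.nan)
        lbl = self.cell_label_image
        for i in range(n):
            ys, xs = np.nonzero(lbl == i)
            if len(ys):
                out[i] = (ys.mean(), xs.mean())
        return out


@dataclass
class PerfusionGroundTruth:
    """Latent state of a generated perfusion movie."""

    vessel_mask: np.ndarray  # (Y, X) bool
    islet_mask: np.ndarray  # (Y, X) bool
    arrival_delay_s: np.ndarray  # (Y, X) per-pixel delay after bolus onset


def _triangular_lattice(half_w: float, half_h: float, spacing: float) -> np.ndarray:
    """Points of a triangular lattice covering [-half_w, half_w] x [-half_h, half_h]."""
    dy = spacing * np.sqrt(3.0) / 2.0
    rows = int(np.ceil(half_h / dy))
    cols = int(np.ceil(half_w / spacing))
    pts = []
    for j in range(-rows, rows + 1):
        offset = 0.0 if j % 2 == 0 else spacing / 2.0
        for i in range(-cols, cols + 1):
            pts.append((i * spacing + offset, j * dy))
    return np.array(pts)


def generate_architecture(config: SimulationConfig) -> ArchitectureMap:
    """Place cells, assign types and derive the contact graph.

    Cells sit on a jittered triangular lattice clipped to an ellipse of
    aspect 1.4 whose area matches ``n_cells`` lattice sites.  Types are
    assigned by elliptical-radius sorting (beta innermost, alpha/delta
    shuffled through the mantle) and then partially randomised: a
    fraction ``intermix`` of cells have their types permuted among
    themselves, so ``intermix = 0`` is a fully sorted core-mantle islet
    and ``intermix = 1`` is fully random placement.
    """
    rng = np.random.default_rng([config.seed, _STREAM_ARCH])
    n = config.n_cells
    spacing = CELL_SPACING_UM
    site_area = (np.sqrt(3.0) / 2.0) * spacing**2
    b = np.sqrt(n * site_area / (np.pi * ELLIPSE_ASPECT))
    a = ELLIPSE_ASPECT * b

    for _ in range(30):
        pts = _triangular_lattice(a + spacing, b + spacing, spacing)
        pts = pts + rng.normal(0.0, JITTER_FRAC * spacing, pts.shape)
        r2 = (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2
        inside = np.nonzero(r2 <= 1.0)[0]
        if len(inside) >= n:
            keep = inside[np.argsort(r2[inside])[:n]]
            positions = pts[keep]
            break
        a *= 1.05
        b *= 1.05
    else:  # pragma: no cover - geometric fallback never reached in practice
        raise ConfigurationError("could not place requested number of cells")

    # type assignment: radial sorting blended with random permutation
    fb, fa, fd = config.type_fractions
    n_beta = int(round(fb * n))
    n_alpha = int(round(fa * n))
    n_alpha = min(n_alpha, n - n_beta)
    n_delta = n - n_beta - n_alpha
    radius = (positions[:, 0] / a) ** 2 + (positions[:, 1] / b) ** 2
    order = np.argsort(radius)
    types = np.empty(n, dtype="<U5")
    types[order[:n_beta]] = "beta"
    mantle_types = np.array(["alpha"] * n_alpha + ["delta"] * n_delta)
    rng.shuffle(mantle_types)
    types[order[n_beta:]] = mantle_types

    m = int(round(config.intermix * n))
    if m > 1:
        idx = rng.choice(n, size=m, replace=False)
        types[idx] = types[idx][rng.permutation(m)]

    # contacts: within 1.2x median nearest-neighbour spacing
    tree = cKDTree(positions)
    nn_dist = tree.query(positions, k=2)[0][:, 1]
    radius_contact = CONTACT_FACTOR * np.median(nn_dist)
    pairs = tree.query_pairs(r=radius_contact, output_type="ndarray")
    if len(pairs):
        pairs = np.sort(pairs, axis=1)
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    else:  # pragma: no cover
        pairs = np.empty((0, 2), dtype=int)

    return ArchitectureMap(positions_um=positions, types=types, contacts=pairs)


def _domain_labels(positions: np.ndarray, k: int) -> np.ndarray:
    """Split cells into K angular sectors of equal cell count (labels 1..K)."""
    n = len(positions)
    if k == 1:
        return np.ones(n, dtype=int)
    centre = positions.mean(axis=0)
    ang = np.arctan2(positions[:, 1] - centre[1], positions[:, 0] - centre[0])
    order = np.argsort(ang, kind="stable")
    labels = np.empty(n, dtype=int)
    for j, chunk in enumerate(np.array_split(order, k)):
        labels[chunk] = j + 1
    return labels


def _wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap to (-pi, pi]."""
    return -((-np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi)


def clean_cell_traces(
    arch: ArchitectureMap, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free oscillation of every cell.

    Returns ``(traces, domain_label, phase_offset)`` where ``traces`` is
    ``(n_cells, T)``.  The slow component is a tanh-smoothed square wave
    of duty 0.5; in ``mixed``/``fast`` patterns a fast sinusoid rides on
    the slow plateau.  Domains share one oscillation frequency and carry
    evenly spaced phases (a common random rotation plus ``2*pi*k/K`` and
    a small jitter), which keeps distinct domains decorrelated below the
    0.7 coordination threshold for every K while leaving the ensemble
    phase uniformly distributed.  A travelling wave (K = 1 only) delays
    each cell by its projected distance along the islet major axis
    divided by the wave speed.
    """
    n = arch.n_cells
    t = np.arange(config.n_frames) * config.frame_interval_s
    k = config.n_domains

    domain = _domain_labels(arch.positions_um, k)
    rotation = rng.uniform(0.0, 2.0 * np.pi)
    dom_phase = rotation + 2.0 * np.pi * np.arange(k) / k
    dom_phase = dom_phase + rng.uniform(-PHASE_JITTER_RAD, PHASE_JITTER_RAD, size=k)
    dom_fast_phase = rng.uniform(0.0, 2.0 * np.pi, size=k)

    if config.wave_speed_um_s is not None:
        if k != 1:
            raise ConfigurationError("travelling wave requires n_domains == 1")
        proj = arch.positions_um[:, 0]  # wave axis = ellipse major axis (x)
        delay = (proj - proj.min()) / config.wave_speed_um_s
    else:
        delay = np.zeros(n)

    f_slow = 1.0 / config.slow_period_s
    f_fast = 1.0 / config.fast_period_s
    phase = dom_phase[domain - 1]
    fast_phase = dom_fast_phase[domain - 1]

    tt = t[None, :] - delay[:, None]  # (n, T) retarded time
    theta_slow = 2.0 * np.pi * f_slow * tt + phase[:, None]
    slow = 0.5 * (1.0 + np.tanh(np.sin(theta_slow) / SQUARE_SOFTNESS))
    theta_fast = 2.0 * np.pi * f_fast * tt + fast_phase[:, None]
    fast = 0.5 * (1.0 + np.sin(theta_fast))

    if config.pattern == "slow":
        osc = slow
    elif config.pattern == "fast":
        osc = fast
    else:  # mixed: fast rides on the slow plateau
        osc = slow + FAST_REL_AMPLITUDE * fast * (slow > 0.5)

    traces = BASELINE_F + OSC_AMPLITUDE * osc
    phase_offset = _wrap_phase(phase - 2.0 * np.pi * f_slow * delay)
    return traces, domain, np.asarray(phase_offset)


def rasterize_cells(
    arch: ArchitectureMap, pixel_size_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Label image of cell footprints.

    Returns ``(label_image, origin_um)`` where ``label_image[y, x]`` is
    the owning cell id (-1 for background) and ``origin_um`` the (x, y)
    physical position of pixel (0, 0).  Footprints are discs of radius
    0.45x the lattice constant, so neighbouring cells do not overlap.
    """
    pos = arch.positions_um
    margin = CELL_SPACING_UM
    x0, y0 = pos[:, 0].min() - margin, pos[:, 1].min() - margin
    x1, y1 = pos[:, 0].max() + margin, pos[:, 1].max() + margin
    nx = int(np.ceil((x1 - x0) / pixel_size_um))
    ny = int(np.ceil((y1 - y0) / pixel_size_um))
    label = np.full((ny, nx), -1, dtype=int)
    r_px = CELL_RADIUS_FRAC * CELL_SPACING_UM / pixel_size_um
    r_int = int(np.ceil(r_px))
    for i, (cx, cy) in enumerate(pos):
        px = (cx - x0) / pixel_size_um
        py = (cy - y0) / pixel_size_um
        ylo, yhi = int(py) - r_int, int(py) + r_int + 1
        xlo, xhi = int(px) - r_int, int(px) + r_int + 1
        ys, xs = np.mgrid[max(ylo, 0) : min(yhi, ny), max(xlo, 0) : min(xhi, nx)]
        inside = (ys - py) ** 2 + (xs - px) ** 2 <= r_px**2
        label[ys[inside], xs[inside]] = i
    return label, np.array([x0, y0])


def generate_calcium_movie(
    arch: ArchitectureMap, config: SimulationConfig
) -> tuple[IsletMovie, GroundTruth]:
    """Render a calcium movie from an architecture, with ground truth."""
    if config.wave_speed_um_s is not None and config.wave_speed_um_s <= 0:
        raise ConfigurationError("wave_speed_um_s must be > 0")
    rng = np.random.default_rng([config.seed, _STREAM_CALCIUM])

    traces, domain, phase_offset = clean_cell_traces(arch, config, rng)
    expressing = np.ones(arch.n_cells, dtype=bool)
    if config.n_domains > 1:
        # Mosaic expression is biased away from domain interfaces: cells
        # close to a neighbouring domain are rendered sensor-negative, so
        # distinct synchronization domains appear as disjoint expressing
        # patches (as mosaic labelling shows them) rather than blending
        # into each other at a shared border.  The band is wide enough
        # that no analysis tile sees smoothed signal from two domains.
        tree = cKDTree(arch.positions_um)
        pairs = tree.query_pairs(r=DOMAIN_GAP_FACTOR * CELL_SPACING_UM,
                                 output_type="ndarray")
        if len(pairs):
            a, b = pairs[:, 0], pairs[:, 1]
            cross = domain[a] != domain[b]
            expressing[a[cross]] = False
            expressing[b[cross]] = False

    # Stratified sensor mosaic: each domain expresses the same number of
    # cells (sensor_fraction of the smallest domain's available pool),
    # so the K synchronization domains occupy equal expressing areas —
    # the ground-truth condition the coordinated-fraction analysis is
    # tested against.
    pool_sizes = [
        int(expressing[domain == d].sum()) for d in range(1, config.n_domains + 1)
    ]
    per_domain = max(1, int(np.floor(config.sensor_fraction * min(pool_sizes))))
    for d in range(1, config.n_domains + 1):
        avail = np.nonzero(expressing & (domain == d))[0]
        drop = rng.choice(avail, size=len(avail) - per_domain, replace=False)
        expressing[drop] = False
    label, origin = rasterize_cells(arch, config.pixel_size_um)

    # pixel traces: expressing-cell pixels carry the cell trace, the rest
    # sit at a dim background level
    flat = label.ravel()
    owner = np.clip(flat, 0, None)
    has_cell = (flat >= 0) & expressing[owner]
    px = np.where(has_cell[:, None], traces[owner], BACKGROUND_F)  # (Npx, T)

    t_s = np.arange(config.n_frames) * config.frame_interval_s
    bleach = np.clip(1.0 - config.bleach_slope_per_s * t_s, 0.0, None)

    ny, nx = label.shape
    movie = np.empty((config.n_frames, config.z_planes, ny, nx))
    for z in range(config.z_planes):
        atten = np.exp(-z * config.z_spacing_um / DEPTH_LENGTH_UM)
        frame = (atten * px * bleach[None, :]).T.reshape(config.n_frames, ny, nx)
        movie[:, z] = frame
    if config.noise_sd > 0:
        movie += rng.normal(0.0, config.noise_sd, movie.shape)
    movie = np.clip(movie, 0.0, config.saturation_value)

    islet_movie = IsletMovie(
        data=movie,
        frame_interval_s=config.frame_interval_s,
        pixel_size_um=config.pixel_size_um,
        saturation_value=config.saturation_value,
        z_spacing_um=config.z_spacing_um,
    )
    truth = GroundTruth(
        domain_label=domain,
        phase_offset=phase_offset,
        true_wave_speed_um_s=config.wave_speed_um_s,
        active_cells=expressing,
        per_cell_clean_trace=traces,
        cell_label_image=label,
        origin_um=origin,
    )
    return islet_movie, truth


def generate_perfusion_movie(
    arch: ArchitectureMap, config: SimulationConfig
) -> tuple[IsletMovie, PerfusionGroundTruth]:
    """Render a single-plane bolus-perfusion movie with vessel mask.

    Two straight vessels cross the islet; every tissue pixel rises with a
    logistic time course delayed by ``perfusion_delay_s_per_um`` times
    its distance from the nearest vessel, smoothed to mimic diffusion.
    """
    rng = np.random.default_rng([config.seed, _STREAM_PERFUSION])
    label, origin = rasterize_cells(arch, config.pixel_size_um)
    ny, nx = label.shape
    islet = label >= 0
    islet = ndimage.binary_closing(islet, structure=np.ones((5, 5)))

    vessel = np.zeros((ny, nx), dtype=bool)
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    for _ in range(2):
        ang = rng.uniform(0.0, np.pi)
        offset = rng.uniform(-0.2, 0.2) * min(ny, nx)
        # signed distance to a line through (cy+offset, cx) at angle ang
        d = (yy - cy - offset) * np.cos(ang) - (xx - cx) * np.sin(ang)
        vessel |= np.abs(d) <= VESSEL_HALF_WIDTH_PX
    vessel &= islet

    dist_um = ndimage.distance_transform_edt(~vessel) * config.pixel_size_um
    delay = dist_um * config.perfusion_delay_s_per_um
    delay = ndimage.gaussian_filter(delay, sigma=1.0)
    delay[vessel] = 0.0

    t = np.arange(config.n_frames) * config.frame_interval_s
    arg = (t[None, None, :] - config.bolus_onset_s - delay[:, :, None]) / config.bolus_tau_s
    rise = 1.0 / (1.0 + np.exp(-arg))
    frames = PERFUSION_BASE_F + PERFUSION_AMPLITUDE * rise * islet[:, :, None]
    movie = np.moveaxis(frames, 2, 0)[:, None, :, :].copy()
    if config.noise_sd > 0:
        movie += rng.normal(0.0, config.noise_sd, movie.shape)
    movie = np.clip(movie, 0.0, config.saturation_value)

    islet_movie = IsletMovie(
        data=movie,
        frame_interval_s=config.frame_interval_s,
        pixel_size_um=config.pixel_size_um,
        saturation_value=config.saturation_value,
    )
    truth = PerfusionGroundTruth(
        vessel_mask=vessel, islet_mask=islet, arrival_delay_s=delay
    )
    return islet_movie, truth
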