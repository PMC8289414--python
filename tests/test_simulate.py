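"""Generator behaviour: determinism, geometry, ground-truth composition."""

import numpy as np
import pytest

from syncscope import (
    SimulationConfig,
    generate_architecture,
    generate_calcium_movie,
    generate_perfusion_movie,
)
from syncscope.architecture import contact_probabilities
from syncscope.errors import ConfigurationError


def test_same_seed_gives_identical_architecture_and_movie():
    cfg = SimulationConfig(seed=11, n_frames=20)
    a1, a2 = generate_architecture(cfg), generate_architecture(cfg)
    assert np.array_equal(a1.positions_um, a2.positions_um)
    assert np.array_equal(a1.types, a2.types)
    assert np.array_equal(a1.contacts, a2.contacts)
    m1, t1 = generate_calcium_movie(a1, cfg)
    m2, t2 = generate_calcium_movie(a2, cfg)
    assert np.array_equal(m1.data, m2.data)
    assert np.array_equal(t1.active_cells, t2.active_cells)


def test_contact_graph_has_no_self_or_duplicate_pairs():
    arch = generate_architecture(SimulationConfig(seed=2))
    pairs = [tuple(p) for p in arch.contacts]
    assert len(pairs) == len(set(pairs))
    assert all(a < b for a, b in pairs)
    assert arch.contacts.max() < arch.n_cells


def test_pure_beta_islet_has_only_homotypic_contacts():
    cfg = SimulationConfig(seed=5, type_fractions=(1.0, 0.0, 0.0), intermix=0.7)
    arch = generate_architecture(cfg)
    assert set(arch.types) == {"beta"}
    probs = contact_probabilities(arch)
    assert probs.p_beta_homotypic == 1.0


def test_beta_homotypic_contacts_decrease_with_intermixing():
    """Sorted islets favour beta-beta contacts over fully random ones."""

    def mean_bb(intermix):
        vals = [
            contact_probabilities(
                generate_architecture(SimulationConfig(seed=s, intermix=intermix))
            ).p_beta_homotypic
            for s in range(20)
        ]
        return np.mean(vals)

    assert mean_bb(0.0) > mean_bb(1.0)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_cells": 5},
        {"type_fractions": (0.5, 0.5, 0.5)},
        {"intermix": 1.5},
        {"wave_speed_um_s": -3.0},
        {"pattern": "chaotic"},
        {"slow_period_s": 10.0},
        {"fast_period_s": 90.0},
        {"sensor_fraction": 0.0},
    ],
)
def test_invalid_configurations_are_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        SimulationConfig(seed=0, **kwargs)


def test_noiseless_pixels_reproduce_the_stored_clean_traces():
    """Composition: at zero noise/bleach an expressing pixel *is* its cell trace."""
    cfg = SimulationConfig(seed=3, noise_sd=0.0, bleach_slope_per_s=0.0, n_frames=30)
    arch = generate_architecture(cfg)
    movie, truth = generate_calcium_movie(arch, cfg)
    lbl = truth.cell_label_image
    for cid in np.nonzero(truth.active_cells)[0][:10]:
        ys, xs = np.nonzero(lbl == cid)
        pix = movie.data[:, 0, ys[0], xs[0]]
        assert np.array_equal(pix, truth.per_cell_clean_trace[cid])


def test_common_source_movie_has_unit_pairwise_correlation():
    cfg = SimulationConfig(
        seed=9, noise_sd=0.0, n_domains=1, sensor_fraction=1.0, n_frames=30
    )
    arch = generate_architecture(cfg)
    _, truth = generate_calcium_movie(arch, cfg)
    traces = truth.per_cell_clean_trace
    corr = np.corrcoef(traces[:20])
    assert np.allclose(corr, 1.0, atol=1e-12)


def test_wave_delay_spans_distance_over_speed():
    speed = 30.0
    cfg = SimulationConfig(seed=1, wave_speed_um_s=speed, n_frames=30)
    arch = generate_architecture(cfg)
    _, truth = generate_calcium_movie(arch, cfg)
    extent = arch.positions_um[:, 0].max() - arch.positions_um[:, 0].min()
    f = 1.0 / cfg.slow_period_s
    # ground-truth phase offsets encode -2*pi*f*delay
    dphi = truth.phase_offset.max() - truth.phase_offset.min()
    assert dphi / (2 * np.pi * f) == pytest.approx(extent / speed, rel=1e-6)


def test_two_domains_are_anticorrelated_across_and_coherent_within():
    cfg = SimulationConfig(seed=6, n_domains=2, noise_sd=0.0, pattern="slow", n_frames=40)
    arch = generate_architecture(cfg)
    _, truth = generate_calcium_movie(arch, cfg)
    tr = truth.per_cell_clean_trace
    dom = truth.domain_label
    within = np.corrcoef(tr[dom == 1][:5])
    assert within.min() > 0.99
    cross = np.corrcoef(tr[dom == 1][0], tr[dom == 2][0])[0, 1]
    assert cross < 0.7


def test_domains_have_equal_expressing_cell_counts():
    cfg = SimulationConfig(seed=8, n_domains=4)
    arch = generate_architecture(cfg)
    _, truth = generate_calcium_movie(arch, cfg)
    counts = [
        int((truth.active_cells & (truth.domain_label == d)).sum()) for d in (1, 2, 3, 4)
    ]
    assert len(set(counts)) == 1


def test_perfusion_movie_is_deterministic_and_delays_grow_with_distance():
    cfg = SimulationConfig(seed=7, frame_interval_s=1.0, n_frames=50)
    arch = generate_architecture(cfg)
    m1, t1 = generate_perfusion_movie(arch, cfg)
    m2, _ = generate_perfusion_movie(arch, cfg)
    assert np.array_equal(m1.data, m2.data)
    assert t1.arrival_delay_s[t1.vessel_mask].max() == 0.0
    far = t1.islet_mask & ~t1.vessel_mask
    assert t1.arrival_delay_s[far].max() > 1.0


def test_zero_tissue_delay_makes_all_islet_pixels_simultaneous():
    cfg = SimulationConfig(
        seed=7,
        frame_interval_s=1.0,
        n_frames=50,
        noise_sd=0.0,
        perfusion_delay_s_per_um=0.0,
    )
    arch = generate_architecture(cfg)
    movie, truth = generate_perfusion_movie(arch, cfg)
    ys, xs = np.nonzero(truth.islet_mask)
    traces = movie.data[:, 0, ys, xs]
    spread = traces.std(axis=1)
    assert spread.max() < 1e-9


def test_known_delay_difference_appears_in_half_rise_times():
    cfg = SimulationConfig(seed=7, frame_interval_s=1.0, n_frames=60, noise_sd=0.0)
    arch = generate_architecture(cfg)
    movie, truth = generate_perfusion_movie(arch, cfg)
    delays = truth.arrival_delay_s
    inside = truth.islet_mask
    p0 = np.argwhere(inside & (np.abs(delays - 0.0) < 0.05))[0]
    p2 = np.argwhere(inside & (np.abs(delays - 2.0) < 0.05))[0]

    def half_rise(trace):
        half = (trace.min() + trace.max()) / 2.0
        return np.argmax(trace >= half)

    t0 = half_rise(movie.data[:, 0, p0[0], p0[1]])
    t2 = half_rise(movie.data[:, 0, p2[0], p2[1]])
    assert abs((t2 - t0) - 2.0) <= 1.0  # within one frame
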