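"""Shared fixtures: cached simulate->preprocess->coordination runs.

Simulation plus preprocessing is the expensive part of many tests, so a
memoised helper hands out one pipeline state per (seed, config) and the
tests treat the returned objects as read-only.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from syncscope import SimulationConfig, generate_architecture, generate_calcium_movie
from syncscope.coordination import analyze_coordination
from syncscope.preprocess import detrend_movie, mask_islet, smooth_movie


class SimState:
    """One simulated islet taken through preprocessing and coordination."""

    def __init__(self, seed: int, **cfg_kwargs):
        self.config = SimulationConfig(seed=seed, **cfg_kwargs)
        self.arch = generate_architecture(self.config)
        self.movie, self.truth = generate_calcium_movie(self.arch, self.config)
        smoothed = smooth_movie(self.movie)
        self.mask = mask_islet(smoothed)
        self.detrended = detrend_movie(smoothed)
        self.cmap, self.blocks = analyze_coordination(self.detrended, self.mask)


@lru_cache(maxsize=96)
def _cached_sim(seed: int, items: tuple) -> SimState:
    return SimState(seed, **dict(items))


def simulated_islet(seed: int, **cfg_kwargs) -> SimState:
    return _cached_sim(seed, tuple(sorted(cfg_kwargs.items())))


@pytest.fixture(scope="session")
def sim_factory():
    return simulated_islet


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
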