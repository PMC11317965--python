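"""Shared fixtures: synthetic datasets and in-memory pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest

from doublebox.pipeline import PipelineConfig, analyse_regions, call_regions
from doublebox.synthetic_data import make_dataset


def run_in_memory(seed: int, profile: str = "paper-like"):
    """Generate a dataset and run region calling + motif analysis in memory."""
    fx = make_dataset(profile, seed=seed)
    cfg = PipelineConfig(seed=seed)
    regions = call_regions(cfg, fx.genome, fx.chip_tracks, fx.control_tracks)
    result = analyse_regions(fx.genome, regions, cfg)
    return fx, regions, result


@pytest.fixture(scope="session")
def small_dataset():
    return make_dataset("small", seed=7)


@pytest.fixture(scope="session")
def paperlike_run():
    """One full paper-like analysis shared across tests (seed 11)."""
    return run_in_memory(11)


def random_pwm(rng: np.random.Generator, width: int,
               sharpness: float = 1.0):
    """A random PWM (Dirichlet columns) with uniform background."""
    from doublebox.motif_model import PWM

    probs = rng.dirichlet(np.full(4, sharpness), size=width)
    probs = np.clip(probs, 1e-6, None)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return PWM(probs, np.full(4, 0.25))


def random_genome(rng: np.random.Generator, length: int, name: str = "g"):
    from doublebox.io_core import Genome

    return Genome(name, "".join("ACGT"[i] for i in rng.integers(4, size=length)))
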