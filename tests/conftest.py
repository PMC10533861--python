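"""Shared fixtures: small phantoms and programmatic patch sets."""

from __future__ import annotations

import numpy as np
import pytest

import aneucad as ac


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Two-level phantom (vessel 1000 / background 100) with exact geometry."""
    config = ac.PhantomConfig(noise_sd=0.0, seed=7)
    volume, lesions, geometry = ac.generate_phantom(config, full_output=True)
    return config, volume, lesions, geometry


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom with noise at 10% of the vessel/background contrast."""
    config = ac.PhantomConfig(noise_sd=90.0, seed=11)
    volume, lesions, geometry = ac.generate_phantom(config, full_output=True)
    return config, volume, lesions, geometry


def make_blob_patch(rng: np.random.Generator, noise_sd: float = 0.05) -> np.ndarray:
    """5x24x24 patch with a bright ball near the center (aneurysm-like)."""
    radius = rng.uniform(4.0, 6.0)  # pixels
    cz = 2 + rng.integers(-1, 2)
    cr, cc = 12 + rng.integers(-1, 2), 12 + rng.integers(-1, 2)
    zz, rr, cc_grid = np.meshgrid(
        np.arange(5), np.arange(24), np.arange(24), indexing="ij"
    )
    # slices are thicker than in-plane pixels in source data; use 2x z scale
    dist = np.sqrt((2.0 * (zz - cz)) ** 2 + (rr - cr) ** 2 + (cc_grid - cc) ** 2)
    patch = (dist <= radius).astype(float)
    return np.clip(patch + rng.normal(0, noise_sd, patch.shape), 0, 1)


def make_tube_patch(rng: np.random.Generator, noise_sd: float = 0.05) -> np.ndarray:
    """5x24x24 patch with a bright straight tube through the center (vessel)."""
    radius = rng.uniform(2.0, 3.0)  # pixels
    theta = rng.uniform(0, np.pi)
    direction = np.array([np.cos(theta), np.sin(theta)])
    rr, cc = np.meshgrid(np.arange(24) - 12.0, np.arange(24) - 12.0, indexing="ij")
    # in-plane distance to the center line
    perp = np.abs(-direction[1] * rr + direction[0] * cc)
    tube2d = perp <= radius
    patch = np.repeat(tube2d[None].astype(float), 5, axis=0)
    return np.clip(patch + rng.normal(0, noise_sd, patch.shape), 0, 1)


def make_patch_dataset(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Balanced separable dataset of blob (label 1) and tube (label 0) patches."""
    rng = np.random.default_rng(seed)
    half = n // 2
    x = np.array(
        [make_blob_patch(rng) for _ in range(half)]
        + [make_tube_patch(rng) for _ in range(n - half)]
    )
    y = np.concatenate([np.ones(half), np.zeros(n - half)])
    order = rng.permutation(n)
    return x[order], y[order]
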