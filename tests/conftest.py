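"""Shared phantom builders for the test suite.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

import stromaquant as sq


def straight_fiber(row: float, c0: float, length: float, width_um: float,
                   peak: float = 180.0, angle_deg: float = 0.0) -> sq.FiberSpec:
    """A straight fiber starting at (row, c0) at the given axial angle."""
    th = np.deg2rad(angle_deg)
    end = np.array([row + length * np.sin(th), c0 + length * np.cos(th)])
    return sq.FiberSpec(centerline=np.array([[row, c0], end]),
                        width_um=width_um, peak_intensity=peak,
                        orientation_deg=angle_deg % 180.0)


def grid_phantom(n_fibers: int, width_um: float = 4.0, length: float = 60.0,
                 noise_sd: float = 0.0, seed: int = 0, peak: float = 180.0,
                 pixel_size_um: float = 1.0):
    """Well-separated straight horizontal fibers on a grid.

    Fibers sit at random sub-pixel row offsets so that discretization
    effects average out, and far enough apart that they never merge.
    Returns (image, truth, true fiber list).
    """
    cols_per_row, cell_h, cell_w = 5, 30, 80
    nr = int(np.ceil(n_fibers / cols_per_row))
    shape = (nr * cell_h + 30, cols_per_row * cell_w + 30)
    rng = np.random.default_rng(seed)
    fibers = []
    for k in range(n_fibers):
        i, j = divmod(k, cols_per_row)
        row = 25.0 + i * cell_h + rng.uniform(-0.5, 0.5)
        fibers.append(straight_fiber(row, 20.0 + j * cell_w, length, width_um,
                                     peak=peak))
    cfg = sq.PhantomConfig(image_size_px=shape, pixel_size_um=pixel_size_um,
                           n_fibers=n_fibers, noise_sd=noise_sd, seed=seed,
                           tissue_full_frame=True)
    image, truth = sq.render_phantom(fibers, cfg)
    return image, truth, fibers


def rs_config(seed: int, size: int = 200) -> sq.PhantomConfig:
    """Reactive-stroma-like phantom: dense, bright, thick, aligned fibers."""
    return sq.PhantomConfig(image_size_px=(size, size), n_fibers=110,
                            shg_intensity_mean=140.0, width_mean_um=3.5,
                            kappa=3.0, mu_deg=40.0, noise_sd=6.0, seed=seed)


def ns_config(seed: int, size: int = 200) -> sq.PhantomConfig:
    """Normal-stroma-like phantom: dim, thin, isotropic fibers.

    Enough fibers are drawn that the ROI-level orientation average is
    meaningful — with only a handful of fibers the coherence of even
    isotropically oriented fibers is upward-biased by ~1/sqrt(n).
    """
    return sq.PhantomConfig(image_size_px=(size, size), n_fibers=45,
                            shg_intensity_mean=55.0, width_mean_um=2.0,
                            kappa=0.0, noise_sd=6.0, seed=seed)


@pytest.fixture(scope="session")
def default_phantom():
    cfg = sq.PhantomConfig(seed=11)
    image, truth = sq.generate_phantom(cfg)
    return cfg, image, truth
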