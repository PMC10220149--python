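"""Deterministic tiny test assets, generated in memory.

Everything other modules need for fast tests without touching disk: a small
flow series on a coarse grid, a velocity field with a known wrap, and the
two-voxel patches whose loss terms can be checked by hand.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .geometry import GeometryConfig, VoxelGrid, catalogue, synthesize_flow
from .mri import Acquisition, simulate_lr

__all__ = [
    "make_fixtures", "tiny_grid", "tiny_geometry",
    "patch_grid", "small_jet_geometry",
]


def patch_grid(shape=(96, 48, 48), spacing: float = 0.25) -> VoxelGrid:
    """Small patch-compatible grid: 24 x 12 x 12 mm, LR side 24 x 12 x 12.

    0.25 mm HR spacing keeps the LR voxel at 1 mm so a 12-voxel LR patch
    spans 12 mm and can reach the 20 % fluid-fraction bound for a 5 mm
    vessel; coarser grids cannot.
    """
    return VoxelGrid.create(shape, spacing=spacing)


def small_jet_geometry(n_frames: int = 8, **overrides) -> GeometryConfig:
    """Geometry 1 compressed into the small patch grid's 24 mm domain."""
    base = catalogue()[0]
    kw = dict(n_frames=n_frames, upstream_length=6.0,
              constriction_length=4.0, taper_length=2.0)
    kw.update(overrides)
    return replace(base, **kw)


def tiny_grid(spacing: float = 0.5, shape=(96, 48, 48)) -> VoxelGrid:
    """Coarse 48 x 24 x 24 mm grid; LR side 24 x 12 x 12 at factor 4."""
    return VoxelGrid.create(shape, spacing=spacing)


def tiny_geometry(n_frames: int = 8) -> GeometryConfig:
    """Geometry 1 shortened to a few frames for smoke tests."""
    return replace(catalogue()[0], n_frames=n_frames)


def make_fixtures(seed: int = 0) -> dict:
    """Small deterministic assets keyed by name.

    - ``flow``: an 8-frame flow series of the first catalogue geometry on a
      0.5 mm 96x48x48-voxel grid.
    - ``lr_wrapped``: an LR simulation of a uniform 2.0 m/s axial field
      acquired at VENC 1.5 m/s -- the x component is aliased by
      construction.
    - ``loss_patch``: (pred, target, mask) with one fluid and one non-fluid
      voxel and component errors 0.1 / 0.2, giving fluid MSE 0.01,
      non-fluid MSE 0.04.
    """
    rng = np.random.default_rng(seed)
    flow = synthesize_flow(tiny_geometry(), tiny_grid())

    shape = (16, 16, 16)
    vel = np.zeros(shape + (3,), dtype=np.float32)
    vel[..., 0] = 2.0
    mask = np.ones(shape, dtype=bool)
    acq = Acquisition(venc=(1.5, 1.5, 1.5), snr_db=40.0, intensity=120.0,
                      seed=int(rng.integers(2**31)))
    lr_wrapped = simulate_lr(vel, mask, acq, factor=4)

    pred = np.zeros((2, 1, 1, 3))
    target = np.zeros((2, 1, 1, 3))
    pred[0, 0, 0, 0] = 0.1   # fluid voxel, x error 0.1
    pred[1, 0, 0, 1] = 0.2   # non-fluid voxel, y error 0.2
    loss_mask = np.array([[[True]], [[False]]])

    return {
        "flow": flow,
        "lr_wrapped": lr_wrapped,
        "loss_patch": (pred, target, loss_mask),
        "seed": seed,
    }
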