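"""Venturi-style jet geometries and analytic high-resolution flow synthesis.

The training corpus for the super-resolution network is built from 20
idealised regurgitant-jet geometries: a straight cylindrical vessel with a
constricted waist (the leaking valve orifice), optionally angled by ``theta``
and/or offset by ``delta`` from the vessel axis to produce eccentric jets.
The first ten geometries vary inlet velocity ``v_I``, inlet radius ``R_I``
and constriction radius ``R_C``; the second ten inherit the third geometry's
radii and velocity and vary angle, offset and direction.

High-resolution velocity fields are produced by an analytic surrogate rather
than a Navier-Stokes solver: parabolic pipe flow upstream, a Gaussian-profile
jet of radius ~``R_C`` along the (possibly tilted/offset) constriction axis
downstream, the whole field modulated by a diastolic temporal envelope with a
rapid rise and slow decay.  The surrogate reproduces the statistical
structure the network needs (a thin fast jet, eccentricity, no-slip walls,
a diastolic waveform) without claiming solver-accurate physics.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

__all__ = [
    "Direction",
    "ShapeClass",
    "GeometryConfig",
    "VoxelGrid",
    "FlowSeries",
    "catalogue",
    "inlet_profile",
    "temporal_envelope",
    "synthesize_flow",
    "synthesize_frame",
    "geometry_mask",
    "knn_mask",
    "surface_points",
]


class ShapeClass(str, Enum):
    BASIC = "basic"
    ANGLED = "angled"
    OFFSET = "offset"
    COMBINED = "combined"


class Direction(str, Enum):
    NONE = "none"
    UPWARD = "upward"
    DOWNWARD = "downward"
    SIDEWAYS = "sideways"


#: In-plane (y, z) unit vectors for the named jet directions.  The flow axis
#: is +x; "upward" tilts/offsets toward +y, "downward" toward -y, "sideways"
#: toward +z.  Offset-only geometries with no named direction use +y.
_DIRECTION_YZ = {
    Direction.NONE: (1.0, 0.0),
    Direction.UPWARD: (1.0, 0.0),
    Direction.DOWNWARD: (-1.0, 0.0),
    Direction.SIDEWAYS: (0.0, 1.0),
}


@dataclass(frozen=True)
class GeometryConfig:
    """Parameters of one constricted-vessel geometry.

    Lengths are millimetres, velocities metres per second, angles degrees.
    """

    id: int
    shape_class: ShapeClass
    v_I: float          # maximum (centreline) inlet velocity, m/s
    R_I: float          # inlet radius, mm
    R_C: float          # constriction radius, mm
    theta: float = 0.0  # constriction angle vs the inlet normal, degrees
    delta: float = 0.0  # constriction offset from the vessel axis, mm
    direction: Direction = Direction.NONE
    upstream_length: float = 20.0   # mm of straight vessel before the waist
    constriction_length: float = 10.0  # mm, axial extent of the waist
    taper_length: float = 4.0       # mm, smooth entrance/exit taper
    n_frames: int = 71
    dt: float = 0.001               # s
    tau: float = 0.015              # s, diastolic envelope peak time
    jet_gain: float = 1.0           # scales the jet core velocity
    cfd_peak_speed: float | None = None  # reference peak jet speed, m/s

    def __post_init__(self) -> None:
        if not self.R_C < self.R_I:
            raise ValueError(f"R_C ({self.R_C}) must be < R_I ({self.R_I})")
        if self.v_I <= 0:
            raise ValueError("v_I must be positive")
        if self.theta < 0 or self.delta < 0:
            raise ValueError("theta and delta must be non-negative")
        if self.shape_class is ShapeClass.BASIC and (self.theta or self.delta):
            raise ValueError("basic geometries have theta = delta = 0")

    @property
    def peak_jet_speed(self) -> float:
        """Nominal jet core speed from flux conservation, m/s.

        A parabolic inlet profile carries flux ``pi R_I^2 v_I / 2``; pushing
        it through the waist of radius ``R_C`` as a Gaussian jet with
        ``sigma = R_C / sqrt(2)`` gives a core speed of
        ``v_I R_I^2 / (2 R_C^2)``, scaled by ``jet_gain``.
        """
        return self.jet_gain * self.v_I * self.R_I**2 / (2.0 * self.R_C**2)

    @property
    def direction_yz(self) -> np.ndarray:
        return np.asarray(_DIRECTION_YZ[self.direction])


@dataclass(frozen=True)
class VoxelGrid:
    """Uniform isotropic Cartesian grid; x is the flow axis.

    Coordinates are voxel-centred and 0-based: voxel ``(i, j, k)`` is at
    ``origin + spacing * (i, j, k)`` mm.
    """

    shape: tuple[int, int, int]
    spacing: float                      # mm per voxel
    origin: tuple[float, float, float]  # mm, centre of voxel (0, 0, 0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @classmethod
    def create(cls, shape: tuple[int, int, int], spacing: float) -> "VoxelGrid":
        """Grid with x starting at 0 and the y/z cross-section centred on 0."""
        nx, ny, nz = shape
        origin = (
            spacing / 2.0,
            -(ny - 1) / 2.0 * spacing,
            -(nz - 1) / 2.0 * spacing,
        )
        return cls(shape=(nx, ny, nz), spacing=spacing, origin=origin)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates along each axis, mm."""
        return tuple(
            self.origin[a] + self.spacing * np.arange(self.shape[a])
            for a in range(3)
        )

    def voxel_centres(self) -> np.ndarray:
        """All voxel centres as an ``(N, 3)`` array, mm (C order)."""
        x, y, z = self.axes()
        g = np.meshgrid(x, y, z, indexing="ij")
        return np.stack([c.ravel() for c in g], axis=1)


# default HR test grid: 0.25 mm spacing over a 64 x 24 x 24 mm domain.  This
# is the coarsest isotropic grid at which a 12-voxel LR patch (12 mm across
# after x4 downsampling) can reach the 20 % minimum fluid fraction for a
# 5 mm-radius vessel.
DEFAULT_GRID = VoxelGrid.create((256, 96, 96), spacing=0.25)

#: (id, v_I [m/s], R_I [mm], R_C [mm], reference peak speed [m/s])
_BASIC_ROWS = [
    (1, 0.30, 5.0, 1.00, 3.82),
    (2, 0.15, 5.0, 1.00, 1.92),
    (3, 0.50, 5.0, 1.50, 2.88),
    (4, 0.10, 5.0, 0.75, 2.29),
    (5, 0.10, 5.0, 0.60, 3.58),
    (6, 0.45, 8.0, 2.00, 2.22),
    (7, 0.45, 6.0, 2.00, 2.09),
    (8, 0.10, 8.0, 1.00, 2.27),
    (9, 0.15, 10.0, 2.00, 2.62),
    (10, 0.10, 10.0, 1.50, 2.96),
]

#: (id, theta [deg], delta [mm], direction, reference peak speed [m/s]);
#: these inherit v_I, R_I, R_C from geometry 3.
_SHAPED_ROWS = [
    (11, 20.0, 0.00, Direction.UPWARD, 3.47),
    (12, 40.0, 0.00, Direction.UPWARD, 4.65),
    (13, 0.0, 1.50, Direction.NONE, 3.27),
    (14, 0.0, 3.00, Direction.NONE, 3.18),
    (15, 20.0, 1.50, Direction.UPWARD, 3.37),
    (16, 40.0, 1.50, Direction.UPWARD, 4.32),
    (17, 20.0, 3.00, Direction.UPWARD, 3.28),
    (18, 40.0, 3.00, Direction.UPWARD, 4.12),
    (19, 30.0, 2.25, Direction.SIDEWAYS, 3.88),
    (20, 30.0, 2.25, Direction.DOWNWARD, 4.48),
]


def catalogue() -> list[GeometryConfig]:
    """The 20-geometry catalogue: 10 basic + 10 angled/offset variants."""
    out = [
        GeometryConfig(
            id=i, shape_class=ShapeClass.BASIC, v_I=v, R_I=ri, R_C=rc,
            cfd_peak_speed=pk,
        )
        for i, v, ri, rc, pk in _BASIC_ROWS
    ]
    base = out[2]  # geometry 3
    for i, theta, delta, direction, pk in _SHAPED_ROWS:
        if theta > 0 and delta > 0:
            cls = ShapeClass.COMBINED
        elif theta > 0:
            cls = ShapeClass.ANGLED
        else:
            cls = ShapeClass.OFFSET
        out.append(
            GeometryConfig(
                id=i, shape_class=cls, v_I=base.v_I, R_I=base.R_I,
                R_C=base.R_C, theta=theta, delta=delta, direction=direction,
                cfd_peak_speed=pk,
            )
        )
    return out


def inlet_profile(x, y, v_I: float, R_I: float):
    """Parabolic axial speed at inlet position ``(x, y)`` mm, m/s.

    ``v = v_I - (x^2 + y^2) v_I / R_I^2``: maximal at the centre, zero on
    the rim.  Points outside the inlet disc raise ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = x**2 + y**2
    if np.any(r2 > R_I**2 * (1.0 + 1e-12)):
        raise ValueError("point outside the inlet disc")
    return v_I - r2 * v_I / R_I**2


def temporal_envelope(t, tau: float):
    """Diastolic waveform surrogate ``g(t) = (t/tau) exp(1 - t/tau)``.

    Dimensionless, in [0, 1]: zero at t = 0, unique peak g(tau) = 1, then a
    slow decay -- a rapid filling phase followed by gradual tapering of the
    regurgitant flow.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    u = t / tau
    return u * np.exp(1.0 - u)


def _centreline(geom: GeometryConfig, x: np.ndarray) -> np.ndarray:
    """In-plane (y, z) centreline of the constricted channel vs x, mm.

    Zero upstream, ramping to the offset ``delta`` over the entrance taper,
    then drifting at ``tan(theta)`` per mm of axial distance through and past
    the waist.  Clamped so the channel stays inside the outer vessel.
    """
    x0 = geom.upstream_length
    x1 = x0 + geom.constriction_length
    t = geom.taper_length
    d = geom.direction_yz
    tan_th = np.tan(np.radians(geom.theta))

    ramp = np.clip((x - (x0 - t)) / t, 0.0, 1.0)
    ramp = 0.5 - 0.5 * np.cos(np.pi * ramp)  # cosine blend 0 -> 1
    mag = geom.delta * ramp + tan_th * np.clip(x - x0, 0.0, None)

    limit = geom.R_I - geom.R_C
    mag = np.clip(mag, 0.0, max(limit, 0.0))
    return mag[:, None] * d[None, :]


def _radius_profile(geom: GeometryConfig, x: np.ndarray) -> np.ndarray:
    """Local channel radius r(x), mm: R_I -> R_C -> R_I with cosine tapers."""
    x0 = geom.upstream_length
    x1 = x0 + geom.constriction_length
    t = geom.taper_length
    r = np.full_like(x, geom.R_I, dtype=float)

    enter = (x >= x0 - t) & (x < x0)
    blend = 0.5 - 0.5 * np.cos(np.pi * (x[enter] - (x0 - t)) / t)
    r[enter] = geom.R_I + (geom.R_C - geom.R_I) * blend

    r[(x >= x0) & (x <= x1)] = geom.R_C

    exit_ = (x > x1) & (x <= x1 + t)
    blend = 0.5 - 0.5 * np.cos(np.pi * (x[exit_] - x1) / t)
    r[exit_] = geom.R_C + (geom.R_I - geom.R_C) * blend
    return r


def geometry_mask(geom: GeometryConfig, grid: VoxelGrid) -> np.ndarray:
    """Boolean fluid mask on ``grid``: inside the constricted channel."""
    xs, ys, zs = grid.axes()
    c = _centreline(geom, xs)          # (nx, 2)
    r = _radius_profile(geom, xs)      # (nx,)
    dy = ys[None, :, None] - c[:, 0, None, None]
    dz = zs[None, None, :] - c[:, 1, None, None]
    return dy**2 + dz**2 < (r**2)[:, None, None]


def _spatial_velocity(geom: GeometryConfig, grid: VoxelGrid) -> np.ndarray:
    """Peak-time velocity field (x, y, z, 3), m/s, before envelope scaling.

    Upstream: parabolic axial pipe flow.  Downstream of the waist entrance:
    a Gaussian-profile jet along the (clamped) constriction centreline, with
    core speed from flux conservation, decaying and spreading past the waist
    exit.  The two are blended over the entrance taper.  No-slip is enforced
    by zeroing velocity at masked-out voxels and at the one-voxel fluid
    boundary layer.
    """
    xs, ys, zs = grid.axes()
    nx, ny, nz = grid.shape
    x0 = geom.upstream_length
    x1 = x0 + geom.constriction_length
    tp = geom.taper_length

    c = _centreline(geom, xs)                       # (nx, 2)
    dc = np.gradient(c, xs, axis=0)                 # d(centreline)/dx
    # unit tangent of the jet path per x-slice
    tang = np.concatenate([np.ones((nx, 1)), dc], axis=1)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)

    dy = ys[None, :, None] - c[:, 0, None, None]    # (nx, ny, 1)
    dz = zs[None, None, :] - c[:, 1, None, None]    # (nx, 1, nz)
    rho2_jet = np.broadcast_to(dy**2 + dz**2, (nx, ny, nz))

    # --- upstream parabolic profile (about the vessel axis) ---
    rho2_pipe = (ys**2)[None, :, None] + (zs**2)[None, None, :]
    v_para = geom.v_I * np.clip(1.0 - rho2_pipe / geom.R_I**2, 0.0, None)
    v_para = np.broadcast_to(v_para, (nx, ny, nz))

    # --- jet along the constriction path ---
    v0 = geom.peak_jet_speed
    sigma0 = geom.R_C / np.sqrt(2.0)
    s_decay = 20.0  # mm, downstream decay/spreading length scale
    s_past = np.clip(xs - x1, 0.0, None)
    amp = v0 / (1.0 + s_past / s_decay)             # (nx,)
    sigma = sigma0 * np.sqrt(1.0 + s_past / s_decay)
    v_jet = amp[:, None, None] * np.exp(
        -rho2_jet / (2.0 * (sigma**2)[:, None, None])
    )

    # blend parabolic -> jet over the entrance taper
    w = np.clip((xs - (x0 - tp)) / tp, 0.0, 1.0)
    w = 0.5 - 0.5 * np.cos(np.pi * w)
    speed = (1.0 - w[:, None, None]) * v_para + w[:, None, None] * v_jet

    vel = speed[..., None] * tang[:, None, None, :]

    mask = geometry_mask(geom, grid)
    core = binary_erosion(mask)
    vel *= core[..., None]
    return vel.astype(np.float32)


@dataclass
class FlowSeries:
    """Time-resolved HR velocity field on a Cartesian grid.

    ``velocity`` has shape ``(n_frames, nx, ny, nz, 3)`` in m/s and is zero
    at every non-fluid voxel; ``mask`` is the static fluid partition.
    """

    grid: VoxelGrid
    velocity: np.ndarray
    mask: np.ndarray
    times: np.ndarray
    geometry: GeometryConfig | None = None

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]


def synthesize_frame(
    geom: GeometryConfig, grid: VoxelGrid, frame: int,
    _spatial: np.ndarray | None = None,
) -> np.ndarray:
    """One HR velocity frame ``(nx, ny, nz, 3)``, m/s.

    The surrogate is separable in time: frame ``f`` is the peak-time spatial
    field scaled by the envelope at ``t = f * dt``.  Passing a precomputed
    ``_spatial`` field avoids recomputation when streaming frames.
    """
    if _spatial is None:
        _spatial = _spatial_velocity(geom, grid)
    g = float(temporal_envelope(frame * geom.dt, geom.tau))
    return _spatial * np.float32(g)


def synthesize_flow(geom: GeometryConfig, grid: VoxelGrid | None = None) -> FlowSeries:
    """Full HR flow series for one geometry (deterministic, no RNG)."""
    if grid is None:
        grid = DEFAULT_GRID
    if geom.R_C < grid.spacing:
        raise ValueError(
            f"constriction radius {geom.R_C} mm is not representable at "
            f"{grid.spacing} mm spacing"
        )
    spatial = _spatial_velocity(geom, grid)
    times = np.arange(geom.n_frames) * geom.dt
    g = temporal_envelope(times, geom.tau).astype(np.float32)
    velocity = spatial[None] * g[:, None, None, None, None]
    return FlowSeries(
        grid=grid, velocity=velocity, mask=geometry_mask(geom, grid),
        times=times, geometry=geom,
    )


def knn_mask(
    fluid_points: np.ndarray,
    wall_points: np.ndarray,
    grid: VoxelGrid,
    k: int = 1,
) -> np.ndarray:
    """Fluid mask by majority vote of the k nearest labelled points.

    Mirrors mask generation from an unstructured solver mesh: each voxel
    centre is fluid iff the majority of its ``k`` (odd) Euclidean-nearest
    points, over the union of both clouds, are fluid points.
    """
    fluid_points = np.atleast_2d(np.asarray(fluid_points, dtype=float))
    wall_points = np.atleast_2d(np.asarray(wall_points, dtype=float))
    if fluid_points.size == 0 or wall_points.size == 0:
        raise ValueError("both point sets must be non-empty")
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be a positive odd integer")
    pts = np.vstack([fluid_points, wall_points])
    labels = np.zeros(len(pts), dtype=bool)
    labels[: len(fluid_points)] = True
    tree = cKDTree(pts)
    _, idx = tree.query(grid.voxel_centres(), k=k)
    votes = labels[idx]
    if k > 1:
        fluid = votes.sum(axis=1) * 2 > k
    else:
        fluid = votes.ravel()
    return fluid.reshape(grid.shape)


def surface_points(
    geom: GeometryConfig, n_axial: int = 80, n_ring: int = 24,
    x_max: float = 64.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic stand-in for a solver mesh: (fluid, wall) point clouds, mm.

    Fluid points sample the channel interior on rings at fractions of the
    local radius; wall points sit on the channel surface.
    """
    xs = np.linspace(0.5, x_max - 0.5, n_axial)
    c = _centreline(geom, xs)
    r = _radius_profile(geom, xs)
    ang = np.linspace(0.0, 2 * np.pi, n_ring, endpoint=False)
    unit = np.stack([np.cos(ang), np.sin(ang)], axis=1)  # (n_ring, 2)

    wall, fluid = [], []
    for i, x in enumerate(xs):
        ring = c[i] + r[i] * unit
        wall.append(np.column_stack([np.full(n_ring, x), ring]))
        for frac in (0.0, 0.45, 0.8):
            ring_f = c[i] + frac * r[i] * unit
            fluid.append(np.column_stack([np.full(n_ring, x), ring_f]))
    return np.vstack(fluid), np.vstack(wall)
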