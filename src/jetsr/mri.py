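"""Forward model of a 4D-flow MR acquisition from an HR velocity field.

Phase-contrast MRI encodes velocity in the phase of a complex image: a
velocity equal to the chosen VENC maps to a 180 degree phase shift, and
speeds beyond VENC wrap around (velocity aliasing).  The simulator forms the
complex image ``intensity * exp(i pi v / venc)`` on the HR grid per velocity
component, truncates the central region of k-space to downsample by 4,
adds complex Gaussian noise at a prescribed SNR in the LR image, and decodes
velocity from the noisy phase.  The augmentation policy draws per-component
VENCs from the 0.3..6.0 m/s grid (deliberately aliasing with 10 %
probability), a constant magnitude intensity in 60..240, and an SNR in
14..17 dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

__all__ = [
    "VENC_GRID",
    "Acquisition",
    "LRSample",
    "velocity_to_phase",
    "decode_velocity",
    "simulate_lr",
    "sample_acquisition",
    "downsample_mask",
]

#: The VENC menu: 0.3 to 6.0 m/s in steps of 0.3.
VENC_GRID = np.round(np.arange(1, 21) * 0.3, 10)

#: Magnitude level of static (non-fluid) tissue relative to fluid.
TISSUE_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class Acquisition:
    """One simulated scan: per-component VENC, SNR, intensity and RNG seed."""

    venc: tuple[float, float, float]  # m/s per velocity component
    snr_db: float                     # magnitude SNR in decibels
    intensity: float                  # constant fluid magnitude level
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.venc):
            raise ValueError("venc values must be positive")

    @property
    def noise_sigma(self) -> float:
        """Std of the Gaussian noise on each of the real/imaginary parts."""
        return self.intensity / 10.0 ** (self.snr_db / 20.0)


@dataclass
class LRSample:
    """A simulated LR acquisition of one HR frame.

    ``velocity`` is decoded from wrapped phase and therefore bounded by the
    per-component VENC; ``magnitude`` carries one channel per velocity
    component (each component's acquisition has independent noise).
    """

    velocity: np.ndarray          # (x', y', z', 3), m/s
    magnitude: np.ndarray         # (x', y', z', 3)
    mask: np.ndarray              # (x', y', z') LR fluid mask
    acquisition: Acquisition
    downsample_factor: int = 4
    aliased: tuple[bool, bool, bool] = (False, False, False)


def velocity_to_phase(v, venc: float):
    """Encode velocity as phase, wrapped into (-pi, pi].

    ``phi = pi v / venc`` modulo 2 pi; invertible iff ``|v| < venc``.
    """
    if venc <= 0:
        raise ValueError("venc must be positive")
    phi = np.pi * np.asarray(v, dtype=float) / venc
    # wrap into (-pi, pi]: the boundary maps to +pi
    wrapped = np.mod(-phi + np.pi, 2.0 * np.pi)
    return np.pi - wrapped


def decode_velocity(phase, venc: float):
    """Inverse phase encoding: ``v = venc * phase / pi``."""
    return np.asarray(phase, dtype=float) * venc / np.pi


def _truncate_kspace(img: np.ndarray, factor: int) -> np.ndarray:
    """Central k-space crop by ``factor`` per axis + inverse transform.

    Amplitude-preserving for the DC component: a spatially constant field
    survives the truncation exactly.
    """
    shape_hr = img.shape
    shape_lr = tuple(s // factor for s in shape_hr)
    k = scipy.fft.fftshift(scipy.fft.fftn(img, workers=1))
    sl = tuple(
        slice(hs // 2 - ls // 2, hs // 2 - ls // 2 + ls)
        for hs, ls in zip(shape_hr, shape_lr)
    )
    k_lr = scipy.fft.ifftshift(k[sl])
    scale = np.prod(shape_lr) / np.prod(shape_hr)
    return scipy.fft.ifftn(k_lr, workers=1) * scale


def downsample_mask(mask: np.ndarray, factor: int = 4) -> np.ndarray:
    """LR fluid mask: a block is fluid iff at least half its HR voxels are."""
    nx, ny, nz = (s // factor for s in mask.shape)
    blocks = mask[: nx * factor, : ny * factor, : nz * factor].reshape(
        nx, factor, ny, factor, nz, factor
    )
    return blocks.mean(axis=(1, 3, 5)) >= 0.5


def simulate_lr(
    hr_velocity: np.ndarray,
    mask: np.ndarray,
    acq: Acquisition,
    factor: int = 4,
    air_mask: np.ndarray | None = None,
) -> LRSample:
    """Simulate one LR MR frame from an HR velocity frame.

    Per component: form the complex image on the HR grid with phase
    ``pi v / venc`` and magnitude ``intensity`` in fluid (a third of that in
    static tissue, near zero in ``air_mask`` voxels if given), truncate
    central k-space by ``factor`` per axis, add zero-mean Gaussian noise of
    std ``intensity / 10^(snr_db/20)`` independently to the real and
    imaginary parts of the LR image, and decode velocity from the noisy
    phase.  The per-component ``aliased`` flag records whether the VENC was
    below that component's true peak speed.
    """
    if factor <= 0:
        raise ValueError("downsample factor must be positive")
    if any(s % factor for s in hr_velocity.shape[:3]):
        pad = [
            (0, (-s) % factor) for s in hr_velocity.shape[:3]
        ]
        hr_velocity = np.pad(hr_velocity, pad + [(0, 0)])
        mask = np.pad(mask, pad)
        if air_mask is not None:
            air_mask = np.pad(air_mask, pad)

    magnitude_hr = np.where(mask, acq.intensity, acq.intensity * TISSUE_FRACTION)
    if air_mask is not None:
        magnitude_hr = np.where(air_mask, acq.intensity * 0.02, magnitude_hr)

    rng = np.random.default_rng(acq.seed)
    vel_lr, mag_lr, aliased = [], [], []
    for j in range(3):
        venc = acq.venc[j]
        v = hr_velocity[..., j]
        phase = np.pi * v / venc  # fftn wraps implicitly via exp
        img = (magnitude_hr * np.exp(1j * phase)).astype(np.complex64)
        lr = _truncate_kspace(img, factor)
        sigma = acq.noise_sigma
        noise = rng.normal(0.0, sigma, lr.shape) + 1j * rng.normal(
            0.0, sigma, lr.shape
        )
        lr = lr + noise
        vel_lr.append(decode_velocity(np.angle(lr), venc))
        mag_lr.append(np.abs(lr))
        aliased.append(bool(venc < np.abs(v).max()))

    return LRSample(
        velocity=np.stack(vel_lr, axis=-1).astype(np.float32),
        magnitude=np.stack(mag_lr, axis=-1).astype(np.float32),
        mask=downsample_mask(mask, factor),
        acquisition=acq,
        downsample_factor=factor,
        aliased=tuple(aliased),
    )


def sample_acquisition(
    rng: np.random.Generator,
    max_speed,
    alias_prob: float = 0.10,
    seed: int | None = None,
) -> Acquisition:
    """Draw one augmentation policy sample.

    Per component: with probability ``1 - alias_prob`` the smallest VENC on
    the 0.3-grid strictly above that component's peak speed (clamped to the
    6.0 m/s menu top); with probability ``alias_prob`` a deliberately
    aliasing VENC 0.3-0.6 m/s below the peak speed, snapped to the nearest
    grid value and floored at 0.3.  Intensity is uniform over the integers
    60..240 and SNR uniform over [14, 17] dB.
    """
    if not 0.0 <= alias_prob <= 1.0:
        raise ValueError("alias_prob must be in [0, 1]")
    max_speed = np.broadcast_to(np.asarray(max_speed, dtype=float), (3,))
    if np.any(max_speed <= 0):
        raise ValueError("max_speed must be positive")

    venc = []
    for ms in max_speed:
        if rng.random() < alias_prob:
            raw = ms - rng.uniform(0.3, 0.6)
            v = np.round(raw / 0.3) * 0.3
            v = float(np.clip(v, VENC_GRID[0], VENC_GRID[-1]))
        else:
            above = VENC_GRID[VENC_GRID > ms]
            v = float(above[0]) if above.size else float(VENC_GRID[-1])
        venc.append(round(v, 10))

    return Acquisition(
        venc=tuple(venc),
        snr_db=float(rng.uniform(14.0, 17.0)),
        intensity=float(rng.integers(60, 241)),
        seed=int(rng.integers(0, 2**31 - 1)) if seed is None else seed,
    )
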