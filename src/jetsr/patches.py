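"""Paired LR/HR training patches and full-volume stitching.

Training samples are 12-voxel LR cubes (3 decoded velocity + 3 magnitude
channels) paired with the co-located 48-voxel HR velocity cube (x4 per
axis).  Patch corners are rejection-sampled until at least 20 % of the LR
patch is fluid; each accepted patch is duplicated under a random proper
90-degree cube rotation, with the velocity *vectors* rotated by the same
matrix.  Full-volume predictions are reassembled from overlapping patches
on a stride-(n-4) lattice with a 4-voxel strip from each patch side.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import permutations

import numpy as np

__all__ = [
    "PatchPair",
    "ROTATIONS",
    "rotation_matrices",
    "apply_rotation",
    "rotate_pair",
    "sample_patches",
    "patch_lattice",
    "stitch",
    "LR_PATCH", "HR_PATCH", "UPSAMPLE",
]

LR_PATCH = 12
HR_PATCH = 48
UPSAMPLE = 4
STRIDE = LR_PATCH - 4   # LR-voxel stride between patch origins
STRIP = 4               # HR voxels stripped from each patch side


def rotation_matrices() -> np.ndarray:
    """The 24 proper (det = +1) signed-permutation 3x3 matrices."""
    mats = []
    for perm in permutations(range(3)):
        for signs in np.ndindex(2, 2, 2):
            m = np.zeros((3, 3), dtype=int)
            for row, col in enumerate(perm):
                m[row, col] = 1 - 2 * signs[row]
            if round(np.linalg.det(m)) == 1:
                mats.append(m)
    mats.sort(key=lambda m: m.ravel().tolist(), reverse=True)
    return np.array(mats)


#: Fixed, deterministic ordering; index 0 is the identity.
ROTATIONS = rotation_matrices()
assert (ROTATIONS[0] == np.eye(3, dtype=int)).all()


def apply_rotation(
    vol: np.ndarray, rot: np.ndarray, vector_channels: bool = False
) -> np.ndarray:
    """Rotate a cubic patch about its centre by a signed permutation matrix.

    ``vol`` has spatial axes first (``(n, n, n)`` or ``(n, n, n, c)``).  With
    ``vector_channels`` the last axis holds an (x, y, z) vector field that is
    transformed by the same matrix (component permutation + sign flips).
    """
    rot = np.asarray(rot)
    if rot.shape != (3, 3) or not np.isin(rot, (-1, 0, 1)).all() \
            or round(abs(np.linalg.det(rot))) != 1:
        raise ValueError("rotation must be a signed permutation matrix")
    if round(np.linalg.det(rot)) != 1:
        raise ValueError("rotation must be orientation-preserving")

    # out[i'] = in[i] with i'_a depending on source axis src[a] = argmax|R[a,:]|
    src = [int(np.flatnonzero(rot[a])[0]) for a in range(3)]
    sign = [int(rot[a, src[a]]) for a in range(3)]
    axes = src + list(range(3, vol.ndim))
    out = vol.transpose(axes)
    flip = [a for a in range(3) if sign[a] < 0]
    if flip:
        out = np.flip(out, axis=flip)
    out = np.ascontiguousarray(out)
    if vector_channels:
        out = np.einsum("ab,...b->...a", rot.astype(out.dtype), out)
    return out


@dataclass
class PatchPair:
    """One LR input patch with its HR target patch.

    ``lr`` is ``(12, 12, 12, 6)``: decoded velocity (m/s) then per-component
    magnitude; ``hr`` is ``(48, 48, 48, 3)`` velocity; ``hr_mask`` the HR
    fluid partition used by the region-split loss.  ``origin`` is the LR
    corner index; the HR corner is ``4 * origin``.
    """

    lr: np.ndarray
    hr: np.ndarray
    hr_mask: np.ndarray
    venc: np.ndarray              # (3,) m/s, per (rotated) component
    fluid_fraction: float
    origin: tuple[int, int, int]
    rotation: int = 0             # index into ROTATIONS


def rotate_pair(pair: PatchPair, rotation: int | np.ndarray) -> PatchPair:
    """Rotated duplicate of a patch pair.

    Spatial axes of every field are permuted/flipped; the velocity channels
    (LR channels 0-2 and all HR channels) are transformed by the same
    rotation matrix; magnitude channels move spatially only.  The
    per-component VENC triple permutes with the components.
    """
    if isinstance(rotation, (int, np.integer)):
        idx, rot = int(rotation), ROTATIONS[int(rotation)]
    else:
        rot = np.asarray(rotation)
        matches = np.flatnonzero((ROTATIONS == rot).all(axis=(1, 2)))
        if matches.size == 0:
            raise ValueError("not one of the 24 proper cube rotations")
        idx = int(matches[0])

    lr_vel = apply_rotation(pair.lr[..., :3], rot, vector_channels=True)
    lr_mag = apply_rotation(pair.lr[..., 3:], rot)
    # magnitude channels follow their component's axis relabelling
    src = [int(np.flatnonzero(rot[a])[0]) for a in range(3)]
    lr_mag = lr_mag[..., src]
    hr = apply_rotation(pair.hr, rot, vector_channels=True)
    hr_mask = apply_rotation(pair.hr_mask, rot)
    venc = np.abs(rot) @ pair.venc
    return replace(
        pair,
        lr=np.concatenate([lr_vel, lr_mag], axis=-1),
        hr=hr, hr_mask=hr_mask, venc=venc, rotation=idx,
    )


def sample_patches(
    lr_sample,
    hr_frame: np.ndarray,
    hr_mask: np.ndarray,
    rng: np.random.Generator,
    n_base: int = 10,
    min_fluid: float = 0.20,
    max_attempts: int = 1000,
) -> list[PatchPair]:
    """Sample ``2 * n_base`` patch pairs from one frame.

    ``n_base`` corners are rejection-sampled uniformly until the LR fluid
    fraction reaches ``min_fluid``; each accepted patch contributes itself
    plus one duplicate under a random non-identity rotation (which copies
    the base patch's noise).  Raises ``RuntimeError`` if ``max_attempts``
    corner draws cannot satisfy the fluid bound.
    """
    lr_vol = np.concatenate([lr_sample.velocity, lr_sample.magnitude], axis=-1)
    lr_mask = lr_sample.mask
    venc = np.asarray(lr_sample.acquisition.venc, dtype=float)
    shape = lr_mask.shape
    if any(s < LR_PATCH for s in shape):
        raise ValueError("LR volume must be at least 12 voxels per axis")
    hi = [s - LR_PATCH for s in shape]

    pairs: list[PatchPair] = []
    for _ in range(n_base):
        for attempt in range(max_attempts):
            c = tuple(int(rng.integers(0, h + 1)) for h in hi)
            sl = tuple(slice(o, o + LR_PATCH) for o in c)
            frac = float(lr_mask[sl].mean())
            if frac >= min_fluid:
                break
        else:
            raise RuntimeError(
                f"no corner with fluid fraction >= {min_fluid} found in "
                f"{max_attempts} attempts"
            )
        hsl = tuple(
            slice(UPSAMPLE * o, UPSAMPLE * o + HR_PATCH) for o in c
        )
        pair = PatchPair(
            lr=np.ascontiguousarray(lr_vol[sl]),
            hr=np.ascontiguousarray(hr_frame[hsl]),
            hr_mask=np.ascontiguousarray(hr_mask[hsl]),
            venc=venc.copy(),
            fluid_fraction=frac,
            origin=c,
        )
        pairs.append(pair)
        rot_idx = int(rng.integers(1, len(ROTATIONS)))  # never the identity
        pairs.append(rotate_pair(pair, rot_idx))
    return pairs


def patch_lattice(length: int, patch: int = LR_PATCH, stride: int = STRIDE) -> list[int]:
    """Patch origins along one LR axis: stride-(n-4), clamped to the end."""
    if length < patch:
        raise ValueError(f"axis of length {length} cannot host a {patch} patch")
    last = length - patch
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)
    return origins


def stitch(
    patches: list[tuple[tuple[int, int, int], np.ndarray]],
    out_shape: tuple[int, int, int],
    strip: int = STRIP,
) -> np.ndarray:
    """Assemble a full SR volume from overlapping HR patches.

    ``patches`` holds ``(lr_origin, hr_patch)`` pairs whose origins form a
    stride-(n-4) lattice in LR index space.  ``strip`` HR voxels are
    discarded from each patch side to avoid boundary artifacts, except where
    the patch touches the volume edge (so the output has no holes); residual
    overlaps resolve last-writer-wins in lattice order.
    """
    first = patches[0][1]
    nchan = first.shape[3:]
    hr_patch = first.shape[0]
    out = np.zeros(tuple(out_shape) + nchan, dtype=first.dtype)
    covered = np.zeros(out_shape, dtype=bool)

    for origin, hrp in sorted(patches, key=lambda p: p[0]):
        if hrp.shape[:3] != (hr_patch,) * 3:
            raise ValueError("inconsistent patch shapes")
        lo_out, hi_out, lo_in, hi_in = [], [], [], []
        for a in range(3):
            start = UPSAMPLE * origin[a]
            s = 0 if start == 0 else strip
            e = 0 if start + hr_patch == out_shape[a] else strip
            if start + hr_patch > out_shape[a]:
                raise ValueError("patch extends past the output volume")
            lo_out.append(start + s)
            hi_out.append(start + hr_patch - e)
            lo_in.append(s)
            hi_in.append(hr_patch - e)
        osl = tuple(slice(lo, hi) for lo, hi in zip(lo_out, hi_out))
        isl = tuple(slice(lo, hi) for lo, hi in zip(lo_in, hi_in))
        out[osl] = hrp[isl]
        covered[osl] = True

    if not covered.all():
        raise ValueError("patch lattice does not cover the output volume")
    return out
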