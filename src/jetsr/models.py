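"""Super-resolution network variants and full-volume prediction.

The architecture upsamples a 12-voxel LR patch (3 velocity + 3 magnitude
channels) to a 48-voxel SR velocity patch: two 2-conv input branches
(velocity, magnitude) are merged by a 1x1 convolution, ``lr_blocks`` blocks
denoise in LR space, a central non-learned trilinear x4 resize followed by a
convolution moves to HR space, ``hr_blocks`` blocks refine, and three
single-component heads emit the velocity components.  The block family
(res / dense / csp) is the only difference between the variants.

Velocity channels are VENC-normalised to [-1, 1] at the input and rescaled
at the output; magnitude channels are normalised by the maximum magnitude
intensity (240).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import Conv1x1, Conv3d, LeakyReLU, Module, Sequential, Upsample3d
from .nn.blocks import make_block
from .patches import HR_PATCH, LR_PATCH, UPSAMPLE, patch_lattice, stitch

__all__ = [
    "NetworkSpec", "SRNet", "build", "count_parameters", "predict_volume",
    "save_checkpoint", "load_checkpoint", "MAGNITUDE_SCALE",
]

#: Magnitude channels are normalised by the top of the intensity range.
MAGNITUDE_SCALE = 240.0


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyper-parameters.

    Defaults reproduce the full-size residual variant (3.34 M parameters);
    ``channels``, block counts and ``head_depth`` scale the network down for
    CPU-sized experiments without changing its structure.
    """

    variant: str = "res"            # res | dense | csp
    lr_blocks: int = 8
    hr_blocks: int = 4
    channels: int = 64
    growth_rate: int = 16
    dense_depth: int = 4
    csp_part_fraction: float = 0.25
    upsample_factor: int = UPSAMPLE
    in_patch: int = LR_PATCH
    out_patch: int = HR_PATCH
    head_depth: int = 2             # convs per output head (last is C -> 1)
    init: str = "he"                # trunk weight init: he | dirac
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("res", "dense", "csp"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.out_patch != self.in_patch * self.upsample_factor:
            raise ValueError("out_patch must equal in_patch * upsample_factor")


class SRNet(Module):
    """The assembled super-resolution network."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        C = spec.channels
        rng = np.random.default_rng(spec.seed)

        init = spec.init

        def block(name):
            return make_block(
                spec.variant, C, rng, growth=spec.growth_rate,
                depth=spec.dense_depth, part_fraction=spec.csp_part_fraction,
                name=name, init=init,
            )

        self.vel_branch = Sequential(
            Conv3d(3, C, rng, "vel.conv1", init=init), LeakyReLU(),
            Conv3d(C, C, rng, "vel.conv2", init=init), LeakyReLU(),
        )
        self.mag_branch = Sequential(
            Conv3d(3, C, rng, "mag.conv1", init=init), LeakyReLU(),
            Conv3d(C, C, rng, "mag.conv2", init=init), LeakyReLU(),
        )
        self.merge = Sequential(
            Conv1x1(2 * C, C, rng, "merge", init=init), LeakyReLU())
        self.lr_stack = Sequential(
            *[block(f"lr{i}") for i in range(spec.lr_blocks)]
        )
        self.upsample = Upsample3d(spec.upsample_factor)
        self.post_up = Sequential(
            Conv3d(C, C, rng, "up.conv", init=init), LeakyReLU())
        self.hr_stack = Sequential(
            *[block(f"hr{i}") for i in range(spec.hr_blocks)]
        )
        self.heads = []
        for j, comp in enumerate("xyz"):
            mods = []
            for d in range(spec.head_depth - 1):
                mods += [Conv3d(C, C, rng, f"head_{comp}.conv{d}"), LeakyReLU()]
            mods.append(Conv3d(C, 1, rng, f"head_{comp}.out"))
            self.heads.append(Sequential(*mods))

    def params(self):
        groups = [self.vel_branch, self.mag_branch, self.merge,
                  self.lr_stack, self.post_up, self.hr_stack, *self.heads]
        return [p for g in groups for p in g.params()]

    def forward(self, x, train=False):
        """``(B, 6, n, n, n)`` normalised input -> ``(B, 3, 4n, 4n, 4n)``."""
        v = self.vel_branch.forward(np.ascontiguousarray(x[:, :3]), train)
        m = self.mag_branch.forward(np.ascontiguousarray(x[:, 3:]), train)
        h = self.merge.forward(np.concatenate([v, m], axis=1), train)
        h = self.lr_stack.forward(h, train)
        h = self.upsample.forward(h, train)
        h = self.post_up.forward(h, train)
        h = self.hr_stack.forward(h, train)
        outs = [head.forward(h, train) for head in self.heads]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        dh = sum(
            head.backward(np.ascontiguousarray(dy[:, j:j + 1]))
            for j, head in enumerate(self.heads)
        )
        dh = self.hr_stack.backward(dh)
        dh = self.post_up.backward(dh)
        dh = self.upsample.backward(dh)
        dh = self.lr_stack.backward(dh)
        d_merge = self.merge.backward(dh)
        C = self.spec.channels
        dv = self.vel_branch.backward(np.ascontiguousarray(d_merge[:, :C]))
        dm = self.mag_branch.backward(np.ascontiguousarray(d_merge[:, C:]))
        return np.concatenate([dv, dm], axis=1)


def build(spec: NetworkSpec) -> SRNet:
    """Instantiate a network from its spec (deterministic given the seed)."""
    return SRNet(spec)


def count_parameters(model: Module) -> int:
    """Total trainable scalar parameters."""
    return int(sum(p.size for p in model.params()))


def normalize_input(lr_velocity, lr_magnitude, venc) -> np.ndarray:
    """Stack LR channels and normalise: velocity by per-component VENC,
    magnitude by the intensity-range top.  Returns ``(6, x', y', z')``."""
    venc = np.asarray(venc, dtype=np.float32)
    v = np.moveaxis(lr_velocity, -1, 0) / venc[:, None, None, None]
    m = np.moveaxis(lr_magnitude, -1, 0) / MAGNITUDE_SCALE
    return np.concatenate([v, m], axis=0).astype(np.float32)


def predict_volume(model: Module, lr_sample, batch: int = 8) -> np.ndarray:
    """Patch-based SR prediction of a whole LR volume.

    Splits the LR volume on the stride-(n-4) lattice, runs the model on
    VENC-normalised 12-voxel patches, rescales by VENC, and stitches the
    48-voxel outputs (4-voxel strip) into a volume 4x the LR shape per axis.
    """
    venc = np.asarray(lr_sample.acquisition.venc, dtype=np.float32)
    full = normalize_input(lr_sample.velocity, lr_sample.magnitude, venc)
    shape = lr_sample.velocity.shape[:3]
    origins = [
        (i, j, k)
        for i in patch_lattice(shape[0])
        for j in patch_lattice(shape[1])
        for k in patch_lattice(shape[2])
    ]
    outs = []
    for start in range(0, len(origins), batch):
        chunk = origins[start:start + batch]
        x = np.stack([
            full[:, i:i + LR_PATCH, j:j + LR_PATCH, k:k + LR_PATCH]
            for i, j, k in chunk
        ])
        y = model.forward(x, train=False)
        y = y * venc[None, :, None, None, None]
        outs.extend(
            (origin, np.moveaxis(y[b], 0, -1))
            for b, origin in enumerate(chunk)
        )
    out_shape = tuple(UPSAMPLE * s for s in shape)
    sr = stitch(outs, out_shape)
    if not np.isfinite(sr).all():
        raise FloatingPointError("non-finite values in stitched prediction")
    return sr


def save_checkpoint(model: SRNet, path: str | Path, extra: dict | None = None):
    """Weights as ``.npz`` plus a JSON sidecar with the spec."""
    path = Path(path)
    arrays = {p.name: p.value for p in model.params()}
    np.savez(path, **arrays)
    sidecar = {"spec": asdict(model.spec), "extra": extra or {}}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> SRNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = build(NetworkSpec(**sidecar["spec"]))
    with np.load(path if path.suffix == ".npz" else f"{path}.npz") as data:
        for p in model.params():
            p.value[...] = data[p.name]
    return model
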