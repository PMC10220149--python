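"""HDF5 persistence, geometry catalogue serialisation and volume export.

Canonical on-disk containers are HDF5: flow series (``/velocity``,
``/mask``, ``/times`` with grid attributes), LR samples (plus
``/magnitude`` and acquisition attributes) and appendable patch stores.
Single frames can be exported to ASCII VTI (ParaView) or NIfTI for visual
inspection.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np

from .geometry import Direction, FlowSeries, GeometryConfig, ShapeClass, VoxelGrid
from .mri import Acquisition, LRSample
from .patches import PatchPair

__all__ = [
    "save_flow_series", "load_flow_series",
    "save_lr_sample", "load_lr_sample",
    "save_volume", "load_volume",
    "PatchStore", "write_manifest",
    "save_catalogue", "load_catalogue",
    "export_vti", "export_nifti",
]


def save_volume(volume: np.ndarray, path: str | Path, name: str = "velocity") -> None:
    """A bare volume (e.g. a stitched SR prediction) as HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset(name, data=np.asarray(volume, dtype=np.float32),
                         compression="gzip", compression_opts=1)


def load_volume(path: str | Path, name: str = "velocity") -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f[name][...]


def _write_grid(g: h5py.Group, grid: VoxelGrid) -> None:
    sub = g.create_group("grid")
    sub.attrs["spacing_mm"] = grid.spacing
    sub.attrs["origin_mm"] = np.asarray(grid.origin)
    sub.attrs["shape"] = np.asarray(grid.shape)


def _read_grid(g: h5py.Group) -> VoxelGrid:
    sub = g["grid"]
    return VoxelGrid(
        shape=tuple(int(s) for s in sub.attrs["shape"]),
        spacing=float(sub.attrs["spacing_mm"]),
        origin=tuple(float(o) for o in sub.attrs["origin_mm"]),
    )


def save_flow_series(series: FlowSeries, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("velocity", data=series.velocity.astype(np.float32),
                         compression="gzip", compression_opts=1)
        f.create_dataset("mask", data=series.mask.astype(np.uint8),
                         compression="gzip", compression_opts=1)
        f.create_dataset("times", data=series.times)
        _write_grid(f, series.grid)


def load_flow_series(path: str | Path) -> FlowSeries:
    with h5py.File(path, "r") as f:
        return FlowSeries(
            grid=_read_grid(f),
            velocity=f["velocity"][...],
            mask=f["mask"][...].astype(bool),
            times=f["times"][...],
        )


def save_lr_sample(sample: LRSample, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("velocity", data=sample.velocity)
        f.create_dataset("magnitude", data=sample.magnitude)
        f.create_dataset("mask", data=sample.mask.astype(np.uint8))
        a = sample.acquisition
        f.attrs["venc"] = np.asarray(a.venc)
        f.attrs["snr_db"] = a.snr_db
        f.attrs["intensity"] = a.intensity
        f.attrs["seed"] = a.seed
        f.attrs["downsample_factor"] = sample.downsample_factor
        f.attrs["aliased"] = np.asarray(sample.aliased, dtype=np.uint8)


def load_lr_sample(path: str | Path) -> LRSample:
    with h5py.File(path, "r") as f:
        acq = Acquisition(
            venc=tuple(float(v) for v in f.attrs["venc"]),
            snr_db=float(f.attrs["snr_db"]),
            intensity=float(f.attrs["intensity"]),
            seed=int(f.attrs["seed"]),
        )
        return LRSample(
            velocity=f["velocity"][...],
            magnitude=f["magnitude"][...],
            mask=f["mask"][...].astype(bool),
            acquisition=acq,
            downsample_factor=int(f.attrs["downsample_factor"]),
            aliased=tuple(bool(b) for b in f.attrs["aliased"]),
        )


class PatchStore:
    """Appendable HDF5 store of LR/HR patch pairs."""

    def __init__(self, path: str | Path, mode: str = "r"):
        self.path = Path(path)
        self._f = h5py.File(self.path, mode)
        if mode in ("w", "w-", "x"):
            self._create()

    def _create(self) -> None:
        f = self._f
        def ds(name, shape, dtype):
            return f.create_dataset(
                name, shape=(0, *shape), maxshape=(None, *shape),
                dtype=dtype, chunks=(8, *shape),
                compression="gzip", compression_opts=1,
            )
        ds("lr", (12, 12, 12, 6), np.float32)
        ds("hr", (48, 48, 48, 3), np.float32)
        ds("hr_mask", (48, 48, 48), np.uint8)
        ds("venc", (3,), np.float32)
        ds("origin", (3,), np.int32)
        ds("rotation", (), np.int32)
        ds("fluid_fraction", (), np.float32)

    def __len__(self) -> int:
        return self._f["lr"].shape[0]

    def append(self, pairs: list[PatchPair]) -> None:
        n0, n1 = len(self), len(self) + len(pairs)
        for name in ("lr", "hr", "hr_mask", "venc", "origin", "rotation",
                     "fluid_fraction"):
            self._f[name].resize(n1, axis=0)
        self._f["lr"][n0:] = np.stack([p.lr for p in pairs])
        self._f["hr"][n0:] = np.stack([p.hr for p in pairs])
        self._f["hr_mask"][n0:] = np.stack(
            [p.hr_mask.astype(np.uint8) for p in pairs])
        self._f["venc"][n0:] = np.stack([p.venc for p in pairs])
        self._f["origin"][n0:] = np.stack([p.origin for p in pairs])
        self._f["rotation"][n0:] = [p.rotation for p in pairs]
        self._f["fluid_fraction"][n0:] = [p.fluid_fraction for p in pairs]

    def read_pairs(self, start: int = 0, stop: int | None = None) -> list[PatchPair]:
        stop = len(self) if stop is None else stop
        f = self._f
        return [
            PatchPair(
                lr=f["lr"][i], hr=f["hr"][i],
                hr_mask=f["hr_mask"][i].astype(bool),
                venc=f["venc"][i],
                fluid_fraction=float(f["fluid_fraction"][i]),
                origin=tuple(int(o) for o in f["origin"][i]),
                rotation=int(f["rotation"][i]),
            )
            for i in range(start, stop)
        ]

    def close(self) -> None:
        self._f.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def write_manifest(rows: list[dict], path: str | Path) -> None:
    """Per-geometry patch-count manifest as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


_CAT_FIELDS = [
    "id", "shape_class", "v_I", "R_I", "R_C", "theta", "delta", "direction",
    "upstream_length", "constriction_length", "taper_length", "n_frames",
    "dt", "tau", "jet_gain", "cfd_peak_speed",
]


def save_catalogue(geoms: list[GeometryConfig], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CAT_FIELDS)
        for g in geoms:
            w.writerow([
                g.id, g.shape_class.value, g.v_I, g.R_I, g.R_C, g.theta,
                g.delta, g.direction.value, g.upstream_length,
                g.constriction_length, g.taper_length, g.n_frames, g.dt,
                g.tau, g.jet_gain,
                "" if g.cfd_peak_speed is None else g.cfd_peak_speed,
            ])


def load_catalogue(path: str | Path) -> list[GeometryConfig]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(GeometryConfig(
                id=int(row["id"]),
                shape_class=ShapeClass(row["shape_class"]),
                v_I=float(row["v_I"]), R_I=float(row["R_I"]),
                R_C=float(row["R_C"]), theta=float(row["theta"]),
                delta=float(row["delta"]),
                direction=Direction(row["direction"]),
                upstream_length=float(row["upstream_length"]),
                constriction_length=float(row["constriction_length"]),
                taper_length=float(row["taper_length"]),
                n_frames=int(row["n_frames"]), dt=float(row["dt"]),
                tau=float(row["tau"]), jet_gain=float(row["jet_gain"]),
                cfd_peak_speed=(
                    None if row["cfd_peak_speed"] == ""
                    else float(row["cfd_peak_speed"])
                ),
            ))
    return out


def export_vti(
    volume: np.ndarray, grid: VoxelGrid, path: str | Path,
    name: str = "velocity",
) -> None:
    """Write one frame as ASCII XML VTK ImageData (.vti).

    ``volume`` is ``(nx, ny, nz)`` scalar or ``(nx, ny, nz, 3)`` vector
    data.  The writer emits the minimal ImageData dialect ParaView reads.
    """
    vec = volume.ndim == 4
    ncomp = 3 if vec else 1
    nx, ny, nz = volume.shape[:3]
    flat = volume.reshape(nx, ny, nz, ncomp)
    # VTK orders points with x fastest
    flat = flat.transpose(2, 1, 0, 3).reshape(-1, ncomp)
    body = "\n".join(
        " ".join(f"{v:.6g}" for v in row) for row in flat
    )
    sp = grid.spacing
    ox, oy, oz = grid.origin
    xml = f"""<?xml version="1.0"?>
<VTKFile type="ImageData" version="0.1" byte_order="LittleEndian">
  <ImageData WholeExtent="0 {nx - 1} 0 {ny - 1} 0 {nz - 1}"
             Origin="{ox} {oy} {oz}" Spacing="{sp} {sp} {sp}">
    <Piece Extent="0 {nx - 1} 0 {ny - 1} 0 {nz - 1}">
      <PointData Scalars="{name}">
        <DataArray type="Float32" Name="{name}"
                   NumberOfComponents="{ncomp}" format="ascii">
{body}
        </DataArray>
      </PointData>
      <CellData/>
    </Piece>
  </ImageData>
</VTKFile>
"""
    Path(path).write_text(xml)


def export_nifti(volume: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    """Write a volume as NIfTI with the grid spacing in the affine (mm)."""
    import nibabel as nib

    affine = np.diag([grid.spacing] * 3 + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    nib.save(img, str(path))
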