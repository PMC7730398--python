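"""Volume and result I/O: multi-page TIFF, raw .npy, HDF5 containers."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .phantom import GrayVolume, GroundTruth
from .segmentation import LabelVolume

__all__ = ["read_volume", "write_volume", "write_truth", "write_labels",
           "read_labels"]


def read_volume(path, voxel_size: float | None = None) -> GrayVolume:
    """Read a grayscale volume (multi-page TIFF, page = Z slice, or .npy).

    The voxel size (um) is taken from a JSON sidecar ``<path>.meta.json``
    when present, else from the ``voxel_size`` argument.  Non-8-bit input
    is rescaled to 8 bit with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = path.with_suffix(path.suffix + ".meta.json")
    if voxel_size is None and meta.exists():
        voxel_size = float(json.loads(meta.read_text()).get("voxel_size_um"))
    if voxel_size is None:
        raise ValueError(
            "voxel size unknown: pass voxel_size or provide a sidecar "
            f"{meta.name}"
        )
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        pages = tifffile.imread(path)  # (z, y, x) page stack
        if pages.ndim != 3:
            raise ValueError(f"expected a 3D stack, got shape {pages.shape}")
        data = np.ascontiguousarray(np.transpose(pages, (2, 1, 0)))
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    if data.dtype != np.uint8:
        warnings.warn(f"converting {data.dtype} volume to 8 bit", stacklevel=2)
        lo, hi = float(data.min()), float(data.max())
        scale = 255.0 / (hi - lo) if hi > lo else 1.0
        data = np.clip((data.astype(np.float64) - lo) * scale, 0, 255)
        data = data.astype(np.uint8)
    return GrayVolume(data=data, voxel_size=float(voxel_size))


def write_volume(vol: GrayVolume, path) -> None:
    """Write a volume as multi-page TIFF (one page per Z slice) or .npy.

    A JSON sidecar records the voxel size so the round trip is lossless.
    """
    path = Path(path)
    data = vol.data
    if data.dtype != np.uint8:
        data = np.clip(np.round(data), 0, 255).astype(np.uint8)
    if path.suffix == ".npy":
        np.save(path, data)
    else:
        tifffile.imwrite(path, np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    meta = path.with_suffix(path.suffix + ".meta.json")
    meta.write_text(json.dumps({"voxel_size_um": vol.voxel_size}))


def write_truth(gt: GroundTruth, path) -> None:
    """Store phantom ground truth (labels + cell table) in an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=gt.labels, compression="gzip")
        f.attrs["voxel_size_um"] = gt.voxel_size
        cells = gt.cells.reset_index(drop=True)
        grp = f.create_group("cells")
        for col in cells.columns:
            vals = cells[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            grp.create_dataset(col, data=vals)


def write_labels(lv: LabelVolume, path, provenance: dict | None = None) -> None:
    """Store a segmentation (labels, ownership, categories) in HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("lumen_label", data=lv.labels, compression="gzip")
        if lv.wall_owner is not None:
            f.create_dataset("wall_owner", data=lv.wall_owner,
                             compression="gzip")
        f.attrs["voxel_size_um"] = lv.voxel_size
        if lv.threshold is not None:
            f.attrs["threshold"] = lv.threshold
        ids = sorted(lv.category)
        f.create_dataset("label_id", data=np.asarray(ids, dtype=np.int32))
        f.create_dataset(
            "category",
            data=np.asarray([lv.category[i] for i in ids], dtype="S"),
        )
        f.create_dataset(
            "detection_pass",
            data=np.asarray([lv.detection_pass.get(i, 0) for i in ids],
                            dtype=np.int8),
        )
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance)


def read_labels(path) -> LabelVolume:
    import h5py

    with h5py.File(path, "r") as f:
        lv = LabelVolume(
            labels=f["lumen_label"][...],
            voxel_size=float(f.attrs["voxel_size_um"]),
            wall_owner=f["wall_owner"][...] if "wall_owner" in f else None,
            threshold=float(f.attrs["threshold"]) if "threshold" in f.attrs
            else None,
        )
        ids = f["label_id"][...]
        cats = [c.decode() for c in f["category"][...]]
        passes = f["detection_pass"][...]
        for i, c, p in zip(ids, cats, passes):
            lv.category[int(i)] = c
            lv.detection_pass[int(i)] = int(p)
    return lv
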