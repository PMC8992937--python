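"""File formats: NIfTI-1 volumes, HDF5 projection stacks, JSON sidecars.

Every writer has a reader; numeric round trips are exact.  Volumes are
written RAS+ with mm voxel sizes in the affine; projection stacks store the
count array plus the acquisition geometry as HDF5 attributes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .acquisition import AcquisitionGeometry, ProjectionStack
from .nema import RoiLayout
from .phantom import VoxelPhantom
from .recon import Volume


def _affine(voxel_size_mm: float, origin_mm) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def save_volume_nifti(path: str | Path, values: np.ndarray, voxel_size_mm: float,
                      origin_mm=(0.0, 0.0, 0.0), sidecar: dict | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32),
                          _affine(voxel_size_mm, origin_mm))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    if sidecar is not None:
        Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json").write_text(
            json.dumps(sidecar, indent=2, default=str)
        )


def load_volume_nifti(path: str | Path) -> tuple[np.ndarray, float, tuple]:
    img = nib.load(str(path))
    vox = float(img.affine[0, 0])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return np.asarray(img.dataobj, dtype=np.float64), vox, origin


def save_phantom(path_prefix: str | Path, phantom: VoxelPhantom) -> None:
    """Write activity/mu NIfTI pairs plus raw float32 + JSON sidecars."""
    prefix = Path(path_prefix)
    meta = {"voxel_size_mm": phantom.voxel_size_mm, "origin_mm": list(phantom.origin_mm),
            "shape": list(phantom.shape)}
    for name, arr in (("activity", phantom.activity), ("mu", phantom.mu_map)):
        save_volume_nifti(prefix.with_name(prefix.name + f"_{name}.nii.gz"),
                          arr, phantom.voxel_size_mm, phantom.origin_mm, sidecar=meta)
        raw = prefix.with_name(prefix.name + f"_{name}.f32")
        np.asarray(arr, dtype=np.float32).tofile(raw)
        raw.with_suffix(".json").write_text(json.dumps({**meta, "dtype": "float32"}, indent=2))


def load_phantom(path_prefix: str | Path) -> VoxelPhantom:
    prefix = Path(path_prefix)
    act, vox, origin = load_volume_nifti(prefix.with_name(prefix.name + "_activity.nii.gz"))
    mu, _, _ = load_volume_nifti(prefix.with_name(prefix.name + "_mu.nii.gz"))
    return VoxelPhantom(activity=act, mu_map=mu, voxel_size_mm=vox, origin_mm=origin)


def save_projections(path: str | Path, stack: ProjectionStack) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("counts", data=stack.counts, compression="gzip")
        f.attrs["n_gate_bins"] = stack.n_gate_bins
        f.attrs["bin_duration_s"] = stack.bin_duration_s
        f.attrs["noise_seed"] = -1 if stack.noise_seed is None else stack.noise_seed
        f.attrs["geometry"] = json.dumps(dataclasses.asdict(stack.geometry))


def load_projections(path: str | Path) -> ProjectionStack:
    with h5py.File(str(path), "r") as f:
        counts = f["counts"][...]
        geo = json.loads(f.attrs["geometry"])
        geo["matrix"] = tuple(geo["matrix"])
        seed = int(f.attrs["noise_seed"])
        return ProjectionStack(
            counts=counts,
            geometry=AcquisitionGeometry(**geo),
            n_gate_bins=int(f.attrs["n_gate_bins"]),
            bin_duration_s=float(f.attrs["bin_duration_s"]),
            noise_seed=None if seed < 0 else seed,
        )


def save_recon_volume(path: str | Path, vol: Volume, origin_mm=(0.0, 0.0, 0.0)) -> None:
    save_volume_nifti(path, vol.values, vol.voxel_size_mm, origin_mm, sidecar=vol.provenance)


def save_layout(path: str | Path, layout: RoiLayout) -> None:
    Path(path).write_text(json.dumps({
        "central_slice": layout.central_slice,
        "analysis_slices": list(layout.analysis_slices),
        "sphere_centers_mm": layout.sphere_centers_mm.tolist(),
        "roi_diameters_mm": list(layout.roi_diameters_mm),
        "background_centers_mm": layout.background_centers_mm.tolist(),
        "margin_mm": layout.margin_mm,
    }, indent=2))


def load_layout(path: str | Path) -> RoiLayout:
    d = json.loads(Path(path).read_text())
    return RoiLayout(
        central_slice=d["central_slice"],
        analysis_slices=tuple(d["analysis_slices"]),
        sphere_centers_mm=np.asarray(d["sphere_centers_mm"]),
        roi_diameters_mm=tuple(d["roi_diameters_mm"]),
        background_centers_mm=np.asarray(d["background_centers_mm"]),
        margin_mm=d["margin_mm"],
    )


def export_view_pngs(out_dir: str | Path, stack: ProjectionStack,
                     views: list[int] | None = None) -> list[Path]:
    """Write summed-over-bins projection views as greyscale PNGs for inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summed = stack.counts.sum(axis=0)
    views = list(range(summed.shape[0])) if views is None else views
    written = []
    for v in views:
        p = out / f"view_{v:03d}.png"
        plt.imsave(p, summed[v], cmap="gray")
        written.append(p)
    return written


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, files: list[Path], extra: dict | None = None) -> dict:
    manifest = {
        "artifacts": [
            {"path": str(p), "sha256": file_sha256(p), "bytes": Path(p).stat().st_size}
            for p in files if Path(p).exists()
        ],
        **(extra or {}),
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest
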