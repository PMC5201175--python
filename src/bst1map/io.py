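"""NIfTI and sidecar I/O.

Volumes travel as NIfTI-1 files (complex data uses the native NIfTI complex
dtype); per-series acquisition metadata travels as a JSON sidecar holding
whichever of ``flip_angles_deg / tr_ms / te_ms / ti_ms / td_ms /
inv_flip_deg / offset_hz`` applies.  ``series_from_volumes`` dispatches on
those keys, so synthetic and user-supplied data enter the pipeline through
the same door.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .core import BSPhasePair, ImageVolume, IRSeries, VFASeries

__all__ = [
    "read_volume",
    "write_volume",
    "series_from_volumes",
    "save_series",
    "load_series",
]


def read_volume(path, expect_complex: bool = False, kind: str = "magnitude") -> ImageVolume:
    """Read a NIfTI volume.

    ``kind`` declares what a real-valued payload represents ("magnitude",
    "phase" or "parameter"); magnitude data is validated non-negative.
    Raises if the file is missing or if ``expect_complex`` but the payload
    is real-valued.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    dtype = img.get_data_dtype()
    is_complex = np.issubdtype(dtype, np.complexfloating)
    if expect_complex and not is_complex:
        raise ValueError(f"{path}: complex data requested but file is magnitude")
    if is_complex:
        data = np.asanyarray(img.dataobj).astype(np.complex128)
    else:
        data = img.get_fdata()
    zooms = img.header.get_zooms()[:3]
    # stored (x, y, z) -> internal (slice, row, col)
    data = np.transpose(data, (2, 1, 0))
    voxel = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return ImageVolume(data=data, voxel_size_mm=voxel, series_id=path.stem, kind=kind)


def write_volume(vol: ImageVolume, path) -> Path:
    """Write an ImageVolume as NIfTI-1; returns the path written."""
    path = Path(path)
    data = np.transpose(vol.data, (2, 1, 0))
    if vol.is_complex:
        data = data.astype(np.complex128)
    affine = np.diag(
        [vol.voxel_size_mm[2], vol.voxel_size_mm[1], vol.voxel_size_mm[0], 1.0]
    )
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(
        (vol.voxel_size_mm[2], vol.voxel_size_mm[1], vol.voxel_size_mm[0])
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def series_from_volumes(volumes: Sequence[ImageVolume], metadata: dict):
    """Assemble a validated series object from volumes plus sidecar metadata.

    The metadata keys select the series type:

    - ``flip_angles_deg`` + ``tr_ms``  -> :class:`VFASeries`
    - ``ti_ms`` + ``td_ms``            -> :class:`IRSeries`
    - ``offset_hz`` (two complex vols) -> :class:`BSPhasePair`
    """
    volumes = list(volumes)
    if "flip_angles_deg" in metadata:
        return VFASeries(
            volumes=volumes,
            flip_angles_deg=list(metadata["flip_angles_deg"]),
            tr_ms=float(metadata["tr_ms"]),
            te_ms=float(metadata.get("te_ms", 0.0)),
        )
    if "ti_ms" in metadata:
        return IRSeries(
            volumes=volumes,
            ti_ms=list(metadata["ti_ms"]),
            td_ms=float(metadata["td_ms"]),
            inv_flip_deg=float(metadata.get("inv_flip_deg", 180.0)),
        )
    if "offset_hz" in metadata:
        if len(volumes) != 2:
            raise ValueError("a Bloch-Siegert pair needs exactly 2 volumes")
        return BSPhasePair(
            img_plus=volumes[0],
            img_minus=volumes[1],
            offset_hz=float(metadata["offset_hz"]),
        )
    raise ValueError(
        "metadata must contain flip_angles_deg, ti_ms, or offset_hz "
        f"(got keys {sorted(metadata)})"
    )


def _series_metadata(series) -> dict:
    if isinstance(series, VFASeries):
        return {
            "flip_angles_deg": series.flip_angles_deg,
            "tr_ms": series.tr_ms,
            "te_ms": series.te_ms,
        }
    if isinstance(series, IRSeries):
        return {
            "ti_ms": series.ti_ms,
            "td_ms": series.td_ms,
            "inv_flip_deg": series.inv_flip_deg,
        }
    if isinstance(series, BSPhasePair):
        return {"offset_hz": series.offset_hz}
    raise TypeError(f"not a series: {type(series)}")


def save_series(series, directory, stem: str) -> Path:
    """Write a series as numbered NIfTI volumes plus a JSON sidecar.

    Returns the sidecar path; the sidecar lists the volume filenames so
    :func:`load_series` can reassemble the series from it alone.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(series, BSPhasePair):
        volumes = [series.img_plus, series.img_minus]
    else:
        volumes = series.volumes
    names = []
    for i, vol in enumerate(volumes):
        name = f"{stem}_{i:02d}.nii"
        write_volume(vol, directory / name)
        names.append(name)
    meta = _series_metadata(series)
    meta["volumes"] = names
    sidecar = directory / f"{stem}.json"
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def load_series(sidecar_path):
    """Reassemble a series written by :func:`save_series`."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    names = meta.pop("volumes")
    expect_complex = "offset_hz" in meta
    volumes = [
        read_volume(sidecar_path.parent / name, expect_complex=expect_complex)
        for name in names
    ]
    return series_from_volumes(volumes, meta)
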