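"""Core imaging containers shared by every pipeline stage.

The package works on small stacks of 2D/3D scalar or complex fields with a
common index convention ``(slice, row, col)``, 0-based.  Every derived map
(B1 correction factor, T1, tissue masks) lives on the exact voxel grid of the
series it was computed from; nothing in the package resamples.

Invalid voxels (failed fits, out-of-range phase, background) carry NaN in the
value arrays and ``False`` in the accompanying validity mask, so they can
never silently enter an ROI mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ImageVolume",
    "VFASeries",
    "IRSeries",
    "BSPhasePair",
    "T1Map",
    "CorrectionFactorMap",
]


def _as_volume_array(data) -> np.ndarray:
    """Coerce input to a 3D ``(slice, row, col)`` array, promoting 2D slices."""
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[np.newaxis, :, :]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2D or 3D array, got ndim={arr.ndim}")
    if any(s < 1 for s in arr.shape):
        raise ValueError(f"all dimensions must be >= 1, got shape {arr.shape}")
    if np.iscomplexobj(arr):
        arr = arr.astype(np.complex128, copy=False)
    else:
        arr = arr.astype(np.float64, copy=False)
    return arr


@dataclass
class ImageVolume:
    """A single magnitude or complex image volume with voxel spacing.

    Parameters
    ----------
    data
        2D or 3D array; 2D input is promoted to shape ``(1, rows, cols)``.
        Real-valued data is interpreted as a magnitude image and must be
        non-negative everywhere.
    voxel_size_mm
        ``(dz, dy, dx)`` voxel edge lengths in millimetres.
    series_id
        Free-text identifier carried through I/O round trips.
    kind
        ``"magnitude"`` (default; real data must be non-negative),
        ``"phase"`` (signed radians) or ``"parameter"`` (signed map, e.g. a
        difference image).  Complex volumes ignore the flag.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    series_id: str = ""
    kind: str = "magnitude"

    _KINDS = ("magnitude", "phase", "parameter")

    def __post_init__(self) -> None:
        self.data = _as_volume_array(self.data)
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be three positive lengths, got {vs}")
        self.voxel_size_mm = vs
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if not self.is_complex and self.kind == "magnitude":
            finite = self.data[np.isfinite(self.data)]
            if finite.size and finite.min() < 0:
                raise ValueError("magnitude image contains negative voxels")

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def magnitude(self) -> np.ndarray:
        return np.abs(self.data) if self.is_complex else self.data

    def phase(self) -> np.ndarray:
        """Per-voxel phase in radians (zero for magnitude volumes)."""
        return np.angle(self.data) if self.is_complex else np.zeros(self.shape)


def _check_stackable(volumes: Sequence[ImageVolume], what: str) -> None:
    if not volumes:
        raise ValueError(f"{what}: no volumes supplied")
    shape = volumes[0].shape
    for v in volumes[1:]:
        if v.shape != shape:
            raise ValueError(f"{what}: volume shapes differ ({v.shape} vs {shape})")


@dataclass
class VFASeries:
    """Multi-flip-angle spoiled gradient-echo series (one volume per angle)."""

    volumes: list[ImageVolume]
    flip_angles_deg: list[float]
    tr_ms: float
    te_ms: float = 0.0

    def __post_init__(self) -> None:
        _check_stackable(self.volumes, "VFASeries")
        angles = [float(a) for a in self.flip_angles_deg]
        if len(angles) != len(self.volumes):
            raise ValueError(
                f"{len(self.volumes)} volumes but {len(angles)} flip angles"
            )
        if any(not (0 < a <= 90) for a in angles):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValueError("flip angles must be strictly increasing")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        self.flip_angles_deg = angles

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    def stack(self) -> np.ndarray:
        """Signals as an ``(n_angles, slice, row, col)`` array."""
        return np.stack([v.data for v in self.volumes])


@dataclass
class IRSeries:
    """Inversion-recovery series: one magnitude volume per inversion time."""

    volumes: list[ImageVolume]
    ti_ms: list[float]
    td_ms: float
    inv_flip_deg: float = 180.0

    def __post_init__(self) -> None:
        _check_stackable(self.volumes, "IRSeries")
        tis = [float(t) for t in self.ti_ms]
        if len(tis) != len(self.volumes):
            raise ValueError(f"{len(self.volumes)} volumes but {len(tis)} TIs")
        if any(t <= 0 for t in tis):
            raise ValueError("inversion times must be positive")
        if any(b <= a for a, b in zip(tis, tis[1:])):
            raise ValueError("inversion times must be strictly increasing")
        if self.td_ms <= 0:
            raise ValueError("td_ms (predelay) must be positive")
        self.ti_ms = tis

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    def stack(self) -> np.ndarray:
        return np.stack([v.data for v in self.volumes])

    def volume_at_ti(self, ti_ms: float, atol: float = 0.5) -> ImageVolume:
        """Return the volume acquired at (approximately) the given TI."""
        for t, v in zip(self.ti_ms, self.volumes):
            if abs(t - ti_ms) <= atol:
                return v
        raise KeyError(f"no volume at TI = {ti_ms} ms (have {self.ti_ms})")


@dataclass
class BSPhasePair:
    """Complex image pair acquired at opposite Bloch-Siegert pulse offsets."""

    img_plus: ImageVolume
    img_minus: ImageVolume
    offset_hz: float

    def __post_init__(self) -> None:
        if not (self.img_plus.is_complex and self.img_minus.is_complex):
            raise ValueError("Bloch-Siegert pair requires complex volumes")
        if self.img_plus.shape != self.img_minus.shape:
            raise ValueError("Bloch-Siegert pair shapes differ")
        if self.offset_hz <= 0:
            raise ValueError("offset_hz must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.img_plus.shape


@dataclass
class T1Map:
    """Per-voxel T1 estimate with fit diagnostics.

    ``t1_ms`` holds NaN wherever ``valid_mask`` is False; only valid voxels
    may enter ROI summaries.  ``method`` records which acquisition/model
    produced the map: ``"VFA"`` (uncorrected), ``"VFA_B1"`` (flip-angle
    corrected) or ``"IR"``.
    """

    t1_ms: np.ndarray
    s0: np.ndarray
    rss: np.ndarray
    method: str
    valid_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    _METHODS = ("VFA", "VFA_B1", "IR")

    def __post_init__(self) -> None:
        self.t1_ms = _as_volume_array(self.t1_ms)
        self.s0 = _as_volume_array(self.s0)
        self.rss = _as_volume_array(self.rss)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.ndim == 2:
            self.valid_mask = self.valid_mask[np.newaxis]
        shapes = {a.shape for a in (self.t1_ms, self.s0, self.rss, self.valid_mask)}
        if len(shapes) != 1:
            raise ValueError(f"T1Map field shapes differ: {shapes}")
        if self.method not in self._METHODS:
            raise ValueError(f"method must be one of {self._METHODS}")
        vals = self.t1_ms[self.valid_mask]
        if vals.size and (not np.all(np.isfinite(vals)) or vals.min() <= 0):
            raise ValueError("valid voxels must carry finite positive T1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1_ms.shape


@dataclass
class CorrectionFactorMap:
    """Per-voxel flip-angle correction factor f = actual / prescribed angle.

    f = 1 means nominal excitation.  Voxels where the factor could not be
    measured (background, phase outside the lookup range) are NaN with
    ``valid_mask`` False.
    """

    f: np.ndarray
    pulse_id: str = ""
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.f = _as_volume_array(self.f)
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.f)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.ndim == 2:
            self.valid_mask = self.valid_mask[np.newaxis]
        if self.valid_mask.shape != self.f.shape:
            raise ValueError("valid_mask shape differs from f")
        vals = self.f[self.valid_mask]
        if vals.size and (not np.all(np.isfinite(vals)) or vals.min() <= 0):
            raise ValueError("defined correction factors must be finite and > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.f.shape
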