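"""Digital phantoms and forward simulation of the three acquisitions.

Two phantom families are generated procedurally:

* an 8-tube gel phantom (circular tubes on a regular layout, one T1 per
  tube, defaults spanning 300-1600 ms), and
* a two-tissue breast phantom: an elliptical body of adipose tissue (AT,
  short T1) enclosing blob-shaped fibroglandular tissue (FGT, long T1) at a
  configurable volume fraction.

A smooth transmit-field (B1) inhomogeneity is attached as a per-voxel
flip-angle scale factor f; the default is a left-right linear ramp over
[0.8, 1.1], the pattern reported for bilateral breast imaging at 3 T.

Forward models: the spoiled gradient-echo and inversion-recovery signal
equations from :mod:`bst1map.relaxometry`, and the Bloch-simulated
phase of the off-resonant pulse for the Bloch-Siegert pair.  Magnitude
noise is Rician (complex Gaussian added in quadrature, then modulus);
complex images receive complex Gaussian noise.  All generators are pure
functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bloch_siegert import PulseSpec, _simulate_phases
from .core import BSPhasePair, CorrectionFactorMap, ImageVolume, IRSeries, VFASeries
from .relaxometry import ir_signal, spgr_signal

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "NoiseSpec",
    "VFAProtocol",
    "IRProtocol",
    "make_gel_phantom",
    "make_breast_phantom",
    "simulate_vfa",
    "simulate_ir",
    "simulate_bs_pair",
    "simulate_testretest",
]

#: Gel-tube T1 defaults (ms): the reference values of the 8-tube test object.
GEL_TUBE_T1_MS = (322.0, 328.0, 835.0, 843.0, 1004.0, 1478.0, 1500.0, 1558.0)

#: Breast tissue T1 defaults (ms).
BREAST_T1_MS = {"AT": 420.0, "FGT": 1290.0}


@dataclass
class PhantomSpec:
    """Geometry + ground-truth parameters of a digital phantom."""

    kind: str = "gel_tubes"
    grid_shape: tuple[int, int, int] = (1, 96, 96)
    tube_t1_ms: tuple[float, ...] = GEL_TUBE_T1_MS
    tissue_t1_ms: dict = field(default_factory=lambda: dict(BREAST_T1_MS))
    s0: float = 1000.0
    b1_field: str = "linear_lr"
    b1_range: tuple[float, float] = (0.8, 1.1)
    tube_radius_vox: int | None = None
    fgt_fraction: float = 0.25
    geometry_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gel_tubes", "breast"):
            raise ValueError("kind must be 'gel_tubes' or 'breast'")
        s, h, w = self.grid_shape
        if s < 1 or h < 8 or w < 8:
            raise ValueError("grid must be at least 8x8 in-plane with >= 1 slice")
        if any(t <= 0 for t in self.tube_t1_ms):
            raise ValueError("tube T1 values must be positive")
        if any(t <= 0 for t in self.tissue_t1_ms.values()):
            raise ValueError("tissue T1 values must be positive")
        if self.b1_field not in ("uniform", "linear_lr", "polynomial"):
            raise ValueError("b1_field must be uniform, linear_lr or polynomial")
        if self.b1_range[0] <= 0:
            raise ValueError("f_min must be positive")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")


@dataclass
class GroundTruth:
    """True parameter maps and region labels for a phantom.

    ``masks`` maps region names (``tube_1`` ... or ``AT``/``FGT``, plus
    ``background``) to boolean arrays; the non-background masks are
    pairwise disjoint and their union is the foreground.
    """

    t1_true: ImageVolume
    s0_true: ImageVolume
    f_true: CorrectionFactorMap
    masks: dict

    def __post_init__(self) -> None:
        fg = np.zeros(self.t1_true.shape, dtype=bool)
        for name, m in self.masks.items():
            if name == "background":
                continue
            m = np.asarray(m, dtype=bool)
            if (fg & m).any():
                raise ValueError(f"mask {name!r} overlaps another foreground mask")
            fg |= m
        if "background" in self.masks:
            if (fg & self.masks["background"]).any():
                raise ValueError("background overlaps foreground")
            if not np.array_equal(fg | self.masks["background"],
                                  np.ones_like(fg)):
                raise ValueError("masks must partition the grid")
        vals = self.t1_true.data[fg]
        if vals.size and (vals <= 0).any():
            raise ValueError("t1_true must be positive on the foreground")

    @property
    def foreground(self) -> np.ndarray:
        fg = np.zeros(self.t1_true.shape, dtype=bool)
        for name, m in self.masks.items():
            if name != "background":
                fg |= np.asarray(m, dtype=bool)
        return fg


@dataclass
class NoiseSpec:
    """Noise model for simulated acquisitions.

    ``sigma`` is the Gaussian SD per real/imaginary channel in signal
    units; ``rician`` applies it in quadrature to magnitude images,
    ``gaussian_complex`` to complex images.  ``seed`` makes every
    simulation bit-reproducible.
    """

    model: str = "none"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("none", "rician", "gaussian_complex"):
            raise ValueError("model must be none, rician or gaussian_complex")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def rng(self, *tags: int) -> np.random.Generator:
        """Independent, reproducible stream per (seed, tags) combination."""
        return np.random.default_rng([int(self.seed), *map(int, tags)])


@dataclass
class VFAProtocol:
    """Acquisition metadata for a simulated multi-flip-angle series."""

    flip_angles_deg: tuple[float, ...] = tuple(range(2, 21, 2))
    tr_ms: float = 7.9
    te_ms: float = 4.6
    voxel_size_mm: tuple[float, float, float] = (4.0, 1.33, 1.33)


@dataclass
class IRProtocol:
    """Acquisition metadata for a simulated inversion-recovery series."""

    ti_ms: tuple[float, ...] = (
        25, 50, 75, 100, 200, 300, 400, 500, 1000, 2000, 4000, 10000)
    td_ms: float = 2500.0
    inv_flip_deg: float = 180.0
    voxel_size_mm: tuple[float, float, float] = (4.0, 1.33, 1.33)


# ---------------------------------------------------------------------------
# B1 fields and phantom geometry


def _b1_field(spec: PhantomSpec) -> np.ndarray:
    s, h, w = spec.grid_shape
    f_min, f_max = spec.b1_range
    if spec.b1_field == "uniform":
        return np.full(spec.grid_shape, 0.5 * (f_min + f_max))
    if spec.b1_field == "linear_lr":
        ramp = f_min + (f_max - f_min) * np.arange(w) / (w - 1)
        return np.broadcast_to(ramp, spec.grid_shape).copy()
    # polynomial: radial quadratic bowl, f_max at centre, f_min at the
    # farthest in-plane corner
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2)
    r2 = r2 / r2.max()
    plane = f_max - (f_max - f_min) * r2
    return np.broadcast_to(plane, spec.grid_shape).copy()


def _masked_ground_truth(spec: PhantomSpec, t1: np.ndarray, s0: np.ndarray,
                         masks: dict) -> GroundTruth:
    fg = np.zeros(spec.grid_shape, dtype=bool)
    for name, m in masks.items():
        if name != "background":
            fg |= m
    f = _b1_field(spec)
    f = np.where(fg, f, np.nan)
    return GroundTruth(
        t1_true=ImageVolume(np.where(fg, t1, np.nan), kind="parameter"),
        s0_true=ImageVolume(np.where(fg, s0, 0.0), kind="parameter"),
        f_true=CorrectionFactorMap(f=f, pulse_id="true", valid_mask=fg),
        masks=masks,
    )


def make_gel_phantom(spec: PhantomSpec) -> GroundTruth:
    """Circular gel tubes on a regular layout (up to 4 per row).

    Each tube carries one T1 from ``spec.tube_t1_ms``; raises if the tubes
    do not fit on the grid without touching.
    """
    if spec.kind != "gel_tubes":
        raise ValueError("spec.kind must be 'gel_tubes'")
    s, h, w = spec.grid_shape
    n = len(spec.tube_t1_ms)
    n_cols = min(n, 4)
    n_rows = int(np.ceil(n / n_cols))
    radius = spec.tube_radius_vox
    if radius is None:
        radius = max(2, int(0.4 * min(h / n_rows, w / n_cols)) - 1)
    centers = []
    for i in range(n):
        r, c = divmod(i, n_cols)
        cy = (h * (2 * r + 1)) / (2 * n_rows)
        cx = (w * (2 * c + 1)) / (2 * n_cols)
        centers.append((cy, cx))
    min_spacing = min(h / n_rows, w / n_cols)
    if 2 * radius >= min_spacing or radius >= min(h, w) / 2:
        raise ValueError(f"{n} tubes of radius {radius} do not fit on {h}x{w}")

    yy, xx = np.mgrid[0:h, 0:w]
    t1 = np.zeros(spec.grid_shape)
    s0 = np.zeros(spec.grid_shape)
    masks = {}
    for i, ((cy, cx), t1_val) in enumerate(zip(centers, spec.tube_t1_ms), start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        mask = np.broadcast_to(disk, spec.grid_shape).copy()
        masks[f"tube_{i}"] = mask
        t1[mask] = t1_val
        s0[mask] = spec.s0
    fg = np.zeros(spec.grid_shape, dtype=bool)
    for m in masks.values():
        fg |= m
    masks["background"] = ~fg
    return _masked_ground_truth(spec, t1, s0, masks)


def make_breast_phantom(spec: PhantomSpec) -> GroundTruth:
    """Elliptical AT body enclosing blob-shaped FGT at ``fgt_fraction``.

    The FGT region is the upper quantile of a smooth random field (sum of
    Gaussian bumps drawn from ``geometry_seed``) restricted to an inner
    ellipse, so an AT shell always encloses it.
    """
    if spec.kind != "breast":
        raise ValueError("spec.kind must be 'breast'")
    if not (0 < spec.fgt_fraction < 1):
        raise ValueError("fgt_fraction must lie in (0, 1)")
    s, h, w = spec.grid_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    body2d = ((yy - cy) / (0.42 * h)) ** 2 + ((xx - cx) / (0.42 * w)) ** 2 <= 1.0
    inner2d = ((yy - cy) / (0.30 * h)) ** 2 + ((xx - cx) / (0.30 * w)) ** 2 <= 1.0

    rng = np.random.default_rng(spec.geometry_seed)
    bump_field = np.zeros((h, w))
    for _ in range(6):
        by = cy + (0.30 * h) * (rng.random() * 2 - 1) * 0.8
        bx = cx + (0.30 * w) * (rng.random() * 2 - 1) * 0.8
        width = (0.06 + 0.08 * rng.random()) * min(h, w)
        bump_field += np.exp(-((yy - by) ** 2 + (xx - bx) ** 2) / (2 * width**2))
    bump_field = np.where(inner2d, bump_field, -np.inf)

    n_target = int(round(spec.fgt_fraction * body2d.sum()))
    n_target = min(n_target, int(inner2d.sum()))
    flat = bump_field.ravel()
    order = np.argsort(flat)[::-1]
    fgt2d = np.zeros(h * w, dtype=bool)
    fgt2d[order[:n_target]] = True
    fgt2d = fgt2d.reshape(h, w) & inner2d
    at2d = body2d & ~fgt2d

    at = np.broadcast_to(at2d, spec.grid_shape).copy()
    fgt = np.broadcast_to(fgt2d, spec.grid_shape).copy()
    t1 = np.zeros(spec.grid_shape)
    t1[at] = spec.tissue_t1_ms["AT"]
    t1[fgt] = spec.tissue_t1_ms["FGT"]
    s0 = np.where(at | fgt, spec.s0, 0.0)
    masks = {"AT": at, "FGT": fgt, "background": ~(at | fgt)}
    return _masked_ground_truth(spec, t1, s0, masks)


# ---------------------------------------------------------------------------
# Forward simulation


def _rician(mag: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    re = mag + rng.normal(0.0, sigma, mag.shape)
    im = rng.normal(0.0, sigma, mag.shape)
    return np.hypot(re, im)


def simulate_vfa(
    gt: GroundTruth,
    protocol: VFAProtocol | None = None,
    noise: NoiseSpec | None = None,
    _tag: int = 1,
) -> VFASeries:
    """Forward-simulate the multi-flip-angle SPGR series."""
    protocol = protocol or VFAProtocol()
    noise = noise or NoiseSpec()
    fg = gt.foreground
    t1 = np.where(fg, gt.t1_true.data, 1.0)
    s0 = np.where(fg, gt.s0_true.data, 0.0)
    f = np.where(fg, gt.f_true.f, 1.0)
    rng = noise.rng(_tag)
    volumes = []
    for a in protocol.flip_angles_deg:
        sig = spgr_signal(t1, s0, a, f=f, tr_ms=protocol.tr_ms)
        if noise.model != "none" and noise.sigma > 0:
            sig = _rician(sig, noise.sigma, rng)
        volumes.append(ImageVolume(sig, voxel_size_mm=protocol.voxel_size_mm,
                                   series_id=f"vfa_fa{a:g}"))
    return VFASeries(volumes=volumes,
                     flip_angles_deg=list(protocol.flip_angles_deg),
                     tr_ms=protocol.tr_ms, te_ms=protocol.te_ms)


def simulate_ir(
    gt: GroundTruth,
    protocol: IRProtocol | None = None,
    noise: NoiseSpec | None = None,
    _tag: int = 2,
) -> IRSeries:
    """Forward-simulate the magnitude inversion-recovery series."""
    protocol = protocol or IRProtocol()
    noise = noise or NoiseSpec()
    fg = gt.foreground
    t1 = np.where(fg, gt.t1_true.data, 1.0)
    s0 = np.where(fg, gt.s0_true.data, 0.0)
    rng = noise.rng(_tag)
    volumes = []
    for ti in protocol.ti_ms:
        sig = ir_signal(t1, s0, ti, td_ms=protocol.td_ms,
                        inv_flip_deg=protocol.inv_flip_deg)
        if noise.model != "none" and noise.sigma > 0:
            sig = _rician(sig, noise.sigma, rng)
        volumes.append(ImageVolume(sig, voxel_size_mm=protocol.voxel_size_mm,
                                   series_id=f"ir_ti{ti:g}"))
    return IRSeries(volumes=volumes, ti_ms=list(protocol.ti_ms),
                    td_ms=protocol.td_ms, inv_flip_deg=protocol.inv_flip_deg)


def simulate_bs_pair(
    gt: GroundTruth,
    pulse: PulseSpec | None = None,
    noise: NoiseSpec | None = None,
    nominal_b1_ut: float | None = None,
    voxel_size_mm: tuple[float, float, float] = (4.0, 1.33, 1.33),
    _tag: int = 3,
) -> BSPhasePair:
    """Forward-simulate the Bloch-Siegert image pair at opposite offsets.

    Each voxel's phase is the Bloch-simulated pulse phase at
    ``f_true * nominal_b1_ut`` (dense-grid interpolation of the same
    simulator the mapping stage uses); magnitude is ``s0_true``.
    """
    pulse = pulse or PulseSpec()
    noise = noise or NoiseSpec()
    if nominal_b1_ut is None:
        nominal_b1_ut = pulse.b1_rms_ut
    fg = gt.foreground
    f = np.where(fg, gt.f_true.f, 0.0)
    b1 = f * nominal_b1_ut
    grid = np.linspace(0.0, max(1e-6, 1.2 * b1.max()), 257)
    ph_plus, _ = _simulate_phases(pulse, grid, +1.0)
    ph_minus, _ = _simulate_phases(pulse, grid, -1.0)
    phase_plus = np.interp(b1, grid, ph_plus)
    phase_minus = np.interp(b1, grid, ph_minus)
    mag = np.where(fg, gt.s0_true.data, 0.0)
    img_p = mag * np.exp(1j * phase_plus)
    img_m = mag * np.exp(1j * phase_minus)
    if noise.model != "none" and noise.sigma > 0:
        rng = noise.rng(_tag)
        img_p = img_p + rng.normal(0, noise.sigma, img_p.shape) \
            + 1j * rng.normal(0, noise.sigma, img_p.shape)
        img_m = img_m + rng.normal(0, noise.sigma, img_m.shape) \
            + 1j * rng.normal(0, noise.sigma, img_m.shape)
    return BSPhasePair(
        img_plus=ImageVolume(img_p, voxel_size_mm=voxel_size_mm, series_id="bs_plus"),
        img_minus=ImageVolume(img_m, voxel_size_mm=voxel_size_mm, series_id="bs_minus"),
        offset_hz=pulse.offset_hz,
    )


def _shift_ground_truth(gt: GroundTruth, jitter: tuple[int, int, int]) -> GroundTruth:
    """Integer-voxel translation (periodic roll; phantoms are interior)."""
    shape = gt.t1_true.shape
    if any(abs(j) >= s for j, s in zip(jitter, shape)):
        raise ValueError(f"jitter {jitter} larger than grid {shape}")
    roll = lambda a: np.roll(a, jitter, axis=(0, 1, 2))
    masks = {k: roll(np.asarray(m, dtype=bool)) for k, m in gt.masks.items()}
    return GroundTruth(
        t1_true=ImageVolume(roll(gt.t1_true.data), gt.t1_true.voxel_size_mm,
                            kind="parameter"),
        s0_true=ImageVolume(roll(gt.s0_true.data), gt.s0_true.voxel_size_mm,
                            kind="parameter"),
        f_true=CorrectionFactorMap(f=roll(gt.f_true.f), pulse_id=gt.f_true.pulse_id,
                                   valid_mask=roll(gt.f_true.valid_mask)),
        masks=masks,
    )


def simulate_testretest(
    gt: GroundTruth,
    vfa_protocol: VFAProtocol | None = None,
    ir_protocol: IRProtocol | None = None,
    pulse: PulseSpec | None = None,
    noise: NoiseSpec | None = None,
    jitter: tuple[int, int, int] = (0, 0, 0),
    gt_session2: GroundTruth | None = None,
) -> tuple[dict, dict]:
    """Two independent-noise acquisitions of {VFA, IR, BS}.

    The second session uses ``gt_session2`` if supplied (e.g. a phantom
    with a different transmit field, emulating repositioning) and is
    translated by ``jitter`` voxels.  Returns two dicts with keys
    ``vfa``, ``ir``, ``bs`` and ``gt``.
    """
    noise = noise or NoiseSpec()
    gt2 = gt_session2 if gt_session2 is not None else gt
    if any(jitter):
        gt2 = _shift_ground_truth(gt2, jitter)
    sessions = []
    for k, g in enumerate((gt, gt2), start=1):
        # per-session tags give distinct noise streams, identical across reruns
        sessions.append({
            "gt": g,
            "vfa": simulate_vfa(g, vfa_protocol, noise, _tag=10 * k + 1),
            "ir": simulate_ir(g, ir_protocol, noise, _tag=10 * k + 2),
            "bs": simulate_bs_pair(g, pulse, noise, _tag=10 * k + 3),
        })
    return sessions[0], sessions[1]
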