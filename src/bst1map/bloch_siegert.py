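"""Bloch-Siegert B1 mapping.

An off-resonant RF pulse imparts a phase on the transverse magnetization
without exciting it; the accrued phase grows (to leading order) as the
square of the RF amplitude B1 and flips sign with the frequency offset.
Acquiring two images at opposite offsets and taking the phase of
``img_plus * conj(img_minus)`` therefore isolates a B1-dependent phase that
is insensitive to B0, receiver phase and relaxation.  The phase-to-B1
relation is obtained by Bloch-equation simulation of the actual pulse
(hard-pulse product of rotations, no relaxation), tabulated on a B1 grid
and inverted by linear interpolation; dividing the mapped B1 by the nominal
transmit amplitude gives the per-voxel flip-angle correction factor f.

Conventions
-----------
The simulator works in the frame rotating at the Larmor frequency of an
on-resonance spin, starting from unit transverse magnetization along +x.
The receiver phase convention is chosen so that a pulse at *positive*
frequency offset accrues *positive* phase; with that convention the
phase-difference table is strictly increasing in B1 over the design range.

Gyromagnetic ratio: 42.577478518 Hz/uT (proton).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import CorrectionFactorMap, ImageVolume, BSPhasePair

__all__ = [
    "GAMMA_HZ_PER_UT",
    "PulseSpec",
    "PhaseLookupTable",
    "PulseRegimeError",
    "simulate_pulse_phase",
    "b0_sensitivity_sweep",
    "build_lookup_table",
    "phase_difference",
    "correction_map_from_phase",
]

GAMMA_HZ_PER_UT = 42.577478518  # Hz per microtesla, proton

_SHAPES = ("constant", "fermi", "gaussian", "freq_swept")


class PulseRegimeError(RuntimeError):
    """The pulse excites magnetization and violates the pure-phase regime."""


@dataclass
class PulseSpec:
    """Off-resonant phase-imparting pulse.

    Parameters
    ----------
    duration_ms
        Pulse length in milliseconds.
    shape
        Amplitude envelope: ``constant``, ``fermi`` (flat top with smooth
        Fermi-function edges), ``gaussian``, or ``freq_swept`` (Fermi
        envelope with a linear frequency sweep).
    offset_hz
        Nominal off-resonance in Hz (magnitude; the pair is acquired at
        +/- this offset).
    b1_rms_ut
        Root-mean-square B1 amplitude in microtesla at nominal transmit.
    shape_params
        Shape-specific overrides: ``flat_ms`` / ``transition_ms`` (fermi,
        freq_swept), ``sigma_ms`` (gaussian), ``sweep_start_hz`` /
        ``sweep_end_hz`` (freq_swept; defaults 2x and 1x ``offset_hz``).
    n_steps
        Hard-pulse integration steps (>= 100).
    """

    duration_ms: float = 2.0
    shape: str = "fermi"
    offset_hz: float = 8000.0
    b1_rms_ut: float = 2.29
    shape_params: dict = field(default_factory=dict)
    n_steps: int = 2000

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if self.offset_hz <= 0:
            raise ValueError("offset_hz must be positive (sign is applied per image)")
        if self.b1_rms_ut <= 0:
            raise ValueError("b1_rms_ut must be positive")
        if self.n_steps < 100:
            raise ValueError("n_steps must be >= 100")
        if self.offset_hz < 10.0 * GAMMA_HZ_PER_UT * self.b1_rms_ut:
            warnings.warn(
                "pulse offset is < 10x gamma*B1: the pure-phase (no-excitation) "
                "regime may be violated",
                stacklevel=2,
            )

    @property
    def pulse_id(self) -> str:
        return (
            f"{self.shape}_{self.duration_ms:g}ms_{self.offset_hz:g}Hz_"
            f"{self.b1_rms_ut:g}uT"
        )

    def _midpoints_s(self) -> np.ndarray:
        dt = self.duration_ms * 1e-3 / self.n_steps
        return (np.arange(self.n_steps) + 0.5) * dt

    def envelope(self) -> np.ndarray:
        """Unit-RMS amplitude envelope sampled at the step midpoints."""
        t = self._midpoints_s()
        T = self.duration_ms * 1e-3
        if self.shape == "constant":
            e = np.ones_like(t)
        elif self.shape in ("fermi", "freq_swept"):
            flat = self.shape_params.get("flat_ms", 0.35 * self.duration_ms) * 1e-3
            trans = self.shape_params.get("transition_ms", 0.05 * self.duration_ms) * 1e-3
            e = 1.0 / (1.0 + np.exp((np.abs(t - T / 2) - flat) / trans))
        elif self.shape == "gaussian":
            sigma = self.shape_params.get("sigma_ms", self.duration_ms / 6.0) * 1e-3
            e = np.exp(-((t - T / 2) ** 2) / (2 * sigma**2))
        else:  # pragma: no cover - guarded in __post_init__
            raise ValueError(self.shape)
        return e / np.sqrt(np.mean(e**2))

    def offset_waveform_hz(self) -> np.ndarray:
        """Instantaneous frequency offset (positive branch) at step midpoints."""
        t = self._midpoints_s()
        if self.shape == "freq_swept":
            start = self.shape_params.get("sweep_start_hz", 2.0 * self.offset_hz)
            end = self.shape_params.get("sweep_end_hz", self.offset_hz)
            T = self.duration_ms * 1e-3
            return start + (end - start) * t / T
        return np.full_like(t, self.offset_hz)


def _simulate_phases(
    pulse: PulseSpec, b1_ut: np.ndarray, offset_sign: float,
    spin_offset_hz: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Hard-pulse Bloch integration for an array of B1 amplitudes.

    Returns ``(phase_rad, mz)`` where ``phase_rad`` is the accrued phase of
    the transverse magnetization and ``mz`` the residual longitudinal
    component (excitation; 0 in the ideal pure-phase regime).  The product
    of exact rotations preserves |M| by construction.  ``spin_offset_hz``
    adds a static off-resonance of the spin itself (used only by the
    validation sweep; the mapping pipeline assumes on-resonance water).
    """
    b1 = np.atleast_1d(np.asarray(b1_ut, dtype=float))
    if np.any(b1 < 0):
        raise ValueError("b1_ut must be non-negative")
    dt = pulse.duration_ms * 1e-3 / pulse.n_steps
    env = pulse.envelope()
    off = pulse.offset_waveform_hz() * float(offset_sign) - spin_offset_hz
    # RF phase at step midpoints: integral of the instantaneous offset
    # relative to the spin's own precession
    phi = 2 * np.pi * (np.cumsum(off) - 0.5 * off) * dt
    ax, ay = np.cos(phi), np.sin(phi)
    theta_scale = 2 * np.pi * GAMMA_HZ_PER_UT * dt
    mx = np.ones_like(b1)
    my = np.zeros_like(b1)
    mz = np.zeros_like(b1)
    for k in range(pulse.n_steps):
        theta = theta_scale * env[k] * b1
        c, s = np.cos(theta), np.sin(theta)
        nx, ny = ax[k], ay[k]
        dot = nx * mx + ny * my
        # cross = n x M with n in the xy-plane
        cx = ny * mz
        cy = -nx * mz
        cz = nx * my - ny * mx
        one_c = 1.0 - c
        mx = mx * c + cx * s + nx * dot * one_c
        my = my * c + cy * s + ny * dot * one_c
        mz = mz * c + cz * s
    # receiver convention: conjugate readout so +offset accrues +phase
    phase = np.arctan2(-my, mx)
    return phase, mz


def b0_sensitivity_sweep(
    pulse: PulseSpec, b1_ut: float, spin_offsets_hz
) -> np.ndarray:
    """Phase difference versus static spin off-resonance (validation only).

    Evaluates the +/- offset phase difference at ``b1_ut`` for each spin
    off-resonance value, quantifying how much a B0 shift (e.g. the fat
    chemical shift) perturbs the mapped phase relative to on-resonance
    water.  This is a diagnostic sweep, not a correction: the mapping
    pipeline itself always assumes on-resonance spins.
    """
    out = []
    for b0 in np.atleast_1d(np.asarray(spin_offsets_hz, dtype=float)):
        plus, _ = _simulate_phases(pulse, np.array([b1_ut]), +1.0, b0)
        minus, _ = _simulate_phases(pulse, np.array([b1_ut]), -1.0, b0)
        out.append(float(plus[0] - minus[0]))
    return np.array(out)


def simulate_pulse_phase(
    pulse: PulseSpec, b1_ut: float, offset_sign: float = +1.0
) -> float:
    """Accrued Bloch-Siegert phase (rad) of transverse magnetization.

    Integrates the Bloch equations (no relaxation) for an on-resonance spin
    under the off-resonant pulse at amplitude ``b1_ut`` (the pulse envelope
    is scaled so its RMS equals ``b1_ut``).  Raises
    :class:`PulseRegimeError` if the pulse excites more than 1% of the
    magnetization (measured as loss of transverse magnitude).
    """
    if b1_ut < 0:
        raise ValueError("b1_ut must be non-negative")
    phase, mz = _simulate_phases(pulse, np.array([b1_ut]), offset_sign)
    excitation = 1.0 - np.sqrt(max(0.0, 1.0 - float(mz[0]) ** 2))
    if excitation > 0.01:
        raise PulseRegimeError(
            f"pulse excites {100 * excitation:.2f}% of the magnetization at "
            f"B1 = {b1_ut:g} uT; not a pure phase-imparting pulse"
        )
    return float(phase[0])


@dataclass
class PhaseLookupTable:
    """Phase-difference-versus-B1 calibration table for one pulse.

    ``phase_diff_rad[i]`` is the phase of the +offset image minus the phase
    of the -offset image simulated at ``b1_grid_ut[i]``.  The table starts
    at B1 = 0 (phase difference exactly 0) and must be strictly increasing
    over the design range, which makes the piecewise-linear inverse
    single-valued.
    """

    b1_grid_ut: np.ndarray
    phase_diff_rad: np.ndarray
    pulse: PulseSpec

    def __post_init__(self) -> None:
        self.b1_grid_ut = np.asarray(self.b1_grid_ut, dtype=float)
        self.phase_diff_rad = np.asarray(self.phase_diff_rad, dtype=float)
        if self.b1_grid_ut.shape != self.phase_diff_rad.shape:
            raise ValueError("grid and phase arrays must have equal length")
        if self.b1_grid_ut[0] != 0.0:
            raise ValueError("B1 grid must start at 0")
        if np.any(np.diff(self.b1_grid_ut) <= 0):
            raise ValueError("B1 grid must be strictly ascending")
        if abs(self.phase_diff_rad[0]) > 1e-12:
            raise ValueError("phase difference at B1 = 0 must be 0")
        if np.any(np.diff(self.phase_diff_rad) <= 0):
            raise ValueError(
                "phase-difference table is not strictly increasing: the pulse "
                "leaves the design regime over this B1 range"
            )

    def b1_from_phase(self, phase_rad: np.ndarray) -> np.ndarray:
        """Piecewise-linear inverse; NaN outside the tabulated phase range."""
        phase = np.asarray(phase_rad, dtype=float)
        out = np.interp(phase, self.phase_diff_rad, self.b1_grid_ut)
        out = np.where(
            (phase < self.phase_diff_rad[0]) | (phase > self.phase_diff_rad[-1]),
            np.nan,
            out,
        )
        return out

    def phase_at(self, b1_ut) -> np.ndarray:
        """Forward interpolation of the phase difference at given B1."""
        return np.interp(np.asarray(b1_ut, dtype=float), self.b1_grid_ut, self.phase_diff_rad)

    def to_csv(self, path) -> Path:
        path = Path(path)
        header = f"b1_ut,phase_diff_rad  # pulse={self.pulse.pulse_id}"
        np.savetxt(
            path,
            np.column_stack([self.b1_grid_ut, self.phase_diff_rad]),
            delimiter=",",
            header=header,
        )
        return path


def build_lookup_table(
    pulse: PulseSpec, b1_max_ut: float | None = None, n_points: int = 64
) -> PhaseLookupTable:
    """Simulate the pulse over a B1 grid and build the calibration table.

    ``b1_max_ut`` defaults to 2.5x the pulse's nominal RMS amplitude and
    must cover at least twice the nominal B1; ``n_points >= 32``.  The
    construction is deterministic: identical specs give bit-identical
    tables.
    """
    if b1_max_ut is None:
        b1_max_ut = 2.5 * pulse.b1_rms_ut
    if b1_max_ut < 2.0 * pulse.b1_rms_ut:
        raise ValueError("b1_max_ut must cover at least 2x the nominal B1")
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    grid = np.linspace(0.0, b1_max_ut, n_points)
    phase_plus, mz_plus = _simulate_phases(pulse, grid, +1.0)
    phase_minus, mz_minus = _simulate_phases(pulse, grid, -1.0)
    mz_worst = float(np.max(np.abs(np.concatenate([mz_plus, mz_minus]))))
    excitation = 1.0 - np.sqrt(max(0.0, 1.0 - mz_worst**2))
    if excitation > 0.01:
        raise PulseRegimeError(
            f"pulse excites {100 * excitation:.2f}% of the magnetization "
            f"within the table range (B1 up to {b1_max_ut:g} uT)"
        )
    return PhaseLookupTable(
        b1_grid_ut=grid, phase_diff_rad=phase_plus - phase_minus, pulse=pulse
    )


def phase_difference(pair: BSPhasePair) -> ImageVolume:
    """Per-voxel phase of ``img_plus * conj(img_minus)`` in (-pi, pi].

    Voxels where either magnitude vanishes carry NaN (no phase defined).
    """
    prod = pair.img_plus.data * np.conj(pair.img_minus.data)
    phase = np.angle(prod)
    invalid = (np.abs(pair.img_plus.data) == 0) | (np.abs(pair.img_minus.data) == 0)
    phase = np.where(invalid, np.nan, phase)
    return ImageVolume(
        data=phase,
        voxel_size_mm=pair.img_plus.voxel_size_mm,
        series_id=f"{pair.img_plus.series_id}_phasediff",
        kind="phase",
    )


def correction_map_from_phase(
    lookup: PhaseLookupTable, phase_map: ImageVolume, nominal_b1_ut: float
) -> CorrectionFactorMap:
    """Convert a measured phase-difference map into a flip-angle correction map.

    Each voxel's B1 is read off the inverse lookup table by linear
    interpolation; ``f = B1 / nominal_b1_ut``.  Phase outside the table
    range is flagged invalid rather than extrapolated.  Raises if the
    nominal B1 lies outside the table or if no voxel is valid.
    """
    if not (lookup.b1_grid_ut[0] <= nominal_b1_ut <= lookup.b1_grid_ut[-1]):
        raise ValueError("nominal_b1_ut outside the lookup-table range")
    if nominal_b1_ut <= 0:
        raise ValueError("nominal_b1_ut must be positive")
    b1 = lookup.b1_from_phase(phase_map.data.real)
    f = b1 / nominal_b1_ut
    valid = np.isfinite(f) & (f > 0)
    if not valid.any():
        raise ValueError("no voxel carries a phase within the lookup-table range")
    f = np.where(valid, f, np.nan)
    return CorrectionFactorMap(f=f, pulse_id=lookup.pulse.pulse_id, valid_mask=valid)
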