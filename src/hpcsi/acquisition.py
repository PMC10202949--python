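"""Acquisition geometry and spectral bookkeeping for dynamic 2D 13C CSI.

The acquisition emulated throughout the package is a 14.1 T dynamic
chemical-shift-imaging protocol: an 8x8 phase-encoded grid over a
24x24 mm^2 field of view (5 mm slice), 128 spectral points over a
2500 Hz window, one frame every 4 s for one minute, 10 degree
excitations at TR = 60 ms.  The 2500 Hz window cannot hold the full
~21 ppm span of urea/pyruvate/lactate at 14.1 T, so off-carrier
resonances alias; :func:`ppm_to_offset_hz` returns apparent (wrapped)
offsets and every consumer works with those.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GAMMA_BAR_13C_MHZ_PER_T",
    "AcquisitionParams",
    "Resonance",
    "ResonanceTable",
    "default_resonances",
    "ppm_to_offset_hz",
]

#: Reduced gyromagnetic ratio of 13C (MHz per tesla).
GAMMA_BAR_13C_MHZ_PER_T = 10.7084


@dataclass(frozen=True)
class AcquisitionParams:
    """Fixed constants of the dynamic CSI acquisition.

    Parameters mirror the protocol described in the module docstring;
    all are overridable for sensitivity studies.  ``carbon_frequency_mhz``
    defaults to ``B0 * 10.7084``.
    """

    b0_tesla: float = 14.1
    spectral_width_hz: float = 2500.0
    n_spectral_points: int = 128
    tr_s: float = 0.06
    flip_angle_deg: float = 10.0
    matrix: int = 8
    fov_mm: float = 24.0
    slice_thickness_mm: float = 5.0
    frame_interval_s: float = 4.0
    n_frames: int = 15
    carrier_ppm: float = 173.0
    carbon_frequency_mhz: float | None = None

    def __post_init__(self) -> None:
        if self.matrix < 2:
            raise ValueError("matrix must be >= 2")
        for name in ("spectral_width_hz", "tr_s", "frame_interval_s", "fov_mm",
                     "slice_thickness_mm", "b0_tesla"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_spectral_points < 2 or self.n_frames < 1:
            raise ValueError("n_spectral_points >= 2 and n_frames >= 1 required")
        if not (0.0 <= self.flip_angle_deg < 90.0):
            raise ValueError("flip angle must be in [0, 90) degrees")
        if self.carbon_frequency_mhz is None:
            object.__setattr__(
                self, "carbon_frequency_mhz",
                GAMMA_BAR_13C_MHZ_PER_T * self.b0_tesla,
            )

    # -- derived quantities -------------------------------------------------

    @property
    def dwell_time_s(self) -> float:
        return 1.0 / self.spectral_width_hz

    @property
    def flip_angle_rad(self) -> float:
        return math.radians(self.flip_angle_deg)

    @property
    def lambda_rf(self) -> float:
        """Continuous-equivalent RF depletion rate -ln(cos theta)/TR (1/s).

        The 64 phase encodes of each frame excite the slice continuously
        at TR spacing; folding the per-excitation cos(theta) loss into a
        first-order rate makes the kinetic ODEs autonomous.
        """
        return -math.log(math.cos(self.flip_angle_rad)) / self.tr_s

    @property
    def total_duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def frame_mid_times_s(self) -> np.ndarray:
        """Midpoint time of each frame (s), frame 0 starting at t = 0."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_interval_s

    @property
    def hz_per_ppm(self) -> float:
        return self.carbon_frequency_mhz  # 1 ppm at f0 MHz is f0 Hz

    def spectral_time_axis(self) -> np.ndarray:
        """FID sampling times t_k = k / SW (s)."""
        return np.arange(self.n_spectral_points) * self.dwell_time_s

    def frequency_axis(self) -> np.ndarray:
        """Centered spectral axis (Hz), monotonically increasing."""
        return np.fft.fftshift(
            np.fft.fftfreq(self.n_spectral_points, d=self.dwell_time_s)
        )

    def replace(self, **kw) -> "AcquisitionParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class Resonance:
    """A single spectral line: chemical shift and Lorentzian linewidth."""

    name: str
    ppm: float
    fwhm_hz: float = 20.0

    def __post_init__(self) -> None:
        if self.fwhm_hz <= 0:
            raise ValueError("fwhm_hz must be positive")


@dataclass(frozen=True)
class ResonanceTable:
    """Ordered set of resonances with distinct chemical shifts."""

    resonances: tuple[Resonance, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        shifts = [r.ppm for r in self.resonances]
        if len(set(shifts)) != len(shifts):
            raise ValueError("chemical shifts must be distinct")

    def __iter__(self):
        return iter(self.resonances)

    def __len__(self) -> int:
        return len(self.resonances)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.resonances)

    def get(self, name: str) -> Resonance:
        for r in self.resonances:
            if r.name == name:
                return r
        raise KeyError(name)

    def apparent_offsets_hz(self, acq: AcquisitionParams) -> dict[str, float]:
        return {r.name: ppm_to_offset_hz(r.ppm, acq) for r in self.resonances}


def default_resonances(fwhm_hz: float = 20.0) -> ResonanceTable:
    """Urea (162.5 ppm), pyruvate (171 ppm), lactate (183.5 ppm)."""
    return ResonanceTable((
        Resonance("urea", 162.5, fwhm_hz),
        Resonance("pyruvate", 171.0, fwhm_hz),
        Resonance("lactate", 183.5, fwhm_hz),
    ))


def ppm_to_offset_hz(ppm: float, acq: AcquisitionParams) -> float:
    """Apparent frequency offset (Hz) of a resonance after aliasing.

    The true offset ``(ppm - carrier_ppm) * f0`` is wrapped into
    ``[-SW/2, SW/2)``; resonances outside the spectral window fold back in
    by the modular identity of discrete sampling.
    """
    offset = (ppm - acq.carrier_ppm) * acq.hz_per_ppm
    sw = acq.spectral_width_hz
    return float((offset + sw / 2.0) % sw - sw / 2.0)
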