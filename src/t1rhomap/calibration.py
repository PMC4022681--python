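"""B0 mapping from WASSR z-spectra, double-angle B1 mapping, and STEAM
reference-voltage calibration.

WASSR (water saturation shift referencing) localizes the direct-saturation
dip of each voxel's z-spectrum; the dip center is the per-voxel B0 offset.
The dip is found by cubic interpolation of the sampled spectrum onto a 1 Hz
grid and taking the minimum — sub-Hz accurate at the protocol's 0.1 ppm
sampling.  Voxels whose minimum falls on the sampled boundary are censored
to NaN (the true dip may lie outside the sweep).

The double-angle method assumes full relaxation between excitations
(long-TR regime; the protocol's 5 s shot TR): from magnitude signals at
nominal flips alpha and 2*alpha, the actual angle is
``arccos(S_2a / (2 S_a))`` and B1rel is actual/nominal.

STEAM single-voxel spectroscopy with three identical flip angles alpha has
signal proportional to sin^3(alpha).  Two spectra at transmitter voltages x
and 2x give S2/S1 = sin^3(2a)/sin^3(a) = 8 cos^3(a), so
``alpha = arccos((S2/(8 S1))^(1/3))``; assuming flip angle linear in
voltage, the reference voltage (a true 90 deg) is ``x * 90/alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .core_io import FieldMap, RegionMask


@dataclass
class ZSpectrumSeries:
    """Signal volumes over saturation frequency offsets.

    offsets_ppm must be strictly increasing; a symmetric design around 0 is
    typical (the knee protocol sweeps -0.8..0.8 ppm in 0.1 ppm steps at
    saturation B1 = 20 Hz, 200 ms).
    """

    volumes: np.ndarray
    offsets_ppm: list[float]
    sat_b1_hz: float = 20.0
    sat_dur_ms: float = 200.0
    field_T: float = 7.0

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.offsets_ppm = [float(o) for o in self.offsets_ppm]
        if self.volumes.ndim != 4 or self.volumes.shape[3] != len(self.offsets_ppm):
            raise ValueError("volumes must be 4D with one volume per offset")
        if np.any(np.diff(self.offsets_ppm) <= 0):
            raise ValueError("offsets_ppm must be strictly increasing")

    @property
    def offsets_hz(self) -> np.ndarray:
        from .spinlock_sim import ppm_to_hz

        return ppm_to_hz(self.offsets_ppm, self.field_T)


@dataclass
class SteamPair:
    """Peak water signals of two STEAM spectra at voltages x and 2x."""

    s1: float
    s2: float
    x_volts: float

    def __post_init__(self) -> None:
        if self.s1 <= 0 or self.s2 < 0 or self.x_volts <= 0:
            raise ValueError("require s1 > 0, s2 >= 0, x_volts > 0")


def wassr_b0_map(z: ZSpectrumSeries, mask: RegionMask | np.ndarray) -> FieldMap:
    """Per-voxel B0 offset (Hz) from the WASSR dip minimum.

    The sampled z-spectrum is upsampled by cubic interpolation to a 1 Hz grid
    spanning the sweep; the offset minimizing the interpolated signal is the
    voxel's B0.  Boundary minima and constant spectra give NaN.
    """
    if len(z.offsets_ppm) < 5:
        raise ValueError("need at least 5 saturation offsets spanning the dip")
    sel = mask.cartilage if isinstance(mask, RegionMask) else np.asarray(mask, bool)
    offsets_hz = z.offsets_hz
    fine = np.arange(np.ceil(offsets_hz[0]), np.floor(offsets_hz[-1]) + 1.0, 1.0)

    spectra = z.volumes[sel]  # (n_vox, n_offsets)
    out = np.full(z.volumes.shape[:3], np.nan)
    vals = np.full(spectra.shape[0], np.nan)
    const = np.ptp(spectra, axis=1) <= 0
    good = ~const
    if np.any(good):
        spline = CubicSpline(offsets_hz, spectra[good], axis=1)
        interp = spline(fine)
        idx = np.argmin(interp, axis=1)
        centers = fine[idx]
        interior = (idx > 0) & (idx < len(fine) - 1)
        centers[~interior] = np.nan
        vals[good] = centers
    out[sel] = vals
    return FieldMap(values=out, kind="b0_hz", voxel_size_mm=z_voxel_size(z, mask))


def z_voxel_size(z: ZSpectrumSeries, mask) -> tuple[float, float, float]:
    if isinstance(mask, RegionMask):
        return tuple(mask.voxel_size_mm)
    return (1.0, 1.0, 1.0)


def double_angle_b1_map(
    s_low: np.ndarray,
    s_high: np.ndarray,
    alpha0_deg: float,
    mask: RegionMask | np.ndarray,
    voxel_size_mm=(1.0, 1.0, 1.0),
) -> FieldMap:
    """Relative B1 from magnitude volumes at nominal flips alpha0 and 2*alpha0.

    actual angle = arccos(S_high / (2 S_low)); B1rel = actual / alpha0.
    Ratios outside the arccos domain, or zero S_low, give NaN.
    """
    s_low = np.asarray(s_low, dtype=float)
    s_high = np.asarray(s_high, dtype=float)
    sel = mask.cartilage if isinstance(mask, RegionMask) else np.asarray(mask, bool)
    if isinstance(mask, RegionMask):
        voxel_size_mm = tuple(mask.voxel_size_mm)

    out = np.full(s_low.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s_high / (2.0 * s_low)
    ok = sel & (s_low > 0) & (ratio > 0.0) & (ratio < 1.0)  # cos(actual) in (0, 1)
    actual_deg = np.degrees(np.arccos(ratio[ok]))
    out[ok] = actual_deg / alpha0_deg
    return FieldMap(values=out, kind="b1rel", voxel_size_mm=voxel_size_mm)


def steam_flip_angle(pair: SteamPair) -> float:
    """Actual flip angle (degrees) at the preset voltage, from S proportional to sin^3."""
    ratio = pair.s2 / (8.0 * pair.s1)
    if ratio > 1.0:
        raise ValueError(
            f"inconsistent STEAM pair: s2/(8*s1) = {ratio:.4f} > 1 has no real flip angle"
        )
    return float(np.degrees(np.arccos(np.cbrt(ratio))))


def reference_voltage(pair: SteamPair) -> float:
    """Transmitter voltage producing a true 90 deg flip, assuming linearity.

    V = x * (90 / alpha) where alpha is the actual angle at preset voltage x.
    """
    alpha = steam_flip_angle(pair)
    return pair.x_volts * 90.0 / alpha


def frequency_offset_summary(b0: FieldMap, mask: RegionMask | np.ndarray) -> tuple[float, float]:
    """(mean, s.d.) of the B0 offset in Hz over masked finite voxels."""
    sel = mask.cartilage if isinstance(mask, RegionMask) else np.asarray(mask, bool)
    vals = b0.values[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 masked voxels with finite B0 values")
    return float(np.mean(vals)), float(np.std(vals, ddof=1))
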