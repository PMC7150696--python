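"""Inverse-filter restoration and the sharpness high-pass filter.

The measured scan-direction transfer H(f) of the detector chain is flattened
by multiplying row spectra with a capped reciprocal gain 1/H(f).  A plain
capped reciprocal (not a Wiener filter) is used: noise control is delegated to
frame integration, which is the point of the acquisition scheme.  The
high-pass filter isolates fine structure for the S_sigma(HPF) sharpness score;
only its half-amplitude wavelength matters, not its exact shape.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .spectra import FrequencyProfile

__all__ = [
    "InverseFilter",
    "FilterSpec",
    "design_inverse_filter",
    "apply_inverse_filter",
    "highpass",
    "highpass_transfer",
]

DEFAULT_GAIN_CAP = 10.0
DEFAULT_SMOOTH_WINDOW = 9


@dataclasses.dataclass(frozen=True)
class InverseFilter:
    """Frequency-domain gains >= 1 on the horizontal axis, unity at DC."""

    frequencies: np.ndarray
    gains: np.ndarray
    gain_cap: float
    source_profile: FrequencyProfile | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, float)
        g = np.asarray(self.gains, float)
        if f.shape != g.shape or f.ndim != 1:
            raise ValueError("frequencies and gains must be 1-D of equal length")
        if np.any(g < 1.0 - 1e-9) or np.any(g > self.gain_cap + 1e-9):
            raise ValueError("gains must lie in [1, gain_cap]")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "gains", g)

    @classmethod
    def identity(cls, n: int = 64) -> "InverseFilter":
        f = np.linspace(0.0, 0.5, n)
        return cls(f, np.ones(n), gain_cap=1.0)

    def to_csv(self, path) -> None:
        FrequencyProfile(self.frequencies, self.gains, "horizontal").to_csv(path)

    @classmethod
    def from_csv(cls, path, gain_cap: float | None = None) -> "InverseFilter":
        prof = FrequencyProfile.from_csv(path)
        cap = gain_cap if gain_cap is not None else float(prof.values.max())
        return cls(prof.frequencies, prof.values, gain_cap=cap)


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """High-pass specification: largest passed structure, in pixels.

    The filter suppresses spatial wavelengths longer than ``structure_size``.
    For a 640x480 frame the working default is 8 px; the parameter scales with
    the pixel count (16 px at 1280x960), so the normalized transfer depends
    only on ``frequency * structure_size``.
    """

    structure_size: float = 8.0
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.structure_size < 2:
            raise ValueError("structure_size must be >= 2 pixels")
        if self.image_shape is not None:
            self.validate_shape(self.image_shape)

    def validate_shape(self, shape: tuple[int, int]) -> None:
        if self.structure_size >= min(shape) / 2:
            raise ValueError(
                f"structure_size {self.structure_size} out of range for image shape {shape}"
            )


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    if window % 2 == 0:
        window += 1
    pad = window // 2
    padded = np.pad(values, pad, mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def design_inverse_filter(
    profile: FrequencyProfile,
    gain_cap: float = DEFAULT_GAIN_CAP,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> InverseFilter:
    """Capped reciprocal of the (smoothed) measured transfer.

    ``gains = clip(1 / smoothed(profile), 1, gain_cap)``, renormalized so the
    gain at the lowest frequency is exactly 1.  Smoothing (moving average over
    ``smooth_window`` frequency bins) prevents amplification of estimation
    noise in a measured profile.
    """
    if gain_cap < 1.0:
        raise ValueError("gain_cap must be >= 1")
    smoothed = _moving_average(profile.values, smooth_window)
    if np.any(smoothed <= 0):
        if not np.isfinite(gain_cap):
            raise ValueError("profile contains zeros and no active gain cap")
        raw = np.where(smoothed > 0, 1.0 / np.where(smoothed > 0, smoothed, 1.0), gain_cap)
    else:
        raw = 1.0 / smoothed
    gains = np.clip(raw, 1.0, gain_cap)
    gains = np.clip(gains / gains[0], 1.0, gain_cap)
    return InverseFilter(profile.frequencies, gains, gain_cap, profile)


def apply_inverse_filter(image: np.ndarray, filt: InverseFilter) -> np.ndarray:
    """Multiply row spectra by the filter gains; the vertical axis is untouched."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    ncols = image.shape[1]
    freqs = np.fft.rfftfreq(ncols)
    gains = np.interp(freqs, filt.frequencies, filt.gains)
    return np.fft.irfft(np.fft.rfft(image, axis=1) * gains, n=ncols, axis=1)


def highpass_transfer(shape: tuple[int, int], spec: FilterSpec) -> np.ndarray:
    """Isotropic high-pass transfer on the unshifted 2-D frequency grid.

    Gaussian transition with half amplitude at wavelength ``structure_size``:
    ``T(f) = 1 - exp(-ln2 * (f * structure_size)**2)``, so T(0) = 0 and the
    output is zero-mean.
    """
    spec.validate_shape(shape)
    fy = np.fft.fftfreq(shape[0])
    fx = np.fft.fftfreq(shape[1])
    r2 = fy[:, None] ** 2 + fx[None, :] ** 2
    return 1.0 - np.exp(-np.log(2.0) * r2 * spec.structure_size**2)


def highpass(image: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Frequency-domain high pass keeping structures smaller than the spec size."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    transfer = highpass_transfer(image.shape, spec)
    return np.real(np.fft.ifft2(np.fft.fft2(image) * transfer))
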