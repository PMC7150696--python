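"""Amplitude spectra and frequency-characteristic measurement.

The scan-direction transfer function of a video-rate SEM detector chain is
estimated from pure-noise frames (specimen perfectly defocused): white noise
entering the chain leaves the detector carrying the chain's frequency response
imprinted along the fast-scan (horizontal) axis, while the vertical axis is
untouched.  Averaged spectral line profiles therefore measure the transfer
directly, and the vertical profile provides the flat reference that cancels the
noise floor.
"""
from __future__ import annotations

import csv
import dataclasses
import warnings
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "FrequencyProfile",
    "amplitude_spectrum",
    "axis_profile",
    "radial_profile",
    "measure_detector_response",
]

Axis = Literal["horizontal", "vertical", "radial"]

#: fraction of the lowest frequencies treated as the "plateau" when a profile
#: is normalized so its low-frequency level is 1.
PLATEAU_FRACTION = 0.05


@dataclasses.dataclass(frozen=True)
class FrequencyProfile:
    """Amplitude versus normalized spatial frequency along one axis.

    Frequencies are in cycles/pixel on ``[0, 0.5]`` (0.5 = Nyquist).  The
    ``horizontal`` axis is the fast-scan direction; this is where the detector
    chain's low-pass behaviour lives.
    """

    frequencies: np.ndarray
    values: np.ndarray
    axis: Axis = "horizontal"

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if f.ndim != 1 or v.ndim != 1 or f.size != v.size:
            raise ValueError("frequencies and values must be 1-D of equal length")
        if f.size < 2:
            raise ValueError("a profile needs at least two points")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if f[0] < 0 or f[-1] > 0.5 + 1e-12:
            raise ValueError("frequencies must lie in [0, 0.5] cycles/pixel")
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(v))):
            raise ValueError("profile contains non-finite entries")
        if np.any(v < 0):
            raise ValueError("profile values must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", v)

    @classmethod
    def flat(cls, value: float = 1.0, n: int = 64, axis: Axis = "horizontal") -> "FrequencyProfile":
        f = np.linspace(0.0, 0.5, n)
        return cls(f, np.full(n, float(value)), axis)

    def resample(self, frequencies: np.ndarray) -> np.ndarray:
        """Linearly interpolate the profile onto ``frequencies`` (edge-held)."""
        return np.interp(np.asarray(frequencies, float), self.frequencies, self.values)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["frequency", "amplitude"])
            for f, v in zip(self.frequencies, self.values):
                w.writerow([repr(float(f)), repr(float(v))])

    @classmethod
    def from_csv(cls, path, axis: Axis = "horizontal") -> "FrequencyProfile":
        freqs: list[float] = []
        vals: list[float] = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                try:
                    f = float(row[0])
                except ValueError:
                    continue  # header line
                freqs.append(f)
                vals.append(float(row[1]))
        return cls(np.asarray(freqs), np.asarray(vals), axis)


@dataclasses.dataclass(frozen=True)
class Spectrum:
    """Centred amplitude spectrum ``|DFT|`` of a mean-removed image.

    Scaled by ``1/sqrt(N)`` so that ``sum(amplitudes**2)`` equals the summed
    squared deviation of the image from its mean (Parseval).
    """

    amplitudes: np.ndarray
    source_shape: tuple[int, int]

    @property
    def center(self) -> tuple[int, int]:
        return self.amplitudes.shape[0] // 2, self.amplitudes.shape[1] // 2


def amplitude_spectrum(image: np.ndarray) -> Spectrum:
    """Centred amplitude spectrum of a 2-D image after mean removal."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    x = image - image.mean()
    amp = np.abs(np.fft.fftshift(np.fft.fft2(x))) / np.sqrt(x.size)
    return Spectrum(amp, image.shape)


def _fold_line(line: np.ndarray, center: int) -> tuple[np.ndarray, np.ndarray]:
    """Fold a centred 1-D spectrum line to positive frequencies, DC excluded."""
    n = line.size
    k = np.arange(1, (n - 1) // 2 + 1)
    vals = 0.5 * (line[center + k] + line[center - k])
    freqs = k / n
    if n % 2 == 0:
        # unpaired Nyquist bin sits at index 0 of the shifted array
        freqs = np.append(freqs, 0.5)
        vals = np.append(vals, line[0])
    return freqs, vals


def _normalize_plateau(values: np.ndarray) -> np.ndarray:
    nlow = max(1, int(round(PLATEAU_FRACTION * values.size)))
    level = values[:nlow].mean()
    if level <= 0:
        return values
    return values / level


def axis_profile(
    spectrum: Spectrum,
    axis: Literal["horizontal", "vertical"],
    n_lines: int = 256,
    normalize: bool = True,
) -> FrequencyProfile:
    """Line profile of the spectrum averaged over ``n_lines`` lines.

    For the horizontal profile the ``n_lines`` spectrum rows nearest the
    horizontal axis through DC are averaged (a few hundred lines suppresses
    the per-bin noise) and folded to positive horizontal frequencies.  The DC
    bin is excluded; with ``normalize`` the low-frequency plateau is scaled
    to 1.
    """
    amp = spectrum.amplitudes
    if axis == "vertical":
        amp = amp.T
    rows, cols = amp.shape
    if not 1 <= n_lines <= rows:
        raise ValueError(f"n_lines={n_lines} exceeds available lines ({rows})")
    cy, cx = rows // 2, cols // 2
    start = min(max(cy - n_lines // 2, 0), rows - n_lines)
    line = amp[start : start + n_lines].mean(axis=0)
    freqs, vals = _fold_line(line, cx)
    if normalize:
        vals = _normalize_plateau(vals)
    return FrequencyProfile(freqs, vals, axis)


def radial_profile(spectrum: Spectrum, n_bins: int = 64) -> FrequencyProfile:
    """Mean spectrum amplitude in concentric annuli of equal radial width.

    The radius is the normalized spatial frequency ``hypot(fy, fx)``; annuli
    span ``[0, 0.5]``.  Annular averaging reduces noise, and the profile is
    normalized by the innermost bin when that bin is nonzero, so profiles of
    differently scaled images compare directly.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    amp = spectrum.amplitudes
    rows, cols = amp.shape
    fy = (np.arange(rows) - rows // 2) / rows
    fx = (np.arange(cols) - cols // 2) / cols
    r = np.hypot(fy[:, None], fx[None, :])
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    inside = r <= edges[-1] + 1e-12
    idx = np.clip(np.searchsorted(edges, r[inside], side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        raise ValueError("empty annulus; reduce n_bins")
    sums = np.bincount(idx, weights=amp[inside], minlength=n_bins)
    vals = sums / counts
    if vals[0] != 0:
        vals = vals / vals[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FrequencyProfile(centers, vals, "radial")


#: maximum deviation of the vertical profile from flat before the input frames
#: are suspected to contain specimen structure.
STRUCTURE_TOLERANCE = 0.15


def measure_detector_response(
    noise_frames,
    n_lines: int | None = None,
) -> FrequencyProfile:
    """Estimate the scan-direction transfer function from defocused noise frames.

    Per frame, the normalized horizontal and vertical line profiles of the
    amplitude spectrum are computed and averaged across frames; the horizontal
    average is divided by the (assumed flat) vertical average to cancel the
    noise floor, and the result is clipped to ``[0, 1]``.

    ``noise_frames`` may be a FrameStack or an ``(n, rows, cols)`` array.
    """
    frames = np.asarray(getattr(noise_frames, "frames", noise_frames), dtype=float)
    if frames.ndim != 3:
        raise ValueError("expected a stack of 2-D frames")
    n, rows, cols = frames.shape
    if n < 2:
        raise ValueError("at least 2 noise frames are required")
    nl_h = min(n_lines or 256, rows)
    nl_v = min(n_lines or 256, cols)

    h_acc = v_acc = None
    h_freqs = v_freqs = None
    for frame in frames:
        spec = amplitude_spectrum(frame)
        hp = axis_profile(spec, "horizontal", nl_h)
        vp = axis_profile(spec, "vertical", nl_v)
        if h_acc is None:
            h_acc, v_acc = hp.values.copy(), vp.values.copy()
            h_freqs, v_freqs = hp.frequencies, vp.frequencies
        else:
            h_acc += hp.values
            v_acc += vp.values
    h_mean = h_acc / n
    v_mean = v_acc / n

    if np.max(np.abs(v_mean - 1.0)) > STRUCTURE_TOLERANCE:
        warnings.warn(
            "vertical spectral profile is not flat; frames may contain "
            "specimen structure, the transfer estimate may be biased",
            stacklevel=2,
        )
    floor = np.interp(h_freqs, v_freqs, v_mean)
    est = np.clip(h_mean / floor, 0.0, 1.0)
    return FrequencyProfile(h_freqs, est, "horizontal")
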