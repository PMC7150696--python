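"""Synthetic fast-scan frame stacks.

Emulates the statistical structure of video-rate SEM acquisition so that every
downstream stage (restoration, registration, integration, montage) is testable
without instrument data: a broadband textured specimen, a scan-direction
low-pass detector response, per-frame translational drift (optionally varying
across the field of view), slow brightness drift mimicking charging, and
Poisson/Gaussian noise calibrated down to single-frame amplitude SNR 0.25.

Generation-time shifts may be subpixel (cubic-spline resampling of the ground
truth); the restoration/integration path never interpolates — that constraint
belongs to the measurement method, not to the simulated physics.
"""
from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .spectra import FrequencyProfile

__all__ = [
    "GroundTruth",
    "DriftModel",
    "ChargingModel",
    "NoiseModel",
    "FrameStack",
    "make_ground_truth",
    "detector_lowpass",
    "simulate_stack",
]

#: acquisition metadata defaults: video-rate scan period and the fraction of
#: that period actually spent collecting image pixels (the rest is blanking).
DEFAULT_FRAME_PERIOD_S = 0.04
DEFAULT_ACTIVE_FRACTION_TV = 0.8
DEFAULT_ACTIVE_FRACTION_SLOW = 0.9

#: default texture: (gaussian smoothing sigma in px, amplitude weight) pairs.
#: Mimics a specimen with structure from smooth relief down to granular detail
#: of about a pixel: broadband, with the fine-structure band concentrated near
#: 8-px wavelengths and a small unsmoothed floor so a few percent of the power
#: sits above half-Nyquist.
DEFAULT_TEXTURE_COMPONENTS: tuple[tuple[float, float], ...] = (
    (12.0, 0.6),
    (5.0, 0.4),
    (1.1, 0.45),
    (0.0, 0.07),
)

#: "granular" preset: strong pixel-scale grain, emulating the appearance of an
#: inverse-filtered high-magnification frame whose structural details span one
#: or a few pixels.  This is the regime in which translation matching stays
#: reliable at very low SNR, because the correlation peak is sharp.
GRANULAR_TEXTURE_COMPONENTS: tuple[tuple[float, float], ...] = (
    (16.0, 0.35),
    (6.0, 0.35),
    (2.0, 0.5),
    (0.0, 0.6),
)

TEXTURE_PRESETS: dict[str, tuple[tuple[float, float], ...]] = {
    "default": DEFAULT_TEXTURE_COMPONENTS,
    "granular": GRANULAR_TEXTURE_COMPONENTS,
}


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Noise-free specimen image with values in [0, 1]."""

    pixels: np.ndarray
    pixel_size: float = 1.0
    seed: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclasses.dataclass(frozen=True)
class DriftModel:
    """Per-frame translational drift of the field of view.

    ``global`` drift applies ``trajectory[t] = (dy, dx)`` uniformly; content
    moves down/right by positive (dy, dx).  ``spatially_varying`` drift
    interpolates the displacement linearly in column index between a left and
    a right anchor trajectory, emulating a field whose two sides drift
    differently under charging.
    """

    kind: Literal["none", "global", "spatially_varying"] = "none"
    trajectory: np.ndarray | None = None
    left_trajectory: np.ndarray | None = None
    right_trajectory: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("trajectory", "left_trajectory", "right_trajectory"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.ndim != 2 or v.shape[1] != 2 or not np.all(np.isfinite(v)):
                    raise ValueError(f"{name} must be a finite (n, 2) array of (dy, dx)")
                object.__setattr__(self, name, v)
        if self.kind == "global" and self.trajectory is None:
            raise ValueError("global drift requires a trajectory")
        if self.kind == "spatially_varying" and (
            self.left_trajectory is None or self.right_trajectory is None
        ):
            raise ValueError("spatially varying drift requires left and right trajectories")

    def n_defined(self) -> int:
        if self.kind == "none":
            return np.iinfo(np.int64).max
        if self.kind == "global":
            return len(self.trajectory)
        return min(len(self.left_trajectory), len(self.right_trajectory))

    @classmethod
    def none(cls) -> "DriftModel":
        return cls("none")

    @classmethod
    def constant_rate(cls, rate: tuple[float, float], n_frames: int) -> "DriftModel":
        """Linear drift: displacement ``t * rate`` at frame ``t``."""
        t = np.arange(n_frames, dtype=float)[:, None]
        return cls("global", trajectory=t * np.asarray(rate, float)[None, :])

    @classmethod
    def varying(cls, left: np.ndarray, right: np.ndarray) -> "DriftModel":
        return cls("spatially_varying", left_trajectory=left, right_trajectory=right)


@dataclasses.dataclass(frozen=True)
class ChargingModel:
    """Slow anomalous-brightness drift: ``frame = gain_t * frame + offset_t``."""

    offset_trajectory: np.ndarray
    gain_trajectory: np.ndarray

    def __post_init__(self) -> None:
        off = np.asarray(self.offset_trajectory, dtype=float)
        gain = np.asarray(self.gain_trajectory, dtype=float)
        if off.ndim != 1 or gain.ndim != 1:
            raise ValueError("charging trajectories must be 1-D")
        if np.any(gain <= 0):
            raise ValueError("gains must be positive")
        object.__setattr__(self, "offset_trajectory", off)
        object.__setattr__(self, "gain_trajectory", gain)

    @classmethod
    def none(cls, n_frames: int) -> "ChargingModel":
        return cls(np.zeros(n_frames), np.ones(n_frames))

    @classmethod
    def exponential_decay(
        cls, n_frames: int, b0: float = 0.1, tau: float = 100.0, gain: float = 1.0
    ) -> "ChargingModel":
        """Monotone brightness decay ``offset_t = b0 * exp(-t / tau)``."""
        t = np.arange(n_frames, dtype=float)
        return cls(b0 * np.exp(-t / tau), np.full(n_frames, float(gain)))


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Detector noise cascade: scaled-Poisson shot noise, then Gaussian readout.

    ``poisson_scale`` is the number of quanta per unit intensity (0 disables
    shot noise); ``gaussian_sigma`` is the readout amplitude in intensity
    units.
    """

    gaussian_sigma: float = 0.0
    poisson_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0 or self.poisson_scale < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def active(self) -> bool:
        return self.gaussian_sigma > 0 or self.poisson_scale > 0

    @classmethod
    def for_target_snr(cls, clean_image: np.ndarray, snr: float, seed: int = 0) -> "NoiseModel":
        """Gaussian noise sized so a single frame has amplitude SNR ``snr``.

        Amplitude SNR is the signal standard deviation over the noise standard
        deviation, so ``sigma = std(clean) / snr``.
        """
        if snr <= 0:
            raise ValueError("snr must be positive")
        return cls(gaussian_sigma=float(np.std(clean_image)) / snr, seed=seed)


@dataclasses.dataclass
class FrameStack:
    """Time-ordered stack of equally shaped grayscale frames plus metadata."""

    frames: np.ndarray
    frame_period: float = DEFAULT_FRAME_PERIOD_S
    active_fraction: float = DEFAULT_ACTIVE_FRACTION_TV
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) array")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def subset(self, index) -> "FrameStack":
        """A new stack holding ``frames[index]`` with the same metadata."""
        frames = self.frames[index]
        if frames.ndim == 2:
            frames = frames[None]
        return FrameStack(frames, self.frame_period, self.active_fraction, dict(self.metadata))

    def __len__(self) -> int:
        return self.n_frames


def make_ground_truth(
    height: int,
    width: int,
    texture_params: dict | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Generate a broadband textured specimen, deterministic for a fixed seed.

    ``texture_params`` options: ``kind`` (``"broadband"`` or ``"constant"``),
    ``preset`` (a :data:`TEXTURE_PRESETS` name), ``components`` (sequence of
    ``(sigma, weight)`` smoothing scales for the broadband texture) and
    ``level`` (for a constant field).
    """
    if height < 32 or width < 32:
        raise ValueError("height and width must be >= 32")
    params = dict(texture_params or {})
    kind = params.get("kind", "broadband")
    if kind == "constant":
        level = float(params.get("level", 0.5))
        return GroundTruth(np.full((height, width), level), seed=seed)
    if kind != "broadband":
        raise ValueError(f"unknown texture kind {kind!r}")
    components: Sequence[tuple[float, float]] = params.get(
        "components", TEXTURE_PRESETS[params.get("preset", "default")]
    )
    rng = np.random.default_rng(seed)
    field = np.zeros((height, width))
    for sigma, weight in components:
        noise = rng.standard_normal((height, width))
        if sigma > 0:
            noise = ndimage.gaussian_filter(noise, sigma, mode="wrap")
            noise /= max(noise.std(), 1e-12)
        field += weight * noise
    lo, hi = field.min(), field.max()
    field = (field - lo) / (hi - lo)
    return GroundTruth(field, seed=seed)


def detector_lowpass(image: np.ndarray, profile: FrequencyProfile) -> np.ndarray:
    """Filter each row so its transfer magnitude equals ``profile``.

    Models the detector chain's degraded frequency response, which acts along
    the fast-scan (horizontal) direction only; columns are unmodified.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if np.any(profile.values > 1.0 + 1e-9) or np.any(profile.values < 0):
        raise ValueError("detector profile values must lie in [0, 1]")
    ncols = image.shape[1]
    freqs = np.fft.rfftfreq(ncols)
    gains = profile.resample(freqs)
    return np.fft.irfft(np.fft.rfft(image, axis=1) * gains, n=ncols, axis=1)


def _bspline3_weights(f: float) -> tuple[float, float, float, float]:
    """Cubic B-spline tap weights for a constant fractional offset f in (0, 1)."""
    return (
        f**3 / 6.0,
        2.0 / 3.0 - (1.0 - f) ** 2 + (1.0 - f) ** 3 / 2.0,
        2.0 / 3.0 - f**2 + f**3 / 2.0,
        (1.0 - f) ** 3 / 6.0,
    )


def _shift_axis(coeffs: np.ndarray, d: float, axis: int) -> np.ndarray:
    """Periodic cubic-spline translation of prefiltered data along one axis.

    The fractional offset is the same at every pixel, so the spline evaluation
    reduces to four circular-shifted taps — equivalent to ``map_coordinates``
    on the same coefficients, but vectorized.
    """
    n = int(np.floor(d))
    f = d - n
    rolled = np.roll(coeffs, n, axis=axis)
    # note f == 0 still needs the [1/6, 2/3, 1/6] reconstruction taps: the
    # input is spline coefficients, not samples
    w = _bspline3_weights(f)
    out = np.zeros_like(rolled)
    for weight, j in zip(w, (-2, -1, 0, 1)):
        out += weight * np.roll(rolled, -j, axis=axis)
    return out


def _shift_global(img: np.ndarray, dy: float, dx: float, coeffs: np.ndarray | None) -> np.ndarray:
    """Periodic translation by (dy, dx); exact roll for integer shifts."""
    if float(dy).is_integer() and float(dx).is_integer():
        return np.roll(img, (int(dy), int(dx)), axis=(0, 1))
    if coeffs is None:
        coeffs = ndimage.spline_filter(img, order=3, mode="grid-wrap")
    return _shift_axis(_shift_axis(coeffs, dy, 0), dx, 1)


def _shift_varying(
    img: np.ndarray,
    left: tuple[float, float],
    right: tuple[float, float],
    coeffs: np.ndarray | None,
) -> np.ndarray:
    """Column-interpolated displacement between a left and right anchor."""
    if tuple(left) == tuple(right):
        return _shift_global(img, left[0], left[1], coeffs)
    h, w = img.shape
    frac = np.arange(w) / (w - 1)
    dy = left[0] + (right[0] - left[0]) * frac
    dx = left[1] + (right[1] - left[1]) * frac
    rr = np.arange(h)[:, None] - dy[None, :]
    cc = np.arange(w)[None, :] - dx[None, :]
    rr = np.broadcast_to(rr, (h, w))
    cc = np.broadcast_to(cc, (h, w))
    src = coeffs if coeffs is not None else img
    return ndimage.map_coordinates(
        src, [rr, cc], order=3, mode="grid-wrap", prefilter=coeffs is None
    )


def simulate_stack(
    truth: GroundTruth,
    drift: DriftModel | None = None,
    charging: ChargingModel | None = None,
    noise: NoiseModel | None = None,
    detector: FrequencyProfile | None = None,
    n_frames: int = 1,
    seed: int = 0,
) -> FrameStack:
    """Simulate a continuously acquired stack of video-rate frames.

    Frame ``t`` is ``noise(gain_t * lowpass(shift_t(truth)) + offset_t)``.
    The stack is bit-identical for identical arguments.  Metadata records the
    acquisition constants, the drift trajectories and the noise parameters so
    downstream tests can use them as ground-truth oracles.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    drift = drift or DriftModel.none()
    if drift.n_defined() < n_frames:
        raise ValueError("drift trajectory shorter than n_frames")
    if charging is not None and (
        len(charging.offset_trajectory) < n_frames or len(charging.gain_trajectory) < n_frames
    ):
        raise ValueError("charging trajectories shorter than n_frames")

    base = np.asarray(truth.pixels, dtype=float)
    needs_spline = False
    if drift.kind == "global":
        needs_spline = not np.all(drift.trajectory[:n_frames] == np.round(drift.trajectory[:n_frames]))
    elif drift.kind == "spatially_varying":
        needs_spline = True
    coeffs = (
        ndimage.spline_filter(base, order=3, mode="grid-wrap") if needs_spline else None
    )

    rng = np.random.default_rng([int(seed), int(noise.seed) if noise else 0])
    frames = np.empty((n_frames,) + base.shape, dtype=float)
    for t in range(n_frames):
        if drift.kind == "none":
            frame = base.copy()
        elif drift.kind == "global":
            dy, dx = drift.trajectory[t]
            frame = _shift_global(base, dy, dx, coeffs)
        else:
            frame = _shift_varying(
                base, tuple(drift.left_trajectory[t]), tuple(drift.right_trajectory[t]), coeffs
            )
        if detector is not None:
            frame = detector_lowpass(frame, detector)
        if charging is not None:
            frame = charging.gain_trajectory[t] * frame + charging.offset_trajectory[t]
        if noise is not None and noise.active:
            if noise.poisson_scale > 0:
                frame = rng.poisson(np.clip(frame, 0, None) * noise.poisson_scale) / noise.poisson_scale
            if noise.gaussian_sigma > 0:
                frame = frame + rng.normal(0.0, noise.gaussian_sigma, frame.shape)
        frames[t] = frame

    metadata = {
        "truth_seed": truth.seed,
        "seed": int(seed),
        "drift_kind": drift.kind,
        "noise": dataclasses.asdict(noise) if noise else None,
    }
    if drift.kind == "global":
        metadata["drift_trajectory"] = drift.trajectory[:n_frames].tolist()
    elif drift.kind == "spatially_varying":
        metadata["drift_left_trajectory"] = drift.left_trajectory[:n_frames].tolist()
        metadata["drift_right_trajectory"] = drift.right_trajectory[:n_frames].tolist()
    return FrameStack(frames, metadata=metadata)
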