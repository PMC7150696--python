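"""Noise-robust integer-pixel translation registration.

Zero-mean normalized cross-correlation (ZNCC) of a template ROI against a
search window, accelerated coarse-to-fine over an image pyramid.  Matching is
restricted to integer translations by design: the restoration path never
interpolates, because resampling creates new pixels and hence blur.  At the
working point of this acquisition scheme a single frame can have amplitude
SNR around 0.25, so the stack aligner's default template is a running mean of
the already-aligned frames, whose SNR grows as alignment proceeds.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import signal

from .synthscope import FrameStack

__all__ = [
    "ROI",
    "Shift",
    "ShiftTrajectory",
    "zncc_surface",
    "match_pyramid",
    "align_stack",
    "peak_margin",
    "placement_counts",
    "default_levels",
]

#: the ZNCC surface of an N-pixel template has noise floor ~1/sqrt(N); a peak
#: below this multiple of the floor is indistinguishable from noise, and the
#: frame is flagged low-confidence and excluded from integration.  (A genuine
#: match at single-frame amplitude SNR 0.25 scores ~0.06 — far above the
#: floor of any usefully sized ROI, so a fixed absolute threshold would
#: either reject the working point or never trip on small ROIs.)
SCORE_FLOOR_FACTOR = 5.0
DEFAULT_SEARCH_MARGIN = 64
#: default pyramid depth keeps the coarsest template side at least this large.
DEFAULT_COARSEST_SIDE = 32
MIN_COARSE_TEMPLATE = 8
#: refinement half-width (pixels) around the upscaled candidate at each level.
REFINE_RADIUS = 2
_TIE_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class ROI:
    """0-based, half-open rectangular region (row0, col0, row1, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError(f"degenerate roi {self}")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError(f"negative roi bounds {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.row1 - self.row0, self.col1 - self.col0

    @property
    def center(self) -> tuple[float, float]:
        return (self.row0 + self.row1 - 1) / 2.0, (self.col0 + self.col1 - 1) / 2.0

    def crop(self, image: np.ndarray) -> np.ndarray:
        if self.row1 > image.shape[0] or self.col1 > image.shape[1]:
            raise ValueError(f"roi {self} outside image of shape {image.shape}")
        return image[self.row0 : self.row1, self.col0 : self.col1]

    def astuple(self) -> tuple[int, int, int, int]:
        return self.row0, self.col0, self.row1, self.col1


@dataclasses.dataclass(frozen=True)
class Shift:
    """Integer translation (dy, dx) with its peak ZNCC score."""

    dy: int
    dx: int
    score: float = 1.0

    def __post_init__(self) -> None:
        if abs(self.score) > 1 + 1e-9:
            raise ValueError(f"score {self.score} outside [-1, 1]")


@dataclasses.dataclass
class ShiftTrajectory:
    """Per-frame shifts relative to a reference frame."""

    shifts: list[Shift]
    reference_index: int = 0
    min_score: float = 0.0

    def __post_init__(self) -> None:
        ref = self.shifts[self.reference_index]
        if (ref.dy, ref.dx) != (0, 0):
            raise ValueError("reference frame must have zero shift")

    def __len__(self) -> int:
        return len(self.shifts)

    def __getitem__(self, index) -> "ShiftTrajectory":
        if isinstance(index, slice):
            sub = self.shifts[index]
            if not sub:
                raise ValueError("empty trajectory slice")
            return ShiftTrajectory(sub, min(self.reference_index, len(sub) - 1), self.min_score)
        raise TypeError("only slices are supported")

    @property
    def dy(self) -> np.ndarray:
        return np.array([s.dy for s in self.shifts], dtype=int)

    @property
    def dx(self) -> np.ndarray:
        return np.array([s.dx for s in self.shifts], dtype=int)

    @property
    def scores(self) -> np.ndarray:
        return np.array([s.score for s in self.shifts], dtype=float)

    def low_confidence(self) -> list[int]:
        """Indices of frames whose match score fell below ``min_score``."""
        return [i for i, s in enumerate(self.shifts) if s.score < self.min_score]

    @classmethod
    def from_displacements(
        cls, displacements: np.ndarray, reference_index: int = 0
    ) -> "ShiftTrajectory":
        """Trajectory from an (n, 2) integer (dy, dx) array (e.g. a sidecar oracle)."""
        d = np.asarray(displacements)
        shifts = [Shift(int(dy), int(dx), 1.0) for dy, dx in d]
        return cls(shifts, reference_index)


def _window_sums(a: np.ndarray, th: int, tw: int) -> np.ndarray:
    """Sums of ``a`` over every th-by-tw sliding window (integral image)."""
    ii = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    ii[1:, 1:] = a.cumsum(axis=0).cumsum(axis=1)
    return ii[th:, tw:] - ii[:-th, tw:] - ii[th:, :-tw] + ii[:-th, :-tw]


def zncc_surface(template: np.ndarray, inspection: np.ndarray) -> np.ndarray:
    """ZNCC of the template at every valid placement inside the inspection.

    Each value is the correlation of the mean-removed, norm-scaled template
    with the equally normalized inspection patch, so the surface lies in
    [-1, 1] and is invariant to affine gain/offset of either input.
    """
    t = np.asarray(template, dtype=float)
    x = np.asarray(inspection, dtype=float)
    if t.ndim != 2 or x.ndim != 2:
        raise ValueError("template and inspection must be 2-D")
    if t.shape[0] > x.shape[0] or t.shape[1] > x.shape[1]:
        raise ValueError(f"template {t.shape} larger than inspection {x.shape}")
    t0 = t - t.mean()
    tnorm = math.sqrt(float(np.sum(t0 * t0)))
    scale = float(np.abs(t).max(initial=0.0))
    if tnorm <= 1e-12 * t.size * max(scale, 1.0):
        raise ValueError("template has zero variance")

    cross = signal.correlate(x, t0, mode="valid", method="auto")
    s1 = _window_sums(x, *t.shape)
    s2 = _window_sums(x * x, *t.shape)
    var = s2 - s1 * s1 / t.size
    xscale = float(np.abs(x).max(initial=0.0))
    tol = 1e-12 * t.size * max(xscale * xscale, 1.0)
    good = var > tol
    denom = np.sqrt(np.clip(var, tol, None)) * tnorm
    out = np.where(good, cross / denom, 0.0)
    return np.clip(out, -1.0, 1.0)


def peak_margin(surface: np.ndarray, exclusion_radius: int = 2) -> float:
    """Peak value minus the best score outside a small neighbourhood of the peak."""
    flat = int(np.argmax(surface))
    py, px = np.unravel_index(flat, surface.shape)
    masked = surface.copy()
    masked[
        max(0, py - exclusion_radius) : py + exclusion_radius + 1,
        max(0, px - exclusion_radius) : px + exclusion_radius + 1,
    ] = -np.inf
    runner_up = float(masked.max())
    if not np.isfinite(runner_up):
        return float("inf")
    return float(surface[py, px]) - runner_up


def _box_downsample(a: np.ndarray) -> np.ndarray:
    h, w = a.shape
    a = a[: h - h % 2, : w - w % 2]
    return a.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def default_levels(template_shape: tuple[int, int], coarsest_side: int = DEFAULT_COARSEST_SIDE) -> int:
    """Deepest pyramid whose coarsest template side stays >= ``coarsest_side``."""
    side = min(template_shape)
    levels = 1
    while side // 2 >= coarsest_side:
        side //= 2
        levels += 1
    return levels


def _argbest(surface: np.ndarray, origin: tuple[float, float], offset=(0, 0)) -> tuple[int, int, float]:
    """Argmax with deterministic tie-breaking by shift magnitude then (dy, dx)."""
    best = float(surface.max())
    cand = np.argwhere(surface >= best - _TIE_EPS)
    keys = []
    for py, px in cand:
        sy = py + offset[0] - origin[0]
        sx = px + offset[1] - origin[1]
        keys.append((abs(sy) + abs(sx), sy, sx, py, px))
    keys.sort()
    _, _, _, py, px = keys[0]
    return int(py + offset[0]), int(px + offset[1]), best


def match_pyramid(
    template: np.ndarray,
    inspection: np.ndarray,
    levels: int | None = None,
    origin: tuple[int, int] = (0, 0),
) -> Shift:
    """Coarse-to-fine ZNCC translation match.

    Returns the placement of the template's top-left corner relative to
    ``origin`` in inspection coordinates (so with the default origin, a
    template embedded at offset (y, x) is recovered as ``Shift(y, x)``).
    ``levels=1`` is an exhaustive full-resolution search; deeper pyramids run
    a full search at the coarsest level and refine within +-2 px per finer
    level.  Ties are broken towards the smallest |dy|+|dx|, then dy, then dx.
    """
    t = np.asarray(template, dtype=float)
    x = np.asarray(inspection, dtype=float)
    if levels is None:
        levels = default_levels(t.shape)
    if levels < 1:
        raise ValueError("levels must be >= 1")

    tpl = [t]
    insp = [x]
    for _ in range(levels - 1):
        tpl.append(_box_downsample(tpl[-1]))
        insp.append(_box_downsample(insp[-1]))
    if min(tpl[-1].shape) < MIN_COARSE_TEMPLATE:
        raise ValueError(
            f"pyramid of {levels} levels collapses the template to {tpl[-1].shape}; "
            f"coarsest side must be >= {MIN_COARSE_TEMPLATE}"
        )

    coarse_origin = (origin[0] / 2 ** (levels - 1), origin[1] / 2 ** (levels - 1))
    surface = zncc_surface(tpl[-1], insp[-1])
    py, px, score = _argbest(surface, coarse_origin)

    for level in range(levels - 2, -1, -1):
        ty, tx = tpl[level].shape
        max_py = insp[level].shape[0] - ty
        max_px = insp[level].shape[1] - tx
        cy, cx = py * 2, px * 2
        y0 = max(0, min(cy - REFINE_RADIUS, max_py))
        y1 = min(max_py, cy + REFINE_RADIUS)
        x0 = max(0, min(cx - REFINE_RADIUS, max_px))
        x1 = min(max_px, cx + REFINE_RADIUS)
        window = insp[level][y0 : y1 + ty, x0 : x1 + tx]
        sub = zncc_surface(tpl[level], window)
        level_origin = (origin[0] / 2**level, origin[1] / 2**level)
        py, px, score = _argbest(sub, level_origin, offset=(y0, x0))

    return Shift(py - origin[0], px - origin[1], score)


def placement_counts(
    template_shape: tuple[int, int],
    inspection_shape: tuple[int, int],
    levels: int,
) -> tuple[int, int]:
    """(pyramid, full-search) counts of candidate placements evaluated.

    The pyramid runs a full search only at the coarsest level and at most
    ``(2*REFINE_RADIUS + 1)**2`` placements per finer level.
    """
    th, tw = template_shape
    ih, iw = inspection_shape
    full = (ih - th + 1) * (iw - tw + 1)
    f = 2 ** (levels - 1)
    coarse = max(1, ih // f - th // f + 1) * max(1, iw // f - tw // f + 1)
    pyramid = coarse + (levels - 1) * (2 * REFINE_RADIUS + 1) ** 2
    return pyramid, full


def align_stack(
    stack: FrameStack,
    roi: ROI,
    reference: str = "running_mean",
    search_margin: int = DEFAULT_SEARCH_MARGIN,
    levels: int | None = None,
    min_score: float | None = None,
) -> ShiftTrajectory:
    """Per-frame integer shift of the ROI patch against a reference template.

    ``reference="first"`` matches every frame against frame 0's ROI patch;
    ``"running_mean"`` (default) updates the template with the mean of the
    already-aligned patches, which raises the template SNR over time and is
    what makes matching reliable at single-frame SNR well below 1.  Shift
    (dy, dx) means the frame content moved down/right by (dy, dx) relative to
    the reference.  Frames whose peak score falls below ``min_score``
    (default: ``SCORE_FLOOR_FACTOR / sqrt(roi pixels)``, the correlation
    noise ceiling) are flagged, skipped by integration and excluded from the
    running mean, but still get their best-guess shift.
    """
    if reference not in ("first", "running_mean"):
        raise ValueError(f"unknown reference {reference!r}")
    frames = stack.frames
    n, h, w = frames.shape
    r0, c0, r1, c1 = roi.astuple()
    m = int(search_margin)
    if m < 1:
        raise ValueError("search_margin must be >= 1")
    if r0 - m < 0 or c0 - m < 0 or r1 + m > h or c1 + m > w:
        raise ValueError(
            f"roi {roi} with search margin {m} exceeds frame bounds {(h, w)}"
        )
    if levels is None:
        levels = default_levels(roi.shape)
    if min_score is None:
        min_score = SCORE_FLOOR_FACTOR / math.sqrt(roi.shape[0] * roi.shape[1])

    template_acc = frames[0][r0:r1, c0:c1].astype(float).copy()
    n_acc = 1
    shifts = [Shift(0, 0, 1.0)]
    for t in range(1, n):
        window = frames[t][r0 - m : r1 + m, c0 - m : c1 + m]
        template = template_acc / n_acc if reference == "running_mean" else template_acc
        sh = match_pyramid(template, window, levels=levels, origin=(m, m))
        shifts.append(sh)
        if reference == "running_mean" and sh.score >= min_score:
            template_acc += frames[t][r0 + sh.dy : r1 + sh.dy, c0 + sh.dx : c1 + sh.dx]
            n_acc += 1
    return ShiftTrajectory(shifts, reference_index=0, min_score=min_score)
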