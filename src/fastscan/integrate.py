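"""Frame integration and the optimal-frame-count diagnostic.

Averaging n aligned same-view frames raises the amplitude SNR by sqrt(n) —
until residual drift starts blurring the accumulating image, at which point
the fine-structure signal S_sigma(HPF) collapses.  The integration curve
makes that trade visible: the inverse-filtered stack is split into the
even-index and odd-index halves, each half is integrated up to a series of
checkpoints, and S_sigma(HPF) of the resulting pair (two independent images
of the same view) is plotted against sqrt(n).  The optimal frame count is the
largest n whose score is still within a tolerance of the curve's maximum.

Alignment uses pure integer index offsets — no interpolation, so no pixel of
an integrated image is anything but a mean of original frame pixels.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .register import ROI, ShiftTrajectory, align_stack
from .restore import FilterSpec
from .snrtools import s_sigma_hpf
from .synthscope import FrameStack

__all__ = [
    "IntegratedImage",
    "IntegrationCurve",
    "average_frames",
    "odd_even_split",
    "interleave",
    "integration_curve",
    "estimate_optimal_n",
    "DEFAULT_CHECKPOINTS",
]

#: perfect squares so the curve is uniform on a sqrt(n) axis.
DEFAULT_CHECKPOINTS: tuple[int, ...] = tuple(k * k for k in range(1, 17))

DEFAULT_TOLERANCE_FRACTION = 0.05


@dataclasses.dataclass
class IntegratedImage:
    """Per-pixel mean of contributing frames with a contribution count map.

    Pixels shifted out of every frame have ``count_map == 0``; they are set
    to 0 and are invalid (the dark border of an aligned integration).
    """

    pixels: np.ndarray
    count_map: np.ndarray
    n_frames: int

    @property
    def valid_mask(self) -> np.ndarray:
        return self.count_map > 0

    def common_support(self) -> tuple[int, int, int, int]:
        """Bounding box (row0, col0, row1, col1) of pixels seen by every frame."""
        full = self.count_map == self.count_map.max()
        rows = np.flatnonzero(full.any(axis=1))
        cols = np.flatnonzero(full.any(axis=0))
        return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


@dataclasses.dataclass
class IntegrationCurve:
    """(n, S_sigma(HPF)) checkpoints for one stack, n strictly increasing."""

    points: list[tuple[int, float]]
    structure_size: float

    def __post_init__(self) -> None:
        ns = [n for n, _ in self.points]
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ValueError("checkpoints must be strictly increasing")

    @property
    def n_values(self) -> np.ndarray:
        return np.array([n for n, _ in self.points], dtype=int)

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.points], dtype=float)


def average_frames(
    stack: FrameStack,
    trajectory: ShiftTrajectory | None = None,
    crop_to_common: bool = False,
) -> IntegratedImage:
    """Mean of the frames after undoing their integer shifts.

    Each frame is translated by pure index offsetting (no interpolation) and
    accumulated; the per-pixel mean divides by the number of frames that
    actually covered that pixel.  Frames flagged low-confidence by the
    trajectory are excluded.
    """
    frames = stack.frames
    n, h, w = frames.shape
    if trajectory is not None and len(trajectory) != n:
        raise ValueError(f"trajectory length {len(trajectory)} != n_frames {n}")

    acc = np.zeros((h, w))
    count = np.zeros((h, w), dtype=int)
    n_used = 0
    for t in range(n):
        if trajectory is None:
            dy = dx = 0
        else:
            sh = trajectory.shifts[t]
            if sh.score < trajectory.min_score:
                continue
            dy, dx = sh.dy, sh.dx
        ys, ye = max(0, -dy), min(h, h - dy)
        xs, xe = max(0, -dx), min(w, w - dx)
        if ys >= ye or xs >= xe:
            continue
        acc[ys:ye, xs:xe] += frames[t, ys + dy : ye + dy, xs + dx : xe + dx]
        count[ys:ye, xs:xe] += 1
        n_used += 1
    if count.max() == 0:
        raise ValueError("no pixel received any contribution (shifts exceed frame size?)")
    pixels = np.where(count > 0, acc / np.maximum(count, 1), 0.0)
    out = IntegratedImage(pixels, count, n_used)
    if crop_to_common:
        r0, c0, r1, c1 = out.common_support()
        out = IntegratedImage(pixels[r0:r1, c0:c1], count[r0:r1, c0:c1], n_used)
    return out


def odd_even_split(stack: FrameStack) -> tuple[FrameStack, FrameStack]:
    """Split into the even-time-index and odd-time-index halves, order kept.

    The two halves are interleaved acquisitions of the same view with
    independent noise — exactly what the covariance SNR estimator needs.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames to split")
    return stack.subset(slice(0, None, 2)), stack.subset(slice(1, None, 2))


def interleave(even_half: FrameStack, odd_half: FrameStack) -> FrameStack:
    """Inverse of :func:`odd_even_split`."""
    n = even_half.n_frames + odd_half.n_frames
    frames = np.empty((n,) + even_half.frame_shape, dtype=even_half.frames.dtype)
    frames[0::2] = even_half.frames
    frames[1::2] = odd_half.frames
    return FrameStack(
        frames, even_half.frame_period, even_half.active_fraction, dict(even_half.metadata)
    )


def integration_curve(
    stack: FrameStack,
    checkpoints: list[int] | None = None,
    aligned: bool = True,
    roi: ROI | None = None,
    spec: FilterSpec | None = None,
    search_margin: int = 64,
    levels: int | None = None,
    reference: str = "running_mean",
    trajectories: tuple[ShiftTrajectory, ShiftTrajectory] | None = None,
) -> IntegrationCurve:
    """S_sigma(HPF) of the odd/even integrated pair at each checkpoint n.

    Each half is aligned independently (keeping their noise independent) when
    ``aligned`` is true; ``trajectories`` may supply precomputed or
    ground-truth per-half trajectories instead.  The pair is evaluated on a
    fixed central region excluding the widest shift margin so every
    checkpoint sees fully covered pixels.
    """
    spec = spec or FilterSpec()
    half_a, half_b = odd_even_split(stack)
    n_half = min(half_a.n_frames, half_b.n_frames)
    if checkpoints is None:
        checkpoints = [n for n in DEFAULT_CHECKPOINTS if n <= n_half]
    if not checkpoints:
        raise ValueError("no checkpoints")
    if max(checkpoints) > n_half:
        raise ValueError(
            f"checkpoint {max(checkpoints)} exceeds half-stack size {n_half}"
        )

    traj_a = traj_b = None
    if trajectories is not None:
        traj_a, traj_b = trajectories
    elif aligned:
        if roi is None:
            raise ValueError("aligned integration curve requires an alignment roi")
        traj_a = align_stack(half_a, roi, reference, search_margin, levels)
        traj_b = align_stack(half_b, roi, reference, search_margin, levels)

    h, w = stack.frame_shape
    if traj_a is not None:
        my = int(max(np.abs(traj_a.dy).max(), np.abs(traj_b.dy).max()))
        mx = int(max(np.abs(traj_a.dx).max(), np.abs(traj_b.dx).max()))
    else:
        my = mx = 0
    ev = (slice(my, h - my if my else None), slice(mx, w - mx if mx else None))

    points: list[tuple[int, float]] = []
    for n in sorted(checkpoints):
        img_a = average_frames(half_a.subset(slice(0, n)), traj_a[:n] if traj_a else None)
        img_b = average_frames(half_b.subset(slice(0, n)), traj_b[:n] if traj_b else None)
        score = s_sigma_hpf(img_a.pixels[ev], img_b.pixels[ev], spec)
        points.append((n, score))
    return IntegrationCurve(points, spec.structure_size)


def estimate_optimal_n(
    curve: IntegrationCurve, tolerance_fraction: float = DEFAULT_TOLERANCE_FRACTION
) -> int:
    """Largest checkpoint whose score is within tolerance of the curve maximum.

    Returns the per-half frame count n; the total integration uses 2n frames
    (n from the odd half plus n from the even half).
    """
    if not curve.points:
        raise ValueError("empty curve")
    if not 0 < tolerance_fraction < 1:
        raise ValueError("tolerance_fraction must lie in (0, 1)")
    threshold = (1.0 - tolerance_fraction) * curve.scores.max()
    best = max((n for n, s in curve.points if s >= threshold), default=None)
    if best is None:  # numerically impossible: the max itself qualifies
        best = curve.points[0][0]
    return int(best)
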