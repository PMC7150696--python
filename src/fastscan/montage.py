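"""Multi-ROI integration and seam-suppressed montage.

When charging makes different parts of the field drift differently, no single
translation aligns the whole frame: an integration aligned on one ROI is
sharp near that ROI and blurred elsewhere.  The remedy is to integrate the
stack once per anchor ROI and blend the partial integrations so each region
keeps its sharpest version.  Blending is a convex, purely per-pixel
combination of existing pixel values (no resampling), with weights assigned
by nearest anchor and feathered across region boundaries so no seam is
visible.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .integrate import IntegratedImage, average_frames, odd_even_split
from .register import ROI, align_stack
from .restore import FilterSpec
from .snrtools import s_sigma_hpf
from .synthscope import FrameStack

__all__ = [
    "MontagePlan",
    "integrate_per_roi",
    "montage_weights",
    "make_montage_plan",
    "blend_montage",
    "rank_roi_candidates",
]

DEFAULT_FEATHER_WIDTH = 64


@dataclasses.dataclass
class MontagePlan:
    """Anchor ROIs, their partial integrations, and per-pixel blend weights."""

    rois: list[ROI]
    partials: list[IntegratedImage]
    weights: np.ndarray | None = None  # (n_roi, rows, cols), sums to 1 where valid


def integrate_per_roi(
    stack: FrameStack,
    rois: list[ROI],
    search_margin: int = 16,
    reference: str = "running_mean",
    levels: int | None = None,
) -> list[IntegratedImage]:
    """Align the stack once per ROI and integrate; order matches the ROI list."""
    if not rois:
        raise ValueError("need at least one roi")
    partials = []
    for roi in rois:
        traj = align_stack(stack, roi, reference, search_margin, levels)
        partials.append(average_frames(stack, traj))
    return partials


def montage_weights(
    shape: tuple[int, int],
    rois: list[ROI],
    partials: list[IntegratedImage] | None = None,
    feather_width: int = DEFAULT_FEATHER_WIDTH,
) -> np.ndarray:
    """Convex blend weights: nearest-anchor partition, feathered at boundaries.

    Each pixel's raw weight for anchor i is 1 while anchor i is the nearest
    (by distance to ROI center) and ramps linearly to 0 as the pixel's extra
    distance beyond the nearest anchor grows to ``2 * feather_width``; weights
    are zeroed where a partial has no data and normalized to sum to 1.  The
    ramp slope bounds the output step across a seam between partials at
    ``(max - min) / feather_width`` per pixel.
    """
    if feather_width < 1:
        raise ValueError("feather_width must be >= 1")
    rows, cols = shape
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    dist = np.empty((len(rois), rows, cols))
    for i, roi in enumerate(rois):
        cy, cx = roi.center
        dist[i] = np.hypot(rr - cy, cc - cx)
    dmin = dist.min(axis=0)
    raw = np.clip(1.0 - (dist - dmin) / (2.0 * feather_width), 0.0, 1.0)
    if partials is not None:
        valid = np.stack([p.valid_mask for p in partials])
        raw *= valid
        # where the nearest anchors have no data but some partial does (e.g.
        # inside another partial's shifted-out border), fall back to the
        # nearest valid anchor instead of dropping the pixel
        orphan = (raw.sum(axis=0) == 0) & valid.any(axis=0)
        if np.any(orphan):
            dist_valid = np.where(valid, dist, np.inf)
            nearest = np.argmin(dist_valid, axis=0)
            rows, cols = np.nonzero(orphan)
            raw[nearest[orphan], rows, cols] = 1.0
    total = raw.sum(axis=0)
    weights = np.divide(raw, total, out=np.zeros_like(raw), where=total > 0)
    return weights


def make_montage_plan(
    rois: list[ROI],
    partials: list[IntegratedImage],
    feather_width: int = DEFAULT_FEATHER_WIDTH,
) -> MontagePlan:
    if len(rois) != len(partials):
        raise ValueError("one partial per roi required")
    shape = partials[0].pixels.shape
    if any(p.pixels.shape != shape for p in partials):
        raise ValueError("partials must share one shape")
    weights = montage_weights(shape, rois, partials, feather_width)
    return MontagePlan(list(rois), list(partials), weights)


def blend_montage(plan: MontagePlan, feather_width: int = DEFAULT_FEATHER_WIDTH) -> IntegratedImage:
    """Weight-sum of the partial integrations: a convex per-pixel combination.

    Pixels valid in no partial stay invalid (count 0) rather than being
    inpainted.  The count map reports the weight-averaged contribution count,
    rounded.
    """
    if not plan.partials:
        raise ValueError("plan holds no partials")
    weights = plan.weights
    if weights is None:
        weights = montage_weights(
            plan.partials[0].pixels.shape, plan.rois, plan.partials, feather_width
        )
    pixels = np.einsum("khw,khw->hw", weights, np.stack([p.pixels for p in plan.partials]))
    counts = np.einsum("khw,khw->hw", weights, np.stack([p.count_map.astype(float) for p in plan.partials]))
    valid = weights.sum(axis=0) > 0
    pixels = np.where(valid, pixels, 0.0)
    count_map = np.where(valid, np.maximum(np.rint(counts).astype(int), 1), 0)
    n_frames = max(p.n_frames for p in plan.partials)
    return IntegratedImage(pixels, count_map, n_frames)


def rank_roi_candidates(
    stack_halves: tuple[FrameStack, FrameStack],
    candidate_rois: list[ROI],
    eval_roi: ROI,
    spec: FilterSpec | None = None,
    search_margin: int = 16,
    reference: str = "running_mean",
    levels: int | None = None,
) -> list[tuple[ROI, float]]:
    """Score alignment-ROI candidates by the sharpness they deliver in ``eval_roi``.

    For each candidate, both halves (from :func:`odd_even_split`) are aligned
    with that candidate, integrated, and the pair's S_sigma(HPF) restricted to
    ``eval_roi`` is recorded.  Returned sorted best-first: the candidate that
    tracks the local drift of ``eval_roi`` wins, and an oversized candidate
    spanning regions with different drift scores lower.
    """
    spec = spec or FilterSpec()
    half_a, half_b = stack_halves
    scored = []
    for roi in candidate_rois:
        ta = align_stack(half_a, roi, reference, search_margin, levels)
        tb = align_stack(half_b, roi, reference, search_margin, levels)
        ia = average_frames(half_a, ta)
        ib = average_frames(half_b, tb)
        score = s_sigma_hpf(ia.pixels, ib.pixels, spec, roi=eval_roi)
        scored.append((roi, float(score)))
    scored.sort(key=lambda rs: -rs[1])
    return scored
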