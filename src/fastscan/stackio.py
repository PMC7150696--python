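"""Stack I/O, run configuration and the end-to-end pipeline.

Stacks travel as multipage TIFF (or a directory of equally shaped PNG/TIFF
frames) with an optional JSON sidecar carrying acquisition metadata and, for
synthetic stacks, the ground-truth drift trajectories used by test oracles.
Profiles, shift trajectories and integration curves are two-to-four-column
CSV; SNR reports are JSON.  Every artifact written by a pipeline run embeds a
hash of the run configuration, and a rerun with identical configuration and
seeds reproduces the text artifacts byte for byte.
"""
from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .integrate import (
    average_frames,
    estimate_optimal_n,
    integration_curve,
    odd_even_split,
)
from .montage import blend_montage, integrate_per_roi, make_montage_plan
from .register import ROI, Shift, ShiftTrajectory, align_stack
from .restore import FilterSpec, InverseFilter, apply_inverse_filter, design_inverse_filter
from .snrtools import blanking_corrected_snr, covariance_stats, s_sigma_hpf
from .spectra import FrequencyProfile, measure_detector_response
from .synthscope import (
    DEFAULT_ACTIVE_FRACTION_SLOW,
    DEFAULT_ACTIVE_FRACTION_TV,
    DEFAULT_FRAME_PERIOD_S,
    FrameStack,
)

__all__ = [
    "read_stack",
    "write_stack",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_curve_csv",
    "RunConfig",
    "config_hash",
    "run_pipeline",
]

log = logging.getLogger("fastscan")

_FRAME_SUFFIXES = (".png", ".tif", ".tiff")


def _sidecar_path(path: Path) -> Path:
    return path / "stack.json" if path.is_dir() else path.with_suffix(".json")


def read_stack(path) -> FrameStack:
    """Read a multipage TIFF or a directory of frames in acquisition order.

    Directory frames are ordered lexicographically by filename.  Pixel values
    are promoted to float64; metadata (frame period, active fraction, drift
    trajectories, a stored uint16 scale) is restored from the JSON sidecar
    when present.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        if not files:
            raise ValueError(f"no frames found in {path}")
        frames = []
        for p in files:
            frame = np.asarray(iio.imread(p))
            if frame.ndim != 2:
                raise ValueError(f"{p} is not a single grayscale frame")
            frames.append(frame)
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        data = np.stack(frames)
    else:
        data = np.asarray(tifffile.imread(path))
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"{path} does not hold 2-D grayscale frames")
    data = data.astype(np.float64)

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    scale = meta.get("uint16_scale")
    if scale is not None:
        data = data * scale["step"] + scale["offset"]
    return FrameStack(
        data,
        frame_period=meta.get("frame_period", DEFAULT_FRAME_PERIOD_S),
        active_fraction=meta.get("active_fraction", DEFAULT_ACTIVE_FRACTION_TV),
        metadata=meta.get("metadata", {}),
    )


def write_stack(stack: FrameStack, path, dtype=None, sidecar: bool = True) -> Path:
    """Write a stack as multipage TIFF plus a JSON sidecar.

    With the default ``dtype=None`` the frames are written in their native
    floating dtype, so a read round-trips bit-identically.  ``dtype="uint16"``
    quantizes to the full 16-bit range and stores the scale in the sidecar
    (for interoperability with microscopy viewers).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "frame_period": stack.frame_period,
        "active_fraction": stack.active_fraction,
        "metadata": stack.metadata,
    }
    frames = stack.frames
    if dtype is not None and np.dtype(dtype) == np.uint16:
        lo = float(frames.min())
        hi = float(frames.max())
        step = (hi - lo) / 65535.0 if hi > lo else 1.0
        quantized = np.round((frames - lo) / step).astype(np.uint16)
        meta["uint16_scale"] = {"offset": lo, "step": step}
        tifffile.imwrite(path, quantized, photometric="minisblack")
    else:
        tifffile.imwrite(
            path,
            frames if dtype is None else frames.astype(dtype),
            photometric="minisblack",
        )
    if sidecar:
        _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True, indent=1))
    return path


def write_trajectory_csv(trajectory: ShiftTrajectory, path, header_extra: str = "") -> None:
    with open(path, "w", newline="") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        w = csv.writer(fh)
        w.writerow(["frame", "dy", "dx", "score"])
        for i, s in enumerate(trajectory.shifts):
            w.writerow([i, s.dy, s.dx, repr(float(s.score))])


def read_trajectory_csv(path) -> ShiftTrajectory:
    shifts = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#") or row[0] == "frame":
                continue
            shifts.append(Shift(int(row[1]), int(row[2]), float(row[3])))
    return ShiftTrajectory(shifts)


def write_curve_csv(curve, path, header_extra: str = "") -> None:
    with open(path, "w", newline="") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        w = csv.writer(fh)
        w.writerow(["n", "sqrt_n", "s_sigma_hpf"])
        for n, s in curve.points:
            w.writerow([n, repr(float(np.sqrt(n))), repr(float(s))])


@dataclasses.dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run.

    ``input`` is a stack path.  The detector transfer comes from ``mtf``
    (CSV), or is measured from ``noise_stack``; with neither, restoration is
    skipped.  ``roi`` drives alignment; ``montage_rois`` switches on the
    multi-ROI montage path.  The acquisition constants default to video-rate
    scanning: 0.04 s per frame, active fraction 0.8, compared against a
    slow-scan reference fraction of 0.9.
    """

    input: str
    out_dir: str
    mtf: str | None = None
    noise_stack: str | None = None
    gain_cap: float = 10.0
    smooth_window: int = 9
    structure_size: float = 8.0
    roi: tuple[int, int, int, int] | None = None
    montage_rois: list[tuple[int, int, int, int]] | None = None
    levels: int | None = None
    search_margin: int = 64
    checkpoints: list[int] | None = None
    tolerance_fraction: float = 0.05
    feather_width: int = 64
    active_fraction: float = DEFAULT_ACTIVE_FRACTION_TV
    reference_fraction: float = DEFAULT_ACTIVE_FRACTION_SLOW
    uint16_output: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        if not Path(self.input).exists():
            raise ValueError(f"input stack {self.input} does not exist")
        for name in ("mtf", "noise_stack"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} path {p} does not exist")
        if not (0 < self.tolerance_fraction < 1):
            raise ValueError("tolerance_fraction must lie in (0, 1)")


def config_hash(config: RunConfig) -> str:
    """Hash of the analysis parameters (the output destination is excluded,
    so reruns into different directories compare equal)."""
    payload = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _load_or_measure_mtf(config: RunConfig) -> InverseFilter | None:
    if config.mtf is not None:
        profile = FrequencyProfile.from_csv(config.mtf)
    elif config.noise_stack is not None:
        log.info("measuring detector response from %s", config.noise_stack)
        profile = measure_detector_response(read_stack(config.noise_stack))
    else:
        return None
    return design_inverse_filter(profile, config.gain_cap, config.smooth_window)


def run_pipeline(config: RunConfig) -> dict:
    """Measure/load the MTF, restore, align, integrate, report.

    Writes into ``config.out_dir``: the restored+integrated image and its
    count map (TIFF), per-half shift CSVs, the integration curve CSV, an SNR
    JSON report and a run log JSON capturing every parameter.  Returns a dict
    of artifact paths plus the in-memory results.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    log.info("pipeline run, config hash %s", chash)

    stack = read_stack(config.input)
    filt = _load_or_measure_mtf(config)
    if filt is not None:
        log.info("applying inverse filter (cap %.3g)", config.gain_cap)
        restored = np.stack([apply_inverse_filter(f, filt) for f in stack.frames])
        stack = FrameStack(
            restored, stack.frame_period, stack.active_fraction, dict(stack.metadata)
        )
        filt.to_csv(out / "inverse_filter.csv")

    spec = FilterSpec(config.structure_size)
    roi = ROI(*config.roi) if config.roi else None
    half_a, half_b = odd_even_split(stack)

    artifacts: dict = {"config_hash": chash}
    traj_a = traj_b = None
    if roi is not None:
        traj_a = align_stack(half_a, roi, "running_mean", config.search_margin, config.levels)
        traj_b = align_stack(half_b, roi, "running_mean", config.search_margin, config.levels)
        write_trajectory_csv(traj_a, out / "shifts_even_half.csv", f"config_hash={chash}")
        write_trajectory_csv(traj_b, out / "shifts_odd_half.csv", f"config_hash={chash}")

    curve = integration_curve(
        stack,
        checkpoints=config.checkpoints,
        aligned=roi is not None,
        roi=roi,
        spec=spec,
        search_margin=config.search_margin,
        levels=config.levels,
        trajectories=(traj_a, traj_b) if traj_a is not None else None,
    )
    optimal_n = estimate_optimal_n(curve, config.tolerance_fraction)
    write_curve_csv(curve, out / "integration_curve.csv", f"config_hash={chash}")

    img_a = average_frames(half_a, traj_a)
    img_b = average_frames(half_b, traj_b)
    if roi is not None:
        full_traj = align_stack(stack, roi, "running_mean", config.search_margin, config.levels)
        integrated = average_frames(stack, full_traj)
        write_trajectory_csv(full_traj, out / "shifts.csv", f"config_hash={chash}")
    else:
        integrated = average_frames(stack)

    if config.montage_rois:
        rois = [ROI(*r) for r in config.montage_rois]
        partials = integrate_per_roi(
            stack, rois, min(config.search_margin, 16), "running_mean", config.levels
        )
        plan = make_montage_plan(rois, partials, config.feather_width)
        integrated = blend_montage(plan)

    est = covariance_stats(img_a.pixels, img_b.pixels)
    report = {
        "config_hash": chash,
        "n_frames": stack.n_frames,
        "snr": est.as_dict(),
        "snr_blanking_corrected": blanking_corrected_snr(
            est, config.active_fraction, config.reference_fraction
        )
        if np.isfinite(est.snr_amp)
        else None,
        "s_sigma_hpf": s_sigma_hpf(img_a.pixels, img_b.pixels, spec),
        "optimal_n_per_half": optimal_n,
        "optimal_n_total": 2 * optimal_n,
    }
    (out / "snr.json").write_text(json.dumps(report, sort_keys=True, indent=1))

    dtype = "uint16" if config.uint16_output else None
    write_stack(
        FrameStack(integrated.pixels[None], stack.frame_period, stack.active_fraction,
                   {"config_hash": chash}),
        out / "integrated.tif",
        dtype=dtype,
    )
    tifffile.imwrite(out / "count_map.tif", integrated.count_map.astype(np.uint16))
    run_log = {"config": config.to_dict(), "config_hash": chash, "report": report}
    (out / "run.json").write_text(json.dumps(run_log, sort_keys=True, indent=1))

    artifacts.update(
        out_dir=str(out),
        integrated=integrated,
        curve=curve,
        optimal_n=optimal_n,
        report=report,
    )
    return artifacts
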