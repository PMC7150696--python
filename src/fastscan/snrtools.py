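"""Two-image covariance SNR estimation.

Two continuously acquired frames of an identical view share the specimen
signal but carry independent noise, so the pixel covariance of the pair
estimates the signal power and the geometric-mean variance minus the
covariance estimates the noise power:

    S_sigma = sqrt(Cov(t1, t2))
    N_sigma = sqrt(sqrt(Var(t1) * Var(t2)) - Cov(t1, t2))
    SNR     = S_sigma / N_sigma            (amplitude ratio)

The squared ratio ``Cov / (sqrt(Var*Var) - Cov)`` is the power SNR; both are
reported, with the amplitude ratio as the default "SNR" (it is the quantity
that grows as sqrt(n) under n-frame integration).  ``S_sigma`` measured after
a high-pass filter — S_sigma(HPF) — is the sharpness score used for
integration curves and alignment-ROI selection: any blur introduced by
integration removes fine structure and drops it.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from .restore import FilterSpec, highpass

__all__ = ["SNREstimate", "covariance_stats", "s_sigma_hpf", "blanking_corrected_snr"]


@dataclasses.dataclass(frozen=True)
class SNREstimate:
    """Cov/Var statistics of a frame pair and the derived SNR measures.

    Population (1/N) moments are used.  ``negative_cov`` flags a pair whose
    sample covariance came out negative (possible on noise-only regions);
    ``s_sigma`` is clamped to 0 there.  ``infinite_snr`` flags a vanishing
    noise estimate (e.g. the two inputs are identical).
    """

    cov: float
    var1: float
    var2: float
    s_sigma: float
    n_sigma: float
    snr_amp: float
    snr_power: float
    n_pixels: int
    negative_cov: bool = False
    infinite_snr: bool = False

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _crop_roi(a: np.ndarray, roi) -> np.ndarray:
    if roi is None:
        return a
    r0, c0, r1, c1 = (roi.row0, roi.col0, roi.row1, roi.col1) if hasattr(roi, "row0") else roi
    if not (0 <= r0 < r1 <= a.shape[0] and 0 <= c0 < c1 <= a.shape[1]):
        raise ValueError(f"roi {(r0, c0, r1, c1)} outside image of shape {a.shape}")
    return a[r0:r1, c0:c1]


def covariance_stats(t1: np.ndarray, t2: np.ndarray, roi=None) -> SNREstimate:
    """Covariance/variance SNR statistics of a same-view frame pair."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if t1.shape != t2.shape:
        raise ValueError(f"shape mismatch: {t1.shape} vs {t2.shape}")
    x1 = _crop_roi(t1, roi).ravel()
    x2 = _crop_roi(t2, roi).ravel()
    if x1.size == 0:
        raise ValueError("empty roi")
    d1 = x1 - x1.mean()
    d2 = x2 - x2.mean()
    n = x1.size
    cov = float(d1 @ d2) / n
    var1 = float(d1 @ d1) / n
    var2 = float(d2 @ d2) / n

    negative_cov = cov < 0
    s_sigma = math.sqrt(cov) if cov > 0 else 0.0
    denom = math.sqrt(var1 * var2) - cov
    infinite = denom <= 0
    if infinite:
        n_sigma = 0.0
        snr_amp = math.inf if s_sigma > 0 else math.nan
        snr_power = math.inf if cov > 0 else math.nan
    else:
        n_sigma = math.sqrt(denom)
        snr_amp = s_sigma / n_sigma
        snr_power = cov / denom
    return SNREstimate(
        cov=cov,
        var1=var1,
        var2=var2,
        s_sigma=s_sigma,
        n_sigma=n_sigma,
        snr_amp=snr_amp,
        snr_power=snr_power,
        n_pixels=n,
        negative_cov=negative_cov,
        infinite_snr=infinite,
    )


def s_sigma_hpf(t1: np.ndarray, t2: np.ndarray, spec: FilterSpec | None = None, roi=None) -> float:
    """S_sigma of the high-pass-filtered pair: the fine-structure sharpness score.

    The high pass is applied to the full images before any ROI restriction so
    the score over a small ROI still reflects that ROI's local sharpness.
    """
    spec = spec or FilterSpec()
    h1 = highpass(t1, spec)
    h2 = highpass(t2, spec)
    return covariance_stats(h1, h2, roi=roi).s_sigma


def blanking_corrected_snr(
    est: SNREstimate | float, active_fraction: float, reference_fraction: float
) -> float:
    """Normalize an SNR to a reference signal-collection duty fraction.

    Scan modes spend different fractions of the acquisition time actually
    collecting pixels (the rest is blanking/flyback).  Noise amplitude scales
    as 1/sqrt(active time), so an SNR measured at ``active_fraction`` is put
    on the footing of ``reference_fraction`` by multiplying with
    ``sqrt(reference_fraction / active_fraction)``.
    """
    if not (0 < active_fraction <= 1 and 0 < reference_fraction <= 1):
        raise ValueError("fractions must lie in (0, 1]")
    snr = est.snr_amp if isinstance(est, SNREstimate) else float(est)
    return snr * math.sqrt(reference_fraction / active_fraction)
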