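"""Figure-of-merit suite for voltage-imaging recordings.

Implements the quantities used to characterize scanless two-photon
voltage imaging: response amplitude (-%dF/F0), empirical SNR (response
amplitude over baseline noise), shot-noise SNR ((-dF/F0) sqrt(F0) with F0
in detected photons), photostability (mean baseline fluorescence
normalized to the first frame), photorecovery across dark intervals,
power-response fits (two-photon F0 ~ P^2; SNR linear in P in the
shot-noise limit) and effective-resolution curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lightsculpt import profile_fwhm
from .trace_extraction import Trace

__all__ = [
    "MetricsReport",
    "PowerSeries",
    "snr_metrics",
    "photostability",
    "photorecovery",
    "fit_power_response",
    "resolution_curve",
]


@dataclass
class MetricsReport:
    dff_amp: float = np.nan  # -%dF/F0
    snr_empirical: float = np.nan
    snr_shot: float = np.nan
    photostability: float = np.nan
    photorecovery: float = np.nan
    photorecovery_per_epoch: np.ndarray = field(default_factory=lambda: np.array([]))
    f0_power_exponent: float = np.nan
    snr_power_r2: float = np.nan
    resolution_lateral_fwhm: float = np.nan  # um
    resolution_axial_fwhm: float = np.nan  # um

    def as_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
            elif v is None or (np.isscalar(v) and np.isnan(v)):
                continue
            else:
                d[k] = float(v)
        return d


@dataclass
class PowerSeries:
    """Per-power-level summary used for the power-response fits."""

    power_density: np.ndarray  # mW/um^2
    f0: np.ndarray  # counts (or photons)
    snr: np.ndarray
    dff: np.ndarray  # -%dF/F0 per level

    def __post_init__(self):
        self.power_density = np.asarray(self.power_density, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.power_density.size < 3:
            raise ValueError("need at least 3 power levels for fits")


def snr_metrics(
    trace: Trace,
    response_window: np.ndarray,
    baseline_window: np.ndarray,
    min_baseline: int = 50,
) -> tuple[float, float]:
    """Empirical and shot-noise SNR of a response.

    snr_empirical = |mean dff over the response window| divided by the SD
    of dff over the baseline window.  snr_shot = (-dF/F0) sqrt(F0) with F0
    in detected photons (the trace's photon conversion factor applied to
    its baseline fluorescence) -- the SNR of an ideal shot-noise-limited
    measurement of the same response.
    """
    response_window = np.asarray(response_window)
    baseline_window = np.asarray(baseline_window)
    if response_window.dtype != bool:
        raise ValueError("windows must be boolean frame masks")
    if np.any(response_window & baseline_window):
        raise ValueError("response and baseline windows must be disjoint")
    if baseline_window.sum() < min_baseline:
        raise ValueError(f"need >= {min_baseline} baseline frames")
    if trace.dff is None:
        raise ValueError("trace has no dff; run detrend_dff first")

    dff = trace.dff
    base = dff[baseline_window]
    base = base[np.isfinite(base)]
    resp = dff[response_window]
    resp = resp[np.isfinite(resp)]
    noise = float(base.std())
    if noise <= 0:
        raise ValueError("baseline SD is zero")
    amp = abs(float(resp.mean() - base.mean()))
    snr_empirical = amp / noise

    if trace.baseline_f is not None:
        f0_counts = float(np.nanmean(trace.baseline_f[baseline_window]))
    else:
        f0_counts = float(trace.raw_f[baseline_window].mean())
    f0_photons = f0_counts * trace.photons_per_unit
    snr_shot = amp * np.sqrt(max(f0_photons, 0.0))
    return snr_empirical, snr_shot


def photostability(
    trace: Trace, baseline_frames: np.ndarray | None = None
) -> float:
    """Mean baseline fluorescence over the record, normalized to the first
    frame: sum(F_baseline) / (F0 * n_t), with F0 the fluorescence in the
    first (baseline) frame.  1 = no bleaching.  Response frames are
    excluded via ``baseline_frames`` when given."""
    f = trace.raw_f
    if baseline_frames is not None:
        f = f[np.asarray(baseline_frames)]
    if f.size == 0:
        raise ValueError("no baseline frames")
    f0 = float(f[0])
    if f0 <= 0:
        raise ValueError("non-positive F0 in the first frame")
    return float(f.sum() / (f0 * f.size))


def photorecovery(
    trace: Trace,
    epochs: list[tuple[int, int]] | None = None,
    pre_window: int | None = None,
) -> tuple[float, np.ndarray]:
    """Baseline recovery across dark intervals.

    For each illumination epoch the fluorescence prior to the
    depolarization (the mean over the epoch's first ``pre_window`` frames,
    default the first quarter of the epoch) is measured; the recovery of
    epoch k is its pre-step fluorescence relative to the previous epoch's,
    F_k / F_{k-1}.  Returns the mean ratio and the per-interval ratios.
    Requires at least two epochs.
    """
    epochs = epochs if epochs is not None else trace.epochs
    if epochs is None or len(epochs) < 2:
        raise ValueError("photorecovery needs >= 2 illumination epochs")
    pre = []
    for a, b in epochs:
        w = pre_window if pre_window is not None else max((b - a) // 4, 1)
        pre.append(float(trace.raw_f[a : a + w].mean()))
    pre = np.asarray(pre)
    ratios = pre[1:] / pre[:-1]
    return float(ratios.mean()), ratios


def fit_power_response(series: PowerSeries) -> tuple[float, float, float]:
    """Power-response fits over a power-density series.

    Returns (f0_power_exponent, snr_power_r2, dff_trend): the slope of
    log F0 versus log P (2 for unsaturated two-photon excitation), the
    r^2 of an unconstrained ordinary-least-squares fit of SNR versus P
    (≈1 in the shot-noise-limited regime, where SNR is linear in P), and
    the sign of the -%dF/F0 trend versus P.
    """
    p = series.power_density
    if np.any(series.f0 <= 0):
        raise ValueError("F0 must be positive at all power levels")
    exponent = float(np.polyfit(np.log(p), np.log(series.f0), 1)[0])

    coef = np.polyfit(p, series.snr, 1)
    pred = np.polyval(coef, p)
    ss_res = float(((series.snr - pred) ** 2).sum())
    ss_tot = float(((series.snr - series.snr.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    dff_trend = float(np.sign(np.polyfit(p, series.dff, 1)[0]))
    return exponent, r2, dff_trend


def resolution_curve(
    responses: np.ndarray, displacements: np.ndarray
) -> float:
    """Effective-resolution FWHM from a response-versus-displacement scan.

    ``responses`` holds the -%dF/F0 of an evoked spike as the excitation
    spot is displaced from the soma by ``displacements`` (um, either
    axis).  The FWHM of the normalized curve is found by interpolated
    half-maximum crossings; the scan must bracket the half maximum on
    both sides.  A delta-like response spanning a single sample returns
    the scan step.
    """
    responses = np.asarray(responses, dtype=float)
    displacements = np.asarray(displacements, dtype=float)
    if responses.size != displacements.size:
        raise ValueError("responses and displacements must have equal length")
    order = np.argsort(displacements)
    x, y = displacements[order], responses[order]
    y = y / y.max()
    try:
        return profile_fwhm(x, y)
    except ValueError as exc:
        raise ValueError(
            "displacement scan does not bracket the half maximum"
        ) from exc
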