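"""Single-cell fluorescence trace extraction.

Mirrors the analysis pipeline used for widefield-style voltage-imaging
movies: crop a region of interest around each targeted cell, segment
candidate membrane pixels from the mean image, refine them by regressing
every pixel's time series against the mean trace of the initial
segmentation (pixels that follow the cell's temporal signature get high
weights, background pixels get zero), extract a weighted mean trace, and
detrend it per illumination epoch to obtain dF/F0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_closing, binary_opening, median_filter
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu

from .synthetic_movies import Movie

__all__ = [
    "ROI",
    "WeightMask",
    "Trace",
    "crop_roi",
    "initial_segmentation",
    "regression_weight_mask",
    "extract_trace",
    "detrend_dff",
    "illumination_epochs",
]


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest around one cell (pixel units)."""

    origin_rowcol: tuple[int, int] = (0, 0)
    height: int = 100
    width: int = 100
    spot_centroid: tuple[float, float] | None = None


@dataclass
class WeightMask:
    """Per-pixel extraction weights over an ROI."""

    weights: np.ndarray
    support: np.ndarray
    n_pixels_initial: int
    n_pixels_final: int


@dataclass
class Trace:
    """Extracted fluorescence time series.

    ``raw_f`` is offset-corrected counts per frame (weighted mean over the
    supported pixels), ``baseline_f`` the detrended baseline, ``f0`` the
    baseline fluorescence of each illumination epoch and ``dff`` the
    fractional change (raw - baseline)/baseline, defined only inside
    illumination epochs (NaN elsewhere).  ``photons_per_unit`` converts
    trace units to detected photons (for shot-noise SNR estimates).
    """

    time: np.ndarray  # ms
    raw_f: np.ndarray
    baseline_f: np.ndarray | None = None
    dff: np.ndarray | None = None
    f0: float | None = None
    epochs: list = field(default_factory=list)  # (start, stop) frame slices
    photons_per_unit: float = 1.0
    frame_rate: float | None = None  # effective Hz

    def copy(self) -> "Trace":
        return Trace(
            time=self.time.copy(),
            raw_f=self.raw_f.copy(),
            baseline_f=None if self.baseline_f is None else self.baseline_f.copy(),
            dff=None if self.dff is None else self.dff.copy(),
            f0=self.f0,
            epochs=list(self.epochs),
            photons_per_unit=self.photons_per_unit,
            frame_rate=self.frame_rate,
        )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def crop_roi(movie: Movie, roi: ROI) -> np.ndarray:
    r0, c0 = roi.origin_rowcol
    if r0 < 0 or c0 < 0 or r0 + roi.height > movie.data.shape[1] \
            or c0 + roi.width > movie.data.shape[2]:
        raise ValueError("ROI exceeds the frame bounds")
    return movie.data[:, r0 : r0 + roi.height, c0 : c0 + roi.width]


def initial_segmentation(
    movie: Movie,
    roi: ROI | None = None,
    illuminated: np.ndarray | None = None,
) -> np.ndarray:
    """Candidate membrane pixels from the mean image.

    Pixels are thresholded (Otsu) on the offset-corrected mean image over
    illuminated frames, then cleaned with a morphological opening/closing
    that favours the ring-like membrane structure.  Deterministic given
    the movie.  Raises if nothing exceeds the threshold (blank movie).
    """
    data = crop_roi(movie, roi) if roi is not None else movie.data
    if illuminated is None:
        illuminated = np.ones(data.shape[0], dtype=bool)
    mean_img = data[illuminated].mean(axis=0) - movie.acq.offset
    mean_img = np.maximum(mean_img, 0.0)

    smoothed = median_filter(mean_img, size=3)
    if smoothed.max() <= max(3.0 * movie.acq.read_noise, 1e-9):
        raise ValueError("no pixels above threshold: the movie appears blank")
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    mask = binary_opening(mask, iterations=1)
    mask = binary_closing(mask, iterations=2)
    if not mask.any():
        raise ValueError("segmentation produced an empty mask")
    return mask


def regression_weight_mask(
    movie: Movie,
    initial_mask: np.ndarray,
    roi: ROI | None = None,
    illuminated: np.ndarray | None = None,
    support_quantile: float = 0.5,
) -> WeightMask:
    """Regression-based pixel weighting.

    Each ROI pixel's time series is regressed on the mean trace of the
    initial segmentation; the weight is the regression slope, clipped at
    zero (anti-correlated pixels are background).  The support keeps the
    top (1 - support_quantile) fraction of positively weighted pixels
    inside the initial mask -- with the default 0.5 this retains roughly
    half of the initial pixels, the most voltage-responsive ones.
    """
    data = crop_roi(movie, roi) if roi is not None else movie.data
    if not initial_mask.any():
        raise ValueError("initial mask is empty")
    if illuminated is None:
        illuminated = np.ones(data.shape[0], dtype=bool)
    if illuminated.sum() < 100:
        warnings.warn("fewer than 100 frames available for the regression",
                      stacklevel=2)

    x = data[illuminated].astype(float)
    ref = x[:, initial_mask].mean(axis=1)
    ref = ref - ref.mean()
    var = float(ref @ ref)
    if var <= 0:
        raise ValueError(
            "reference trace has no temporal structure; use a segment "
            "containing a stimulus"
        )
    flat = x.reshape(x.shape[0], -1)
    slopes = (ref @ (flat - flat.mean(axis=0))) / var
    weights = np.maximum(slopes.reshape(initial_mask.shape), 0.0)

    inside = weights[initial_mask]
    pos = inside[inside > 0]
    if pos.size == 0:
        raise ValueError("no positively weighted pixels inside the initial mask")
    thr = np.quantile(pos, support_quantile)
    support = initial_mask & (weights > thr)
    if not support.any():
        support = initial_mask & (weights > 0)
    return WeightMask(
        weights=weights,
        support=support,
        n_pixels_initial=int(initial_mask.sum()),
        n_pixels_final=int(support.sum()),
    )


# ---------------------------------------------------------------------------
# trace extraction
# ---------------------------------------------------------------------------

def extract_trace(
    movie: Movie,
    weights: WeightMask | np.ndarray,
    roi: ROI | None = None,
) -> Trace:
    """Weighted mean trace over the supported pixels.

    Boolean/positive arrays are accepted as uniform or explicit weights.
    The weighted mean is invariant to a global rescaling of the weights.
    A photon conversion factor is estimated from the weights and the mean
    image so that shot-noise-limited SNR estimates ((-dF/F0) sqrt(F0) with
    F0 in photons) can be computed downstream.
    """
    data = crop_roi(movie, roi) if roi is not None else movie.data
    if isinstance(weights, WeightMask):
        w = np.where(weights.support, weights.weights, 0.0)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != data.shape[1:]:
        raise ValueError("weight shape does not match the (cropped) frame")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights sum to zero")

    wf = w.reshape(-1)
    n_frames = data.shape[0]
    raw = np.empty(n_frames)
    mu = np.zeros(wf.size)
    for a in range(0, n_frames, 512):  # chunked: movies can be large
        chunk = data[a : a + 512].reshape(-1, wf.size).astype(float)
        chunk -= movie.acq.offset
        raw[a : a + 512] = chunk @ wf / wsum
        mu += chunk.sum(axis=0)
    mu = np.maximum(mu / n_frames, 1e-12) / movie.acq.gain  # photons

    # effective photon count of the weighted mean: F_phot = raw * scale,
    # with Var(raw) = sum(w^2 mu)/sum(w)^2 for Poisson pixels
    num = float(wf @ mu)
    den = float((wf**2) @ mu)
    scale = num * wsum / den if den > 0 else 1.0

    period = movie.acq.frame_period
    return Trace(
        time=movie.frame_times.copy(),
        raw_f=raw,
        photons_per_unit=scale / movie.acq.gain,
        frame_rate=1e3 / period,
    )


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------

def illumination_epochs(
    illumination: np.ndarray, min_frames: int = 2, threshold: float = 0.999
) -> list[tuple[int, int]]:
    """Contiguous fully illuminated frame intervals [start, stop).

    Frames whose exposure only partially overlaps the illumination gate
    are excluded: their fluorescence is scaled by the overlap fraction,
    which would corrupt baselines far beyond shot noise.
    """
    on = np.asarray(illumination) >= threshold
    edges = np.flatnonzero(np.diff(np.concatenate([[0], on.view(np.int8), [0]])))
    return [
        (int(a), int(b))
        for a, b in zip(edges[::2], edges[1::2])
        if b - a >= min_frames
    ]


def _biexp(t, a, tau1, b, tau2, c):
    return a * np.exp(-t / tau1) + b * np.exp(-t / tau2) + c


def detrend_dff(
    trace: Trace,
    illumination: np.ndarray | None = None,
    method: str = "biexp",
    event_mask: np.ndarray | None = None,
    event_halfwidth_ms: float = 10.0,
    percentile: float = 50.0,
    percentile_window: int = 101,
    f0_mode: str = "epoch_start",
) -> Trace:
    """Per-epoch baseline estimation and dF/F0 computation.

    The baseline of each illumination epoch is a bi-exponential fit to the
    event-masked frames (``method='biexp'``; falls back to simpler models
    and finally a running-percentile filter when the fit cannot be
    performed), or a running-percentile filter directly
    (``method='percentile'``).  Frames within ``event_halfwidth_ms`` of
    candidate events are excluded from the fit unless an explicit
    ``event_mask`` (True = exclude) is given.

    dff = (raw - baseline)/baseline inside epochs, NaN outside.  ``f0`` is
    the baseline at the first epoch's start (``f0_mode='epoch_start'``) or
    the mean pre-event baseline (``'pre_event'``).  The input trace is not
    modified; a new Trace is returned with ``raw_f`` untouched.
    """
    out = trace.copy()
    n = out.raw_f.size
    if illumination is None:
        epochs = [(0, n)]
    else:
        epochs = illumination_epochs(illumination)
        if not epochs:
            epochs = [(0, n)]
    out.epochs = epochs

    if event_mask is None:
        event_mask = _candidate_event_mask(out, epochs, event_halfwidth_ms)

    baseline = np.full(n, np.nan)
    for a, b in epochs:
        seg = out.raw_f[a:b]
        t = np.arange(b - a, dtype=float)
        keep = ~event_mask[a:b]
        if keep.sum() < max(6, 0.1 * seg.size):
            keep = np.ones(seg.size, dtype=bool)
        baseline[a:b] = _fit_baseline(
            t, seg, keep, method, percentile, percentile_window
        )

    out.baseline_f = baseline
    with np.errstate(invalid="ignore", divide="ignore"):
        out.dff = (out.raw_f - baseline) / baseline
    mask_out = np.ones(n, dtype=bool)
    for a, b in epochs:
        mask_out[a:b] = False
    out.dff[mask_out] = np.nan

    a0, _ = epochs[0]
    if f0_mode == "epoch_start":
        out.f0 = float(baseline[a0])
    elif f0_mode == "first_frame":
        out.f0 = float(out.raw_f[a0])
    else:  # pre_event mean over the first epoch's masked-out baseline
        a, b = epochs[0]
        keep = ~event_mask[a:b]
        out.f0 = float(out.raw_f[a:b][keep].mean())
    if out.f0 is not None and out.f0 <= 0:
        raise ValueError("non-positive F0; the trace has no baseline fluorescence")
    return out


def _candidate_event_mask(trace, epochs, halfwidth_ms):
    """Frames near candidate events (robust 4-sigma excursions of the
    high-passed trace), to be excluded from baseline fits."""
    n = trace.raw_f.size
    mask = np.zeros(n, dtype=bool)
    if trace.frame_rate is None or n < 8:
        return mask
    halfwidth = max(int(round(halfwidth_ms * trace.frame_rate / 1e3)), 1)
    for a, b in epochs:
        seg = trace.raw_f[a:b]
        win = min(21, 2 * (seg.size // 4) + 1)
        if win < 5:
            continue
        resid = seg - median_filter(seg, size=win, mode="nearest")
        sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if sigma <= 0:
            continue
        hits = np.flatnonzero(np.abs(resid) > 4.0 * sigma)
        for h in hits:
            mask[a + max(h - halfwidth, 0) : a + min(h + halfwidth + 1, b - a)] = True
    return mask


def _fit_baseline(t, seg, keep, method, percentile, percentile_window):
    if method == "percentile":
        return _percentile_baseline(seg, percentile, percentile_window)
    if method == "constant":
        # per-epoch constant baseline (bleach-free strobed epochs)
        return np.full(seg.size, float(seg[keep].mean()))
    if method != "biexp":
        raise ValueError(f"unknown detrend method {method!r}")

    tk, yk = t[keep], seg[keep]
    span = max(float(t[-1]), 1.0)
    scale = float(np.median(yk))
    if scale <= 0:
        return _percentile_baseline(seg, percentile, percentile_window)
    tn, yn = tk / span, yk / scale  # normalize: curve_fit conditioning
    y0 = float(np.median(yn[: max(3, yn.size // 10)]))
    yend = float(np.median(yn[-max(3, yn.size // 10):]))
    drop = max(y0 - yend, 1e-3)

    bounds = ([0.0, 1e-3, 0.0, 1e-3, -np.inf],
              [np.inf, 10.0, np.inf, 100.0, np.inf])
    for p0 in (
        [0.7 * drop, 0.1, 0.3 * drop, 1.0, yend],
        [0.9 * drop, 0.3, 0.1 * drop, 3.0, yend],
    ):
        try:
            popt, _ = curve_fit(_biexp, tn, yn, p0=p0, bounds=bounds,
                                maxfev=20000)
            fit = _biexp(t / span, *popt) * scale
            if np.all(np.isfinite(fit)) and fit.min() > 0:
                return fit
        except Exception:
            continue
    # single exponential before giving up entirely
    try:
        popt, _ = curve_fit(
            lambda x, a, tau, c: a * np.exp(-x / tau) + c,
            tn, yn, p0=[drop, 0.5, yend], maxfev=20000,
        )
        fit = (popt[0] * np.exp(-(t / span) / popt[1]) + popt[2]) * scale
        if np.all(np.isfinite(fit)) and fit.min() > 0:
            return fit
    except Exception:
        pass
    warnings.warn(
        "exponential baseline fits failed; falling back to the "
        "running-percentile filter",
        stacklevel=2,
    )
    return _percentile_baseline(seg, percentile, percentile_window)


def _percentile_baseline(seg, percentile, window):
    win = min(window, 2 * (seg.size // 2) - 1)
    if win < 3:
        return np.full(seg.size, np.median(seg))
    from scipy.ndimage import percentile_filter

    return percentile_filter(seg.astype(float), percentile, size=win,
                             mode="nearest")
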