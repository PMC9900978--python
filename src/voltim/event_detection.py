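"""Action-potential detection and trial-averaging on dF/F traces.

Spikes are found by prominence-seeded template matching: the most
prominent negative-going peaks seed an event template, whose normalized
cross-correlation with the trace then yields the final detections with
sub-frame timing by parabolic interpolation.  Detections are scored
against reference (electrophysiology-surrogate) event times by greedy
one-to-one matching within a tolerance, yielding the detection
probability and the timing jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import find_peaks

from .trace_extraction import Trace

__all__ = [
    "SpikeSet",
    "DetectionScore",
    "detect_spikes",
    "score_detection",
    "average_trials",
    "latency_jitter",
]


@dataclass
class SpikeSet:
    """Detected events (negative-going transients, sign folded)."""

    times: np.ndarray = field(default_factory=lambda: np.array([]))  # ms
    amplitudes: np.ndarray = field(default_factory=lambda: np.array([]))  # -dF/F0
    widths: np.ndarray = field(default_factory=lambda: np.array([]))  # ms FWHM
    match_flags: np.ndarray | None = None
    template: np.ndarray | None = None

    def __len__(self):
        return self.times.size


@dataclass
class DetectionScore:
    detection_probability: float
    timing_jitter_sd: float  # ms
    false_positive_rate: float  # events/s
    n_matched: int
    n_reference: int
    n_detected: int


def _baseline_sigma(x: np.ndarray) -> float:
    """Robust baseline noise via the median absolute deviation."""
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def _parabolic_peak(y: np.ndarray, i: int) -> float:
    """Sub-sample peak position by parabolic interpolation around i."""
    if i <= 0 or i >= y.size - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return float(i + 0.5 * (y[i - 1] - y[i + 1]) / denom)


def detect_spikes(
    trace: Trace,
    prominence_sd: float = 4.0,
    seed: int = 0,
    corr_threshold: float = 0.7,
    template_halfwidth_ms: float = 4.0,
    min_separation_ms: float = 4.0,
    min_template_events: int = 3,
) -> SpikeSet:
    """Three-stage spike detection on a dF/F trace.

    1. Peaks of -dff with prominence >= prominence_sd x sigma, where sigma
       is the robust baseline noise of the trace.
    2. The event template is the mean of the stage-1 snippets.
    3. Normalized cross-correlation of the template against the trace;
       events are kept where the correlation exceeds ``corr_threshold``
       and the peak amplitude exceeds the prominence threshold.  Event
       times are parabolic-interpolated peaks of the matched-filter
       output, so timing is sub-frame.

    Returns an empty SpikeSet when no stage-1 peaks exist.  The result is
    invariant to scaling and offsetting of the trace; ``seed`` is part of
    the call contract for deterministic pipelines but no randomness is
    currently used.
    """
    del seed  # deterministic
    if trace.dff is None:
        raise ValueError("trace has no dff; run detrend_dff first")
    dff = np.nan_to_num(trace.dff, nan=0.0)
    if trace.frame_rate is None:
        raise ValueError("trace has no frame rate")
    period = 1e3 / trace.frame_rate

    y = -dff
    sigma = _baseline_sigma(y)
    if sigma <= 0:
        return SpikeSet()
    thr = prominence_sd * sigma
    min_dist = max(int(round(min_separation_ms / period)), 1)
    # seeds must both be prominent and stand above the baseline: on long
    # traces, prominence alone admits ordinary noise peaks measured
    # against distant troughs
    peaks, props = find_peaks(y, prominence=thr, height=thr, distance=min_dist)
    if peaks.size == 0:
        return SpikeSet()
    if peaks.size < min_template_events:
        # too few seeds for a reliable template: accept only unambiguous
        # large events (one sigma above the seeding threshold)
        keep = y[peaks] >= (prominence_sd + 1.0) * sigma
        peaks = peaks[keep]
        times = trace.time[0] + peaks * period
        return SpikeSet(
            times=times.astype(float),
            amplitudes=y[peaks].astype(float),
            widths=np.array([_event_fwhm(y, p, period) for p in peaks]),
        )

    # template window: never wider than the typical inter-event interval,
    # otherwise neighbouring spikes in high-frequency trains contaminate
    # the template and the matched filter
    if peaks.size >= 2:
        isi_ms = float(np.median(np.diff(peaks))) * period
        template_halfwidth_ms = min(template_halfwidth_ms, 0.45 * isi_ms)
    half = max(int(round(template_halfwidth_ms / period)), 2)
    snippets = []
    for p in peaks:
        if half <= p < y.size - half:
            snippets.append(y[p - half : p + half + 1])
    if not snippets:
        snippets = [
            np.pad(
                y[max(p - half, 0) : p + half + 1],
                (max(half - p, 0), max(p + half + 1 - y.size, 0)),
            )
            for p in peaks
        ]
    template = np.mean(snippets, axis=0)
    template = template - template.mean()
    tnorm = np.linalg.norm(template)
    if tnorm == 0:
        return SpikeSet()
    template /= tnorm

    # matched filter: unnormalized output carries the event amplitude
    # (with the matched-filter SNR gain), the normalized cross-correlation
    # gates on waveform shape
    win = template.size
    views = sliding_window_view(y, win)
    vm = views - views.mean(axis=1, keepdims=True)
    mf = vm @ template
    denom = np.linalg.norm(vm, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = mf / denom
    ncc = np.nan_to_num(ncc, nan=-1.0)
    sigma_mf = _baseline_sigma(mf)
    if sigma_mf <= 0:
        return SpikeSet()

    cand, _ = find_peaks(mf, height=prominence_sd * sigma_mf, distance=min_dist)
    cand = cand[ncc[cand] >= corr_threshold]
    centers = cand + half  # window start -> event sample
    # noise coincidences can reach the matched-filter threshold through a
    # multi-frame pattern without any single-frame excursion; require the
    # raw amplitude at the event centre to clear the seeding threshold and
    # to be commensurate with the seed events (half their mean amplitude,
    # generous for real amplitude heterogeneity)
    amp_gate = max(thr, 0.5 * float(np.mean(y[peaks])))
    ok = y[np.clip(centers, 0, y.size - 1)] >= amp_gate
    cand, centers = cand[ok], centers[ok]
    if centers.size == 0:
        return SpikeSet()

    times, amps, widths = [], [], []
    for c0, c in zip(cand, centers):
        sub = _parabolic_peak(mf, c0) + half
        times.append(trace.time[0] + sub * period)
        amps.append(float(y[min(c, y.size - 1)]))
        widths.append(_event_fwhm(y, min(c, y.size - 1), period))
    order = np.argsort(times)
    return SpikeSet(
        times=np.asarray(times)[order],
        amplitudes=np.asarray(amps)[order],
        widths=np.asarray(widths)[order],
        template=template,
    )


def _event_fwhm(y: np.ndarray, peak: int, period: float) -> float:
    half = y[peak] / 2.0
    left = peak
    while left > 0 and y[left] > half:
        left -= 1
    right = peak
    while right < y.size - 1 and y[right] > half:
        right += 1
    return (right - left) * period


def score_detection(
    spikes: SpikeSet,
    reference_times: np.ndarray,
    tolerance: float = 5.0,
    duration_ms: float | None = None,
) -> DetectionScore:
    """Score detections against reference event times.

    Greedy one-to-one matching: reference events are paired with the
    nearest unmatched detection within ``tolerance`` ms, in order of
    increasing time difference.  detection_probability = matched /
    n_reference; timing jitter is the SD of (optical - reference) over
    matched pairs (constant latency offsets do not contribute).
    """
    reference_times = np.asarray(reference_times, dtype=float)
    if reference_times.size == 0:
        raise ValueError("reference event set is empty")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    det = np.asarray(spikes.times, dtype=float)
    pairs = []
    if det.size:
        diffs = np.abs(det[:, None] - reference_times[None, :])
        order = np.argsort(diffs, axis=None)
        used_d, used_r = set(), set()
        for flat in order:
            i, j = np.unravel_index(flat, diffs.shape)
            if diffs[i, j] > tolerance:
                break
            if i in used_d or j in used_r:
                continue
            used_d.add(i)
            used_r.add(j)
            pairs.append((i, j))

    matched = len(pairs)
    offsets = np.array([det[i] - reference_times[j] for i, j in pairs])
    jitter = float(np.std(offsets)) if matched > 1 else 0.0
    spikes.match_flags = np.zeros(det.size, dtype=bool)
    for i, _ in pairs:
        spikes.match_flags[i] = True

    if duration_ms is None:
        span = reference_times.max() - reference_times.min()
        duration_ms = span if span > 0 else tolerance
    fp = det.size - matched
    return DetectionScore(
        detection_probability=matched / reference_times.size,
        timing_jitter_sd=jitter,
        false_positive_rate=fp / (duration_ms / 1e3),
        n_matched=matched,
        n_reference=int(reference_times.size),
        n_detected=int(det.size),
    )


def average_trials(
    traces: list[Trace],
    alignment: np.ndarray | None = None,
    window_ms: tuple[float, float] | None = None,
    response_window_ms: tuple[float, float] | None = None,
    baseline_window_ms: tuple[float, float] | None = None,
) -> tuple[Trace, np.ndarray]:
    """Stimulus-aligned trial averaging with the SNR-versus-n curve.

    ``traces`` may be one trace per trial (optionally re-aligned to the
    stimulus ``alignment`` onsets) with a common time base.  Returns the
    across-trial mean trace and, when response/baseline windows are given,
    the empirical SNR (|mean response dff| / SD of baseline dff of the
    averaged trace) for n = 1..N accumulated trials.
    """
    if len(traces) < 1:
        raise ValueError("need at least one trial")
    n_samples = traces[0].dff.size if traces[0].dff is not None else traces[0].raw_f.size
    mat = []
    for tr in traces:
        y = tr.dff if tr.dff is not None else tr.raw_f
        if y.size != n_samples:
            raise ValueError("trials have mismatched lengths")
        mat.append(np.nan_to_num(y, nan=0.0))
    mat = np.asarray(mat)
    if alignment is not None and len(alignment) == len(traces):
        # shift each trial so its onset lands at alignment[0]
        period = 1e3 / traces[0].frame_rate
        shifts = np.round((np.asarray(alignment) - alignment[0]) / period).astype(int)
        mat = np.asarray([np.roll(row, -s) for row, s in zip(mat, shifts)])

    mean_trace = Trace(
        time=traces[0].time.copy(),
        raw_f=mat.mean(axis=0),
        dff=mat.mean(axis=0),
        frame_rate=traces[0].frame_rate,
    )

    snr_vs_n = np.array([])
    if response_window_ms is not None and baseline_window_ms is not None:
        t = traces[0].time
        rsel = (t >= response_window_ms[0]) & (t < response_window_ms[1])
        bsel = (t >= baseline_window_ms[0]) & (t < baseline_window_ms[1])
        csum = np.cumsum(mat, axis=0)
        snrs = []
        for n in range(1, mat.shape[0] + 1):
            avg = csum[n - 1] / n
            noise = float(avg[bsel].std())
            amp = abs(float(avg[rsel].mean() - avg[bsel].mean()))
            snrs.append(amp / noise if noise > 0 else np.inf)
        snr_vs_n = np.asarray(snrs)
    return mean_trace, snr_vs_n


def latency_jitter(
    spikes: SpikeSet,
    stim_onsets: np.ndarray,
    window_ms: float = 20.0,
) -> tuple[float, float, int]:
    """Per-pulse spike latency statistics.

    Each stimulation onset is assigned the first spike within
    ``window_ms`` after it; additional spikes in the same window and
    spikes preceding any onset are excluded and counted.  Returns
    (latency mean, latency SD, n excluded).
    """
    stim_onsets = np.asarray(stim_onsets, dtype=float)
    times = np.sort(np.asarray(spikes.times, dtype=float))
    latencies = []
    excluded = 0
    used = np.zeros(times.size, dtype=bool)
    for onset in stim_onsets:
        in_win = np.flatnonzero(
            (times >= onset) & (times < onset + window_ms) & (~used)
        )
        if in_win.size == 0:
            continue
        first = in_win[0]
        used[first] = True
        latencies.append(times[first] - onset)
        excluded += in_win.size - 1
        used[in_win[1:]] = True
    excluded += int((~used).sum())
    if not latencies:
        return np.nan, np.nan, excluded
    lat = np.asarray(latencies)
    return float(lat.mean()), float(lat.std()), excluded
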