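"""Synthetic GEVI camera movies with known ground truth.

Generates camera recordings that emulate soma-targeted JEDI-2P-kv imaging
under sculpted two-photon illumination: membrane-annulus somata, a
negative-going voltage-to-fluorescence transduction with first-order
on/off kinetics, Poisson photon statistics, bi-exponential photobleaching
with recovery across dark intervals, strobed or continuous illumination,
and an optogenetic actuation model (spike probability, latency and jitter
versus photostimulation power density).

All stimulation protocols used in the characterization experiments are
available through :func:`make_protocol`; movies are rendered frame by
frame from a supersampled (0.1 ms) voltage/illumination time base.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SensorModel",
    "CellSpec",
    "ProtocolSpec",
    "AcquisitionSpec",
    "ActuatorModel",
    "GroundTruth",
    "Movie",
    "make_protocol",
    "voltage_to_dff",
    "render_movie",
    "simulate_actuation",
    "membrane_mask",
    "heterogeneous_responsivity",
    "effective_frame_rate",
    "fov_extent",
]

DT_MS = 0.1  # internal supersampling step


# ---------------------------------------------------------------------------
# camera arithmetic
# ---------------------------------------------------------------------------

def effective_frame_rate(exposure_ms: float, readout_ms: float = 0.02) -> float:
    """Effective acquisition rate (Hz) of a rolling sCMOS acquisition.

    One frame takes exposure + readout, e.g. 1 ms exposure with 0.02 ms
    readout gives 980 Hz.
    """
    if exposure_ms <= 0:
        raise ValueError("exposure must be positive")
    return 1e3 / (exposure_ms + readout_ms)


def fov_extent(n_rows: int, pixel_size: float = 0.1625) -> float:
    """Field-of-view extent (um) spanned by ``n_rows`` camera rows.

    At a given acquisition rate the camera can only read a limited number
    of rows (266 at the nominal 1 kHz, 532 at 500 Hz in dynamic-range
    mode), which bounds one dimension of the imaging field.
    """
    if n_rows <= 0:
        raise ValueError("row count must be positive")
    return n_rows * pixel_size


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorModel:
    """Voltage-indicator response model.

    ``sensitivity`` is the fractional fluorescence change per 100 mV
    depolarization (negative-going: -0.43 means a 100 mV step dims the
    membrane by 43 %).  ``tau_on``/``tau_off`` are first-order activation/
    deactivation time constants; the defaults are calibrated so that a
    3 ms, 100 mV command integrated by a 1 ms exposure peaks near -30 %
    dF/F0 and near -26 % with a 2 ms exposure.  Photobleaching is
    bi-exponential in cumulative illuminated time with both time constants
    scaling inversely with power density; ``recovery_fraction`` of the
    reversibly bleached deficit recovers across a dark interval (with time
    constant ``recovery_tau``).
    """

    sensitivity: float = -0.43  # dF/F per 100 mV
    tau_on: float = 2.0  # ms
    tau_off: float = 1.2  # ms
    bleach_fast_tau: float = 0.2  # s at the reference power density
    bleach_slow_tau: float = 40.0  # s at the reference power density
    bleach_fast_amp: float = 0.2  # amplitude of the fast component
    recovery_fraction: float = 0.97
    recovery_tau: float = 0.3  # s
    reference_power_density: float = 1.0  # mW/um^2

    def __post_init__(self):
        if self.sensitivity >= 0:
            raise ValueError("sensitivity must be negative (negative-going GEVI)")
        if self.tau_on <= 0 or self.tau_off <= 0:
            raise ValueError("kinetic time constants must be positive")
        if not (0.0 <= self.recovery_fraction <= 1.0):
            raise ValueError("recovery_fraction must be in [0, 1]")
        if not (0.0 <= self.bleach_fast_amp <= 1.0):
            raise ValueError("bleach_fast_amp must be in [0, 1]")


@dataclass(frozen=True)
class CellSpec:
    """A membrane-annulus soma in camera coordinates (um)."""

    centroid_xy: tuple[float, float] = (0.0, 0.0)
    radius: float = 6.0  # um
    membrane_thickness: float = 1.0  # um
    expression: float = 10.0  # photons/pixel/ms at F0 under full excitation
    responsivity_map: np.ndarray | None = None  # full-frame multiplier

    def __post_init__(self):
        if self.radius <= 0 or self.membrane_thickness <= 0:
            raise ValueError("radius and membrane thickness must be positive")
        if self.expression < 0:
            raise ValueError("expression must be nonnegative")


@dataclass
class ProtocolSpec:
    """Stimulation/illumination protocol on a supersampled time base."""

    kind: str
    time: np.ndarray  # ms
    voltage_command: np.ndarray  # mV
    illumination_gate: np.ndarray  # bool
    acquisition_rate: float  # nominal Hz
    event_times: np.ndarray = field(default_factory=lambda: np.array([]))  # ms
    stim_onsets: np.ndarray = field(default_factory=lambda: np.array([]))  # ms
    power_density: float = 1.0  # mW/um^2
    holding_mv: float = -75.0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.time)
        if len(self.voltage_command) != n or len(self.illumination_gate) != n:
            raise ValueError("command and gate must share the protocol time base")

    @property
    def duration_ms(self) -> float:
        return float(self.time[-1] + (self.time[1] - self.time[0]))


@dataclass(frozen=True)
class AcquisitionSpec:
    """Camera acquisition parameters (sCMOS, linear 16-bit)."""

    pixel_size: float = 0.1625  # um
    exposure: float = 1.0  # ms
    readout: float = 0.02  # ms
    n_rows: int = 100
    n_cols: int = 100
    offset: float = 100.0  # counts
    read_noise: float = 2.0  # counts rms
    gain: float = 1.0  # counts per photon
    bit_depth: int = 16

    def __post_init__(self):
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")

    @property
    def frame_period(self) -> float:
        return self.exposure + self.readout

    @property
    def effective_rate(self) -> float:
        return effective_frame_rate(self.exposure, self.readout)

    @classmethod
    def from_rate(cls, rate_hz: float, **kwargs) -> "AcquisitionSpec":
        """Acquisition at a nominal rate: exposure = 1/rate, e.g. 1 ms at
        the nominal 1 kHz (effective 980 Hz after 0.02 ms readout)."""
        return cls(exposure=1e3 / rate_hz, **kwargs)


@dataclass(frozen=True)
class ActuatorModel:
    """Spike-outcome model of a soma-targeted channelrhodopsin.

    Photocurrents saturate at ``saturation_density``; per pulse an action
    potential is drawn Bernoulli with probability following a saturating
    curve in power density, scaled by a desensitization state that decays
    per delivered pulse and recovers between pulses.  Spike time = pulse
    onset + latency_mean + N(0, latency_jitter_sd).
    """

    saturation_density: float = 0.02  # mW/um^2
    p_max: float = 0.9
    latency_mean: float = 4.3  # ms
    latency_jitter_sd: float = 1.0  # ms
    desensitization: float = 0.15  # per-pulse probability decrement
    desensitization_recovery_tau: float = 250.0  # ms

    def probability(self, power_density: float) -> float:
        """AP probability versus power density: linear rise to saturation."""
        if power_density <= 0:
            return 0.0
        return self.p_max * min(power_density / self.saturation_density, 1.0)


@dataclass
class GroundTruth:
    """Per-frame truth accompanying a rendered movie."""

    frame_times: np.ndarray  # ms, exposure start
    voltage: np.ndarray  # (n_cells, n_frames) frame-averaged mV
    dff: np.ndarray  # (n_cells, n_frames) noiseless frame-integrated dF/F
    event_times: list  # per cell, ms
    bleach: np.ndarray  # (n_frames,) bleach factor
    illumination: np.ndarray  # (n_frames,) fraction of exposure illuminated
    membrane_masks: list  # per cell, boolean (n_rows, n_cols)


@dataclass
class Movie:
    """Camera stack with acquisition metadata."""

    data: np.ndarray  # (n_frames, n_rows, n_cols) uint16
    acq: AcquisitionSpec
    frame_times: np.ndarray  # ms
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def _ap_waveform(time: np.ndarray, onset: float, amplitude: float = 100.0,
                 rise_ms: float = 1.0, fall_ms: float = 2.0) -> np.ndarray:
    """Stylized triangular action potential (configurable; the granule-cell
    waveform itself is not modelled)."""
    t = time - onset
    up = (t >= 0) & (t < rise_ms)
    down = (t >= rise_ms) & (t < rise_ms + fall_ms)
    wav = np.zeros_like(time)
    wav[up] = amplitude * t[up] / rise_ms
    wav[down] = amplitude * (1.0 - (t[down] - rise_ms) / fall_ms)
    return wav


def make_protocol(kind: str, params: dict | None = None, seed: int = 0) -> ProtocolSpec:
    """Build one of the characterization protocols.

    * ``protocol1`` - three 100 ms / 100 mV steps under 3 s continuous
      illumination, 100 Hz sampling (voltage-sensitivity measurement).
    * ``protocol2`` - the same steps with 200 ms illumination pulses
      centred on each step and 2.5 s dark inter-pulse intervals
      (photostability/photorecovery and power sweeps).
    * ``protocol3`` - a 20 Hz train of ten 3 ms / 100 mV rectangular
      pulses under 500 ms continuous illumination at the nominal 1 kHz.
    * ``ap_train`` - ten action potentials at ``rate_hz`` (25-125 Hz).
    * ``subthreshold`` - 20 ms steps of ``amplitude_mv`` (0-2.5 mV)
      repeated ``n_trials`` times under 40 ms strobed illumination.
    * ``spontaneous`` - Ornstein-Uhlenbeck sub-threshold drive plus
      Poisson action potentials under continuous illumination.

    ``params`` overrides protocol defaults; randomness (spontaneous only)
    is driven by ``seed``.
    """
    p = dict(params or {})
    rate = p.pop("acquisition_rate", None)
    power = p.pop("power_density", None)

    def timebase(duration_ms):
        n = int(round(duration_ms / DT_MS))
        return np.arange(n) * DT_MS

    if kind == "protocol1":
        hold = p.pop("holding_mv", -55.0)
        time = timebase(3000.0)
        v = np.full_like(time, hold)
        for onset in (500.0, 1500.0, 2500.0):
            v[(time >= onset) & (time < onset + 100.0)] = hold + 100.0
        gate = np.ones_like(time, dtype=bool)
        return ProtocolSpec(kind, time, v, gate, rate or 100.0,
                            event_times=np.array([500.0, 1500.0, 2500.0]),
                            power_density=power or 0.88, holding_mv=hold, params=p)

    if kind == "protocol2":
        hold = p.pop("holding_mv", -55.0)
        lead = p.pop("lead_ms", 100.0)
        inter = p.pop("inter_pulse_ms", 2500.0)
        n_epochs = p.pop("n_epochs", 3)
        epoch = 200.0
        duration = 2 * lead + n_epochs * epoch + (n_epochs - 1) * inter
        time = timebase(duration)
        v = np.full_like(time, hold)
        gate = np.zeros_like(time, dtype=bool)
        onsets = []
        for k in range(n_epochs):
            t0 = lead + k * (epoch + inter)
            gate[(time >= t0) & (time < t0 + epoch)] = True
            v[(time >= t0 + 50.0) & (time < t0 + 150.0)] = hold + 100.0
            onsets.append(t0 + 50.0)
        return ProtocolSpec(kind, time, v, gate, rate or 100.0,
                            event_times=np.array(onsets),
                            power_density=power or 0.88, holding_mv=hold, params=p)

    if kind == "protocol3":
        hold = p.pop("holding_mv", -75.0)
        time = timebase(500.0)
        v = np.full_like(time, hold)
        onsets = 30.0 + 50.0 * np.arange(10)
        for onset in onsets:
            v[(time >= onset) & (time < onset + 3.0)] = hold + 100.0
        gate = np.ones_like(time, dtype=bool)
        return ProtocolSpec(kind, time, v, gate, rate or 1000.0,
                            event_times=onsets, power_density=power or 1.33,
                            holding_mv=hold, params=p)

    if kind == "ap_train":
        hold = p.pop("holding_mv", -75.0)
        train_hz = p.pop("rate_hz", 25.0)
        n_ap = p.pop("n_ap", 10)
        amplitude = p.pop("ap_amplitude_mv", 100.0)
        lead = p.pop("lead_ms", 100.0)
        isi = 1e3 / train_hz
        duration = lead + (n_ap - 1) * isi + 100.0
        time = timebase(duration)
        onsets = lead + isi * np.arange(n_ap)
        v = np.full_like(time, hold)
        for onset in onsets:
            v += _ap_waveform(time, onset, amplitude)
        gate = np.ones_like(time, dtype=bool)
        return ProtocolSpec(kind, time, v, gate, rate or 1000.0,
                            event_times=onsets, power_density=power or 1.11,
                            holding_mv=hold, params=p)

    if kind == "subthreshold":
        hold = p.pop("holding_mv", -75.0)
        amplitude = p.pop("amplitude_mv", 1.0)
        n_trials = p.pop("n_trials", 50)
        step_ms = p.pop("step_ms", 20.0)
        inter_ms = p.pop("inter_ms", 30.0)
        strobe_ms = p.pop("strobe_ms", 40.0)
        period = step_ms + inter_ms
        time = timebase(n_trials * period)
        v = np.full_like(time, hold)
        gate = np.zeros_like(time, dtype=bool)
        onsets = []
        for k in range(n_trials):
            t0 = k * period + inter_ms / 2.0
            v[(time >= t0) & (time < t0 + step_ms)] = hold + amplitude
            g0 = t0 + step_ms / 2.0 - strobe_ms / 2.0
            gate[(time >= g0) & (time < g0 + strobe_ms)] = True
            onsets.append(t0)
        return ProtocolSpec(kind, time, v, gate, rate or 1000.0,
                            event_times=np.array(onsets),
                            power_density=power or 1.33, holding_mv=hold, params=p)

    if kind == "all_optical":
        # imaging + photostimulation with a single beam: strobed stimulation
        # pulses ride on continuous imaging illumination; evoked spikes are
        # drawn separately by simulate_actuation and inserted by the caller
        hold = p.pop("holding_mv", -75.0)
        n_pulses = p.pop("n_pulses", 5)
        pulse_hz = p.pop("pulse_hz", 5.0)
        pulse_ms = p.pop("pulse_ms", 15.0)
        period_ms = 1e3 / pulse_hz
        duration = n_pulses * period_ms
        time = timebase(duration)
        onsets = 0.5 * period_ms + period_ms * np.arange(n_pulses)
        v = np.full_like(time, hold)
        ap_times = np.asarray(p.pop("ap_times_ms", ()), dtype=float)
        for t_ap in ap_times:
            v += _ap_waveform(time, t_ap)
        gate = np.ones_like(time, dtype=bool)
        return ProtocolSpec(kind, time, v, gate, rate or 1000.0,
                            event_times=ap_times, stim_onsets=onsets,
                            power_density=power or 0.04, holding_mv=hold,
                            params={"pulse_ms": pulse_ms, **p})

    if kind == "spontaneous":
        hold = p.pop("holding_mv", -75.0)
        duration = p.pop("duration_ms", 30000.0)
        theta_ms = p.pop("ou_tau_ms", 100.0)
        sigma = p.pop("ou_sigma_mv", 2.0)
        ap_rate = p.pop("ap_rate_hz", 2.0)
        rng = np.random.default_rng(seed)
        time = timebase(duration)
        # Ornstein-Uhlenbeck sub-threshold drive
        n = time.size
        x = np.zeros(n)
        a = math.exp(-DT_MS / theta_ms)
        scale = sigma * math.sqrt(1.0 - a * a)
        noise = rng.normal(size=n)
        for i in range(1, n):
            x[i] = a * x[i - 1] + scale * noise[i]
        v = hold + x
        n_ap = rng.poisson(ap_rate * duration / 1e3)
        onsets = np.sort(rng.uniform(5.0, duration - 10.0, size=n_ap))
        for onset in onsets:
            v += _ap_waveform(time, onset)
        gate = np.ones_like(time, dtype=bool)
        return ProtocolSpec(kind, time, v, gate, rate or 1000.0,
                            event_times=onsets, power_density=power or 1.33,
                            holding_mv=hold, params=p)

    raise ValueError(f"unknown protocol kind: {kind!r}")


# ---------------------------------------------------------------------------
# sensor transduction
# ---------------------------------------------------------------------------

def voltage_to_dff(
    voltage: np.ndarray,
    sensor: SensorModel | None = None,
    dt_ms: float = DT_MS,
    v_rest: float | None = None,
) -> np.ndarray:
    """Fluorescence response dF/F(t) to a membrane-voltage time series.

    The steady-state response is sensitivity x (V - V_rest)/100 (linear
    over the physiological range); the indicator relaxes toward it with
    tau_on while activating (growing |dF/F|) and tau_off while
    deactivating.  Depolarizations are negative-going.
    """
    sensor = sensor or SensorModel()
    voltage = np.asarray(voltage, dtype=float)
    if v_rest is None:
        v_rest = float(voltage[0])
    target = sensor.sensitivity * (voltage - v_rest) / 100.0

    k_on = 1.0 - math.exp(-dt_ms / sensor.tau_on)
    k_off = 1.0 - math.exp(-dt_ms / sensor.tau_off)
    out = np.empty_like(target)
    s = target[0]
    out[0] = s
    for i in range(1, target.size):
        k = k_on if abs(target[i]) > abs(s) else k_off
        s += k * (target[i] - s)
        out[i] = s
    return out


def _bleach_series(
    gate: np.ndarray, sensor: SensorModel, power_density: float, dt_ms: float
) -> np.ndarray:
    """Bleach factor on the protocol time base.

    Bi-exponential in cumulative illuminated time, both rates scaling with
    power density; the fast component's deficit recovers by
    recovery_fraction x (1 - exp(-dark/recovery_tau)) across each dark
    interval, while the slow component is irreversible.
    """
    scale = power_density / sensor.reference_power_density
    tau_f = sensor.bleach_fast_tau * 1e3 / max(scale, 1e-12)  # ms
    tau_s = sensor.bleach_slow_tau * 1e3 / max(scale, 1e-12)
    a_f = sensor.bleach_fast_amp

    b = np.ones(gate.size)
    r_epoch = 1.0  # fast-component scale at the current epoch start
    t_epoch = 0.0  # illuminated time within the current epoch
    t_cum = 0.0  # cumulative illuminated time
    dark = 0.0
    for i in range(gate.size):
        if gate[i]:
            if dark > 0.0:  # dark interval just ended: apply recovery
                rho = sensor.recovery_fraction * (
                    1.0 - math.exp(-dark / (sensor.recovery_tau * 1e3))
                )
                deficit = r_epoch * a_f * (1.0 - math.exp(-t_epoch / tau_f))
                r_epoch -= deficit * (1.0 - rho)
                t_epoch = 0.0
                dark = 0.0
            t_epoch += dt_ms
            t_cum += dt_ms
            fast = a_f * math.exp(-t_epoch / tau_f) + (1.0 - a_f)
            b[i] = r_epoch * fast * math.exp(-t_cum / tau_s)
        else:
            dark += dt_ms
            b[i] = b[i - 1] if i else 1.0
    return b


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def membrane_mask(cell: CellSpec, acq: AcquisitionSpec) -> np.ndarray:
    """Boolean membrane-annulus mask of a cell on the camera grid."""
    ys = (np.arange(acq.n_rows) - (acq.n_rows - 1) / 2.0) * acq.pixel_size
    xs = (np.arange(acq.n_cols) - (acq.n_cols - 1) / 2.0) * acq.pixel_size
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    r = np.hypot(xx - cell.centroid_xy[0], yy - cell.centroid_xy[1])
    half = cell.membrane_thickness / 2.0
    return np.abs(r - cell.radius) <= half


def heterogeneous_responsivity(
    cell: CellSpec, acq: AcquisitionSpec, sd: float = 0.3, seed: int = 0
) -> np.ndarray:
    """Full-frame responsivity multiplier with per-membrane-pixel
    heterogeneity (lognormal, mean 1), emulating the variable voltage
    response of different membrane locations."""
    mask = membrane_mask(cell, acq)
    rng = np.random.default_rng(seed)
    out = np.ones(mask.shape)
    sigma = math.sqrt(math.log(1.0 + sd**2))
    out[mask] = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=int(mask.sum()))
    return out


def _excitation_profile(
    excitation, cell: CellSpec, acq: AcquisitionSpec
) -> np.ndarray:
    """Two-photon excitation profile on the camera grid, peak-normalized.

    ``excitation`` may be None (uniform), a scalar (uniform scale), or an
    ExcitationMap resampled onto the camera grid centred on the cell.
    """
    if excitation is None:
        return np.ones((acq.n_rows, acq.n_cols))
    if np.isscalar(excitation):
        return np.full((acq.n_rows, acq.n_cols), float(excitation))
    tp = excitation.intensity**2
    if tp.ndim == 3:
        tp = tp[tp.shape[0] // 2]
    tp = tp / tp.max()
    src_n = tp.shape
    ys = (np.arange(acq.n_rows) - (acq.n_rows - 1) / 2.0) * acq.pixel_size
    xs = (np.arange(acq.n_cols) - (acq.n_cols - 1) / 2.0) * acq.pixel_size
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    rr = np.clip(
        np.round(yy / excitation.pixel_size + (src_n[0] - 1) / 2.0).astype(int),
        0, src_n[0] - 1,
    )
    cc = np.clip(
        np.round(xx / excitation.pixel_size + (src_n[1] - 1) / 2.0).astype(int),
        0, src_n[1] - 1,
    )
    return tp[rr, cc]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_movie(
    cells: list[CellSpec] | CellSpec,
    excitation,
    protocol: ProtocolSpec,
    acq: AcquisitionSpec | None = None,
    sensor: SensorModel | None = None,
    seed: int = 0,
    background_rate: float = 0.2,
) -> tuple[Movie, GroundTruth]:
    """Render a camera movie of one or more cells under a protocol.

    Per frame the photon expectation of each membrane pixel is
    expression x two-photon profile x (1 + responsivity x dF/F(t)) x
    bleach(t), integrated over the illuminated part of the exposure;
    photons are Poisson, then camera gain, offset and Gaussian read noise
    are applied.  Bleaching only advances while the illumination gate is
    on and partially recovers across dark intervals.

    Returns the movie and frame-aligned ground truth.  Identical seeds
    give bit-identical output.
    """
    if isinstance(cells, CellSpec):
        cells = [cells]
    acq = acq or AcquisitionSpec.from_rate(protocol.acquisition_rate)
    sensor = sensor or SensorModel()
    rng = np.random.default_rng(seed)

    time = protocol.time
    dt = float(time[1] - time[0])
    gate = protocol.illumination_gate.astype(float)
    dff_fine = voltage_to_dff(
        protocol.voltage_command, sensor, dt_ms=dt, v_rest=protocol.holding_mv
    )
    bleach_fine = _bleach_series(
        protocol.illumination_gate, sensor, protocol.power_density, dt
    )

    period = acq.frame_period
    n_frames = int(math.floor(protocol.duration_ms / period))
    frame_times = np.arange(n_frames) * period

    # frame integrals of gate*bleach and gate*bleach*dff over each exposure
    cs_g = np.concatenate([[0.0], np.cumsum(gate * bleach_fine) * dt])
    cs_gd = np.concatenate([[0.0], np.cumsum(gate * bleach_fine * dff_fine) * dt])
    cs_v = np.concatenate([[0.0], np.cumsum(protocol.voltage_command) * dt])
    i0 = np.clip(np.round(frame_times / dt).astype(int), 0, time.size)
    i1 = np.clip(np.round((frame_times + acq.exposure) / dt).astype(int), 0, time.size)
    g0 = cs_g[i1] - cs_g[i0]  # ms of illuminated-and-bleached exposure
    g1 = cs_gd[i1] - cs_gd[i0]
    v_frame = (cs_v[i1] - cs_v[i0]) / np.maximum((i1 - i0) * dt, dt)
    illum_frac = np.array([
        gate[a:b].mean() if b > a else 0.0 for a, b in zip(i0, i1)
    ])
    cs_b = np.concatenate([[0.0], np.cumsum(bleach_fine) * dt])
    bleach_frame = (cs_b[i1] - cs_b[i0]) / np.maximum((i1 - i0) * dt, dt)

    frames = np.zeros((n_frames, acq.n_rows, acq.n_cols), dtype=np.float32)

    masks, truth_dff, truth_v = [], [], []
    max_count = 2**acq.bit_depth - 1
    for cell in cells:
        mask = membrane_mask(cell, acq)
        if not mask.any():
            raise ValueError(f"cell at {cell.centroid_xy} has no pixels in frame")
        masks.append(mask)
        profile = _excitation_profile(excitation, cell, acq)[mask]
        resp = (
            cell.responsivity_map[mask]
            if cell.responsivity_map is not None
            else np.ones(profile.size)
        )
        # expectation (photons) = expr * prof * (g0 + resp * g1)
        lam = cell.expression * profile[:, None] * (
            g0[None, :] + resp[:, None] * g1[None, :]
        )
        lam = np.maximum(lam, 0.0)
        counts = rng.poisson(lam).astype(float)
        rr, cc = np.nonzero(mask)
        frames[:, rr, cc] += counts.T

        w = profile * resp
        denom = profile.sum()
        truth_dff.append(
            np.divide(g1 * w.sum() / denom, g0, out=np.zeros_like(g0), where=g0 > 0)
        )
        truth_v.append(v_frame.copy())

    # uniform background fluorescence (scales with illuminated exposure)
    if background_rate > 0:
        lam_bg = background_rate * np.maximum(g0, 0.0)
        frames += rng.poisson(
            np.broadcast_to(lam_bg[:, None, None], frames.shape)
        ).astype(np.float32)

    frames *= acq.gain
    frames += acq.offset
    noise = rng.standard_normal(size=frames.shape, dtype=np.float32)
    noise *= acq.read_noise
    frames += noise
    del noise
    if frames.max() > max_count:
        warnings.warn(
            f"photon expectation exceeds the {acq.bit_depth}-bit range; clipping",
            stacklevel=2,
        )
    np.clip(frames, 0, max_count, out=frames)
    np.rint(frames, out=frames)
    data = frames.astype(np.uint16)

    movie = Movie(
        data=data, acq=acq, frame_times=frame_times,
        meta={
            "protocol": protocol.kind,
            "seed": seed,
            "power_density": protocol.power_density,
            "acquisition_rate": protocol.acquisition_rate,
        },
    )
    truth = GroundTruth(
        frame_times=frame_times,
        voltage=np.asarray(truth_v),
        dff=np.asarray(truth_dff),
        event_times=[np.asarray(protocol.event_times, dtype=float)] * len(cells),
        bleach=bleach_frame,
        illumination=illum_frac,
        membrane_masks=masks,
    )
    return movie, truth


# ---------------------------------------------------------------------------
# optogenetic actuation
# ---------------------------------------------------------------------------

def simulate_actuation(
    cells,
    actuator: ActuatorModel | None = None,
    stim_onsets: np.ndarray | None = None,
    power_density: float = 0.02,
    seed: int = 0,
) -> list[np.ndarray]:
    """Draw light-evoked spike times for each cell.

    Per pulse, an action potential occurs Bernoulli with probability
    probability_curve(power) x desensitization state; each delivered pulse
    decrements the state multiplicatively and it recovers exponentially
    between pulses.  Spike time = onset + latency_mean + N(0, jitter).
    """
    actuator = actuator or ActuatorModel()
    if stim_onsets is None or len(stim_onsets) == 0:
        raise ValueError("stim_onsets must contain at least one pulse")
    stim_onsets = np.asarray(stim_onsets, dtype=float)
    if isinstance(cells, (int, np.integer)):
        n_cells = int(cells)
    else:
        cells = [cells] if isinstance(cells, CellSpec) else list(cells)
        n_cells = len(cells)

    rng = np.random.default_rng(seed)
    p_base = actuator.probability(power_density)
    events = []
    for _ in range(n_cells):
        desens = 1.0
        last_t = None
        times = []
        for onset in stim_onsets:
            if last_t is not None:
                gap = onset - last_t
                desens = 1.0 - (1.0 - desens) * math.exp(
                    -gap / actuator.desensitization_recovery_tau
                )
            if rng.random() < p_base * desens:
                t_ap = onset + actuator.latency_mean + rng.normal(
                    0.0, actuator.latency_jitter_sd
                )
                times.append(t_ap)
            desens *= 1.0 - actuator.desensitization
            last_t = onset
        events.append(np.asarray(times))
    return events
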