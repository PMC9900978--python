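"""Sculpted-light synthesis and focal-volume two-photon excitation.

Models the three scanless excitation modalities used for parallel
two-photon voltage imaging and photostimulation:

* **GPC** (generalized phase contrast): a binary pi-phase disk displayed on
  a spatial light modulator (SLM) is converted into a quasi-flat-top
  intensity spot by a pi-shifting phase-contrast filter (PCF) in the Fourier
  plane.
* **Low-NA Gaussian**: an expanded Gaussian beam cropped to the target
  diameter (the power outside the crop is discarded, which is what makes
  this modality power-hungry).
* **CGH** (computer-generated holography): a phase-only hologram computed
  with the iterative Gerchberg-Saxton (GS) algorithm, or its weighted
  variant for multi-spot equalization.  CGH spots carry fully developed
  speckle whose high photon density boosts two-photon excitation.

Temporal focusing is modelled by discretizing the femtosecond pulse
spectrum, shearing each spectral component at the grating-conjugate plane
according to the grating dispersion, and summing component intensities
incoherently at every defocus plane.

Coordinates: sample-plane micrometres, origin on the optical axis, z = 0 at
the objective focus.  Arrays are row-major with pixel (0, 0) top-left.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.fft import fft2, fftfreq, fftshift, ifft2, ifftshift
from scipy.ndimage import binary_erosion, gaussian_filter

__all__ = [
    "SLMGeometry",
    "OpticalTrain",
    "PhaseMask",
    "SpotSpec",
    "ExcitationMap",
    "BeamMetrics",
    "make_gpc_mask",
    "gpc_synthesize",
    "gaussian_flattop_spot",
    "gs_hologram",
    "weighted_gs_multiplex",
    "reconstruct_hologram",
    "propagate_stack",
    "two_photon_map",
    "beam_metrics",
    "power_per_cell",
    "profile_fwhm",
    "speckle_field",
]

SPEED_OF_LIGHT_UM_PER_S = 2.99792458e14  # um/s


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SLMGeometry:
    """Pixel grid of a liquid-crystal-on-silicon SLM.

    Defaults correspond to a Hamamatsu LCOS panel of 600 x 800 pixels with
    20 um pitch addressed at 940 nm.
    """

    n_rows: int = 600
    n_cols: int = 800
    pitch: float = 20.0  # um
    wavelength: float = 940.0  # nm
    aperture_radius: float | None = None  # um; None -> inscribed circle

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("SLM pixel counts must be positive")
        if self.pitch <= 0:
            raise ValueError("SLM pitch must be positive")
        if self.aperture_radius is None:
            object.__setattr__(
                self, "aperture_radius",
                0.5 * min(self.n_rows, self.n_cols) * self.pitch,
            )

    @property
    def wavelength_um(self) -> float:
        return self.wavelength * 1e-3

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates (um), origin at the panel centre."""
        y = (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * self.pitch
        x = (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * self.pitch
        return np.meshgrid(y, x, indexing="ij")


@dataclass(frozen=True)
class OpticalTrain:
    """Lens train relaying the SLM to the sample plane.

    ``focal_lengths`` holds, in order, the Fourier lens after the SLM, the
    recombining lens, the grating collimator and the two relay lenses
    (mm); defaults are the path-1 values (400, 300, 500, 500, 300) with a
    40x/0.8 NA objective of 5 mm focal length and a 600 lines/mm grating.
    ``spectral_samples = 1`` disables temporal focusing.
    """

    focal_lengths: tuple[float, ...] = (400.0, 300.0, 500.0, 500.0, 300.0)
    objective_focal: float = 5.0  # mm
    objective_na: float = 0.8
    grating_density: float = 600.0  # lines/mm
    pulse_duration: float = 100.0  # fs
    spectral_samples: int = 1

    def __post_init__(self):
        if not (0.0 < self.objective_na <= 1.0):
            raise ValueError("objective NA must be in (0, 1]")
        if self.grating_density <= 0:
            raise ValueError("grating density must be positive")
        if self.spectral_samples < 1:
            raise ValueError("spectral_samples must be >= 1")

    @property
    def demagnification(self) -> float:
        """Lateral demagnification from the SLM plane to the sample plane.

        For the lens train (f3, f4, f5, f6, f7) and objective f_obj the
        image-plane chain gives M = (f3/f4) * f5 * (f7/f6) / f_obj.
        """
        f3, f4, f5, f6, f7 = self.focal_lengths
        return (f3 / f4) * f5 * (f7 / f6) / self.objective_focal

    def spectral_components(self, wavelength_um: float):
        """Wavelength offsets (um) and intensity weights of the discretized
        pulse spectrum.

        A transform-limited Gaussian pulse of duration ``pulse_duration``
        has spectral FWHM 0.441/tau; the spectrum is sampled uniformly over
        +/- 1.5 FWHM with Gaussian weights.
        """
        n = self.spectral_samples
        if n == 1:
            return np.array([0.0]), np.array([1.0])
        dnu_fwhm = 0.441 / (self.pulse_duration * 1e-15)  # Hz
        dlam_fwhm = wavelength_um**2 * dnu_fwhm / SPEED_OF_LIGHT_UM_PER_S
        offsets = np.linspace(-1.5 * dlam_fwhm, 1.5 * dlam_fwhm, n)
        sigma = dlam_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        weights = np.exp(-0.5 * (offsets / sigma) ** 2)
        return offsets, weights / weights.sum()

    def sample_angular_dispersion(self, magnification: float) -> float:
        """d(theta)/d(lambda) at the sample (rad/um of wavelength).

        First-order diffraction around normal exit: dtheta/dlambda = 1/d at
        the grating, magnified by the lateral demagnification of the
        image-plane relay between grating and sample.
        """
        groove_um = 1e3 / self.grating_density  # um per line
        return magnification / groove_um


@dataclass
class PhaseMask:
    """Phase-only SLM pattern, radians wrapped to [0, 2pi)."""

    phase: np.ndarray
    geometry: SLMGeometry

    def __post_init__(self):
        self.phase = np.mod(np.asarray(self.phase, dtype=float), 2.0 * np.pi)
        if self.phase.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise ValueError(
                f"phase shape {self.phase.shape} does not match geometry "
                f"({self.geometry.n_rows}, {self.geometry.n_cols})"
            )


@dataclass(frozen=True)
class SpotSpec:
    """A target excitation spot in sample-plane coordinates."""

    center_xyz: tuple[float, float, float] = (0.0, 0.0, 0.0)
    diameter: float = 12.0  # um
    weight: float = 1.0

    def __post_init__(self):
        if self.diameter < 0:
            raise ValueError("spot diameter must be >= 0")
        if self.weight <= 0:
            raise ValueError("spot weight must be positive")


@dataclass
class ExcitationMap:
    """2D or 3D excitation intensity sampled at the sample plane."""

    intensity: np.ndarray
    pixel_size: float  # um
    z_step: float = 0.0  # um, 3D stacks only
    z_values: np.ndarray | None = None

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")

    @property
    def two_photon(self) -> np.ndarray:
        """Elementwise square of the intensity, peak-normalized."""
        sq = self.intensity**2
        peak = sq.max()
        return sq / peak if peak > 0 else sq


@dataclass
class BeamMetrics:
    lateral_fwhm: float = np.nan  # um
    axial_fwhm: float = np.nan  # um, plane-integrated two-photon signal
    axial_fwhm_onaxis: float = np.nan  # um, on-axis two-photon intensity
    speckle_enhancement: float = np.nan  # <I^2>/<I>^2 over the spot support
    throughput: float = np.nan  # fraction of input power in the spot


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _grid_coords(n: int, dx: float) -> np.ndarray:
    """Pixel-centre coordinates of an n-point grid centred on the axis."""
    return (np.arange(n) - (n - 1) / 2.0) * dx


def profile_fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum of a 1D profile.

    Half-maximum crossings are located by linear interpolation on either
    side of the global maximum.  Raises if the profile does not drop below
    half maximum on both sides of the peak.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    i_max = int(np.argmax(y))
    half = y[i_max] / 2.0

    left = np.nonzero(y[: i_max + 1] < half)[0]
    right = np.nonzero(y[i_max:] < half)[0]
    if left.size == 0 or right.size == 0:
        raise ValueError("profile does not drop below half maximum within the grid")

    i = left[-1]  # last sub-half sample left of the peak
    xl = np.interp(half, [y[i], y[i + 1]], [x[i], x[i + 1]])
    j = i_max + right[0]  # first sub-half sample right of the peak
    xr = np.interp(half, [y[j], y[j - 1]], [x[j], x[j - 1]])
    return float(xr - xl)


def _centroid(img: np.ndarray) -> tuple[float, float]:
    total = img.sum()
    if total <= 0:
        raise ValueError("cannot locate centroid of an all-zero image")
    r = np.arange(img.shape[0])
    c = np.arange(img.shape[1])
    return (
        float((img.sum(axis=1) * r).sum() / total),
        float((img.sum(axis=0) * c).sum() / total),
    )


# ---------------------------------------------------------------------------
# GPC
# ---------------------------------------------------------------------------

def make_gpc_mask(
    disk: SpotSpec,
    geom: SLMGeometry | None = None,
    train: OpticalTrain | None = None,
) -> PhaseMask:
    """Binary pi-phase disk for generalized phase contrast.

    The requested sample-plane disk is mapped back through the relay
    magnifications onto the SLM; pixels inside the mapped disk get a pi
    phase shift, all others zero.
    """
    geom = geom or SLMGeometry()
    train = train or OpticalTrain()
    mag = train.demagnification

    radius_slm = 0.5 * disk.diameter * mag
    if radius_slm > geom.aperture_radius:
        raise ValueError(
            f"mapped disk radius {radius_slm:.1f} um exceeds the SLM aperture "
            f"radius {geom.aperture_radius:.1f} um"
        )

    yy, xx = geom.pixel_coords()
    cx = disk.center_xyz[0] * mag
    cy = disk.center_xyz[1] * mag
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_slm**2
    phase = np.where(inside, np.pi, 0.0)
    return PhaseMask(phase=phase, geometry=geom)


def matched_input_waist(
    pcf_radius: float = 60.0,
    geom: SLMGeometry | None = None,
    train: OpticalTrain | None = None,
) -> float:
    """SLM-plane 1/e^2 field waist (um) matched to the PCF radius.

    The PCF must cover the focal spot of the unmodulated beam: the Fourier
    lens f3 focuses a Gaussian of waist w to lambda*f3/(pi*w), so the
    matched condition is w = lambda*f3/(pi*r_pcf).
    """
    geom = geom or SLMGeometry()
    train = train or OpticalTrain()
    f3_um = train.focal_lengths[0] * 1e3
    return geom.wavelength_um * f3_um / (np.pi * pcf_radius)


def gpc_synthesize(
    mask: PhaseMask,
    pcf_radius: float = 60.0,
    input_waist: float | None = None,
    train: OpticalTrain | None = None,
    n_grid: int = 4096,
    pixel_size: float = 0.1625,
) -> tuple[ExcitationMap, BeamMetrics]:
    """Focal-plane intensity of the GPC interferometer.

    The SLM field (Gaussian illumination times the phase mask) is Fourier
    transformed; spatial frequencies inside the PCF radius are phase
    shifted by pi; the inverse transform gives the output image.  The
    computation runs on a sample-referred grid of ``n_grid`` pixels at
    ``pixel_size`` um so the output is directly comparable with camera
    data.

    Returns the focal intensity map and metrics with ``throughput`` set to
    the fraction of input power landing inside the nominal disk.
    """
    train = train or OpticalTrain()
    geom = mask.geometry
    mag = train.demagnification
    lam = geom.wavelength_um
    f3_um = train.focal_lengths[0] * 1e3

    if pcf_radius <= 0:
        raise ValueError("pcf_radius must be positive")
    if input_waist is None:
        input_waist = matched_input_waist(pcf_radius, geom, train)

    # sample-referred grid; the SLM plane maps onto it through 1/mag
    coords = _grid_coords(n_grid, pixel_size)
    xx, yy = np.meshgrid(coords, coords)

    # resample the SLM mask (nearest neighbour; SLM pixels are far larger
    # than the sample-referred grid step)
    row = np.round(yy * mag / geom.pitch + (geom.n_rows - 1) / 2.0).astype(int)
    col = np.round(xx * mag / geom.pitch + (geom.n_cols - 1) / 2.0).astype(int)
    on_panel = (
        (row >= 0) & (row < geom.n_rows) & (col >= 0) & (col < geom.n_cols)
    )
    phase = np.zeros_like(xx)
    phase[on_panel] = mask.phase[row[on_panel], col[on_panel]]

    w_sample = input_waist / mag
    amplitude = np.exp(-(xx**2 + yy**2) / w_sample**2) * on_panel
    field = amplitude * np.exp(1j * phase)

    # Fourier plane of f3; PCF cutoff as a sample-referred spatial frequency
    nu = fftfreq(n_grid, d=pixel_size)
    nu_xx, nu_yy = np.meshgrid(nu, nu)
    nu_cut = pcf_radius * mag / (lam * f3_um)
    if nu_cut > np.abs(nu).max():
        raise ValueError(
            f"PCF radius {pcf_radius} um maps to {nu_cut:.3g} cycles/um, beyond "
            f"the frequency-grid extent {np.abs(nu).max():.3g} cycles/um"
        )
    spectrum = fft2(field)
    low = nu_xx**2 + nu_yy**2 <= nu_cut**2
    spectrum[low] *= -1.0  # pi shift
    out = ifft2(spectrum)

    intensity = np.abs(out) ** 2
    energy_in = float((amplitude**2).sum())

    # fraction of input power delivered inside the nominal disk
    radius_slm_px = np.count_nonzero(mask.phase > np.pi / 2)
    if radius_slm_px:
        disk_radius = math.sqrt(radius_slm_px / math.pi) * geom.pitch / mag
        in_disk = xx**2 + yy**2 <= disk_radius**2
        throughput = float(intensity[in_disk].sum() / energy_in)
    else:
        throughput = 0.0

    emap = ExcitationMap(intensity=intensity, pixel_size=pixel_size)
    metrics = BeamMetrics(throughput=throughput)
    return emap, metrics


def gaussian_flattop_spot(
    target_diameter: float,
    uniformity: float,
    n_grid: int = 512,
    pixel_size: float = 0.1625,
) -> tuple[ExcitationMap, float]:
    """Expanded-and-cropped Gaussian spot.

    The Gaussian waist is chosen so that the intensity at the crop edge is
    ``uniformity`` times the peak; everything outside the crop is discarded.
    Returns the cropped intensity map and the throughput, i.e. the fraction
    of the expanded beam's power inside the crop (1 - uniformity).
    """
    if not (0.0 < uniformity < 1.0):
        raise ValueError("uniformity must be in (0, 1)")
    if target_diameter <= 0:
        raise ValueError("target diameter must be positive")

    radius = target_diameter / 2.0
    waist = radius * math.sqrt(2.0 / math.log(1.0 / uniformity))

    coords = _grid_coords(n_grid, pixel_size)
    xx, yy = np.meshgrid(coords, coords)
    rsq = xx**2 + yy**2
    intensity = np.exp(-2.0 * rsq / waist**2)
    intensity[rsq > radius**2] = 0.0

    throughput = 1.0 - uniformity  # closed form of the Gaussian integral
    return ExcitationMap(intensity=intensity, pixel_size=pixel_size), throughput


# ---------------------------------------------------------------------------
# Gerchberg-Saxton holography
# ---------------------------------------------------------------------------

def _default_illumination(shape: tuple[int, int]) -> np.ndarray:
    """Gaussian beam filling the hologram aperture (waist = 1/4 extent)."""
    ny, nx = shape
    y = np.arange(ny) - (ny - 1) / 2.0
    x = np.arange(nx) - (nx - 1) / 2.0
    yy, xx = np.meshgrid(y, x, indexing="ij")
    w = min(ny, nx) / 4.0
    return np.exp(-(xx**2 + yy**2) / w**2)


def reconstruct_hologram(
    mask: PhaseMask, input_amplitude: np.ndarray | None = None
) -> np.ndarray:
    """Focal-plane intensity produced by a phase-only hologram."""
    if input_amplitude is None:
        input_amplitude = _default_illumination(mask.phase.shape)
    field = input_amplitude * np.exp(1j * mask.phase)
    return np.abs(fftshift(fft2(ifftshift(field)))) ** 2


def gs_hologram(
    target: np.ndarray,
    n_iter: int = 50,
    seed: int = 0,
    input_amplitude: np.ndarray | None = None,
    geometry: SLMGeometry | None = None,
    return_history: bool = False,
):
    """Iterative Gerchberg-Saxton phase retrieval.

    ``target`` is the desired focal-plane amplitude on the FFT-conjugate
    grid of the SLM (fftshift-centred).  The focal amplitude is replaced by
    the target inside its support while the computed field is kept outside,
    and the SLM amplitude constraint is re-imposed each round trip.  The
    initial phase is uniform random from ``seed``, so identical seeds give
    bit-identical masks.

    Returns the PhaseMask (and the per-iteration reconstruction error if
    ``return_history``), where the error is 1 - normalized cross-correlation
    between the reconstructed intensity and the target intensity.
    """
    target = np.asarray(target, dtype=float)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if np.all(target <= 0):
        raise ValueError("target amplitude is identically zero")
    if input_amplitude is None:
        input_amplitude = _default_illumination(target.shape)

    support = target > 0
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=target.shape)

    errors = []
    best_err = np.inf
    best_phase = phase
    for _ in range(n_iter):
        field = input_amplitude * np.exp(1j * phase)
        focal = fftshift(fft2(ifftshift(field)))
        amp = np.abs(focal)
        err = _reconstruction_error(amp**2, target**2)
        if err < best_err:  # monitored convergence: keep the best iterate
            best_err, best_phase = err, phase
        errors.append(best_err)
        # amplitude constraint: target (scaled to the focal power) inside
        # the support, computed amplitude kept outside
        scaled = target * math.sqrt(
            float((amp**2).sum()) / float((target**2).sum())
        )
        constrained = np.where(support, scaled, amp)
        focal = constrained * np.exp(1j * np.angle(focal))
        back = fftshift(ifft2(ifftshift(focal)))
        phase = np.angle(back)

    mask = PhaseMask(
        phase=np.mod(best_phase, 2 * np.pi),
        geometry=geometry
        or SLMGeometry(n_rows=target.shape[0], n_cols=target.shape[1]),
    )
    if return_history:
        return mask, np.asarray(errors)
    return mask


def _reconstruction_error(recon: np.ndarray, target_int: np.ndarray) -> float:
    num = float((recon * target_int).sum())
    den = math.sqrt(float((recon**2).sum()) * float((target_int**2).sum()))
    return 1.0 - num / den if den > 0 else 1.0


def weighted_gs_multiplex(
    spots: list[SpotSpec],
    n_iter: int = 50,
    seed: int = 0,
    geometry: SLMGeometry | None = None,
    field_extent: float = 250.0,
    n_grid: int = 512,
    input_amplitude: np.ndarray | None = None,
    return_history: bool = False,
):
    """Weighted Gerchberg-Saxton hologram for multi-spot excitation.

    Places one flat disk per spot on a square addressable field of
    ``field_extent`` um sampled with ``n_grid`` points.  Each iteration the
    per-spot target weights are updated by w <- w * (<A>/A_spot), where
    A_spot is the mean reconstructed amplitude in that spot and <A> the
    mean over spots, which equalizes (or enforces the requested ratio of)
    the spot intensities.
    """
    if not 1 <= len(spots) <= 100:
        raise ValueError("between 1 and 100 spots are supported")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    dx = field_extent / n_grid
    coords = _grid_coords(n_grid, dx)
    xx, yy = np.meshgrid(coords, coords)

    half_field = field_extent / 2.0
    disks = []
    for s in spots:
        cx, cy = s.center_xyz[0], s.center_xyz[1]
        if abs(cx) > half_field or abs(cy) > half_field:
            raise ValueError(f"spot at {s.center_xyz} outside the addressable field")
        disks.append((xx - cx) ** 2 + (yy - cy) ** 2 <= (s.diameter / 2.0) ** 2)
    for i in range(len(spots)):
        for j in range(i + 1, len(spots)):
            d = math.hypot(
                spots[i].center_xyz[0] - spots[j].center_xyz[0],
                spots[i].center_xyz[1] - spots[j].center_xyz[1],
            )
            min_sep = 0.5 * (spots[i].diameter + spots[j].diameter)
            if d < min_sep:
                warnings.warn(
                    f"spots {i} and {j} are {d:.1f} um apart, closer than one "
                    "diameter; their intensities will overlap",
                    stacklevel=2,
                )

    if input_amplitude is None:
        input_amplitude = _default_illumination((n_grid, n_grid))

    requested = np.array([s.weight for s in spots], dtype=float)
    w = np.ones(len(spots))
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=(n_grid, n_grid))

    ideal = np.zeros((n_grid, n_grid))
    for d, rk in zip(disks, requested):
        ideal[d] = rk

    errors = []
    best_err = np.inf
    best_phase = phase
    for _ in range(n_iter):
        field = input_amplitude * np.exp(1j * phase)
        focal = fftshift(fft2(ifftshift(field)))
        amp = np.abs(focal)

        err = _reconstruction_error(amp**2, ideal)
        if err < best_err:
            best_err, best_phase = err, phase
        errors.append(best_err)

        # weight update: boost spots lagging behind their requested share
        achieved = np.array([amp[d].mean() for d in disks])
        rel = achieved / np.sqrt(requested)
        w *= rel.mean() / np.maximum(rel, 1e-12)

        target = np.zeros_like(amp)
        for d, wk, rk in zip(disks, w, requested):
            target[d] = wk * math.sqrt(rk)
        target *= math.sqrt(float((amp**2).sum()) / max((target**2).sum(), 1e-300))

        constrained = np.where(target > 0, target, amp)
        focal = constrained * np.exp(1j * np.angle(focal))
        back = fftshift(ifft2(ifftshift(focal)))
        phase = np.angle(back)

    mask = PhaseMask(
        phase=np.mod(best_phase, 2 * np.pi),
        geometry=geometry or SLMGeometry(n_rows=n_grid, n_cols=n_grid),
    )
    if return_history:
        return mask, np.asarray(errors), (dx, disks, input_amplitude)
    return mask


def speckle_field(
    n_grid: int = 512,
    correlation_px: float = 4.0,
    seed: int = 0,
    envelope: np.ndarray | None = None,
) -> np.ndarray:
    """Fully developed speckle intensity with circular-Gaussian statistics.

    Complex white noise is band-limited to a speckle grain of
    ``correlation_px`` pixels, giving a field whose real and imaginary
    parts are independent zero-mean Gaussians -- the fully developed
    speckle regime, where the intensity is negative-exponential and
    <I^2>/<I>^2 = 2.  Optionally multiplied by an intensity ``envelope``.
    """
    rng = np.random.default_rng(seed)
    white = rng.normal(size=(n_grid, n_grid)) + 1j * rng.normal(size=(n_grid, n_grid))
    nu = fftfreq(n_grid)
    nxx, nyy = np.meshgrid(nu, nu)
    keep = nxx**2 + nyy**2 <= (0.5 / correlation_px) ** 2
    fld = ifft2(fft2(white) * keep)
    intensity = np.abs(fld) ** 2
    if envelope is not None:
        intensity = intensity * envelope
    return intensity


# ---------------------------------------------------------------------------
# propagation and temporal focusing
# ---------------------------------------------------------------------------

def _angular_spectrum(
    field: np.ndarray, dx: float, wavelength_um: float, z: float
) -> np.ndarray:
    """Band-limited angular-spectrum propagation over distance z (um)."""
    ny, nx = field.shape
    nu_x = fftfreq(nx, d=dx)
    nu_y = fftfreq(ny, d=dx)
    nxx, nyy = np.meshgrid(nu_x, nu_y)
    nu_sq = nxx**2 + nyy**2
    k_sq = 1.0 / wavelength_um**2
    arg = np.maximum(k_sq - nu_sq, 0.0)
    h = np.exp(2j * np.pi * z * np.sqrt(arg))
    h[nu_sq >= k_sq] = 0.0  # drop evanescent components
    return ifft2(fft2(field) * h)


def propagate_stack(
    mask: PhaseMask,
    train: OpticalTrain | None = None,
    z_range: np.ndarray | tuple[float, float, float] = (-30.0, 30.0, 1.0),
    input_amplitude: np.ndarray | None = None,
    focal_pixel_size: float | None = None,
    magnification: float | None = None,
) -> ExcitationMap:
    """Through-focus intensity stack of a hologram.

    The mask plane is treated as the pupil conjugate: the focal field is
    its (amplitude-weighted) Fourier transform, and each z plane is reached
    by band-limited angular-spectrum propagation.  With
    ``train.spectral_samples > 1`` the pulse spectrum is discretized and
    each component given the lateral tilt imposed by the grating dispersion
    before propagation; component intensities are summed incoherently,
    which reproduces the axial confinement of temporal focusing without a
    full space-time simulation.

    ``focal_pixel_size`` defaults to the FFT-conjugate sampling
    lambda*f_eff/(N*pitch) of the mask grid.
    """
    train = train or OpticalTrain()
    geom = mask.geometry
    lam = geom.wavelength_um
    if isinstance(z_range, tuple):
        z0, z1, dz = z_range
        z_values = np.arange(z0, z1 + dz / 2.0, dz)
    else:
        z_values = np.asarray(z_range, dtype=float)

    if input_amplitude is None:
        input_amplitude = _default_illumination(mask.phase.shape)
    field_slm = input_amplitude * np.exp(1j * mask.phase)
    n = mask.phase.shape[0]
    if mask.phase.shape[0] != mask.phase.shape[1]:
        side = max(mask.phase.shape)
        padded = np.zeros((side, side), dtype=complex)
        r0 = (side - mask.phase.shape[0]) // 2
        c0 = (side - mask.phase.shape[1]) // 2
        padded[r0 : r0 + mask.phase.shape[0], c0 : c0 + mask.phase.shape[1]] = field_slm
        field_slm = padded
        n = side

    if magnification is None:
        # effective demagnified Fourier focal length of the relay
        magnification = train.demagnification
    if focal_pixel_size is None:
        f_eff_um = train.focal_lengths[0] * 1e3 / magnification
        focal_pixel_size = lam * f_eff_um / (n * geom.pitch)

    focal0 = fftshift(fft2(ifftshift(field_slm)))

    offsets, weights = train.spectral_components(lam)
    dispersion = train.sample_angular_dispersion(magnification)
    coords = _grid_coords(n, focal_pixel_size)
    xx = coords[np.newaxis, :]  # tilt along the grating dispersion axis (x)

    stack = np.zeros((z_values.size, n, n))
    for dlam, wgt in zip(offsets, weights):
        lam_i = lam + dlam
        tilt_angle = dispersion * dlam
        tilted = focal0 * np.exp(2j * np.pi * math.sin(tilt_angle) * xx / lam_i)
        pupil = fft2(tilted)
        nu_x = fftfreq(n, d=focal_pixel_size)
        nxx, nyy = np.meshgrid(nu_x, nu_x)
        nu_sq = nxx**2 + nyy**2
        k_sq = 1.0 / lam_i**2
        arg = np.maximum(k_sq - nu_sq, 0.0)
        prop_ok = nu_sq < k_sq
        root = np.sqrt(arg)
        for iz, z in enumerate(z_values):
            h = np.where(prop_ok, np.exp(2j * np.pi * z * root), 0.0)
            stack[iz] += wgt * np.abs(ifft2(pupil * h)) ** 2

    dz_arr = np.diff(z_values)
    z_step = float(dz_arr[0]) if dz_arr.size else 0.0
    emap = ExcitationMap(
        intensity=stack, pixel_size=focal_pixel_size, z_step=z_step, z_values=z_values
    )

    axial = (stack**2).sum(axis=(1, 2))
    try:
        ax_fwhm = profile_fwhm(z_values, axial)
        if z_step > ax_fwhm / 4.0:
            warnings.warn(
                f"z step {z_step:.2f} um is coarser than a quarter of the axial "
                f"FWHM {ax_fwhm:.2f} um; the axial profile is undersampled",
                stacklevel=2,
            )
    except ValueError:
        pass
    return emap


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def two_photon_map(
    stack: ExcitationMap, support: np.ndarray | None = None
) -> tuple[ExcitationMap, BeamMetrics]:
    """Two-photon excitation map and speckle statistics.

    The two-photon signal is the elementwise square of the intensity.  The
    speckle enhancement <I^2>/<I>^2 is evaluated over the spot support: by
    default the region where the smoothed intensity envelope exceeds 10 %
    of its peak, eroded by the smoothing radius so dim edge pixels do not
    dilute the statistics.  It equals 1 for a uniform spot and 2 for fully
    developed speckle.
    """
    intensity = stack.intensity
    plane = intensity if intensity.ndim == 2 else intensity[intensity.shape[0] // 2]

    if support is None:
        sigma = max(2.0 / stack.pixel_size, 1.0)  # ~2 um envelope smoothing
        envelope = gaussian_filter(plane, sigma)
        support = envelope > 0.1 * envelope.max()
        # the smoothed envelope leaks ~2 sigma beyond the true spot edge;
        # erode past it so dim edge pixels do not dilute the statistics
        it = max(int(3 * sigma) + 1, 1)
        support = binary_erosion(support, iterations=it)
        if not support.any():
            support = envelope > 0.1 * envelope.max()

    vals = plane[support]
    mean = vals.mean()
    enhancement = float((vals**2).mean() / mean**2) if mean > 0 else np.nan

    tp = ExcitationMap(
        intensity=intensity**2,
        pixel_size=stack.pixel_size,
        z_step=stack.z_step,
        z_values=stack.z_values,
    )
    return tp, BeamMetrics(speckle_enhancement=enhancement)


def beam_metrics(stack: ExcitationMap, two_photon: bool = True) -> BeamMetrics:
    """FWHM metrics of an excitation map.

    Lateral FWHM is measured on row/column profiles through the
    intensity-weighted centroid of the (two-photon) focal plane, averaging
    the x and y cuts; crossings are linearly interpolated.  For 3D stacks
    the axial FWHM is measured both on the plane-integrated two-photon
    signal and on the on-axis (centroid pixel) profile, since the two
    estimators differ for structured spots.
    """
    intensity = stack.intensity
    if intensity.ndim == 2:
        plane = intensity
        z_values = None
    else:
        z_values = (
            stack.z_values
            if stack.z_values is not None
            else np.arange(intensity.shape[0]) * stack.z_step
        )
        plane = intensity[int(np.argmax((intensity**2).sum(axis=(1, 2))))]

    signal = plane**2 if two_photon else plane
    r0, c0 = _centroid(signal)
    ir, ic = int(round(r0)), int(round(c0))
    x = _grid_coords(signal.shape[1], stack.pixel_size)
    y = _grid_coords(signal.shape[0], stack.pixel_size)
    fw_x = profile_fwhm(x, signal[ir, :])
    fw_y = profile_fwhm(y, signal[:, ic])
    metrics = BeamMetrics(lateral_fwhm=0.5 * (fw_x + fw_y))

    if z_values is not None:
        cube = intensity**2 if two_photon else intensity
        integrated = cube.sum(axis=(1, 2))
        metrics.axial_fwhm = profile_fwhm(z_values, integrated)
        metrics.axial_fwhm_onaxis = profile_fwhm(z_values, cube[:, ir, ic])
    return metrics


def power_per_cell(
    power_density: float, diameter: float, round_to_mw: float | None = 5.0
) -> float:
    """Average power (mW) delivered to one cell-sized spot.

    power = density (mW/um^2) x disk area, rounded to the nearest 5 mW by
    default, the convention in which per-cell powers are reported alongside
    power densities (e.g. 1.33 mW/um^2 over a 12 um disk -> 150 mW).
    """
    if power_density < 0 or diameter < 0:
        raise ValueError("power density and diameter must be nonnegative")
    power = power_density * math.pi * (diameter / 2.0) ** 2
    if round_to_mw:
        power = round(power / round_to_mw) * round_to_mw
    return float(power)
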