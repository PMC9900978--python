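# Methods

`voltim` simulates and analyses scanless two-photon voltage imaging: a
camera records the fluorescence of a soma-targeted, negative-going
genetically encoded voltage indicator (GEVI, modelled on JEDI-2P-kv)
excited by a sculpted, temporally focused two-photon spot that covers the
whole soma at once.  The package has three layers — an optical model of
the sculpted excitation, a forward model producing synthetic camera
movies with ground truth, and the analysis pipeline (segmentation, trace
extraction, spike detection, figures of merit) that consumes such movies.

## Optical model (`voltim.lightsculpt`)

**Geometry.** All computations use sample-plane micrometres with z = 0 at
the objective focus.  The reference system is a 600 × 800 pixel, 20 µm
pitch SLM at 940 nm, relayed to a 40×/0.8 NA objective (f = 5 mm) by the
lens train (400, 300, 500, 500, 300) mm, giving a lateral demagnification
of 80× on the imaging path (a 12 µm sample-plane disk maps to a 960 µm
disk on the SLM).  The holographic path uses an effective 100×
demagnification.

**GPC.** Generalized phase contrast is modelled as an ideal common-path
interferometer: the field after the π-disk mask is Fourier transformed,
spatial frequencies inside the phase-contrast filter (PCF, 60 µm radius
at the 400 mm Fourier lens) are multiplied by −1, and the inverse
transform gives the focal image.  The input Gaussian waist defaults to
the matched condition w = λf/(π·r_PCF) ≈ 2.0 mm, i.e. the PCF just covers
the focal spot of the unmodulated beam.  The simulated 12 µm spot has a
lateral two-photon FWHM of 12.0 µm and delivers ≈ 0.46 of the input power
into the nominal disk.  Because the model contains no system losses
(grating and SLM efficiency, aberrations), this in-disk throughput is an
upper bound; the efficiency advantage over the expand-and-crop Gaussian
(throughput exactly 1 − uniformity, e.g. 0.1 at 90 % edge uniformity) is
therefore ~4.5× in the ideal model, compared with the ~3× power penalty
observed on real systems.

**CGH.** Phase-only holograms are computed by iterative Gerchberg–Saxton
phase retrieval with a random initial phase: the focal amplitude is
replaced by the (power-rescaled) target inside its support while the
computed field is kept outside, and the SLM amplitude constraint is
re-imposed each round trip.  Convergence is monitored by 1 − normalized
cross-correlation with the target intensity, and the best iterate is
kept, making the reported error non-increasing by construction.  The
weighted variant updates per-spot target weights each iteration by
w ← w·(⟨A⟩/A_spot), which equalizes multi-spot intensities (8-spot
coefficient of variation < 0.01 after 50 iterations) and makes spot
intensity proportional to the requested weight.

**Speckle.** GS spots evaluated on a 4× oversampled continuum retain mild
residual speckle (⟨I²⟩/⟨I⟩² ≈ 1.06–1.11), already enough to beat the
essentially flat GPC spot (1.0002) in integrated two-photon signal at
equal average intensity.  Fully developed speckle — the regime where the
field is circular-Gaussian and ⟨I²⟩/⟨I⟩² = 2 exactly — is modelled by the
separate `speckle_field` generator (band-limited complex white noise).
Speckle statistics over a spot are computed on a support obtained by
smoothing the intensity (~2 µm), thresholding at 10 % of the peak and
eroding past the smoothing tail, so dim edge pixels do not dilute the
moments.

**Temporal focusing.** The femtosecond spectrum (transform-limited
Gaussian, FWHM 0.441/τ with τ = 100 fs → ≈ 13 nm at 940 nm) is sampled
at N equally spaced wavelengths over ±1.5 FWHM with Gaussian weights.
Each component receives the lateral tilt imposed by the 600 lines/mm
grating (dθ/dλ = 1/d, magnified by the relay), is propagated through
focus by band-limited angular-spectrum propagation, and component
intensities are summed incoherently.  This reproduces the axial
confinement of temporal focusing — off focus the spectrally sheared
components separate laterally and the summed intensity (and much more so
its square) collapses — without a full space–time simulation; exact
pulse-front physics is out of scope.  Axial width is reported with two
estimators that genuinely differ for extended spots: the plane-integrated
two-photon signal and the on-axis profile (the measurement a point-like
microsphere approximates).  Only their orderings are asserted: TF
narrower than non-TF, and on-axis narrower than plane-integrated.

## Synthetic movies (`voltim.synthetic_movies`)

**Sensor.** ΔF/F(t) = sensitivity·(V − V_rest)/100 passed through
first-order on/off kinetics; sensitivity defaults to −0.43 per 100 mV
(linear over −90..+25 mV; the real sensitivity curve is not optimized for
sub-threshold voltages and its nonlinearity is unavailable).  The time
constants are free parameters calibrated analytically, before any test
was run, so that a 3 ms/100 mV command integrated by a 1 ms exposure
peaks near −31 %ΔF/F₀ and by a 2 ms exposure near −26 % (pulse onset on a
frame boundary): τ_on = 2.0 ms, τ_off = 1.2 ms.  The resulting 500 Hz/1 kHz
amplitude ratio (0.85) also reproduces the observed ~1.2× per-spike SNR
advantage of 500 Hz sampling once the doubled photon count is accounted
for.

**Photobleaching.** Bi-exponential in cumulative illuminated time,
B(t) = R_k·[a_f·e^(−t/τ_f) + (1 − a_f)]·e^(−t_cum/τ_s), with both rates
scaling linearly with power density (defaults a_f = 0.2, τ_f = 0.2 s,
τ_s = 40 s at 1 mW/µm²).  Across a dark interval of length Δ the fast
deficit recovers by recovery_fraction·(1 − e^(−Δ/τ_rec)) (defaults 0.97
and 0.3 s); the slow component is irreversible.  With these defaults the
protocol-2 consecutive pre-step ratios exceed 0.99, consistent with the
>97 % photorecovery regime; configuring an all-fast, fully equilibrating
bleach makes the cycle stationary and the ratios equal the recovery
fraction exactly, which is what the recovery-recovery test exploits.

**Rendering.** Cells are membrane annuli (radius 6 µm, thickness 1 µm at
0.1625 µm pixels) with optional per-pixel lognormal responsivity
heterogeneity.  Per frame, the photon expectation of a membrane pixel is
expression × two-photon profile × (1 + responsivity·ΔF/F) × bleach,
integrated over the illuminated part of the exposure on a 0.1 ms time
base; photons are Poisson, then gain, offset (100 counts) and Gaussian
read noise (2 counts) are applied and the frame is quantized to 16 bits.
Frame count is ⌊duration/(exposure + readout)⌋ with 0.02 ms readout, so
the nominal 1 kHz (1 ms exposure) runs at an effective 980 Hz.  Identical
seeds give bit-identical movies.

**Protocols.** The characterization protocols are built on the same time
base: three 100 ms/100 mV steps under 3 s continuous light (protocol 1,
100 Hz); the same steps with 200 ms illumination pulses centred on each
step and 2.5 s dark intervals (protocol 2); a 20 Hz train of ten
3 ms/100 mV pulses under 500 ms light at the nominal 1 kHz (protocol 3);
10-AP trains at 25–125 Hz; 20 ms sub-threshold steps of 0–2.5 mV under
40 ms strobes, 50 trials; Ornstein–Uhlenbeck sub-threshold drive plus
Poisson APs for spontaneous activity; and a single-beam photostimulation
train for all-optical scenarios.  The AP waveform is a stylized triangle
(1 ms rise, 2 ms fall, 100 mV) — the real granule-cell waveform is not
modelled and the shape is configurable.  After kinetics and frame
integration its peak is ≈ −17 %ΔF/F₀ at 1 kHz, so train scenarios specify
photon budgets as amplitude/SNR rather than a fixed ΔF/F.

**Actuation.** The channelrhodopsin model draws one Bernoulli spike per
pulse with probability rising linearly to p_max = 0.9 at the saturation
density 0.02 mW/µm², times a desensitization state that drops 15 % per
pulse and recovers with τ = 250 ms (so 5 Hz trains are nearly
desensitization-free while 50 Hz trains lose spikes — a qualitative
match; the magnitude is not constrained by printed data).  Spike time =
onset + 4.3 ms + N(0, 1.0 ms).

## Analysis pipeline (`voltim.trace_extraction`, `voltim.event_detection`)

Segmentation thresholds the offset-corrected mean image (Otsu) with a
morphological clean-up; pixel weights are the per-pixel regression slopes
against the mean trace of that initial mask, negatives clipped to zero
(anti-correlated pixels are background), and the support keeps the top
half of the positively weighted pixels inside the initial mask — chosen
to reproduce the ~2× pixel reduction of the reference pipeline.  Traces
are weighted means over the support; a photon conversion factor
(Σwµ)²/(Σw²µ) is carried so shot-noise SNR can be computed downstream.

Detrending fits a bi-exponential baseline per illumination epoch on
event-masked frames (parameters normalized for conditioning; single
exponential, then a running-percentile filter as fallbacks), or a
per-epoch constant for bleach-free strobed data.  Only fully illuminated
frames belong to an epoch: a frame whose exposure partially overlaps the
gate is dimmed by the overlap fraction, which would corrupt baselines far
beyond shot noise.  F₀ defaults to the baseline at the first epoch's
start (the first-frame convention used for photostability, and the one
that keeps power-response fits free of power-dependent bleaching); the
pre-event mean is available as an option.

Spike detection is prominence-seeded template matching: seeds are peaks
of −ΔF/F with both prominence and height ≥ 4σ (σ robust MAD; height
matters on long traces, where prominence alone admits noise peaks
measured against distant troughs); the template is the mean seed snippet,
its half-width capped at 0.45× the median inter-seed interval so
high-frequency trains do not contaminate it; detections are peaks of the
unnormalized matched-filter output above 4σ of its own noise, gated by a
normalized cross-correlation ≥ 0.7 and by a raw amplitude at least half
the mean seed amplitude (generous for real amplitude heterogeneity,
decisive against multi-frame noise coincidences).  With fewer than three
seeds no template is built and only unambiguous 5σ events are accepted.
Event times are parabolic interpolations of the matched-filter peak, so
timing is sub-frame (~0.07 ms at SNR 14).  Scoring uses greedy one-to-one
matching within ±5 ms (tolerance configurable; the reference tolerance
is unpublished); jitter is the SD of matched time differences, so
constant latencies do not contribute.

## Figures of merit (`voltim.performance_metrics`)

Empirical SNR = |mean response ΔF/F| / SD(baseline ΔF/F); shot-noise
SNR = (−ΔF/F₀)·√F₀ with F₀ in detected photons (gain defaults to
1 count/photon for synthetic data).  Photostability = Σ baseline F /
(F₀·n_t) with F₀ the first frame; photorecovery = mean of consecutive
pre-step fluorescence ratios F_k/F_{k−1} across illumination epochs.
Power-response fits: slope of log F₀ vs log P (2.00 for unsaturated
two-photon excitation) and unconstrained OLS of SNR vs P with the
intercept reported.  The effective resolution curve takes evoked-spike
−%ΔF/F₀ versus spot displacement and returns the interpolated FWHM; on
the matched geometry (12 µm spot over a 12 µm soma, with neighbouring
labelled somata contributing half the on-target fluorescence when the
spot is displaced — a dense-labelling assumption set once) the lateral
FWHM is ≈ 15 µm.

## Problem sizes and statistical limits

The power-sweep scenario uses 5 levels × 10 cells, single-cell 96×96
movies at 1 kHz with ≥10⁶ expected photons per frame in the membrane
mask; the camera rate was set to 1 kHz (within the default rate set)
because at 100 Hz the ~30 baseline frames per movie put a ~13 % χ² floor
on each SD estimate and no photon budget can lower it.  Even at 1 kHz the
~270 baseline frames the protocol permits leave ~1.3 % noise on each
per-level mean SNR, so the expected 1 − r² of the SNR–power fit is ~10⁻³:
the fit is linear to within estimator noise (empirical/shot SNR ratio
1.00 ± 0.03), and r² lands on either side of 0.999 depending on the seed.
The sub-threshold scenario calibrates the photon budget from the target
single-trial SNR of 50 for a 100 mV step (≈ 1.35·10⁴ photons/frame) and
averages 25 of 50 trials; SNR-versus-n curves are averaged over 16
permutations of the (exchangeable) trial order because a single
accumulation path is strongly autocorrelated.  With only ~9 baseline
frames per 40 ms strobe the SD of a 25-trial average is itself a
9-sample estimate, so the √n scaling is asserted on long-baseline trials
at the same calibration, not on the strobed movie.

## What the generator does and does not emulate

It reproduces membrane-annulus geometry, shot-noise-limited counting
statistics, negative-going voltage transduction with finite kinetics,
power-scaled bi-exponential bleaching with dark recovery, strobed
illumination with partial-frame effects, response heterogeneity across
the membrane, and spike-outcome optogenetics.  It does not model tissue
scattering, motion or axial drift, camera rolling-shutter structure,
indicator sensitivity nonlinearity, channelrhodopsin photocurrent
waveforms, or crosstalk between imaging and stimulation light.  Passing
tests therefore validate the pipeline's statistical behaviour in the
photon-limited regime, not its robustness to motion or scattering.

## Known limitations

The GPC model is an ideal interferometer (throughput is an upper bound);
GS speckle depends on iteration count and is weaker than the fully
developed speckle of real holographic spots; the 9 µm axial FWHM of the
real system is not asserted numerically because the printed value does
not specify its estimator (the two implemented estimators bracket it);
and the desensitization and background-labelling parameters are
plausibility choices, not fits to published curves.
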