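"""Synthetic multi-subject fNIRS cohorts for the n-back paradigm.

The forward model is deliberately simple but physiologically shaped:

* each workload class activates a distinct, load-ordered spatial pattern
  over channels (progressively broader frontal recruitment with higher
  n-back load, plus a parietal component at the highest load) — these
  patterns are population-level structure shared by every subject, which
  is exactly what subject-transfer can exploit;
* the per-class pattern is scaled by the subject's workload-dependent
  activation amplitude (uM peak dHbO), gated by a boxcar over the task
  blocks, and convolved with a canonical double-gamma hemodynamic
  response function (HRF);
* a per-subject multiplicative channel gain (optode coupling / anatomy)
  jitters the measured pattern;
* block-to-block (series-level) log-normal jitter of the evoked amplitude,
  reflecting the large trial-to-trial variability of real hemodynamic
  responses;
* dHbR modeled as a scaled negative copy of the clean dHbO response
  (ratio 1/3 by default);
* additive physiological noise: Mayer waves (~0.1 Hz), respiration
  (~0.3 Hz), cardiac pulsation (~1.1 Hz) and slow in-band drift
  (<0.05 Hz components) are *systemic* — one random-phase time course per
  component, seen coherently by every channel through a per-channel
  loading, the way superficial/global physiology contaminates real
  recordings — plus independent white measurement noise per channel;
* the modified Beer-Lambert law run forward to produce dual-wavelength
  optical-density changes, which is what the instrument records.

Every random quantity derives from an explicit seed, so a cohort is a pure
function of (configuration, master seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

from . import mbll
from .exceptions import ValidationError
from .paradigm import CLASS_NAMES, BlockSchedule, build_schedule
from .recordings import HemoRecording, OpticalRecording

_SEED_MASK = 0x7FFFFFFF  # keep derived seeds in signed-int32 range


@dataclass
class SubjectProfile:
    """Everything subject-specific the forward model needs.

    ``class_amplitudes`` are peak dHbO responses in uM for (0-back, 2-back,
    3-back); rest has no evoked component.  Noise amplitudes are uM-equivalent.
    """

    subject_id: str
    class_amplitudes: np.ndarray  # (3,), uM
    channel_gains: np.ndarray  # (channels,)
    class_patterns: np.ndarray | None = None  # (3, channels), unit-peak spatial maps
    hrf_peak_delay_s: float = 6.0
    hrf_undershoot_delay_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    noise_mayer: float = 0.0
    noise_respiratory: float = 0.0
    noise_cardiac: float = 0.0
    noise_drift: float = 0.0
    noise_white: float = 0.0
    block_amplitude_jitter_sd: float = 0.0  # log-normal sigma, per series
    rng_seed: int = 0

    def __post_init__(self):
        self.class_amplitudes = np.asarray(self.class_amplitudes, dtype=float)
        self.channel_gains = np.asarray(self.channel_gains, dtype=float)
        if self.class_amplitudes.shape != (len(CLASS_NAMES),):
            raise ValidationError(f"class_amplitudes must have shape ({len(CLASS_NAMES)},)")
        if self.class_patterns is not None:
            self.class_patterns = np.asarray(self.class_patterns, dtype=float)
            expected = (len(CLASS_NAMES), self.channel_gains.shape[0])
            if self.class_patterns.shape != expected:
                raise ValidationError(f"class_patterns must have shape {expected}")
        for name in ("noise_mayer", "noise_respiratory", "noise_cardiac", "noise_drift", "noise_white"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class PopulationConfig:
    """Population distributions the per-subject profiles are drawn from.

    Amplitude means rise with workload (0-back < 2-back < 3-back); the
    monotone ordering is re-imposed after per-subject jitter when
    ``enforce_monotone`` is set.  Every subject shares the same
    load-ordered spatial activation patterns (see :meth:`class_patterns`);
    channel gains are pure per-subject measurement jitter (log-normal
    around 1).  Noise amplitudes are drawn uniformly from the stated
    ranges (uM-equivalent).
    """

    n_channels: int = 36
    class_amplitude_means: tuple[float, float, float] = (0.15, 0.35, 0.5)
    class_amplitude_sd: float = 0.08
    enforce_monotone: bool = True
    frontal_channels: int = 16
    pattern_separation: float = 0.5  # scale of the class-specific topography
    gain_jitter_sd: float = 0.15  # log-normal sigma
    hrf_peak_delay_range_s: tuple[float, float] = (5.0, 7.0)
    hrf_undershoot_delay_range_s: tuple[float, float] = (14.0, 18.0)
    noise_mayer_range: tuple[float, float] = (0.05, 0.15)
    noise_respiratory_range: tuple[float, float] = (0.03, 0.10)
    noise_cardiac_range: tuple[float, float] = (0.03, 0.10)
    noise_drift_range: tuple[float, float] = (0.10, 0.30)
    noise_white_range: tuple[float, float] = (0.05, 0.15)
    block_amplitude_jitter_sd: float = 0.35
    hbr_ratio: float = 1.0 / 3.0

    def class_patterns(self) -> np.ndarray:
        """Unit-peak spatial activation map per workload class, (3, channels).

        Modeled after load-dependent prefrontal recruitment: all classes
        activate the same broad frontal network; load adds a small
        topographic shift (``pattern_separation`` scales it) — a laterally
        displaced patch that grows with n-back level, plus a weak parietal
        component at the highest load.  The class-specific part is subtle
        relative to the shared map, so amplitude ordering and topography
        are both informative but neither trivially so.  The maps are
        population-level constants: the structure subject transfer can
        exploit.
        """
        ch = np.arange(self.n_channels)
        nf = min(self.frontal_channels, self.n_channels)

        def bump(center: float, width: float) -> np.ndarray:
            return np.exp(-0.5 * ((ch - center) / width) ** 2)

        common = bump(nf * 0.5, nf / 3.0)
        sep = self.pattern_separation
        centers = (0.25, 0.50, 0.75)
        patterns = []
        for c, frac in enumerate(centers):
            p = common + sep * c / 2.0 * bump(nf * frac, nf * 0.12)
            if c == 2 and self.n_channels > nf + 8:
                p = p + sep * 0.6 * bump(nf + 6, 2.0)  # parietal recruitment
            patterns.append(p)
        patterns = np.stack(patterns)
        return patterns / patterns.max(axis=1, keepdims=True)


#: Physiological oscillation frequencies (Hz): Mayer, respiratory, cardiac.
NOISE_FREQS_HZ: tuple[float, float, float] = (0.1, 0.3, 1.1)

#: Slow drift component frequencies (Hz); all below the 0.2 Hz analysis band
#: edge, so drift survives low-pass filtering like it does in real data.
DRIFT_FREQS_HZ: tuple[float, ...] = (0.01, 0.02, 0.033, 0.05)


def double_gamma_hrf(
    sampling_rate: float,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    duration_s: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma HRF kernel, normalized to unit peak."""
    t = np.arange(0.0, duration_s, 1.0 / sampling_rate)
    h = gamma_dist.pdf(t, a=peak_delay_s + 1.0) - undershoot_ratio * gamma_dist.pdf(
        t, a=undershoot_delay_s + 1.0
    )
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


def hemodynamic_forward(
    schedule: BlockSchedule,
    profile: SubjectProfile,
    hbr_ratio: float = 1.0 / 3.0,
) -> HemoRecording:
    """Simulate per-channel dHbO/dHbR concentration series for one subject.

    The evoked response is a class-amplitude boxcar over task blocks —
    each series' amplitude additionally jittered by a mean-one log-normal
    factor (trial-to-trial hemodynamic variability) — convolved with the
    subject's HRF and scaled by the channel gains.  dHbR is ``-hbr_ratio``
    times the clean dHbO response; each chromophore then receives its own
    independently drawn noise realization (the HbR noise scaled by the
    same ratio).
    """
    fs = schedule.sampling_rate
    n = schedule.n_samples
    n_ch = profile.channel_gains.shape[0]
    rng = np.random.default_rng(profile.rng_seed)

    sd = profile.block_amplitude_jitter_sd
    jitter = (
        rng.lognormal(mean=-0.5 * sd * sd, sigma=sd, size=schedule.n_series)
        if sd > 0
        else np.ones(schedule.n_series)
    )
    # per-channel class amplitude: shared spatial pattern x subject amplitude
    patterns = (
        profile.class_patterns
        if profile.class_patterns is not None
        else np.ones((len(CLASS_NAMES), n_ch))
    )
    class_maps = profile.class_amplitudes[:, None] * patterns  # (3, channels)
    neural = np.zeros((n_ch, n))
    for seg in schedule.segments(include_rest=False):
        neural[:, seg.start : seg.stop] = (
            class_maps[seg.label][:, None] * jitter[seg.series_index]
        )
    hrf = double_gamma_hrf(
        fs, profile.hrf_peak_delay_s, profile.hrf_undershoot_delay_s, profile.hrf_undershoot_ratio
    )
    # unit-sum kernel: a sustained task block plateaus at the configured
    # class amplitude, keeping dHbO on its physical uM scale
    hrf = hrf / hrf.sum()
    if np.any(neural):
        response = fftconvolve(neural, hrf[None, :], axes=1)[:, :n]
    else:
        response = neural

    clean_hbo = profile.channel_gains[:, None] * response
    t = np.arange(n) / fs
    data = np.empty((n_ch, 2, n))
    for k, (sign_scale, noise_scale) in enumerate([(1.0, 1.0), (-hbr_ratio, hbr_ratio)]):
        noise = np.zeros((n_ch, n))
        components = list(
            zip(NOISE_FREQS_HZ,
                (profile.noise_mayer, profile.noise_respiratory, profile.noise_cardiac))
        ) + [(f, profile.noise_drift / np.sqrt(len(DRIFT_FREQS_HZ))) for f in DRIFT_FREQS_HZ]
        for freq, amp in components:
            if amp > 0:
                # systemic: one time course, coherent across channels via loadings
                phase = rng.uniform(0.0, 2.0 * np.pi)
                loadings = rng.uniform(0.5, 1.5, size=n_ch)
                noise += amp * loadings[:, None] * np.sin(
                    2.0 * np.pi * freq * t[None, :] + phase
                )
        if profile.noise_white > 0:
            noise += profile.noise_white * rng.standard_normal((n_ch, n))
        data[:, k, :] = sign_scale * clean_hbo + noise_scale * noise
    return HemoRecording(
        data=data, sampling_rate=fs, subject_id=profile.subject_id, schedule=schedule
    )


def mbll_forward(
    hemo: HemoRecording,
    extinction: np.ndarray | None = None,
    distance_mm: float = mbll.DEFAULT_DISTANCE_MM,
    dpf=mbll.DEFAULT_DPF,
    wavelengths_nm=mbll.DEFAULT_WAVELENGTHS,
) -> OpticalRecording:
    """Run the MBLL forward: concentrations (uM) -> optical-density changes."""
    if extinction is None:
        extinction = mbll.extinction_matrix(wavelengths_nm)
    od = mbll.od_from_concentration(hemo.data, extinction, distance_mm, dpf)
    return OpticalRecording(
        data=od,
        sampling_rate=hemo.sampling_rate,
        subject_id=hemo.subject_id,
        schedule=hemo.schedule,
        wavelengths_nm=tuple(wavelengths_nm),
        source_detector_mm=distance_mm,
    )


def draw_profile(
    subject_id: str, population: PopulationConfig, seed_seq: np.random.SeedSequence
) -> SubjectProfile:
    """Draw one subject's profile from the population distributions."""
    rng = np.random.default_rng(seed_seq)
    amps = np.asarray(population.class_amplitude_means) + population.class_amplitude_sd * (
        rng.standard_normal(len(CLASS_NAMES))
    )
    amps = np.clip(amps, 0.0, None)
    if population.enforce_monotone:
        amps = np.sort(amps)
    gains = np.exp(population.gain_jitter_sd * rng.standard_normal(population.n_channels))
    u = rng.uniform
    return SubjectProfile(
        subject_id=subject_id,
        class_amplitudes=amps,
        channel_gains=gains,
        class_patterns=population.class_patterns(),
        hrf_peak_delay_s=u(*population.hrf_peak_delay_range_s),
        hrf_undershoot_delay_s=u(*population.hrf_undershoot_delay_range_s),
        noise_mayer=u(*population.noise_mayer_range),
        noise_respiratory=u(*population.noise_respiratory_range),
        noise_cardiac=u(*population.noise_cardiac_range),
        noise_drift=u(*population.noise_drift_range),
        noise_white=u(*population.noise_white_range),
        block_amplitude_jitter_sd=population.block_amplitude_jitter_sd,
        rng_seed=int(seed_seq.generate_state(1)[0]) & _SEED_MASK,
    )


def make_cohort(
    n_subjects: int = 26,
    population: PopulationConfig | None = None,
    master_seed: int = 0,
    schedule: BlockSchedule | None = None,
    mbll_kwargs: dict | None = None,
) -> list[OpticalRecording]:
    """Simulate a cohort of optical recordings (one per subject).

    Per-subject profiles are drawn from the population distributions with
    child seeds derived deterministically from ``master_seed``; the same
    master seed therefore reproduces the cohort bit for bit.  Ground-truth
    labels travel with each recording via its attached schedule
    (``rec.schedule.label_track()``).
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    population = population or PopulationConfig()
    schedule = schedule or build_schedule()
    mbll_kwargs = mbll_kwargs or {}
    children = np.random.SeedSequence(master_seed).spawn(n_subjects)
    cohort = []
    for i, child in enumerate(children):
        profile = draw_profile(f"S{i + 1:02d}", population, child)
        hemo = hemodynamic_forward(schedule, profile, hbr_ratio=population.hbr_ratio)
        cohort.append(mbll_forward(hemo, **mbll_kwargs))
    return cohort
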