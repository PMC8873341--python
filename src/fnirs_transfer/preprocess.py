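"""Optical density -> hemoglobin concentrations, filtering, and epoching.

The stage order mirrors standard fNIRS practice: invert the modified
Beer-Lambert law channel by channel, low-pass the concentration series to
suppress cardiac/respiratory/blood-pressure components, then cut labeled
sliding windows for the classifier.  Windows never straddle a segment
boundary, and each window carries its (subject, series) group so that
splits can be made leakage-safe downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from . import mbll
from .exceptions import EmptyEpochsError, ValidationError
from .paradigm import LABEL_NAMES, REST_CODE, BlockSchedule
from .recordings import HemoRecording, OpticalRecording

#: Supported class modes: 3-class drops rest windows, 4-class keeps them.
CLASS_MODES = ("3class", "4class")


@dataclass
class EpochSet:
    """Labeled windowed examples cut from one or more recordings.

    ``X`` has shape (n_examples, channels, chromophores, window_samples);
    labels are integer class codes (0/1/2 for 0-/2-/3-back, 3 for rest).
    ``subject_ids`` and ``series_idx`` identify each example's origin so a
    split can keep whole series on one side of a fold.
    """

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray  # (n,) str
    series_idx: np.ndarray  # (n,) int
    window_s: float
    step_s: float
    class_mode: str = "3class"
    sampling_rate: float = 10.0
    normalization: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.subject_ids) == len(self.series_idx) == n):
            raise ValidationError("labels/groups length must match the number of examples")
        if self.class_mode not in CLASS_MODES:
            raise ValidationError(f"class_mode must be one of {CLASS_MODES}")
        allowed = {0, 1, 2} if self.class_mode == "3class" else {0, 1, 2, REST_CODE}
        if n and not set(np.unique(self.y)).issubset(allowed):
            raise ValidationError(f"labels {set(np.unique(self.y))} outside class mode {self.class_mode}")

    @property
    def n_examples(self) -> int:
        return self.X.shape[0]

    @property
    def n_classes(self) -> int:
        return 3 if self.class_mode == "3class" else 4

    @property
    def groups(self) -> np.ndarray:
        """Series-level group key per example (subject id + series index)."""
        return np.array([f"{s}/{i}" for s, i in zip(self.subject_ids, self.series_idx)])

    def label_names(self) -> list[str]:
        return [LABEL_NAMES[c] for c in sorted(set(self.y.tolist()))]

    def subset(self, idx) -> "EpochSet":
        return replace(
            self,
            X=self.X[idx],
            y=self.y[idx],
            subject_ids=self.subject_ids[idx],
            series_idx=self.series_idx[idx],
        )


def mbll_invert(
    optical: OpticalRecording,
    extinction: np.ndarray | None = None,
    distance_mm: float | None = None,
    dpf=mbll.DEFAULT_DPF,
) -> HemoRecording:
    """Invert the MBLL: dual-wavelength dOD -> (dHbO, dHbR) in uM.

    Solves the per-channel, per-sample 2x2 linear system; exact inverse of
    the simulator's forward map when run with the same constants.
    """
    if optical.data.shape[1] != 2:
        raise ValidationError("MBLL inversion requires exactly 2 wavelengths")
    if extinction is None:
        extinction = mbll.extinction_matrix(optical.wavelengths_nm)
    if distance_mm is None:
        distance_mm = optical.source_detector_mm
    conc = mbll.concentration_from_od(optical.data, extinction, distance_mm, dpf)
    return HemoRecording(
        data=conc,
        sampling_rate=optical.sampling_rate,
        subject_id=optical.subject_id,
        schedule=optical.schedule,
        filtered=False,
    )


def lowpass_filter(
    hemo: HemoRecording, cutoff_hz: float = 0.2, order: int = 4
) -> HemoRecording:
    """Zero-phase Butterworth low-pass, applied per channel/chromophore.

    Forward-backward filtering (`filtfilt`) doubles the attenuation in dB
    and cancels phase; edges are handled by reflective padding.  The evoked
    hemodynamic response lives well below the 0.2 Hz default cutoff while
    cardiac (~1.1 Hz) and respiratory (~0.3 Hz) components lie above it.
    """
    nyq = hemo.sampling_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValidationError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff_hz}")
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=hemo.sampling_rate)
    out = signal.filtfilt(b, a, hemo.data, axis=-1)
    return hemo.copy_with(data=out, filtered=True)


def filter_magnitude_response(
    freq_hz: float, cutoff_hz: float = 0.2, order: int = 4, sampling_rate: float = 10.0
) -> float:
    """Analytic amplitude gain of the zero-phase filter at ``freq_hz``.

    filtfilt applies the designed Butterworth twice, so the effective gain
    is the squared magnitude of the single-pass digital response.
    """
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=sampling_rate)
    _, h = signal.freqz(b, a, worN=[freq_hz], fs=sampling_rate)
    return float(np.abs(h[0]) ** 2)


def segment_epochs(
    hemo: HemoRecording,
    schedule: BlockSchedule | None = None,
    window_s: float = 10.0,
    step_s: float = 5.0,
    class_mode: str = "3class",
) -> EpochSet:
    """Cut labeled sliding windows from every labeled segment.

    A segment of ``L`` samples yields ``floor((L - W)/S) + 1`` windows of
    ``W`` samples at step ``S``; windows lie entirely within their segment,
    so no example ever mixes labels.  Ordering is deterministic: segments
    in time order, onsets ascending.
    """
    if class_mode not in CLASS_MODES:
        raise ValidationError(f"class_mode must be one of {CLASS_MODES}")
    if step_s <= 0 or window_s <= 0:
        raise ValidationError("window_s and step_s must be positive")
    schedule = schedule or hemo.schedule
    fs = hemo.sampling_rate
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    include_rest = class_mode == "4class"

    windows, labels, series = [], [], []
    for seg in schedule.segments(include_rest=include_rest):
        n_fit = (seg.n_samples - win) // step + 1
        for j in range(max(n_fit, 0)):
            start = seg.start + j * step
            windows.append(hemo.data[:, :, start : start + win])
            labels.append(seg.label)
            series.append(seg.series_index)
    if not windows:
        raise EmptyEpochsError(
            f"window of {window_s}s ({win} samples) longer than every labeled segment"
        )
    n = len(windows)
    return EpochSet(
        X=np.stack(windows),
        y=np.asarray(labels),
        subject_ids=np.array([hemo.subject_id] * n),
        series_idx=np.asarray(series),
        window_s=float(window_s),
        step_s=float(step_s),
        class_mode=class_mode,
        sampling_rate=fs,
    )


def normalize_examples(
    epochs: EpochSet,
    scheme: str = "zscore",
    train_idx: np.ndarray | None = None,
    eps: float = 1e-8,
) -> EpochSet:
    """Normalize examples without leaking held-out statistics.

    ``zscore`` standardizes each (channel, chromophore) over samples and
    examples using statistics computed on ``train_idx`` only (all examples
    if omitted), then applies them to every example — held-out data keeps
    any shift it carries.  ``none`` is the identity.
    """
    if scheme == "none":
        return epochs
    if scheme != "zscore":
        raise ValidationError(f"unknown normalization scheme {scheme!r}")
    fit = epochs.X if train_idx is None else epochs.X[train_idx]
    if fit.shape[0] == 0:
        raise ValidationError("cannot fit normalization statistics on an empty training set")
    mean = fit.mean(axis=(0, 3), keepdims=True)  # per channel x chromophore
    sd = fit.std(axis=(0, 3), keepdims=True)
    if np.any(sd < eps):
        warnings.warn("zero-variance channel(s) during normalization; epsilon guard applied")
    sd = np.maximum(sd, eps)
    out = replace(epochs, X=(epochs.X - mean) / sd)
    out.normalization = {"scheme": "zscore", "mean": mean, "sd": sd}
    return out
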