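"""In-memory containers for optical and hemoglobin recordings."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ValidationError
from .mbll import DEFAULT_DISTANCE_MM, DEFAULT_WAVELENGTHS
from .paradigm import BlockSchedule

#: Fixed chromophore axis order for HemoRecording and EpochSet tensors.
CHROMOPHORES: tuple[str, str] = ("HbO", "HbR")


@dataclass
class OpticalRecording:
    """Dual-wavelength optical-density change, ``data[channel, wavelength, sample]``.

    Optical density is dimensionless; ``wavelengths_nm`` orders the second
    axis and ``source_detector_mm`` is the (shared) optode separation.
    """

    data: np.ndarray  # (channels, 2, samples), dOD
    sampling_rate: float
    subject_id: str
    schedule: BlockSchedule
    wavelengths_nm: tuple[float, float] = DEFAULT_WAVELENGTHS
    source_detector_mm: float = DEFAULT_DISTANCE_MM

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValidationError(
                f"optical data must be (channels, 2 wavelengths, samples), got {self.data.shape}"
            )
        if self.source_detector_mm <= 0:
            raise ValidationError("source-detector distance must be positive")
        if abs(self.data.shape[2] - self.schedule.n_samples) > 1:
            raise ValidationError(
                f"sample count {self.data.shape[2]} inconsistent with schedule "
                f"duration ({self.schedule.n_samples} samples)"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class HemoRecording:
    """Hemoglobin concentration change in uM, ``data[channel, chromophore, sample]``.

    The chromophore axis is always ordered (HbO, HbR).  ``filtered`` records
    whether the temporal low-pass has been applied.
    """

    data: np.ndarray  # (channels, 2 [HbO, HbR], samples), uM
    sampling_rate: float
    subject_id: str
    schedule: BlockSchedule
    filtered: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValidationError(
                f"hemoglobin data must be (channels, 2 chromophores, samples), got {self.data.shape}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy_with(self, **kwargs) -> "HemoRecording":
        return replace(self, **kwargs)
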