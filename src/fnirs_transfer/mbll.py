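"""Modified Beer-Lambert law (MBLL) constants and the 2x2 linear map.

The MBLL relates optical-density change at a wavelength to chromophore
concentration changes through

    dOD(lambda) = [eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR]
                  * distance * DPF(lambda)

where ``eps`` are specific extinction coefficients, ``distance`` is the
source-detector separation and ``DPF`` the differential pathlength factor.
Concentrations are in micromolar (uM), distances in millimetres, and the
extinction coefficients below are expressed in OD per (uM * mm) so the
product is dimensionless optical density.

Both the forward map (simulation) and its inverse (preprocessing) reduce
to a per-sample 2x2 linear system; the helpers here are the single shared
implementation of that system.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigurationError

#: Default dual-wavelength pair (nm) of a typical CW-NIRS instrument.
DEFAULT_WAVELENGTHS: tuple[float, float] = (760.0, 850.0)

#: Specific extinction coefficients, OD / (uM * mm), keyed by wavelength.
#: Columns: (HbO, HbR).  Values converted from the widely used compiled
#: molar extinction tables (1/(M*cm) scale / 1e7).
EXTINCTION_OD_PER_UM_MM: dict[float, tuple[float, float]] = {
    760.0: (1.4866e-4, 3.8437e-4),
    850.0: (2.5264e-4, 1.7986e-4),
}

#: Differential pathlength factor per wavelength (dimensionless).
DEFAULT_DPF: tuple[float, float] = (6.0, 6.0)

#: Default source-detector separation in millimetres.
DEFAULT_DISTANCE_MM: float = 30.0


def extinction_matrix(wavelengths=DEFAULT_WAVELENGTHS) -> np.ndarray:
    """Return the 2x2 extinction matrix, rows = wavelengths, cols = (HbO, HbR)."""
    try:
        rows = [EXTINCTION_OD_PER_UM_MM[float(w)] for w in wavelengths]
    except KeyError as exc:  # pragma: no cover - exercised via custom matrices
        raise ConfigurationError(
            f"no packaged extinction coefficients for wavelength {exc}; "
            "pass an explicit 2x2 extinction matrix"
        ) from None
    return np.asarray(rows, dtype=float)


def _check_matrix(extinction: np.ndarray) -> np.ndarray:
    extinction = np.asarray(extinction, dtype=float)
    if extinction.shape != (2, 2):
        raise ConfigurationError(
            f"extinction matrix must be 2x2 (wavelength x chromophore), got {extinction.shape}"
        )
    if abs(np.linalg.det(extinction)) < 1e-12:
        raise ConfigurationError("extinction matrix is singular; wavelengths do not separate HbO/HbR")
    return extinction


def _pathlength(distance_mm: float, dpf) -> np.ndarray:
    dpf = np.asarray(dpf, dtype=float)
    if distance_mm <= 0 or np.any(dpf <= 0):
        raise ConfigurationError("source-detector distance and DPF must be positive")
    return distance_mm * dpf  # per-wavelength effective pathlength, mm


def od_from_concentration(conc, extinction, distance_mm, dpf) -> np.ndarray:
    """Forward MBLL: map (..., 2[HbO,HbR], T) concentrations to (..., 2[wl], T) dOD."""
    extinction = _check_matrix(extinction)
    conc = np.asarray(conc, dtype=float)
    path = _pathlength(distance_mm, dpf)  # (2,)
    od = np.einsum("lc,...ct->...lt", extinction, conc)
    return od * path[:, None]


def concentration_from_od(od, extinction, distance_mm, dpf) -> np.ndarray:
    """Inverse MBLL: solve the per-sample 2x2 system for (dHbO, dHbR)."""
    extinction = _check_matrix(extinction)
    od = np.asarray(od, dtype=float)
    path = _pathlength(distance_mm, dpf)
    scaled = od / path[:, None]  # (..., 2, T), one pathlength per wavelength
    inv = np.linalg.inv(extinction)
    return np.einsum("cl,...lt->...ct", inv, scaled)
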