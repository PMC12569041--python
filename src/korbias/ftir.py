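"""Ligand-exchange FTIR difference spectra and band-shift analysis.

Absolute absorbance spectra of antagonist-bound (inactive) and agonist-bound
(active) receptor films are subtracted (active minus inactive) to give a
difference spectrum in which positive bands belong to the active state and
negative bands to the inactive state. Band extrema are located on the
instrument grid (2 cm^-1 by default) and refined to sub-grid precision by
parabolic interpolation through the three points around the extremum.

Diagnostic windows for KOR: S-H stretch of cysteine 2600-2500 cm^-1,
C-N stretch of histidine 1200-1100 cm^-1, amide-I 1700-1600 cm^-1.

Spectral corrections (swelling/shrinkage scaling, vapor/CO2/buffer reference
subtraction) are least-squares scalar fits in configurable windows; every
applied correction is recorded in the difference-spectrum provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "DifferenceSpectrum",
    "BandPeak",
    "WINDOWS",
    "regrid",
    "correct",
    "difference",
    "find_band",
    "band_shift",
]

#: default diagnostic windows (cm^-1), low..high
WINDOWS = {
    "sh": (2500.0, 2600.0),
    "his_cn": (1100.0, 1200.0),
    "amide_I": (1600.0, 1700.0),
}


def _check_grid(x: np.ndarray) -> None:
    if x.ndim != 1 or x.size < 3:
        raise ValueError("grid must be a 1-D array with >= 3 points")
    steps = np.diff(x)
    if np.any(steps <= 0):
        raise ValueError("wavenumber grid must be strictly ascending")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("wavenumber grid must be uniform")


@dataclass
class Spectrum:
    """Absorbance on a uniform ascending wavenumber grid (cm^-1)."""

    wavenumber: np.ndarray
    absorbance: np.ndarray
    label: str = ""
    corrections: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        _check_grid(self.wavenumber)
        if self.wavenumber.shape != self.absorbance.shape:
            raise ValueError("grid and absorbance lengths differ")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "Spectrum":
        return cls(
            df["wavenumber_cm-1"].to_numpy(), df["absorbance"].to_numpy(), label
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavenumber_cm-1": self.wavenumber, "absorbance": self.absorbance}
        )

    @property
    def step(self) -> float:
        return float(self.wavenumber[1] - self.wavenumber[0])


@dataclass
class DifferenceSpectrum:
    """Active minus inactive absorbance with provenance."""

    wavenumber: np.ndarray
    delta: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def step(self) -> float:
        return float(self.wavenumber[1] - self.wavenumber[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavenumber_cm-1": self.wavenumber, "absorbance": self.delta}
        )


@dataclass(frozen=True)
class BandPeak:
    """A located extremum: sub-grid position, sign and amplitude."""

    position: float      # cm^-1, parabolic-refined
    sign: str            # "positive" | "negative"
    amplitude: float
    window: tuple[float, float]


def regrid(spectrum: Spectrum, target: np.ndarray) -> Spectrum:
    """Linear interpolation onto a new grid (no extrapolation)."""
    target = np.asarray(target, dtype=float)
    _check_grid(target)
    src = spectrum.wavenumber
    if target[0] < src[0] - 1e-9 or target[-1] > src[-1] + 1e-9:
        raise ValueError(
            f"target grid [{target[0]}, {target[-1]}] extends beyond source "
            f"range [{src[0]}, {src[-1]}]"
        )
    return Spectrum(
        target, np.interp(target, src, spectrum.absorbance), spectrum.label
    )


def _window_mask(x: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = min(window), max(window)
    mask = (x >= lo) & (x <= hi)
    if not mask.any():
        raise ValueError(f"window {window} contains no grid points")
    return mask


def correct(
    spectrum: Spectrum,
    scale_to: Spectrum | None = None,
    scale_window: tuple[float, float] | None = None,
    vapor: Spectrum | None = None,
    vapor_window: tuple[float, float] = (1700.0, 1900.0),
) -> Spectrum:
    """Apply scale and/or vapor-subtraction corrections.

    ``scale_to``: multiply by the scalar minimizing the squared residual
    against the reference inside ``scale_window`` (whole overlap when None)
    — compensates film swelling/shrinkage. ``vapor``: subtract ``alpha *
    vapor`` with alpha minimizing the residual roughness (squared first
    differences) inside ``vapor_window`` (default 1900-1700 cm^-1, where
    water-vapor rotational lines dominate). With no corrections requested
    this is the identity.
    """
    x = spectrum.wavenumber
    y = spectrum.absorbance.copy()
    applied: dict[str, float] = {}

    if scale_to is not None:
        if not np.array_equal(x, scale_to.wavenumber):
            scale_to = regrid(scale_to, x)
        mask = (
            _window_mask(x, scale_window) if scale_window is not None
            else np.ones_like(x, dtype=bool)
        )
        s, r = y[mask], scale_to.absorbance[mask]
        denom = float(s @ s)
        if denom == 0:
            raise ValueError("cannot scale an all-zero spectrum")
        factor = float(s @ r) / denom
        y = y * factor
        applied["scale_factor"] = factor

    if vapor is not None:
        if not np.array_equal(x, vapor.wavenumber):
            vapor = regrid(vapor, x)
        mask = _window_mask(x, vapor_window)
        ds = np.diff(y[mask])
        dv = np.diff(vapor.absorbance[mask])
        denom = float(dv @ dv)
        if denom == 0:
            raise ValueError("vapor reference is flat in the fit window")
        alpha = float(ds @ dv) / denom
        y = y - alpha * vapor.absorbance
        applied["vapor_alpha"] = alpha

    return Spectrum(x, y, spectrum.label, corrections=applied)


def difference(active: Spectrum, inactive: Spectrum) -> DifferenceSpectrum:
    """Pointwise active minus inactive absorbance on the common grid."""
    if not np.array_equal(active.wavenumber, inactive.wavenumber):
        raise ValueError("spectra are on different grids; regrid first")
    prov = {
        "active": active.label,
        "inactive": inactive.label,
        "active_corrections": dict(active.corrections),
        "inactive_corrections": dict(inactive.corrections),
    }
    return DifferenceSpectrum(
        active.wavenumber.copy(), active.absorbance - inactive.absorbance, prov
    )


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points i-1, i, i+1 (falls back to i)."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-300:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    step = x[1] - x[0]
    pos = float(x[i] + delta * step)
    amp = float(y1 - 0.25 * (y0 - y2) * delta)
    return pos, amp


def find_band(
    diff: DifferenceSpectrum,
    window: tuple[float, float],
    sign: str = "positive",
    min_amplitude: float = 0.0,
) -> BandPeak | None:
    """Locate the extremum of the requested sign inside a window.

    Returns ``None`` when the window is flat or holds no extremum of that
    sign (absence is reported, never a fabricated peak).
    """
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    x = diff.wavenumber
    mask = _window_mask(x, window)
    xi = x[mask]
    yi = diff.delta[mask]
    if np.ptp(yi) < 1e-14:
        return None
    if sign == "positive":
        i = int(np.argmax(yi))
        if yi[i] <= min_amplitude:
            return None
    else:
        i = int(np.argmin(yi))
        if yi[i] >= -min_amplitude:
            return None
    pos, amp = _parabolic_refine(xi, yi, i)
    lo, hi = min(window), max(window)
    pos = float(np.clip(pos, lo, hi))
    return BandPeak(position=pos, sign=sign, amplitude=amp, window=(lo, hi))


def band_shift(negative: BandPeak | None, positive: BandPeak | None) -> float:
    """Upshift (cm^-1) from the inactive (negative) to active (positive) band."""
    if negative is None or positive is None:
        raise ValueError("band shift requires both peaks; one is absent")
    return positive.position - negative.position
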