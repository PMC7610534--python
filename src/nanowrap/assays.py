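"""Fluorescence assay reductions: calcein leakage, calibration, emission peaks.

Calcein encapsulated at a self-quenching concentration is dark inside intact
vesicles; membrane disruption dilutes it into the bulk and fluorescence
rises.  Leakage is reported as the control-subtracted fluorescence normalised
to the detergent-lysis maximum.  Nile Red is a solvatochromic membrane probe:
its emission maximum blue-shifts when the probe environment becomes less
polar, so a Gaussian fit of the emission spectrum and the sign of the
centre shift report on particle positioning at the headgroup/tail interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from lmfit.models import ConstantModel, GaussianModel
from scipy import optimize, stats

__all__ = [
    "Spectrum",
    "PeakFit",
    "LeakageReading",
    "ShiftLabel",
    "CalibrationFit",
    "leakage_percent",
    "fit_emission_peak",
    "emission_shift",
    "calcein_calibration",
    "fit_leakage_rate",
]


@dataclass(frozen=True)
class Spectrum:
    """Emission spectrum: wavelength grid (nm, strictly increasing), intensity (a.u.)."""

    wavelength: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "intensity", it)
        if wl.ndim != 1 or wl.shape != it.shape:
            raise ValueError("wavelength and intensity must be 1-D of equal length")
        if wl.size < 10:
            raise ValueError("spectrum needs at least 10 points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")


@dataclass(frozen=True)
class PeakFit:
    """Gaussian + constant-baseline fit of an emission peak.

    center/width in nm (width is the Gaussian sigma), amplitude is the peak
    height above baseline.  converged is False for degenerate or failed fits.
    """

    center: float
    width: float
    amplitude: float
    baseline: float
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class LeakageReading:
    """One leakage well: sample, particle-free control, and post-lysis maximum."""

    F_sample: float
    F_control: float
    F_max: float

    def __post_init__(self) -> None:
        if self.F_max <= 0:
            raise ValueError("F_max must be > 0")


class ShiftLabel:
    BLUE = "BLUE"
    RED = "RED"
    NONE = "NONE"


def leakage_percent(
    reading: LeakageReading, subtract_control_from_max: bool = False
) -> float:
    """Leakage as 100*(F_sample - F_control)/F_max.

    May be negative (sample dimmer than control); reported as computed.
    subtract_control_from_max normalises to (F_max - F_control) instead —
    an alternative reading of the normalisation, off by default.
    """
    denom = reading.F_max
    if subtract_control_from_max:
        denom = reading.F_max - reading.F_control
        if denom <= 0:
            raise ValueError("F_max - F_control must be > 0 for this normalisation")
    return 100.0 * (reading.F_sample - reading.F_control) / denom


def fit_emission_peak(spectrum: Spectrum) -> PeakFit:
    """Least-squares Gaussian + constant baseline; centre is the emission maximum.

    Degenerate spectra (no dominant peak) and non-converged optimisations
    return converged=False with diagnostics in message.
    """
    wl, it = spectrum.wavelength, spectrum.intensity
    span = float(np.ptp(it))
    if span <= 0:
        return PeakFit(np.nan, np.nan, 0.0, float(it[0]), False, "flat spectrum")
    model = GaussianModel(prefix="g_") + ConstantModel(prefix="b_")
    i_max = int(np.argmax(it))
    params = model.make_params(
        g_center=float(wl[i_max]),
        g_sigma=float(np.ptp(wl)) / 10.0,
        g_amplitude=span * float(np.ptp(wl)) / 10.0 * np.sqrt(2 * np.pi),
        b_c=float(np.min(it)),
    )
    params["g_sigma"].set(min=np.median(np.diff(wl)) / 2, max=float(np.ptp(wl)))
    params["g_center"].set(min=float(wl[0]), max=float(wl[-1]))
    params["g_amplitude"].set(min=0.0)
    try:
        result = model.fit(it, params, x=wl)
    except Exception as exc:  # pragma: no cover - lmfit raises rarely
        return PeakFit(np.nan, np.nan, np.nan, np.nan, False, str(exc))
    sigma = float(result.params["g_sigma"].value)
    center = float(result.params["g_center"].value)
    height = float(result.params["g_amplitude"].value) / (sigma * np.sqrt(2 * np.pi))
    baseline = float(result.params["b_c"].value)
    residual_sd = float(np.std(it - result.best_fit))
    converged = bool(result.success)
    message = ""
    if not result.success:
        message = result.message or "optimiser failure"
    elif height < 3.0 * residual_sd or not (wl[0] < center < wl[-1]):
        converged = False
        message = "no dominant peak resolved"
    return PeakFit(center, sigma, height, baseline, converged, message)


def emission_shift(
    reference_center_nm: float,
    sample_center_nm: float,
    noise_threshold_nm: float = 1.0,
) -> tuple[float, str]:
    """Signed emission-maximum shift (sample - reference, nm) and its label.

    BLUE for shifts below -threshold (less polar environment), RED above
    +threshold, NONE within the noise threshold.
    """
    if not (np.isfinite(reference_center_nm) and np.isfinite(sample_center_nm)):
        raise ValueError("centres must be finite")
    shift = sample_center_nm - reference_center_nm
    if abs(shift) <= noise_threshold_nm:
        label = ShiftLabel.NONE
    elif shift < 0:
        label = ShiftLabel.BLUE
    else:
        label = ShiftLabel.RED
    return shift, label


@dataclass(frozen=True)
class CalibrationFit:
    """Ordinary least-squares calibration line F = slope*c + intercept."""

    slope: float
    intercept: float
    stderr_slope: float
    rvalue: float

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def inverse(self, fluorescence: float) -> float:
        """Map a fluorescence reading back to total calcein."""
        return (fluorescence - self.intercept) / self.slope


def calcein_calibration(
    standards: Sequence[tuple[float, float]],
) -> CalibrationFit:
    """Fit a calibration line through (concentration, fluorescence) standards."""
    if len(standards) < 3:
        raise ValueError("at least 3 calibration standards are required")
    conc, fluor = np.asarray(standards, dtype=float).T
    res = stats.linregress(conc, fluor)
    if res.slope == 0:
        raise ValueError("zero calibration slope: inverse prediction undefined")
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr_slope=float(res.stderr),
        rvalue=float(res.rvalue),
    )


def fit_leakage_rate(
    time_s: np.ndarray, fluorescence: np.ndarray
) -> tuple[float, Callable[[np.ndarray], np.ndarray]]:
    """Fit a first-order leakage time course F(t) = F0 + F_inf*(1 - exp(-k t)).

    Returns the rate constant k (1/s) and the fitted model function.
    """
    t = np.asarray(time_s, dtype=float)
    f = np.asarray(fluorescence, dtype=float)

    def model(tt, f0, f_inf, k):
        return f0 + f_inf * (1.0 - np.exp(-k * tt))

    f0_guess = float(f[0])
    f_inf_guess = max(float(f[-1] - f[0]), 1e-12)
    k_guess = 1.0 / max(float(t[-1]) / 3.0, 1e-12)
    popt, _ = optimize.curve_fit(
        model,
        t,
        f,
        p0=(f0_guess, f_inf_guess, k_guess),
        bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    return float(popt[2]), lambda tt: model(np.asarray(tt, dtype=float), *popt)
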