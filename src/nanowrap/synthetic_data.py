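"""Seeded generators for every instrument readout the pipeline consumes.

Each generator returns (data, truth) where truth holds the exact parameters
used, so every analysis stage has a closed-loop parameter-recovery test.
All randomness flows through a single numpy Generator created from the seed;
identical seed and configuration give identical output.

What is emulated: multi-injection calorimeter power traces (one-sided
exponential injection pulses of known integrated heat on a drifting noisy
baseline), Gaussian emission peaks, multi-exponential correlograms of size
mixtures, first-order leakage time courses, and lognormal particle-size
populations.  What is not: instrument response functions, detector
saturation, stirring artefacts or any non-Gaussian noise.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .assays import Spectrum
from .dls import Correlogram, OpticalSetup, Population, default_delay_grid, simulate_correlogram
from .itc import InjectionSchedule, Thermogram

__all__ = [
    "gen_thermogram",
    "gen_spectrum",
    "gen_correlogram",
    "gen_leakage_series",
    "gen_population",
]


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_thermogram(
    schedule: InjectionSchedule = InjectionSchedule(),
    true_heats: Sequence[float] | None = None,
    peak_tau: float = 8.0,
    drift: float = 0.0,
    noise_sd: float = 0.02,
    seed: int | np.random.Generator | None = None,
    dt: float = 0.1,
    baseline_power: float = 0.0,
) -> tuple[Thermogram, dict]:
    """Synthetic differential-power trace with known per-injection heats.

    true_heats (uJ, negative = exothermic) may cover all schedule.count + 1
    injections, or only the schedule.count main ones — then the small first
    injection is assigned a heat scaled by the volume ratio.  Each injection
    adds a one-sided exponential pulse (q/tau)*exp(-(t-t_inj)/tau) whose
    integral is exactly q; a linear drift (uW/s) and white Gaussian noise
    (uW per sample) are superimposed.
    """
    if true_heats is None:
        true_heats = [-8.0] * schedule.n_injections
    heats = np.asarray(true_heats, dtype=float)
    if heats.size == schedule.count:
        first = heats[0] * schedule.first_volume / schedule.volume
        heats = np.concatenate([[first], heats])
    if heats.size != schedule.n_injections:
        raise ValueError(
            f"true_heats must have {schedule.count} or {schedule.n_injections} "
            f"entries, got {heats.size}"
        )
    rng = _rng(seed)
    t_end = schedule.injection_times[-1] + schedule.interval
    time = np.arange(0.0, t_end + dt / 2, dt)
    power = baseline_power + drift * time
    for ti, q in zip(schedule.injection_times, heats):
        # bin-averaged sampling of the pulse: each sample is the mean power
        # over [t - dt/2, t + dt/2], so the sampled trace integrates to q
        # without an onset-discontinuity artefact
        lo = np.maximum(time - dt / 2 - ti, 0.0)
        hi = np.maximum(time + dt / 2 - ti, 0.0)
        power = power + q * (np.exp(-lo / peak_tau) - np.exp(-hi / peak_tau)) / dt
    if noise_sd > 0:
        power = power + rng.normal(0.0, noise_sd, size=time.shape)
    truth = {
        "heats_uJ": heats,
        "peak_tau_s": peak_tau,
        "drift_uW_per_s": drift,
        "noise_sd_uW": noise_sd,
        "dt_s": dt,
    }
    return Thermogram(time=time, power=power), truth


def gen_spectrum(
    center: float = 635.0,
    sd: float = 25.0,
    amplitude: float = 100.0,
    baseline: float = 5.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    grid: np.ndarray | None = None,
) -> tuple[Spectrum, dict]:
    """Gaussian emission peak (height `amplitude`) on a 1 nm grid 490-700 nm."""
    if grid is None:
        grid = np.arange(490.0, 701.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    if not grid[0] <= center <= grid[-1]:
        raise ValueError("peak centre must lie inside the wavelength grid")
    rng = _rng(seed)
    intensity = baseline + amplitude * np.exp(-((grid - center) ** 2) / (2 * sd**2))
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=grid.shape)
    truth = {
        "center_nm": center,
        "sd_nm": sd,
        "amplitude": amplitude,
        "baseline": baseline,
        "noise_sd": noise_sd,
    }
    return Spectrum(wavelength=grid, intensity=intensity), truth


def gen_correlogram(
    populations: Sequence[Population],
    setup: OpticalSetup = OpticalSetup(),
    beta: float = 0.8,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    n_points: int = 200,
) -> tuple[Correlogram, dict]:
    """Mixture correlogram on a logarithmic delay grid 0.5 us - 1 s."""
    corr = simulate_correlogram(
        populations,
        setup=setup,
        delays_us=default_delay_grid(n_points),
        beta=beta,
        noise_sd=noise_sd,
        seed=_rng(seed),
    )
    truth = {
        "diameters_nm": [p.diameter for p in populations],
        "number_concentrations": [p.number_concentration for p in populations],
        "beta": beta,
        "noise_sd": noise_sd,
    }
    return corr, truth


def gen_leakage_series(
    k_leak: float = 1e-3,
    F_max: float = 100.0,
    F_control: float = 10.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    duration: float = 3600.0,
    dt: float = 10.0,
) -> tuple[tuple[np.ndarray, np.ndarray], dict]:
    """First-order leakage time course F(t) = F_control + F_max*(1 - exp(-k t))."""
    if k_leak < 0:
        raise ValueError("k_leak must be >= 0")
    rng = _rng(seed)
    time = np.arange(0.0, duration + dt / 2, dt)
    fluor = F_control + F_max * (1.0 - np.exp(-k_leak * time))
    if noise_sd > 0:
        fluor = fluor + rng.normal(0.0, noise_sd, size=time.shape)
    truth = {
        "k_leak_per_s": k_leak,
        "F_max": F_max,
        "F_control": F_control,
        "noise_sd": noise_sd,
    }
    return (time, fluor), truth


def gen_population(
    median_d: float = 179.0,
    gsd: float = 1.2,
    n: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Lognormal diameter sample with given median and geometric SD (gsd >= 1)."""
    if gsd < 1:
        raise ValueError("geometric standard deviation must be >= 1")
    if median_d <= 0:
        raise ValueError("median diameter must be > 0")
    rng = _rng(seed)
    sample = rng.lognormal(mean=math.log(median_d), sigma=math.log(gsd), size=n)
    truth = {"median_nm": median_d, "gsd": gsd, "n": n}
    return sample, truth
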