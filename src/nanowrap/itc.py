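"""Isothermal titration calorimetry reductions.

A power-compensation calorimeter records the differential power (uW) needed
to keep sample and reference cells at equal temperature while the titrant is
injected.  Each injection produces a transient power excursion whose
baseline-corrected time integral is the injection heat dQ (uJ, negative for
exothermic events).  For nanoparticle-vesicle titrations the meaningful
normalisation is per interacting surface area rather than per mole: the heat
of the designated injection divided by the total gold surface area in the
cell gives the surface enthalpy dH in mJ/m^2.  The chained form
(dQ/SA_L)/(SA_Au/SA_L) is algebraically identical and is exposed for
cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "InjectionSchedule",
    "Thermogram",
    "HeatSeries",
    "NormalizedEnthalpy",
    "integrate_thermogram",
    "subtract_dilution",
    "normalize_enthalpy",
    "gibbs_identity",
]


@dataclass(frozen=True)
class InjectionSchedule:
    """Titration schedule: a small first injection followed by `count` main ones.

    Volumes in uL, times in s.  start_delay is the pre-titration
    equilibration span before the first injection; the integrator needs it
    for the first pre-injection baseline segment.
    """

    first_volume: float = 0.4
    volume: float = 3.0
    count: int = 12
    interval: float = 150.0
    rate: float = 0.5
    cell_volume: float = 205.0
    temperature: float = 298.15
    start_delay: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "first_volume",
            "volume",
            "count",
            "interval",
            "rate",
            "cell_volume",
            "temperature",
            "start_delay",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.interval <= self.volume / self.rate:
            raise ValueError("interval must exceed the injection duration")

    @property
    def n_injections(self) -> int:
        """Total injections including the small first one."""
        return self.count + 1

    @property
    def injection_times(self) -> np.ndarray:
        """Injection start times, s."""
        return self.start_delay + self.interval * np.arange(self.n_injections)


@dataclass(frozen=True)
class Thermogram:
    """Differential-power trace: time (s, strictly increasing) and power (uW)."""

    time: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "power", p)
        if t.ndim != 1 or t.shape != p.shape:
            raise ValueError("time and power must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
            raise ValueError("thermogram values must be finite")


@dataclass(frozen=True)
class HeatSeries:
    """Per-injection heats (uJ).  Index 0 is the small first injection,
    flagged discardable by default."""

    heats: np.ndarray
    first_discardable: bool = True
    baselines: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        object.__setattr__(self, "heats", np.asarray(self.heats, dtype=float))


@dataclass(frozen=True)
class NormalizedEnthalpy:
    """Surface-area-normalised enthalpy of the designated injection.

    delta_H : mJ/m^2, heat of the designated injection per gold surface area.
    delta_H_mean : mJ/m^2, mean over the non-discarded injections (the
        alternative summary when replicate injections are averaged).
    """

    delta_H: float
    delta_H_mean: float
    sa_au: float
    sa_l: float | None = None


_BASELINE_SEGMENT_S = 20.0


def integrate_thermogram(
    trace: Thermogram, schedule: InjectionSchedule
) -> HeatSeries:
    """Integrate per-injection heats with a per-window linear baseline.

    For each injection window [t_inj, t_inj + interval) the baseline is a
    straight line fitted through the 20 s immediately before the injection
    and the final 20 s of the window; the heat is the trapezoidal integral
    of (power - baseline) over the window, in uJ.  Affine drifts are
    absorbed exactly.
    """
    t, p = trace.time, trace.power
    t_inj = schedule.injection_times
    missing = [
        i
        for i, ti in enumerate(t_inj)
        if ti - _BASELINE_SEGMENT_S < t[0] or ti + schedule.interval > t[-1]
    ]
    if missing:
        raise ValueError(
            f"trace does not span injection windows {missing} "
            f"(trace covers [{t[0]:g}, {t[-1]:g}] s)"
        )
    heats = np.empty(len(t_inj))
    baselines: list[tuple[float, float]] = []
    for i, ti in enumerate(t_inj):
        t_end = ti + schedule.interval
        pre = (t >= ti - _BASELINE_SEGMENT_S) & (t < ti)
        tail = (t >= t_end - _BASELINE_SEGMENT_S) & (t < t_end)
        fit_mask = pre | tail
        slope, intercept = np.polyfit(t[fit_mask], p[fit_mask], 1)
        window = (t >= ti) & (t < t_end)
        baseline = slope * t[window] + intercept
        heats[i] = np.trapezoid(p[window] - baseline, t[window])
        baselines.append((slope, intercept))
    return HeatSeries(heats=heats, baselines=baselines)


def subtract_dilution(sample: HeatSeries, control: HeatSeries) -> HeatSeries:
    """Subtract the heat-of-dilution control, injection by injection."""
    if len(sample.heats) != len(control.heats):
        raise ValueError(
            f"length mismatch: sample has {len(sample.heats)} injections, "
            f"control has {len(control.heats)}"
        )
    return replace(sample, heats=sample.heats - control.heats, baselines=[])


def normalize_enthalpy(
    heats: HeatSeries,
    sa_au_m2: float,
    sa_l_m2: float | None = None,
    injection_index: int | None = None,
) -> NormalizedEnthalpy:
    """Normalise the designated injection heat to the gold surface area.

    By default the first full injection is used (index 1 when the small
    first injection is flagged discardable, else index 0) — the injection
    representing complete interaction.  delta_H = dQ/SA_Au in mJ/m^2.
    When sa_l_m2 is given, the chained form (dQ/SA_L)/(SA_Au/SA_L) is
    verified against the direct quotient (they are identical by algebra).
    """
    if sa_au_m2 <= 0:
        raise ValueError("sa_au_m2 must be > 0")
    if injection_index is None:
        injection_index = 1 if heats.first_discardable else 0
    q_uJ = heats.heats[injection_index]
    delta_H = q_uJ * 1e-6 / sa_au_m2 * 1e3  # uJ -> J, /m^2, -> mJ
    if sa_l_m2 is not None:
        if sa_l_m2 <= 0:
            raise ValueError("sa_l_m2 must be > 0")
        chained = (q_uJ * 1e-6 / sa_l_m2) / (sa_au_m2 / sa_l_m2) * 1e3
        if not np.isclose(chained, delta_H, rtol=1e-12, atol=0.0):
            raise AssertionError("chained normalisation deviates from direct form")
    start = 1 if heats.first_discardable else 0
    mean_q = float(np.mean(heats.heats[start:]))
    delta_H_mean = mean_q * 1e-6 / sa_au_m2 * 1e3
    return NormalizedEnthalpy(
        delta_H=float(delta_H),
        delta_H_mean=delta_H_mean,
        sa_au=sa_au_m2,
        sa_l=sa_l_m2,
    )


def gibbs_identity(
    temperature: float,
    delta_H: float | None = None,
    delta_S: float | None = None,
    delta_G: float | None = None,
) -> float:
    """Solve dG = dH - T*dS for whichever single quantity is omitted.

    Exactly two of (delta_H, delta_S, delta_G) must be given; the missing
    one is returned (J, J/K and J respectively).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    unknowns = [name for name, v in (
        ("delta_H", delta_H), ("delta_S", delta_S), ("delta_G", delta_G)
    ) if v is None]
    if len(unknowns) != 1:
        raise ValueError(
            "exactly one of delta_H, delta_S, delta_G must be omitted "
            f"(got {len(unknowns)} unknowns)"
        )
    if delta_G is None:
        return delta_H - temperature * delta_S
    if delta_H is None:
        return delta_G + temperature * delta_S
    return (delta_H - delta_G) / temperature
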