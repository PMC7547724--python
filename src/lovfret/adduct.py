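"""Adduct-state fraction simulator for arbitrary illumination trains.

Propagates the two-state photocycle piecewise-exponentially: during a
flash of flux f, dA/dt = k_f(1 − A) − A/r with k_f = f/sensitivity, so
A relaxes toward A_eq = k_f/(k_f + k_r) at rate k_app; in darkness A
decays as e^(−t/r). Used to design minimal-light illumination protocols.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .photocycle import PhotocycleParams, equilibrium_fraction, forward_rate

__all__ = [
    "FlashTrain",
    "AdductTrace",
    "PeriodicSteadyState",
    "InvalidTrainError",
    "InfeasibleTargetError",
    "simulate",
    "periodic_steady_state",
    "ode_oracle",
    "instant_flash",
    "design_min_rate",
]


class InvalidTrainError(ValueError):
    """Raised for overlapping or malformed illumination events."""


class InfeasibleTargetError(ValueError):
    """Raised when no flash period can achieve the requested mean fraction."""


@dataclass(frozen=True)
class FlashTrain:
    """An illumination schedule: (start_s, duration_s, flux) events.

    Flux is in µmol m⁻² s⁻¹. Events must be sorted and non-overlapping.
    Construct periodic trains with :meth:`periodic`.
    """

    events: tuple[tuple[float, float, float], ...]
    total_time: float

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for start, duration, flux in self.events:
            if flux < 0:
                raise InvalidTrainError("flux must be >= 0")
            if flux > 0 and duration <= 0:
                raise InvalidTrainError("events with flux > 0 need duration > 0")
            if start < prev_end - 1e-12:
                raise InvalidTrainError("events must be sorted and non-overlapping")
            prev_end = start + duration
        if self.total_time <= 0:
            raise InvalidTrainError("total_time must be positive")

    @classmethod
    def from_events(
        cls, events: Sequence[Sequence[float]], total_time: float | None = None
    ) -> "FlashTrain":
        evs = tuple(
            (float(s), float(d), float(f))
            for s, d, f in sorted(events, key=lambda e: e[0])
        )
        if total_time is None:
            total_time = max(s + d for s, d, _ in evs) if evs else 1.0
        return cls(events=evs, total_time=float(total_time))

    @classmethod
    def periodic(
        cls,
        dose_per_flash: float,
        flash_duration: float,
        period: float,
        count: int,
    ) -> "FlashTrain":
        """Evenly spaced flashes each delivering ``dose_per_flash`` µmol m⁻²."""
        if flash_duration <= 0 or flash_duration >= period:
            raise InvalidTrainError("need 0 < flash_duration < period")
        if count < 1:
            raise InvalidTrainError("count must be >= 1")
        flux = dose_per_flash / flash_duration
        events = tuple(
            (i * period, flash_duration, flux) for i in range(count)
        )
        return cls(events=events, total_time=count * period)

    @classmethod
    def from_json(cls, s: str) -> "FlashTrain":
        d = json.loads(s)
        if "periodic" in d:
            p = d["periodic"]
            return cls.periodic(
                dose_per_flash=p["dose_umol_m2"],
                flash_duration=p["flash_s"],
                period=p["period_s"],
                count=p["count"],
            )
        return cls.from_events(d["events"], d.get("total_time_s"))

    def flux_at(self, t: float) -> float:
        for start, duration, flux in self.events:
            if start <= t < start + duration:
                return flux
        return 0.0

    def segments(self) -> list[tuple[float, float, float]]:
        """Contiguous (start, end, flux) segments covering [0, total_time]."""
        segs: list[tuple[float, float, float]] = []
        cursor = 0.0
        for start, duration, flux in self.events:
            if start >= self.total_time:
                break
            if start > cursor:
                segs.append((cursor, start, 0.0))
            end = min(start + duration, self.total_time)
            if end > start:
                segs.append((start, end, flux))
            cursor = max(cursor, end)
        if cursor < self.total_time:
            segs.append((cursor, self.total_time, 0.0))
        return segs


@dataclass(frozen=True)
class AdductTrace:
    """Simulated adduct-state fraction over time."""

    times: np.ndarray
    fraction: np.ndarray
    params: PhotocycleParams

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.fraction < -1e-12) | (self.fraction > 1 + 1e-12)):
            raise ValueError("fractions must lie in [0, 1]")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"time_s": self.times, "adduct_fraction": self.fraction}
        ).to_csv(path, index=False)


class PeriodicSteadyState(NamedTuple):
    peak: float
    trough: float
    mean: float


def _propagate(A: float, flux: float, dt: float, params: PhotocycleParams) -> float:
    """Exact one-step propagator of the two-state model at constant flux."""
    if flux <= 0:
        return A * math.exp(-dt / params.relaxation_time)
    k_f = forward_rate(flux, params)
    k_app = k_f + params.k_r
    A_eq = k_f / k_app
    return A_eq + (A - A_eq) * math.exp(-k_app * dt)


def simulate(
    train: FlashTrain,
    params: PhotocycleParams,
    dt: float = 0.05,
    A0: float = 0.0,
) -> AdductTrace:
    """Piecewise-exponential simulation of the adduct fraction.

    Steps through the train's constant-flux segments with the exact
    propagator on a grid of spacing ≤ ``dt``. ``A0`` is the initial
    adduct fraction (default fully dark-relaxed).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (0.0 <= A0 <= 1.0):
        raise ValueError("A0 must lie in [0, 1]")
    times = [0.0]
    values = [A0]
    A = A0
    for start, end, flux in train.segments():
        length = end - start
        n = max(1, int(math.ceil(length / dt)))
        step = length / n
        for i in range(n):
            A = _propagate(A, flux, step, params)
            times.append(start + (i + 1) * step)
            values.append(A)
    return AdductTrace(np.asarray(times), np.asarray(values), params)


def periodic_steady_state(
    dose_per_flash: float,
    flash_duration: float,
    period: float,
    params: PhotocycleParams,
) -> PeriodicSteadyState:
    """Closed-form fixed point of the per-cycle propagation map.

    For flashes of duration d every P seconds at flux dose/d the
    steady-state peak (at flash end) is
    A_eq·(1 − e^(−k_app·d)) / (1 − e^(−k_app·d)·e^(−(P−d)/r)), the
    trough is the peak decayed over the dark gap, and the mean is the
    exact integral of the steady-state cycle divided by P.
    """
    if flash_duration <= 0 or flash_duration >= period:
        raise InvalidTrainError("need 0 < flash_duration < period")
    if dose_per_flash < 0:
        raise ValueError("dose_per_flash must be >= 0")
    if dose_per_flash == 0:
        return PeriodicSteadyState(0.0, 0.0, 0.0)
    flux = dose_per_flash / flash_duration
    k_f = forward_rate(flux, params)
    k_r = params.k_r
    k_app = k_f + k_r
    A_eq = k_f / k_app
    d = flash_duration
    gap = period - d
    lit_decay = math.exp(-k_app * d)
    dark_decay = math.exp(-gap / params.relaxation_time)
    peak = A_eq * (1.0 - lit_decay) / (1.0 - lit_decay * dark_decay)
    trough = peak * dark_decay
    # exact integrals: lit phase starts at trough, dark phase at peak
    lit_integral = A_eq * d + (trough - A_eq) * (1.0 - lit_decay) / k_app
    dark_integral = peak * params.relaxation_time * (1.0 - dark_decay)
    mean = (lit_integral + dark_integral) / period
    return PeriodicSteadyState(peak=peak, trough=trough, mean=mean)


def ode_oracle(
    train: FlashTrain,
    params: PhotocycleParams,
    dt: float = 0.001,
    A0: float = 0.0,
) -> AdductTrace:
    """Brute-force RK4 integration of dA/dt = k_f(t)(1 − A) − A/r.

    Deliberately independent of :func:`simulate`; intended for tests.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")

    k_r = params.k_r

    times = [0.0]
    values = [A0]
    A = A0
    for start, end, flux in train.segments():
        k_f = forward_rate(flux, params)

        def deriv(a: float) -> float:
            return k_f * (1.0 - a) - k_r * a

        length = end - start
        n = max(1, int(math.ceil(length / dt)))
        step = length / n
        for i in range(n):
            k1 = deriv(A)
            k2 = deriv(A + 0.5 * step * k1)
            k3 = deriv(A + 0.5 * step * k2)
            k4 = deriv(A + step * k3)
            A = A + step * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            times.append(start + (i + 1) * step)
            values.append(A)
    return AdductTrace(np.asarray(times), np.asarray(values), params)


def instant_flash(A: float, dose: float, params: PhotocycleParams) -> float:
    """Instantaneous-dose update A += (1 − A)·(1 − e^(−dose/sens)).

    Limit of a brief intense flash (duration ≪ r), appropriate for the
    10–300 ms microscope exposures.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return A + (1.0 - A) * (1.0 - math.exp(-dose / params.sensitivity))


def design_min_rate(
    params: PhotocycleParams,
    dose_per_flash: float,
    flash_duration: float,
    target_mean_fraction: float,
    period_cap: float = 1e6,
) -> float:
    """Longest flash period whose steady-state mean fraction meets target.

    Returns ``math.inf`` for a zero target (no illumination needed).
    Raises :class:`InfeasibleTargetError` if even back-to-back flashing
    cannot reach the target mean.
    """
    if target_mean_fraction < 0:
        raise ValueError("target must be >= 0")
    if target_mean_fraction == 0:
        return math.inf

    def mean_at(period: float) -> float:
        return periodic_steady_state(
            dose_per_flash, flash_duration, period, params
        ).mean

    lo = flash_duration * (1.0 + 1e-9)
    if mean_at(lo * (1.0 + 1e-6)) < target_mean_fraction:
        raise InfeasibleTargetError(
            "target mean fraction unreachable even with continuous flashing"
        )
    hi = lo * 2
    while mean_at(hi) >= target_mean_fraction:
        hi *= 2
        if hi > period_cap:
            return period_cap
    # mean is monotone decreasing in period: bisect
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_at(mid) >= target_mean_fraction:
            lo = mid
        else:
            hi = mid
    return lo
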