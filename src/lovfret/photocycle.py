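"""First-order reversible photocycle model and closed-form trace equations.

The actuator is approximated as a two-state switch: a dark ground state
and an activated adduct state. Blue light drives the forward transition
at rate k_f = flux / sensitivity; thermal relaxation returns the switch
at rate k_r = 1 / relaxation_time. The apparent rate under illumination
is k_app = k_f + k_r, and the equilibrium activated fraction is
k_f / (k_f + k_r).

Fluorescence readout depends on whether the fused fluorophore acts as a
RET donor (quenched in the dark state, so activation *de*quenches it) or
as a RET acceptor (sensitized in the dark state, so activation quenches
it). Both trace equations live here; all fitting and simulation code
references these closed forms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Mode",
    "ModeMismatchError",
    "PhotocycleParams",
    "TraceModelParams",
    "CycleExponentialParams",
    "forward_rate",
    "apparent_rate",
    "equilibrium_fraction",
    "apparent_sensitivity",
    "ed50",
    "dequench_trace",
    "quench_trace",
    "dose_series_trace",
    "cycle_exponential",
    "dark_recovery_amplitude",
    "max_dequench_percent",
    "DEFAULT_FLASH_RATE_HZ",
    "FIRST_DARK_SENTINEL_S",
]

Mode = str  # "donor" | "acceptor"

#: Default flash rate matching the ~4 Hz imaging protocols.
DEFAULT_FLASH_RATE_HZ = 4.0

#: Effective dark time assigned to the first cycle of a session
#: (wells are revisited no sooner than 10 min, far above any measured
#: relaxation time, so the first cycle starts fully relaxed).
FIRST_DARK_SENTINEL_S = 600.0


class ModeMismatchError(ValueError):
    """Raised when a donor-mode equation receives acceptor-mode parameters
    or vice versa."""


@dataclass(frozen=True)
class PhotocycleParams:
    """A construct's switch constants.

    Parameters
    ----------
    sensitivity : float
        Photon dose (µmol m⁻²) producing unit forward drive; the forward
        rate under flux f is f / sensitivity.
    relaxation_time : float
        Dark relaxation time constant r in seconds; k_r = 1 / r.
    transfer_limit : float
        Maximal fractional fluorescence change attributable to RET, in
        [0, 1] (dequench limit for donors, quench limit for acceptors).
    mode : {"donor", "acceptor"}
    """

    sensitivity: float
    relaxation_time: float
    transfer_limit: float = 0.0
    mode: Mode = "donor"

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.relaxation_time <= 0:
            raise ValueError("relaxation_time must be positive")
        if not (0.0 <= self.transfer_limit <= 1.0):
            raise ValueError("transfer_limit must lie in [0, 1]")
        if self.mode not in ("donor", "acceptor"):
            raise ValueError(f"mode must be 'donor' or 'acceptor', got {self.mode!r}")

    @property
    def k_r(self) -> float:
        """Reverse (relaxation) rate constant, s⁻¹."""
        return 1.0 / self.relaxation_time

    def to_dict(self) -> dict:
        return {
            "sensitivity_umol_m2": self.sensitivity,
            "relaxation_s": self.relaxation_time,
            "transfer_limit_frac": self.transfer_limit,
            "mode": self.mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhotocycleParams":
        return cls(
            sensitivity=d["sensitivity_umol_m2"],
            relaxation_time=d["relaxation_s"],
            transfer_limit=d.get("transfer_limit_frac", 0.0),
            mode=d.get("mode", "donor"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "PhotocycleParams":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class TraceModelParams:
    """Photocycle constants plus the trace-level nuisance parameters."""

    photocycle: PhotocycleParams
    offset: float = 1.0
    flash_rate: float = DEFAULT_FLASH_RATE_HZ
    dose_per_flash: float = 14.0

    def __post_init__(self) -> None:
        if self.offset <= 0:
            raise ValueError("offset must be positive")
        if self.flash_rate <= 0:
            raise ValueError("flash_rate must be positive")
        if self.dose_per_flash < 0:
            raise ValueError("dose_per_flash must be >= 0")

    @property
    def flux(self) -> float:
        """Time-averaged photon flux during illumination, µmol m⁻² s⁻¹."""
        return self.flash_rate * self.dose_per_flash


@dataclass(frozen=True)
class CycleExponentialParams:
    """Per-cycle exponential description of repeated (de)quench cycles.

    ``tau_flashes`` is the shared activation constant in units of
    flashes; ``amplitudes`` holds one recovery amplitude per cycle.
    """

    F_limit: float
    amplitudes: Sequence[float]
    tau_flashes: float
    A0: float | None = None
    r: float | None = None

    def __post_init__(self) -> None:
        if self.tau_flashes <= 0:
            raise ValueError("tau_flashes must be positive")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be >= 0")


def forward_rate(flux: float, params: PhotocycleParams) -> float:
    """Forward rate constant k_f = flux / sensitivity, s⁻¹."""
    if flux < 0:
        raise ValueError("flux must be >= 0")
    return flux / params.sensitivity


def apparent_rate(flux: float, params: PhotocycleParams) -> float:
    """Apparent switching rate k_app = k_f + k_r under flux, s⁻¹."""
    return forward_rate(flux, params) + params.k_r


def equilibrium_fraction(flux: float, params: PhotocycleParams) -> float:
    """Activated fraction at photostationary equilibrium, k_f/(k_f + k_r)."""
    k_f = forward_rate(flux, params)
    return k_f / (k_f + params.k_r)


def apparent_sensitivity(flux: float, params: PhotocycleParams) -> float:
    """Observed (relaxation-contaminated) activation dose scale.

    Equals flux / k_app; always strictly below the intrinsic sensitivity
    because concurrent relaxation speeds up the approach to equilibrium.
    """
    if flux <= 0:
        raise ValueError("flux must be positive")
    return flux / apparent_rate(flux, params)


def ed50(params: PhotocycleParams, flash_rate: float = DEFAULT_FLASH_RATE_HZ) -> float:
    """Per-flash photon dose at which k_f = k_r (half-maximal switching).

    Returns sensitivity / (flash_rate × relaxation_time), in µmol m⁻²
    per flash at the given flash rate.
    """
    if flash_rate <= 0:
        raise ValueError("flash_rate must be positive")
    return params.sensitivity / (flash_rate * params.relaxation_time)


def _cycle_kernel(model: TraceModelParams, reading_index, dark_time):
    """Shared core of the cycle trace equations.

    Returns (scaled equilibrium amplitude, approach factor) where the
    approach factor is 1 − (1 − e^(−t/r))·e^(−k_app·x / flash_rate).
    """
    p = model.photocycle
    k_app = apparent_rate(model.flux, p)
    eq = equilibrium_fraction(model.flux, p)
    x = np.asarray(reading_index, dtype=float)
    t = np.asarray(dark_time, dtype=float)
    if np.any(x < 0):
        raise ValueError("reading_index must be >= 0")
    if np.any(t < 0):
        raise ValueError("dark_time must be >= 0")
    recovered = 1.0 - np.exp(-t / p.relaxation_time)
    approach = 1.0 - recovered * np.exp(-k_app * x / model.flash_rate)
    return p.transfer_limit * eq, approach


def dequench_trace(model: TraceModelParams, reading_index, dark_time):
    """Donor-mode normalized fluorescence at a reading within a cycle.

    Y = Offset·(1 − D_limit + D_max·(1 − (1 − e^(−t/r))·e^(−k_app·x/rate)))
    with D_max = D_limit·k_f/(k_f + k_r). Rises from the relaxed,
    maximally quenched level toward the illumination equilibrium.
    """
    if model.photocycle.mode != "donor":
        raise ModeMismatchError("dequench_trace requires donor-mode parameters")
    d_max, approach = _cycle_kernel(model, reading_index, dark_time)
    return model.offset * (1.0 - model.photocycle.transfer_limit + d_max * approach)


def quench_trace(model: TraceModelParams, reading_index, dark_time):
    """Acceptor-mode mirror of :func:`dequench_trace`.

    Y = Offset·(1 − Q_max·(1 − (1 − e^(−t/r))·e^(−k_app·x/rate))); falls
    from the fully sensitized bright level toward the illumination
    equilibrium.
    """
    if model.photocycle.mode != "acceptor":
        raise ModeMismatchError("quench_trace requires acceptor-mode parameters")
    q_max, approach = _cycle_kernel(model, reading_index, dark_time)
    return model.offset * (1.0 - q_max * approach)


def dose_series_trace(model: TraceModelParams, reading_index):
    """Single activation ramp from the fully relaxed state (dark → lit).

    Donor mode: F = Offset·(1 − D_limit + D_max·(1 − e^(−k_app·x/rate)));
    acceptor mode: F = Offset·(1 − Q_max·(1 − e^(−k_app·x/rate))). This
    is the dark_time → ∞ single-cycle special case used for variable-dose
    activation series.
    """
    if model.photocycle.mode == "donor":
        return dequench_trace(model, reading_index, np.inf)
    return quench_trace(model, reading_index, np.inf)


def cycle_exponential(params: CycleExponentialParams, cycle: int, reading):
    """Per-cycle exponential F[x] = F_limit − A[cycle]·e^(−x/Tau)."""
    amps = params.amplitudes
    if not (0 <= cycle < len(amps)):
        raise IndexError(f"cycle {cycle} out of range for {len(amps)} amplitudes")
    x = np.asarray(reading, dtype=float)
    if np.any(x < 0):
        raise ValueError("reading must be >= 0")
    return params.F_limit - amps[cycle] * np.exp(-x / params.tau_flashes)


def dark_recovery_amplitude(A0: float, r: float, dark_time):
    """Recovery amplitude after a dark period: A[t] = A0·(1 − e^(−t/r))."""
    if r <= 0:
        raise ValueError("relaxation time must be positive")
    t = np.asarray(dark_time, dtype=float)
    if np.any(t < 0):
        raise ValueError("dark_time must be >= 0")
    return A0 * (1.0 - np.exp(-t / r))


def max_dequench_percent(A0: float) -> float:
    """Maximal dequench as a percentage: 100·A0 / (1 + A0).

    A0 is the fitted maximal fractional fluorescence increase on full
    relaxation; referred to the maximal (dequenched) fluorescence this
    is A0 / (1 + A0).
    """
    if A0 < 0:
        raise ValueError("A0 must be >= 0")
    return 100.0 * A0 / (1.0 + A0)
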