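"""Seeded synthetic-data generators for every pipeline input.

Each generator is a pure function of its spec (seed included) and emits
data with the statistical structure the analysis assumes: model-exact
signal, multiplicative photobleaching shared with a matched LOV2-free
control, and additive homoscedastic Gaussian noise on the normalized
intensity scale. Defaults emulate the imaging protocols the fitters
were designed around (20 flashes of 14 µmol m⁻² at 4 Hz, 12 dark
periods spanning 1–180 s, 3 replicate repeats).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .fitting import CycleTraceSet
from .photocycle import (
    DEFAULT_FLASH_RATE_HZ,
    FIRST_DARK_SENTINEL_S,
    PhotocycleParams,
    TraceModelParams,
    dequench_trace,
    quench_trace,
)
from .translocation import RatioSeries

__all__ = [
    "CycleProtocol",
    "GeneratorSpec",
    "default_dark_times",
    "gen_cycle_traces",
    "gen_dark_recovery_plate",
    "gen_translocation_ratios",
    "gen_reporter_series",
]


def default_dark_times(
    n: int = 12, t_min: float = 1.0, t_max: float = 180.0
) -> np.ndarray:
    """Log-spaced dark-period schedule, preceded by the 600 s sentinel.

    The first cycle of a session starts effectively fully relaxed (wells
    are revisited no sooner than 10 min), encoded as a 600 s dark time.
    """
    return np.concatenate([[FIRST_DARK_SENTINEL_S], np.geomspace(t_min, t_max, n)])


@dataclass(frozen=True)
class CycleProtocol:
    """Repeated dequench/requench cycling protocol."""

    dark_times: tuple[float, ...] = tuple(default_dark_times())
    readings_per_cycle: int = 20
    dose_per_flash: float = 14.0
    flash_rate: float = DEFAULT_FLASH_RATE_HZ

    def __post_init__(self) -> None:
        if self.readings_per_cycle < 3:
            raise ValueError("need >= 3 readings per cycle")
        if any(t < 0 for t in self.dark_times):
            raise ValueError("dark times must be >= 0")


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground truth + protocol + noise model for a synthetic dataset."""

    truth: Any
    protocol: Any = None
    noise_sd: float = 0.004
    bleach_per_reading: float = 0.0
    n_replicates: int = 3
    seed: int = 0
    control_fast_quench: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.bleach_per_reading < 1.0):
            raise ValueError("bleach_per_reading must lie in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def gen_cycle_traces(spec: GeneratorSpec) -> CycleTraceSet:
    """Dequench/requench cycle traces with a matched control.

    The noise-free construct signal follows the closed-form cycle trace
    for ``spec.truth`` (a :class:`PhotocycleParams`); both construct and
    control are multiplied by the same cumulative per-reading bleach
    factor, then receive independent Gaussian noise. The optional
    ``control_fast_quench`` adds a small control-only fast decay to
    exercise imperfect correction.
    """
    truth: PhotocycleParams = spec.truth
    proto: CycleProtocol = spec.protocol or CycleProtocol()
    rng = np.random.default_rng(spec.seed)
    model = TraceModelParams(
        truth,
        offset=1.0,
        flash_rate=proto.flash_rate,
        dose_per_flash=proto.dose_per_flash,
    )
    trace_fn = dequench_trace if truth.mode == "donor" else quench_trace

    n_cycles = len(proto.dark_times)
    readings = np.arange(proto.readings_per_cycle)
    cyc_idx, read_idx, rep_idx = [], [], []
    signal, control = [], []
    for rep in range(spec.n_replicates):
        global_reading = 0
        for c, dark in enumerate(proto.dark_times):
            clean = trace_fn(model, readings, dark)
            for j, value in enumerate(np.atleast_1d(clean)):
                bleach = (1.0 - spec.bleach_per_reading) ** global_reading
                ctrl = bleach
                if spec.control_fast_quench > 0:
                    ctrl *= 1.0 - spec.control_fast_quench * (
                        1.0 - np.exp(-global_reading / 3.0)
                    )
                cyc_idx.append(c)
                read_idx.append(j)
                rep_idx.append(rep)
                signal.append(value * bleach)
                control.append(ctrl)
                global_reading += 1
    signal = np.asarray(signal)
    control = np.asarray(control)
    signal = signal + rng.normal(0.0, spec.noise_sd, len(signal)) * signal
    control = control + rng.normal(0.0, spec.noise_sd, len(control)) * control
    return CycleTraceSet(
        cycle_index=np.asarray(cyc_idx),
        reading_index=np.asarray(read_idx),
        intensity=signal,
        dark_times=np.asarray(proto.dark_times),
        dose_per_flash=proto.dose_per_flash,
        flash_rate=proto.flash_rate,
        replicate=np.asarray(rep_idx),
        control_intensity=control,
        mode=truth.mode,
    )


def gen_dark_recovery_plate(
    spec: GeneratorSpec,
    n_cycles: int = 20,
    cycle_time_s: float = 3.0,
    A0: float = 0.19,
) -> pd.DataFrame:
    """Post-illumination dequench-recovery traces from a plate protocol.

    Signal rises from the freshly activated (quenched) level toward the
    dark-state plateau with the truth's relaxation time constant:
    F(t) = 1 + A0·(1 − e^(−t/r)). Returns a long-format frame with
    columns replicate, time_s, intensity.
    """
    truth: PhotocycleParams = spec.truth
    rng = np.random.default_rng(spec.seed)
    t = np.arange(n_cycles) * cycle_time_s
    rows = []
    for rep in range(spec.n_replicates):
        clean = 1.0 + A0 * (1.0 - np.exp(-t / truth.relaxation_time))
        noisy = clean + rng.normal(0.0, spec.noise_sd, len(t)) * clean
        rows.append(
            pd.DataFrame({"replicate": rep, "time_s": t, "intensity": noisy})
        )
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class DoseResponseTruth:
    """Saturating per-flash export-rate truth for translocation series."""

    max_rate: float = 0.03  # ratio change per flash at saturating dose
    ed50: float = 48.0  # µmol m⁻² per flash
    baseline_ratio: float = 2.37

    def rate_at(self, dose: float) -> float:
        return self.max_rate * dose / (self.ed50 + dose)


def gen_translocation_ratios(
    spec: GeneratorSpec,
    doses: Sequence[float] = (14.0, 42.0, 140.0, 420.0),
    n_flashes: int = 10,
) -> dict[float, list[RatioSeries]]:
    """Nucleocytoplasmic ratio series during flash trains, per dose.

    The ratio declines linearly during a train at the truth's saturating
    per-flash rate; each replicate gets independent noise. Returns
    ``{dose: [RatioSeries per replicate]}``.
    """
    truth: DoseResponseTruth = spec.truth
    rng = np.random.default_rng(spec.seed)
    out: dict[float, list[RatioSeries]] = {}
    for dose in doses:
        slope = truth.rate_at(dose)
        series = []
        for rep in range(spec.n_replicates):
            flashes = np.arange(n_flashes)
            clean = truth.baseline_ratio - slope * flashes
            noisy = clean + rng.normal(0.0, spec.noise_sd, n_flashes)
            noisy = np.clip(noisy, 1e-6, None)
            series.append(
                RatioSeries(
                    time_s=flashes.astype(float),
                    nc_ratio=noisy,
                    reading_index=flashes,
                    dose_per_flash=dose,
                    sample_id=f"well{rep}",
                )
            )
        out[dose] = series
    return out


@dataclass(frozen=True)
class ReporterTruth:
    """Piecewise lit/dark reporter kinetics truth."""

    floor: float = 1.0
    span: float = 0.8
    tau_lit: float = 300.0
    tau_dark: float = 300.0


def gen_reporter_series(
    spec: GeneratorSpec,
    phase_durations: Sequence[tuple[str, float]] = (
        ("lit", 1200.0),
        ("dark", 1200.0),
        ("lit", 1200.0),
        ("dark", 1200.0),
    ),
    points_per_phase: int = 15,
) -> list[RatioSeries]:
    """Alternating lit/dark reporter curves with seeded noise.

    Lit phases decay from floor+span toward floor with tau_lit; dark
    phases recover with tau_dark. One series per replicate.
    """
    truth: ReporterTruth = spec.truth
    rng = np.random.default_rng(spec.seed)
    out = []
    for rep in range(spec.n_replicates):
        times, ratios, labels = [], [], []
        t0 = 0.0
        for label, duration in phase_durations:
            t_rel = np.linspace(0.0, duration, points_per_phase)
            if label == "lit":
                clean = truth.floor + truth.span * np.exp(-t_rel / truth.tau_lit)
            elif label == "dark":
                clean = truth.floor + truth.span * (
                    1.0 - np.exp(-t_rel / truth.tau_dark)
                )
            else:
                raise ValueError(f"unknown phase label {label!r}")
            noisy = clean + rng.normal(0.0, spec.noise_sd, points_per_phase)
            times.extend(t0 + t_rel)
            ratios.extend(np.clip(noisy, 1e-6, None))
            labels.extend([label] * points_per_phase)
            t0 += duration
        out.append(
            RatioSeries(
                time_s=np.asarray(times),
                nc_ratio=np.asarray(ratios),
                phase=np.asarray(labels, dtype=object),
                sample_id=f"rep{rep}",
            )
        )
    return out
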