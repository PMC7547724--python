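"""Shared-parameter nonlinear least-squares fitting of normalized traces.

Implements the full trace-analysis pipeline: control normalization, the
two-stage per-cycle-exponential → dark-relaxation fit, the global
four-parameter switch fit, the variable-dose reversible-kinetics fit,
the single-site dose-response fit, and the model-comparison statistics
(extra-sum-of-squares F-test, Holm–Šidák step-down).

All fits minimize unweighted squared residuals on the normalized
intensity scale with a trust-region reflective solver; standard errors
come from the inverse curvature at the optimum scaled by ssr/dof
(symmetric, as in conventional curve-fitting reports).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .photocycle import (
    DEFAULT_FLASH_RATE_HZ,
    PhotocycleParams,
    TraceModelParams,
    apparent_sensitivity,
    dequench_trace,
    dose_series_trace,
    ed50,
    equilibrium_fraction,
    max_dequench_percent,
    quench_trace,
)

__all__ = [
    "CycleTraceSet",
    "FitResult",
    "InsufficientDataError",
    "ConvergenceError",
    "ProtocolMismatchError",
    "DegenerateControlError",
    "DegenerateFitError",
    "InvalidComparisonError",
    "normalize_to_control",
    "average_replicates",
    "fit_cycle_exponentials",
    "fit_dark_relaxation",
    "fit_global_switch",
    "fit_reversible_dose_series",
    "fit_single_site",
    "nested_f_test",
    "holm_sidak",
    "TRACE_CSV_COLUMNS",
]

TRACE_CSV_COLUMNS = [
    "sample_id",
    "construct",
    "is_control",
    "cycle_index",
    "reading_index",
    "dark_time_s",
    "dose_per_flash_umol_m2",
    "flash_rate_hz",
    "intensity_au",
]


class InsufficientDataError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


class ProtocolMismatchError(ValueError):
    pass


class DegenerateControlError(ValueError):
    pass


class DegenerateFitError(ValueError):
    pass


class InvalidComparisonError(ValueError):
    pass


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class CycleTraceSet:
    """Fluorescence readings organized as activation cycles.

    Per-reading arrays are aligned: ``cycle_index``, ``reading_index``,
    ``intensity`` and (optionally) ``replicate`` and
    ``control_intensity`` all have one entry per reading.
    ``dark_times`` has one entry per cycle (the dark period preceding
    that cycle).
    """

    cycle_index: np.ndarray
    reading_index: np.ndarray
    intensity: np.ndarray
    dark_times: np.ndarray
    dose_per_flash: float
    flash_rate: float = DEFAULT_FLASH_RATE_HZ
    replicate: np.ndarray | None = None
    control_intensity: np.ndarray | None = None
    normalized: bool = False
    mode: str = "donor"

    def __post_init__(self) -> None:
        self.cycle_index = np.asarray(self.cycle_index, dtype=int)
        self.reading_index = np.asarray(self.reading_index, dtype=int)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.dark_times = np.asarray(self.dark_times, dtype=float)
        n = len(self.intensity)
        if len(self.cycle_index) != n or len(self.reading_index) != n:
            raise ValueError("per-reading arrays must be aligned")
        cycles = np.unique(self.cycle_index)
        if len(self.dark_times) != len(cycles):
            raise ProtocolMismatchError(
                f"dark_times has {len(self.dark_times)} entries for "
                f"{len(cycles)} cycles"
            )
        for c in cycles:
            if np.sum(self.cycle_index == c) < 3:
                raise ValueError(f"cycle {c} has fewer than 3 readings")
        if not self.normalized and np.any(self.intensity <= 0):
            raise ValueError("raw intensities must be positive")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate, dtype=int)
            if len(self.replicate) != n:
                raise ValueError("replicate must be aligned with readings")
        if self.control_intensity is not None:
            self.control_intensity = np.asarray(self.control_intensity, dtype=float)
            if len(self.control_intensity) != n:
                raise ProtocolMismatchError(
                    "control trace length does not match readings"
                )

    @property
    def n_cycles(self) -> int:
        return len(np.unique(self.cycle_index))

    def to_dataframe(
        self, sample_id: str = "s1", construct: str = "construct"
    ) -> pd.DataFrame:
        dark = self.dark_times[
            np.searchsorted(np.unique(self.cycle_index), self.cycle_index)
        ]
        rep = self.replicate if self.replicate is not None else np.zeros(
            len(self.intensity), dtype=int
        )
        rows = pd.DataFrame(
            {
                "sample_id": [f"{sample_id}_r{r}" for r in rep],
                "construct": construct,
                "is_control": 0,
                "cycle_index": self.cycle_index,
                "reading_index": self.reading_index,
                "dark_time_s": dark,
                "dose_per_flash_umol_m2": self.dose_per_flash,
                "flash_rate_hz": self.flash_rate,
                "intensity_au": self.intensity,
            }
        )
        if self.control_intensity is not None:
            ctrl = rows.copy()
            ctrl["is_control"] = 1
            ctrl["intensity_au"] = self.control_intensity
            rows = pd.concat([rows, ctrl], ignore_index=True)
        return rows[TRACE_CSV_COLUMNS]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, mode: str = "donor") -> "CycleTraceSet":
        missing = [c for c in TRACE_CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ProtocolMismatchError(f"missing trace columns: {missing}")
        main = df[df["is_control"] == 0].reset_index(drop=True)
        ctrl = df[df["is_control"] == 1].reset_index(drop=True)
        if main.empty:
            raise InsufficientDataError("no non-control readings in frame")
        key = ["sample_id", "cycle_index", "reading_index"]
        main = main.sort_values(key, kind="stable").reset_index(drop=True)
        control = None
        if not ctrl.empty:
            ctrl = ctrl.sort_values(key, kind="stable").reset_index(drop=True)
            if len(ctrl) != len(main):
                raise ProtocolMismatchError(
                    "control readings do not match main trace readings"
                )
            control = ctrl["intensity_au"].to_numpy()
        dark = (
            main.groupby("cycle_index")["dark_time_s"].first().sort_index().to_numpy()
        )
        rep_codes = pd.factorize(main["sample_id"])[0]
        return cls(
            cycle_index=main["cycle_index"].to_numpy(),
            reading_index=main["reading_index"].to_numpy(),
            intensity=main["intensity_au"].to_numpy(),
            dark_times=dark,
            dose_per_flash=float(main["dose_per_flash_umol_m2"].iloc[0]),
            flash_rate=float(main["flash_rate_hz"].iloc[0]),
            replicate=rep_codes,
            control_intensity=control,
            mode=mode,
        )


@dataclass
class FitResult:
    """Best-fit parameters with standard errors and fit diagnostics."""

    model: str
    params: dict[str, tuple[float, float]]
    dof: int
    ssr: float
    n_points: int
    converged: bool
    derived: dict[str, tuple[float, float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    cov: np.ndarray | None = None
    param_order: list[str] = field(default_factory=list)

    def value(self, name: str) -> float:
        return self.params[name][0]

    def se(self, name: str) -> float:
        return self.params[name][1]

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {
                k: {"best_fit": v, "se": s} for k, (v, s) in self.params.items()
            },
            "derived": {
                k: {"best_fit": v, "se": s} for k, (v, s) in self.derived.items()
            },
            "ssr": self.ssr,
            "dof": self.dof,
            "n_points": self.n_points,
            "converged": self.converged,
            "flags": self.flags,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            model=d["model"],
            params={k: (v["best_fit"], v["se"]) for k, v in d["params"].items()},
            dof=d["dof"],
            ssr=d["ssr"],
            n_points=d["n_points"],
            converged=d["converged"],
            derived={
                k: (v["best_fit"], v["se"]) for k, v in d.get("derived", {}).items()
            },
            flags=list(d.get("flags", [])),
        )

    @classmethod
    def from_json(cls, s: str) -> "FitResult":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# generic least-squares machinery
# ---------------------------------------------------------------------------

_MAX_NFEV = 20000
_GTOL = 1e-12


def _run_least_squares(
    residual: Callable[[np.ndarray], np.ndarray],
    starts: Sequence[np.ndarray],
    bounds: tuple[np.ndarray, np.ndarray],
    names: Sequence[str],
    model: str,
) -> FitResult:
    """Multi-start trust-region least squares with curvature-based SEs."""
    lo, hi = bounds
    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lo + 1e-12, hi - 1e-12)
        try:
            sol = optimize.least_squares(
                residual,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=_GTOL,
                max_nfev=_MAX_NFEV,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ConvergenceError(f"{model}: no start point converged")
    n = len(best.fun)
    k = len(best.x)
    dof = n - k
    if dof <= 0:
        raise InsufficientDataError(
            f"{model}: {n} points cannot constrain {k} parameters"
        )
    ssr = float(2 * best.cost)
    J = best.jac
    # Moore–Penrose guards against rank deficiency at the optimum
    JTJ = J.T @ J
    cov = np.linalg.pinv(JTJ) * (ssr / dof)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    flags: list[str] = []
    tol = 1e-8
    for i, name in enumerate(names):
        at_lo = np.isfinite(lo[i]) and abs(best.x[i] - lo[i]) < tol * max(
            1.0, abs(lo[i])
        )
        at_hi = np.isfinite(hi[i]) and abs(best.x[i] - hi[i]) < tol * max(
            1.0, abs(hi[i])
        )
        if at_lo or at_hi:
            flags.append(f"boundary:{name}")
    if np.linalg.matrix_rank(JTJ) < k:
        flags.append("rank_deficient")
    return FitResult(
        model=model,
        params={name: (float(v), float(s)) for name, v, s in zip(names, best.x, se)},
        dof=dof,
        ssr=ssr,
        n_points=n,
        converged=bool(best.status > 0),
        flags=flags,
        cov=cov,
        param_order=list(names),
    )


def _delta_se(
    fit: FitResult, func: Callable[[np.ndarray], float], eps: float = 1e-6
) -> float:
    """Delta-method SE of a scalar function of the fitted parameters."""
    if fit.cov is None:
        return float("nan")
    x = np.array([fit.value(n) for n in fit.param_order])
    grad = np.zeros_like(x)
    for i in range(len(x)):
        h = eps * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        grad[i] = (func(xp) - func(xm)) / (2 * h)
    var = float(grad @ fit.cov @ grad)
    return math.sqrt(max(var, 0.0))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def average_replicates(traces: CycleTraceSet) -> CycleTraceSet:
    """Average replicate repeats per (cycle, reading) before fitting."""
    if traces.replicate is None or len(np.unique(traces.replicate)) == 1:
        return traces
    df = pd.DataFrame(
        {
            "cycle": traces.cycle_index,
            "reading": traces.reading_index,
            "y": traces.intensity,
        }
    )
    if traces.control_intensity is not None:
        df["ctrl"] = traces.control_intensity
    agg = df.groupby(["cycle", "reading"], as_index=False).mean()
    agg = agg.sort_values(["cycle", "reading"]).reset_index(drop=True)
    return CycleTraceSet(
        cycle_index=agg["cycle"].to_numpy(),
        reading_index=agg["reading"].to_numpy(),
        intensity=agg["y"].to_numpy(),
        dark_times=traces.dark_times,
        dose_per_flash=traces.dose_per_flash,
        flash_rate=traces.flash_rate,
        control_intensity=agg["ctrl"].to_numpy() if "ctrl" in agg else None,
        normalized=traces.normalized,
        mode=traces.mode,
    )


def normalize_to_control(traces: CycleTraceSet) -> CycleTraceSet:
    """Divide by the replicate-averaged control trace, then by the first point.

    The control (a LOV2-free fluorophore exposed to the identical
    illumination protocol) carries the same photobleaching trajectory,
    so pointwise division cancels bleach; the subsequent division by the
    first retained data point anchors the trace at 1.
    """
    if traces.control_intensity is None:
        raise DegenerateControlError("no control trace present")
    if np.any(traces.control_intensity <= 0):
        raise DegenerateControlError("control trace contains non-positive values")
    df = pd.DataFrame(
        {
            "cycle": traces.cycle_index,
            "reading": traces.reading_index,
            "ctrl": traces.control_intensity,
        }
    )
    mean_ctrl = df.groupby(["cycle", "reading"])["ctrl"].transform("mean").to_numpy()
    corrected = traces.intensity / mean_ctrl
    # anchor at the first reading of the first cycle (replicate-averaged)
    first_cycle = traces.cycle_index.min()
    first_reading = traces.reading_index[traces.cycle_index == first_cycle].min()
    anchor_mask = (traces.cycle_index == first_cycle) & (
        traces.reading_index == first_reading
    )
    anchor = corrected[anchor_mask].mean()
    if anchor == 0:
        raise DegenerateControlError("degenerate normalization anchor")
    return CycleTraceSet(
        cycle_index=traces.cycle_index.copy(),
        reading_index=traces.reading_index.copy(),
        intensity=corrected / anchor,
        dark_times=traces.dark_times.copy(),
        dose_per_flash=traces.dose_per_flash,
        flash_rate=traces.flash_rate,
        replicate=None if traces.replicate is None else traces.replicate.copy(),
        control_intensity=None,
        normalized=True,
        mode=traces.mode,
    )


# ---------------------------------------------------------------------------
# two-stage pipeline: per-cycle exponentials then dark relaxation
# ---------------------------------------------------------------------------


def _maybe_average(traces: CycleTraceSet, average: bool) -> CycleTraceSet:
    return average_replicates(traces) if average else traces


def fit_cycle_exponentials(
    traces: CycleTraceSet,
    drop_first: bool = False,
    average: bool = True,
) -> FitResult:
    """Fit F[x] = F_limit − A[cycle]·e^(−x/Tau), shared Tau and F_limit.

    One amplitude per cycle; Tau is in units of flashes (readings).
    ``drop_first`` discards the first reading of each cycle.
    """
    ts = _maybe_average(traces, average)
    cycles = np.unique(ts.cycle_index)
    x = ts.reading_index.astype(float)
    y = ts.intensity.copy()
    keep = np.ones(len(y), dtype=bool)
    if drop_first:
        for c in cycles:
            m = ts.cycle_index == c
            keep &= ~(m & (ts.reading_index == ts.reading_index[m].min()))
    x, y, cyc = x[keep], y[keep], ts.cycle_index[keep]
    n_cycles = len(cycles)
    cyc_pos = np.searchsorted(cycles, cyc)

    names = ["F_limit", "tau_flashes"] + [f"A[{c}]" for c in cycles]

    def residual(theta: np.ndarray) -> np.ndarray:
        f_limit, tau = theta[0], theta[1]
        amps = theta[2:]
        return f_limit - amps[cyc_pos] * np.exp(-x / tau) - y

    f0 = float(np.max(y))
    amp0 = np.array(
        [max(f0 - y[cyc == c].min(), 1e-6) for c in cycles]
    )
    # Tau heuristic: log-linear regression of (F_limit − y) on early readings
    tau0 = _tau_heuristic(x, y, cyc_pos, f0, n_cycles)
    span = max(float(np.ptp(y)), 1e-6)
    starts = [
        np.concatenate([[f0, tau0], amp0]),
        np.concatenate([[f0 * 1.02, max(x.max() / 3.0, 1.0)], amp0]),
        np.concatenate([[f0 + span, 2.0], np.full(n_cycles, span)]),
    ]
    lo = np.concatenate([[1e-12, 1e-6], np.zeros(n_cycles)])
    hi = np.concatenate([[np.inf, np.inf], np.full(n_cycles, np.inf)])
    fit = _run_least_squares(residual, starts, (lo, hi), names, "cycle_exponentials")
    if n_cycles < 2:
        fit.flags.append("single_cycle")
    return fit


def _tau_heuristic(x, y, cyc_pos, f_limit, n_cycles) -> float:
    resid = np.clip(f_limit * (1.0 + 1e-6) - y, 1e-12, None)
    try:
        slope = np.polyfit(x, np.log(resid), 1)[0]
        if slope < -1e-9:
            return float(np.clip(-1.0 / slope, 0.1, 1e4))
    except Exception:
        pass
    return max(float(x.max()) / 3.0, 1.0)


def fit_dark_relaxation(
    dark_times: Sequence[float],
    amplitudes: Sequence[float],
    ses: Sequence[float] | None = None,
) -> FitResult:
    """Fit A[t] = A0·(1 − e^(−t/r)) to per-cycle recovery amplitudes.

    Returns the relaxation time constant r, the asymptotic amplitude A0,
    and the derived maximal dequench percentage 100·A0/(1 + A0).
    """
    t = np.asarray(dark_times, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if len(np.unique(t)) < 3:
        raise InsufficientDataError("need >= 3 distinct dark times")
    if np.ptp(a) < 1e-12 * max(1.0, abs(a).max()):
        return FitResult(
            model="dark_relaxation",
            params={"A0": (float(a.mean()), float("nan")), "r": (float("nan"), float("nan"))},
            dof=len(a) - 2,
            ssr=float(np.sum((a - a.mean()) ** 2)),
            n_points=len(a),
            converged=False,
            flags=["non_identifiable"],
        )

    def residual(theta: np.ndarray) -> np.ndarray:
        A0, r = theta
        return A0 * (1.0 - np.exp(-t / r)) - a

    a0_guess = max(float(a.max()), 1e-6)
    r_grid = [t[t > 0].min() if np.any(t > 0) else 1.0, float(np.median(t)), float(t.max())]
    starts = [np.array([a0_guess, r]) for r in r_grid]
    lo = np.array([0.0, 1e-9])
    hi = np.array([np.inf, np.inf])
    fit = _run_least_squares(residual, starts, (lo, hi), ["A0", "r"], "dark_relaxation")
    A0 = fit.value("A0")
    fit.derived["max_dequench_pct"] = (
        max_dequench_percent(A0),
        _delta_se(fit, lambda th: max_dequench_percent(th[0])),
    )
    return fit


def two_stage_relaxation(
    traces: CycleTraceSet, drop_first: bool = False
) -> tuple[FitResult, FitResult]:
    """Convenience wrapper: per-cycle exponentials, then dark relaxation."""
    stage1 = fit_cycle_exponentials(traces, drop_first=drop_first)
    cycles = np.unique(traces.cycle_index)
    amps = [stage1.value(f"A[{c}]") for c in cycles]
    ses = [stage1.se(f"A[{c}]") for c in cycles]
    stage2 = fit_dark_relaxation(traces.dark_times, amps, ses)
    return stage1, stage2


# ---------------------------------------------------------------------------
# global switch fit (all cycles jointly)
# ---------------------------------------------------------------------------


def fit_global_switch(
    traces: CycleTraceSet,
    mode: str | None = None,
    average: bool = True,
) -> FitResult:
    """Joint fit of Offset, transfer limit, sensitivity and relaxation time.

    Fits every reading of every cycle to the donor (dequench) or
    acceptor (quench) closed-form trace, sharing all four parameters.
    Derived quantities (ED50 per flash, apparent sensitivity, the
    equilibrium switch percentage) carry delta-method standard errors.
    """
    mode = mode or traces.mode
    if mode not in ("donor", "acceptor"):
        raise ValueError(f"mode must be 'donor' or 'acceptor', got {mode!r}")
    ts = _maybe_average(traces, average)
    cycles = np.unique(ts.cycle_index)
    cyc_pos = np.searchsorted(cycles, ts.cycle_index)
    dark = ts.dark_times[cyc_pos]
    x = ts.reading_index.astype(float)
    y = ts.intensity
    rate = ts.flash_rate
    dose = ts.dose_per_flash
    trace_fn = dequench_trace if mode == "donor" else quench_trace

    def predict(theta: np.ndarray) -> np.ndarray:
        offset, limit, sens, r = theta
        p = PhotocycleParams(
            sensitivity=sens, relaxation_time=r, transfer_limit=limit, mode=mode
        )
        m = TraceModelParams(p, offset=offset, flash_rate=rate, dose_per_flash=dose)
        return trace_fn(m, x, dark)

    def residual(theta: np.ndarray) -> np.ndarray:
        return predict(theta) - y

    span = max(float(np.ptp(y)), 1e-4)
    offset0 = float(y[x == x.min()].mean()) if mode == "acceptor" else float(y.max())
    limit0 = float(np.clip(2.0 * span, 0.02, 0.95))
    # coarse grid on r; sensitivity scaled from the per-flash dose
    starts = [
        np.array([offset0, limit0, dose * 10.0, r0]) for r0 in (2.0, 8.0, 30.0)
    ]
    lo = np.array([1e-9, 0.0, 1e-9, 1e-6])
    hi = np.array([np.inf, 1.0, np.inf, np.inf])
    names = ["offset", "transfer_limit", "sensitivity", "r"]
    fit = _run_least_squares(residual, starts, (lo, hi), names, f"global_switch_{mode}")

    def _params(th: np.ndarray) -> PhotocycleParams:
        return PhotocycleParams(
            sensitivity=th[2],
            relaxation_time=th[3],
            transfer_limit=float(np.clip(th[1], 0.0, 1.0)),
            mode=mode,
        )

    flux = rate * dose
    fit.derived["ed50_umol_m2_per_flash"] = (
        ed50(_params(np.array([fit.value(n) for n in names])), rate),
        _delta_se(fit, lambda th: th[2] / (rate * th[3])),
    )
    fit.derived["apparent_sensitivity_umol_m2"] = (
        apparent_sensitivity(flux, _params(np.array([fit.value(n) for n in names]))),
        _delta_se(fit, lambda th: flux / (flux / th[2] + 1.0 / th[3])),
    )

    def _switch_pct(th: np.ndarray) -> float:
        kf = flux / th[2]
        return 100.0 * th[1] * kf / (kf + 1.0 / th[3])

    theta_hat = np.array([fit.value(n) for n in names])
    fit.derived["equilibrium_switch_pct"] = (
        _switch_pct(theta_hat),
        _delta_se(fit, _switch_pct),
    )
    return fit


# ---------------------------------------------------------------------------
# variable-dose reversible-kinetics fit
# ---------------------------------------------------------------------------


def fit_reversible_dose_series(
    curves: Sequence[tuple[np.ndarray, np.ndarray]],
    doses: Sequence[float],
    flash_rate: float = DEFAULT_FLASH_RATE_HZ,
    mode: str = "donor",
    drop_first: bool = False,
) -> FitResult:
    """Joint first-order reversible fit across activation ramps at several doses.

    ``curves[i]`` is ``(reading_index, intensity)`` for ``doses[i]``.
    Shares Plateaumax (offset), the transfer limit, sensitivity and the
    relaxation time across doses; each dose contributes its own apparent
    rate k_app = dose·rate/sens + 1/r.
    """
    if len(curves) != len(doses):
        raise ValueError("curves and doses must have equal length")
    if len(doses) < 3:
        raise InsufficientDataError("need >= 3 doses")
    xs, ys, dose_ids = [], [], []
    for i, (x, y) in enumerate(curves):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if drop_first:
            m = x > x.min()
            x, y = x[m], y[m]
        xs.append(x)
        ys.append(y)
        dose_ids.append(np.full(len(x), i))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    which = np.concatenate(dose_ids)
    dose_arr = np.asarray(doses, dtype=float)[which]

    def residual(theta: np.ndarray) -> np.ndarray:
        offset, limit, sens, r = theta
        k_app = dose_arr * flash_rate / sens + 1.0 / r
        eq = (dose_arr * flash_rate / sens) / (
            dose_arr * flash_rate / sens + 1.0 / r
        )
        approach = 1.0 - np.exp(-k_app * x / flash_rate)
        if mode == "donor":
            pred = offset * (1.0 - limit + limit * eq * approach)
        else:
            pred = offset * (1.0 - limit * eq * approach)
        return pred - y

    span = max(float(np.ptp(y)), 1e-4)
    starts = [
        np.array([float(np.max(y)), min(2.0 * span, 0.9), np.median(doses) * 10, r0])
        for r0 in (2.0, 8.0, 30.0)
    ]
    lo = np.array([1e-9, 0.0, 1e-9, 1e-6])
    hi = np.array([np.inf, 1.0, np.inf, np.inf])
    names = ["offset", "transfer_limit", "sensitivity", "r"]
    fit = _run_least_squares(
        residual, starts, (lo, hi), names, f"reversible_dose_series_{mode}"
    )
    sens, r = fit.value("sensitivity"), fit.value("r")
    fit.derived["inv_k1_umol_m2"] = (sens, fit.se("sensitivity"))
    fit.derived["inv_k_minus1_s"] = (r, fit.se("r"))
    fit.derived["ed50_umol_m2_per_flash"] = (
        sens / (flash_rate * r),
        _delta_se(fit, lambda th: th[2] / (flash_rate * th[3])),
    )
    return fit


# ---------------------------------------------------------------------------
# single-site dose response
# ---------------------------------------------------------------------------


def fit_single_site(
    x: Sequence[float],
    y: Sequence[float],
    groups: Sequence | None = None,
    shared_max: bool = False,
) -> FitResult:
    """Fit the single-site saturation model y = a / (1 + b/x).

    ``a`` is the maximal response, ``b`` the 50% effective dose (ED50).
    With ``groups`` and ``shared_max``, all groups share ``a`` and fit
    separate ``b`` values (per-group ED50 comparison).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be aligned")
    if len(np.unique(x)) < 3:
        raise InsufficientDataError("need >= 3 distinct doses")
    if not np.any(np.abs(y) > 0):
        raise DegenerateFitError("all responses are zero")
    if np.any(x <= 0):
        raise ValueError("doses must be positive")

    sign = 1.0 if np.mean(y) >= 0 else -1.0
    ymax = float(np.max(np.abs(y))) * sign

    if groups is None or not shared_max:
        if groups is not None:
            raise ValueError("groups provided without shared_max; fit groups separately")

        def residual(theta: np.ndarray) -> np.ndarray:
            a, b = theta
            return a / (1.0 + b / x) - y

        b0 = float(np.median(x))
        starts = [np.array([ymax, b0]), np.array([ymax * 1.5, b0 / 4]),
                  np.array([ymax * 1.1, b0 * 4])]
        if sign > 0:
            lo = np.array([0.0, 1e-12])
            hi = np.array([np.inf, np.inf])
        else:
            lo = np.array([-np.inf, 1e-12])
            hi = np.array([0.0, np.inf])
        return _run_least_squares(
            residual, starts, (lo, hi), ["a", "b"], "single_site"
        )

    labels = pd.unique(pd.Series(groups))
    g_pos = pd.Series(groups).map({l: i for i, l in enumerate(labels)}).to_numpy()
    names = ["a"] + [f"b[{l}]" for l in labels]

    def residual(theta: np.ndarray) -> np.ndarray:
        a = theta[0]
        b = theta[1:][g_pos]
        return a / (1.0 + b / x) - y

    b0 = float(np.median(x))
    starts = [
        np.concatenate([[ymax], np.full(len(labels), b0)]),
        np.concatenate([[ymax * 1.5], np.full(len(labels), b0 / 4)]),
    ]
    if sign > 0:
        lo = np.concatenate([[0.0], np.full(len(labels), 1e-12)])
        hi = np.full(1 + len(labels), np.inf)
    else:
        lo = np.concatenate([[-np.inf], np.full(len(labels), 1e-12)])
        hi = np.concatenate([[0.0], np.full(len(labels), np.inf)])
    return _run_least_squares(
        residual, starts, (lo, hi), names, "single_site_shared_max"
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


def nested_f_test(
    fit_restricted: FitResult, fit_full: FitResult
) -> tuple[float, int, int, float]:
    """Extra-sum-of-squares F-test between nested least-squares fits.

    F = ((ssr_r − ssr_f)/(df_r − df_f)) / (ssr_f/df_f), with the p-value
    from the upper tail of F(df_r − df_f, df_f).
    """
    ssr_r, ssr_f = fit_restricted.ssr, fit_full.ssr
    df_r, df_f = fit_restricted.dof, fit_full.dof
    if df_r <= df_f:
        raise InvalidComparisonError(
            "restricted model must have more degrees of freedom than the full model"
        )
    if ssr_f > ssr_r * (1 + 1e-9):
        raise InvalidComparisonError(
            "full model fits worse than restricted model; models are not nested "
            "or the full fit failed to converge"
        )
    df1 = df_r - df_f
    df2 = df_f
    if df2 <= 0:
        raise InvalidComparisonError("full model has no residual degrees of freedom")
    ssr_drop = max(ssr_r - ssr_f, 0.0)
    F = (ssr_drop / df1) / (ssr_f / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), int(df1), int(df2), p


def holm_sidak(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm–Šidák step-down multiplicity adjustment.

    Sorts ascending, applies adjusted_i = 1 − (1 − p_(i))^(m − i),
    enforces monotonicity, and flags rejections at ``alpha``. Returned
    arrays are in the original input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        adj = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, adj)
        adjusted_sorted[rank] = running
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    reject = adjusted <= alpha
    return adjusted, reject
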