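"""Downstream-readout analyses: nuclear-export rates, dose-response, and
bidirectional reporter kinetics with the relaxing-inhibitor rate model."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import (
    FitResult,
    InsufficientDataError,
    ProtocolMismatchError,
    _delta_se,
    _run_least_squares,
    fit_single_site,
)

__all__ = [
    "RatioSeries",
    "ReporterKinetics",
    "export_rate",
    "dose_response",
    "reporter_model",
    "fit_reporter_phases",
    "RATIO_CSV_COLUMNS",
]

RATIO_CSV_COLUMNS = [
    "sample_id",
    "construct",
    "phase",
    "phase_index",
    "time_s",
    "reading_index",
    "dose_per_flash_umol_m2",
    "nc_ratio",
]


@dataclass
class RatioSeries:
    """A nuclear:cytoplasmic ratio time series for one sample.

    ``phase``/``phase_index`` label contiguous lit/dark stretches for
    reporter experiments; they may be empty for plain translocation
    series.
    """

    time_s: np.ndarray
    nc_ratio: np.ndarray
    reading_index: np.ndarray | None = None
    dose_per_flash: float = 0.0
    phase: np.ndarray | None = None
    phase_index: np.ndarray | None = None
    sample_id: str = "s1"
    construct: str = "construct"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.nc_ratio = np.asarray(self.nc_ratio, dtype=float)
        if len(self.time_s) != len(self.nc_ratio):
            raise ValueError("time and ratio arrays must be aligned")
        if np.any(self.nc_ratio <= 0):
            raise ValueError("nc_ratio values must be positive")
        if self.reading_index is None:
            self.reading_index = np.arange(len(self.time_s))
        else:
            self.reading_index = np.asarray(self.reading_index, dtype=int)
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=object)
            if self.phase_index is None:
                # contiguous runs of the same label get increasing indices
                idx = np.zeros(len(self.phase), dtype=int)
                for i in range(1, len(self.phase)):
                    idx[i] = idx[i - 1] + (self.phase[i] != self.phase[i - 1])
                self.phase_index = idx
            else:
                self.phase_index = np.asarray(self.phase_index, dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "construct": self.construct,
                "phase": self.phase if self.phase is not None else "",
                "phase_index": self.phase_index
                if self.phase_index is not None
                else 0,
                "time_s": self.time_s,
                "reading_index": self.reading_index,
                "dose_per_flash_umol_m2": self.dose_per_flash,
                "nc_ratio": self.nc_ratio,
            }
        )[RATIO_CSV_COLUMNS]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RatioSeries":
        missing = [c for c in RATIO_CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ProtocolMismatchError(f"missing ratio columns: {missing}")
        phase = df["phase"].to_numpy(dtype=object)
        has_phase = any(str(p) for p in phase)
        return cls(
            time_s=df["time_s"].to_numpy(),
            nc_ratio=df["nc_ratio"].to_numpy(),
            reading_index=df["reading_index"].to_numpy(),
            dose_per_flash=float(df["dose_per_flash_umol_m2"].iloc[0]),
            phase=phase if has_phase else None,
            phase_index=df["phase_index"].to_numpy() if has_phase else None,
            sample_id=str(df["sample_id"].iloc[0]),
            construct=str(df["construct"].iloc[0]),
        )


@dataclass(frozen=True)
class ReporterKinetics:
    """Bidirectional reporter rate parameters.

    ``k_f``/``k_r`` drive the reporter toward its lit/dark asymptotes;
    ``A_inhib`` is the maximal fractional reduction of ``k_f`` by the
    optogenetic inhibitor and ``rho`` the time constant at which that
    inhibition relaxes once light stops.
    """

    baseline: float
    span: float
    k_f: float
    k_r: float
    A_inhib: float = 0.0
    rho: float = 120.0

    def __post_init__(self) -> None:
        if self.k_f < 0 or self.k_r < 0:
            raise ValueError("rates must be >= 0")
        if not (0.0 <= self.A_inhib <= 1.0):
            raise ValueError("A_inhib must lie in [0, 1]")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


def export_rate(series: RatioSeries) -> tuple[float, float, float]:
    """Per-flash nuclear-export rate from an in-train ratio series.

    Ordinary least-squares regression of nc_ratio on flash number;
    returns (gradient, offset, se_of_gradient).
    """
    x = series.reading_index.astype(float)
    y = series.nc_ratio
    n = len(x)
    if n < 3:
        raise InsufficientDataError("need >= 3 points for a gradient")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.stderr)


def dose_response(
    doses: Sequence[float],
    rates: Sequence[float],
    groups: Sequence | None = None,
    normalize: bool = False,
    shared_max: bool = False,
) -> FitResult:
    """Single-site fit of export rate vs photon dose.

    Response = Max·dose/(ED50 + dose), identical to a/(1 + b/x). Export
    gradients are negative for nuclear export; pass them as measured —
    the fit sign-follows the data. With ``normalize`` the responses are
    reported relative to the fitted Max (the ED50 is unaffected).
    """
    doses = np.asarray(doses, dtype=float)
    rates = np.asarray(rates, dtype=float)
    fit = fit_single_site(doses, rates, groups=groups, shared_max=shared_max)
    a_name = "a"
    fit.derived["max_response"] = fit.params[a_name]
    for name in list(fit.params):
        if name.startswith("b"):
            suffix = name[1:]
            fit.derived[f"ed50_umol_m2_per_flash{suffix}"] = fit.params[name]
    if normalize:
        a = fit.value(a_name)
        if a == 0:
            raise ZeroDivisionError("fitted Max is zero; cannot normalize")
        fit.flags.append("normalized_to_max")
    return fit


def _inhibited_exponent(
    k_f: float, k_r: float, A_inhib: float, rho: float, t
) -> np.ndarray:
    """−∫₀ᵗ ((1 − A·e^(−τ/ρ))·k_f + k_r) dτ in closed form."""
    t = np.asarray(t, dtype=float)
    return -((k_f + k_r) * t - k_f * A_inhib * rho * (1.0 - np.exp(-t / rho)))


def reporter_model(kin: ReporterKinetics, t, inhibited: bool = False):
    """Reporter ratio over time under the bidirectional rate model.

    Uninhibited: baseline + span·e^(−(k_f+k_r)·t). Inhibited with a
    relaxing inhibitor, the forward rate decays as
    (1 − A_inhib·e^(−t/ρ))·k_f and the exponent is the closed-form
    integral of the instantaneous total rate.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if inhibited and kin.A_inhib > 0:
        expo = _inhibited_exponent(kin.k_f, kin.k_r, kin.A_inhib, kin.rho, t)
    else:
        expo = -(kin.k_f + kin.k_r) * t
    return kin.baseline + kin.span * np.exp(expo)


def _split_phases(series: RatioSeries):
    if series.phase is None:
        raise ProtocolMismatchError("series has no lit/dark phase labels")
    out = []
    for pi in np.unique(series.phase_index):
        m = series.phase_index == pi
        label = str(series.phase[m][0])
        if label not in ("lit", "dark"):
            raise ProtocolMismatchError(f"unknown phase label {label!r}")
        t = series.time_s[m]
        if m.sum() < 3:
            raise InsufficientDataError(f"phase {pi} has fewer than 3 points")
        out.append((label, t - t.min(), series.nc_ratio[m]))
    return out


def fit_reporter_phases(
    series_list: Sequence[RatioSeries],
    share_span: bool = True,
    use_relaxing_kf: bool = False,
    rho: float = 120.0,
    equal_tau: bool = False,
) -> FitResult:
    """Fit alternating lit/dark reporter phases to exponential kinetics.

    The lit (reduction) phase follows floor + span·e^(−t/tau_lit) and
    the dark (recovery) phase floor + span·(1 − e^(−t/tau_dark)), with
    the span shared between the two phase kinds when ``share_span``
    (the restricted/full pair for the phase-comparison F-test is
    obtained with ``equal_tau=True`` / ``False``).

    With ``use_relaxing_kf`` the dark-phase recovery exponent accounts
    for the inhibitor relaxing with time constant ``rho``: the total
    rate 1/tau_dark is split evenly between forward and reverse drive
    and the forward part ramps up as the inhibitor decays.
    """
    phases: list[tuple[str, np.ndarray, np.ndarray]] = []
    for s in series_list:
        phases.extend(_split_phases(s))
    if not any(p[0] == "lit" for p in phases) or not any(
        p[0] == "dark" for p in phases
    ):
        raise ProtocolMismatchError("need at least one lit and one dark phase")

    y_all = np.concatenate([p[2] for p in phases])
    span0 = max(float(np.ptp(y_all)), 1e-3)
    floor0 = float(y_all.min())
    t_scale = float(np.median([p[1].max() for p in phases]))

    if share_span:
        names = ["floor", "span", "tau_lit", "tau_dark"]
    else:
        names = ["floor", "span_lit", "span_dark", "tau_lit", "tau_dark"]
    if equal_tau:
        names = [n for n in names if n != "tau_dark"]

    def unpack(theta: np.ndarray) -> dict[str, float]:
        d = dict(zip(names, theta))
        if equal_tau:
            d["tau_dark"] = d["tau_lit"]
        if share_span:
            d["span_lit"] = d["span_dark"] = d["span"]
        return d

    def residual(theta: np.ndarray) -> np.ndarray:
        d = unpack(theta)
        out = []
        for label, t, y in phases:
            if label == "lit":
                pred = d["floor"] + d["span_lit"] * np.exp(-t / d["tau_lit"])
            else:
                tau = d["tau_dark"]
                if use_relaxing_kf:
                    k_tot = 1.0 / tau
                    expo = _inhibited_exponent(
                        0.5 * k_tot, 0.5 * k_tot, 1.0, rho, t
                    )
                else:
                    expo = -t / tau
                pred = d["floor"] + d["span_dark"] * (1.0 - np.exp(expo))
            out.append(pred - y)
        return np.concatenate(out)

    base = {"floor": floor0, "span": span0, "span_lit": span0, "span_dark": span0}
    starts = []
    for tau0 in (t_scale / 3.0, t_scale, 3.0 * t_scale):
        theta0 = []
        for n in names:
            if n.startswith("tau"):
                theta0.append(tau0)
            else:
                theta0.append(base[n])
        starts.append(np.array(theta0))
    lo = np.array([-np.inf if n == "floor" else 1e-9 for n in names])
    hi = np.full(len(names), np.inf)
    model = "reporter_phases_equal_tau" if equal_tau else "reporter_phases"
    fit = _run_least_squares(residual, starts, (lo, hi), names, model)
    if equal_tau:
        fit.derived["tau_dark"] = fit.params["tau_lit"]
    return fit
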