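"""Experimental thermostability analytics.

Residual pigment after heat incubation, single-exponential decoloration
kinetics of the 530 nm absorbance, DSC thermogram processing (buffer
subtraction → molar normalization → baseline subtraction) with peak-top Tm
extraction, and the ΔTm ≥ 1 °C stabilization classification.

The decoloration model is a pure single exponential P(t) = P₀·e^{−kt} with
no floor term (an optional plateau variant exists, off by default); Tm is
taken literally at the on-grid peak top, with no sub-grid interpolation and
no scan-rate or irreversibility correction — the reported values are
apparent Tm of a kinetically controlled transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DecolorationSeries",
    "DecayFit",
    "DSCThermogram",
    "ThermalStabilityRecord",
    "residual_pigment",
    "fit_decoloration",
    "process_dsc",
    "extract_tm",
    "classify_stabilized",
    "records_from_table",
]

_STAGES = ("raw", "buffer_subtracted", "normalized", "baseline_subtracted")


@dataclass
class DecolorationSeries:
    """Residual pigment (% of initial 530 nm absorbance) versus time (min)."""

    times: np.ndarray  # minutes
    pigment: np.ndarray  # percent
    construct_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pigment = np.asarray(self.pigment, dtype=float)
        if self.times.shape != self.pigment.shape:
            raise ValueError("times and pigment must have equal length")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and increasing")
        if np.any(self.pigment < 0):
            raise ValueError("pigment values must be non-negative")


@dataclass
class DecayFit:
    """Single-exponential decoloration fit result."""

    k: float  # min^-1
    tau_half: float  # minutes; ln2/k, +inf when k == 0
    p0: float  # fitted initial pigment, %
    fit_sse: float
    n_points: int
    k_stderr: float = float("nan")  # asymptotic standard error of k


@dataclass
class DSCThermogram:
    """A DSC scan at one processing stage.

    ``signal`` is the raw instrument heat signal until the normalization
    step, after which it is molar heat capacity in consistent units.
    """

    temperatures: np.ndarray  # °C
    signal: np.ndarray
    stage: str = "raw"
    construct_label: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperatures.shape != self.signal.shape:
            raise ValueError("temperature and signal grids must match")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class ThermalStabilityRecord:
    """Per-construct stability summary (one characterization-table row)."""

    construct_label: str
    residual_pigment: float  # %
    residual_pigment_sem: float
    n_replicates: int = 3
    relative_yield: float | None = None
    k: float | None = None  # min^-1
    k_sem: float | None = None
    tm: float | None = None  # °C
    tm_sem: float | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for sem in (self.residual_pigment_sem, self.k_sem, self.tm_sem):
            if sem is not None and not np.isnan(sem) and sem < 0:
                raise ValueError("sem fields must be non-negative")


def residual_pigment(abs_before: float, abs_after: float) -> float:
    """Residual pigment: 100 · A(after incubation) / A(before), percent."""
    if abs_before <= 0:
        raise ValueError("absorbance before incubation must be positive")
    if abs_after < 0:
        raise ValueError("absorbance after incubation must be non-negative")
    return 100.0 * abs_after / abs_before


def fit_decoloration(series: DecolorationSeries,
                     with_plateau: bool = False) -> DecayFit:
    """Nonlinear least-squares single-exponential fit of a decay series.

    Fits P(t) = P₀·e^{−kt} (both parameters free, k ≥ 0), initialized from
    a log-linear regression on the positive pigment values.  With
    ``with_plateau=True`` an additive floor c is fitted as well
    (P₀·e^{−kt} + c); the default is the pure exponential.
    """
    t, p = series.times, series.pigment
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if p[0] <= 0:
        raise ValueError("initial pigment must be positive")
    if np.all(p == 0):
        raise ValueError("all-zero pigment series")
    pos = p > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(p[pos]), 1)
        k0, p00 = max(-slope, 0.0), float(np.exp(intercept))
    else:
        k0, p00 = 1.0, float(p[0])
    if with_plateau:
        model = lambda t, p0, k, c: p0 * np.exp(-k * t) + c
        guess = [p00, max(k0, 1e-9), 0.0]
        bounds = ([0, 0, 0], [np.inf, np.inf, np.inf])
    else:
        model = lambda t, p0, k: p0 * np.exp(-k * t)
        guess = [p00, k0]
        bounds = ([0, 0], [np.inf, np.inf])
    popt, pcov = curve_fit(model, t, p, p0=guess, bounds=bounds, maxfev=10000)
    k = float(popt[1])
    resid = p - model(t, *popt)
    k_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    return DecayFit(k=k, tau_half=float(np.log(2) / k) if k > 0 else np.inf,
                    p0=float(popt[0]), fit_sse=float(np.sum(resid ** 2)),
                    n_points=int(t.size), k_stderr=k_se)


def _window_mask(T: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (T >= lo) & (T <= hi)


def process_dsc(sample: DSCThermogram, buffer: DSCThermogram,
                molar_conc: float,
                baseline_windows: tuple[tuple[float, float], tuple[float, float]] | None = None,
                baseline: str = "linear") -> DSCThermogram:
    """Full DSC processing chain on a raw sample/buffer scan pair.

    The buffer signal is interpolated onto the sample grid and subtracted;
    the difference is normalized to the molar protein concentration; a
    baseline interpolated across the transition — fitted on the pre- and
    post-transition windows (defaults: first and last 10 °C of the scan),
    linear by default, cubic optional — is subtracted.  The stage field
    advances raw → buffer_subtracted → normalized → baseline_subtracted.
    """
    if sample.stage != "raw" or buffer.stage != "raw":
        raise ValueError("process_dsc expects raw sample and buffer scans")
    if molar_conc <= 0:
        raise ValueError("molar concentration must be positive")
    T = sample.temperatures
    if buffer.temperatures[0] > T[0] + 1e-9 or buffer.temperatures[-1] < T[-1] - 1e-9:
        raise ValueError("buffer grid does not cover the sample grid")
    sig = sample.signal - np.interp(T, buffer.temperatures, buffer.signal)
    sig = sig / molar_conc
    if baseline_windows is None:
        baseline_windows = ((T[0], T[0] + 10.0), (T[-1] - 10.0, T[-1]))
    pre, post = baseline_windows
    mask = _window_mask(T, pre) | _window_mask(T, post)
    if mask.sum() < (2 if baseline == "linear" else 4):
        raise ValueError("too few points in the baseline windows")
    i_peak = int(np.argmax(sig))
    if _window_mask(np.array([T[i_peak]]), pre)[0] or _window_mask(np.array([T[i_peak]]), post)[0]:
        warnings.warn("baseline window overlaps the apparent peak region",
                      stacklevel=2)
    deg = 1 if baseline == "linear" else 3
    if baseline not in ("linear", "cubic"):
        raise ValueError(f"unknown baseline kind {baseline!r}")
    coef = np.polyfit(T[mask], sig[mask], deg)
    sig = sig - np.polyval(coef, T)
    return DSCThermogram(temperatures=T.copy(), signal=sig,
                         stage="baseline_subtracted",
                         construct_label=sample.construct_label)


def extract_tm(thermogram: DSCThermogram) -> float:
    """Apparent Tm: temperature of the on-grid global maximum.

    Requires a baseline-subtracted thermogram with an interior peak; a flat
    or monotone curve (maximum on the scan edge) raises.
    """
    if thermogram.stage != "baseline_subtracted":
        raise ValueError("extract_tm expects a baseline_subtracted thermogram")
    sig = thermogram.signal
    if np.ptp(sig) == 0:
        raise ValueError("flat curve: no peak")
    i = int(np.argmax(sig))
    if i == 0 or i == sig.size - 1:
        raise ValueError("no interior peak (curve monotone over the scan)")
    return float(thermogram.temperatures[i])


def classify_stabilized(records: Sequence[ThermalStabilityRecord],
                        wild_type_label: str,
                        delta_threshold: float = 1.0) -> dict[str, str]:
    """ΔTm classification: stabilized iff Tm − Tm(WT) ≥ delta_threshold.

    Constructs without a measured Tm are labelled ``unmeasured``; the
    threshold is boundary-inclusive ("not less than 1 °C").
    """
    by_label = {r.construct_label: r for r in records}
    if wild_type_label not in by_label:
        raise KeyError(f"wild-type record {wild_type_label!r} missing")
    wt = by_label[wild_type_label]
    if wt.tm is None or np.isnan(wt.tm):
        raise ValueError("wild-type record lacks a Tm")
    out = {}
    for r in records:
        if r.construct_label == wild_type_label:
            continue
        if r.tm is None or np.isnan(r.tm):
            out[r.construct_label] = "unmeasured"
        elif r.tm - wt.tm >= delta_threshold:
            out[r.construct_label] = "stabilized"
        else:
            out[r.construct_label] = "not_stabilized"
    return out


def records_from_table(df: pd.DataFrame) -> list[ThermalStabilityRecord]:
    """Build stability records from a characterization table.

    Expects the column layout of :func:`thermoshift.datasets.load_characterization`.
    """
    def _opt(v):
        return None if pd.isna(v) else float(v)

    return [ThermalStabilityRecord(
        construct_label=row["construct"],
        residual_pigment=float(row["residual_pigment"]),
        residual_pigment_sem=float(row["residual_pigment_sem"]),
        n_replicates=int(row["n"]),
        relative_yield=_opt(row.get("relative_yield")),
        k=_opt(row.get("k")), k_sem=_opt(row.get("k_sem")),
        tm=_opt(row.get("tm")), tm_sem=_opt(row.get("tm_sem")),
    ) for _, row in df.iterrows()]
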