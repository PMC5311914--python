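"""Thermal-melt fitting: extract Tm from DSF or single-wavelength CD ramps.

A two-state unfolding transition monitored by dye fluorescence (DSF) or by
ellipticity at a fixed wavelength (CD) follows the Boltzmann sigmoid

    S(T) = L + (U − L) / (1 + exp((Tm − T) / k))

with lower/upper baselines L and U, midpoint Tm (the melting temperature)
and slope factor k > 0 (°C).  CD melts, where the signal decreases through
the transition, are handled by allowing U < L; DSF curves often show a
post-transition decay from dye–aggregate dissociation, which is truncated
at the signal extremum before fitting (disable with ``truncate_max=False``).

Fitting is nonlinear least squares (scipy) with a deterministic
initialisation: baselines from the first/last signal deciles, Tm from the
maximum of the numerical derivative, k = 2 °C.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger("isopepgraft")

__all__ = [
    "MeltCurve",
    "BoltzmannFit",
    "MeltFitError",
    "boltzmann",
    "fit_boltzmann",
    "simulate_melt",
    "delta_tm",
    "read_melt_csv",
]

MIN_POINTS = 8
TEMP_RANGE = (0.0, 120.0)  # plausible aqueous melt range, °C


class MeltFitError(ValueError):
    """Bad curve data or a failed sigmoid fit."""


@dataclass
class MeltCurve:
    """A temperature ramp and its signal; temperatures strictly increasing."""

    temperatures: np.ndarray  # °C
    signals: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.temperatures.shape != self.signals.shape or self.temperatures.ndim != 1:
            raise MeltFitError("temperatures and signals must be 1-D arrays of equal length")
        if len(self.temperatures) < MIN_POINTS:
            raise MeltFitError(f"melt curve needs >= {MIN_POINTS} points, got {len(self.temperatures)}")
        if np.any(np.diff(self.temperatures) <= 0):
            raise MeltFitError("temperatures must be strictly increasing")
        lo, hi = TEMP_RANGE
        if self.temperatures[0] < lo or self.temperatures[-1] > hi:
            raise MeltFitError(f"temperatures outside plausible range {TEMP_RANGE} °C")


@dataclass
class BoltzmannFit:
    tm: float  # °C
    slope: float  # k, °C, > 0
    baseline_low: float  # L (pre-transition)
    baseline_high: float  # U (post-transition)
    rss: float


def boltzmann(T, L, U, tm, k):
    """The two-state melt sigmoid S(T) = L + (U−L)/(1+exp((Tm−T)/k))."""
    T = np.asarray(T, dtype=float)
    return L + (U - L) / (1.0 + np.exp((tm - T) / k))


def _initial_guess(T: np.ndarray, S: np.ndarray) -> tuple[float, float, float, float]:
    n = len(T)
    decile = max(1, n // 10)
    L0 = float(np.mean(S[:decile]))
    U0 = float(np.mean(S[-decile:]))
    dS = np.gradient(S, T)
    # steepest point in the direction of the transition (rise or fall)
    idx = int(np.argmax(dS)) if U0 >= L0 else int(np.argmin(dS))
    return L0, U0, float(T[idx]), 2.0


def fit_boltzmann(curve: MeltCurve, truncate_max: bool = True) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a melt curve.

    With ``truncate_max`` (the DSF default) points after the signal
    extremum — the aggregation-decay tail — are dropped before fitting.
    The returned slope is always positive; a decreasing (CD-style) curve
    simply has baseline_high < baseline_low.  Deterministic: same curve,
    same fit.
    """
    T, S = curve.temperatures, curve.signals
    if np.ptp(S) == 0:
        raise MeltFitError("flat signal (zero range): no transition to fit")

    if truncate_max:
        span = np.ptp(S)
        decile = max(1, len(S) // 10)
        rising = np.mean(S[-decile:]) >= np.mean(S[:decile])
        cut = int(np.argmax(S)) if rising else int(np.argmin(S))
        # only truncate if a real tail follows the extremum
        if cut >= MIN_POINTS - 1 and cut < len(S) - 1 and abs(S[-1] - S[cut]) > 0.05 * span:
            T, S = T[: cut + 1], S[: cut + 1]

    L0, U0, tm0, k0 = _initial_guess(T, S)
    try:
        popt, _ = curve_fit(
            boltzmann,
            T,
            S,
            p0=(L0, U0, tm0, k0),
            bounds=([-np.inf, -np.inf, T[0], 1e-6], [np.inf, np.inf, T[-1], 100.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise MeltFitError(
            f"Boltzmann fit did not converge (init L={L0:.3g} U={U0:.3g} "
            f"Tm={tm0:.3g} k={k0:.3g}): {exc}"
        ) from exc
    L, U, tm, k = (float(v) for v in popt)
    rss = float(np.sum((boltzmann(T, L, U, tm, k) - S) ** 2))
    return BoltzmannFit(tm=tm, slope=k, baseline_low=L, baseline_high=U, rss=rss)


def simulate_melt(
    tm: float,
    slope: float,
    baseline_low: float = 0.0,
    baseline_high: float = 1.0,
    t_start: float = 25.0,
    t_end: float = 95.0,
    step: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> MeltCurve:
    """Simulate a Boltzmann melt on a temperature grid (default 25–95 °C, 1 °C).

    Gaussian noise of standard deviation ``noise_sd`` (signal units) is
    added when requested; a fixed seed reproduces the curve exactly.  The
    midpoint signal at T = Tm is exactly (L+U)/2.
    """
    if t_start >= t_end:
        raise MeltFitError("t_start must be below t_end")
    if step <= 0:
        raise MeltFitError("step must be positive")
    if slope <= 0:
        raise MeltFitError("slope must be positive")
    T = np.arange(t_start, t_end + step / 2, step)
    S = boltzmann(T, baseline_low, baseline_high, tm, slope)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        S = S + rng.normal(0.0, noise_sd, size=S.shape)
    return MeltCurve(temperatures=T, signals=S)


def delta_tm(curve_a: MeltCurve, curve_b: MeltCurve, truncate_max: bool = True) -> float:
    """Tm(b) − Tm(a) in °C; sign preserved (b more stable → positive)."""
    fa = fit_boltzmann(curve_a, truncate_max=truncate_max)
    fb = fit_boltzmann(curve_b, truncate_max=truncate_max)
    return fb.tm - fa.tm


def read_melt_csv(path: str | Path) -> MeltCurve:
    """Read a two-column CSV (temperature_C, signal); header row optional."""
    rows = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), 1):
            if not row or not "".join(row).strip():
                continue
            try:
                rows.append((float(row[0]), float(row[1])))
            except (ValueError, IndexError):
                if lineno == 1:
                    continue  # header
                raise MeltFitError(f"{path}:{lineno}: cannot parse row {row!r}")
    if not rows:
        raise MeltFitError(f"{path}: no data rows")
    T, S = zip(*rows)
    return MeltCurve(temperatures=np.array(T), signals=np.array(S))
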