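"""T1 relaxometry primitives.

Conversions between longitudinal relaxation time T1 (ms) and rate
R1 = 1/T1 (s^-1), two-parameter saturation-recovery T1 fitting of the
form S(TS) = A * (1 - exp(-TS/T1)), and linear calibration of a contrast
agent's relaxivity r1 from a dilution series (R1 = R1_native + r1*[CA]).

Unit convention for the whole package: T1 is always milliseconds, R1 is
always s^-1, concentrations are mM and relaxivity is mM^-1 s^-1.  The
factor of 1000 lives only in :func:`t1_to_r1` / :func:`r1_to_t1`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sstats

__all__ = [
    "EQUILIBRIUM",
    "ContrastAgentSpec",
    "SaturationRecoverySeries",
    "T1Estimate",
    "RelaxivityCalibration",
    "t1_to_r1",
    "r1_to_t1",
    "saturation_recovery_signal",
    "fit_saturation_recovery",
    "calibrate_relaxivity",
    "calibrate_relaxivity_from_t1",
]

#: Sentinel saturation time marking the unsaturated "equilibrium" image
#: (fully recovered magnetization, S = A).
EQUILIBRIUM = float("inf")

# Bounds for the T1 optimizer, in ms.  Estimates pinned at either bound
# carry no decay information and are flagged as non-converged.
_T1_LOWER = 1.0
_T1_UPPER = 1.0e4


def t1_to_r1(t1_ms):
    """Longitudinal relaxation rate R1 (s^-1) from T1 (ms).

    Accepts scalars or arrays; raises ``ValueError`` on non-positive input.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be strictly positive (ms)")
    out = 1000.0 / t1
    return float(out) if np.isscalar(t1_ms) else out


def r1_to_t1(r1_s):
    """T1 (ms) from R1 (s^-1); exact inverse of :func:`t1_to_r1`."""
    r1 = np.asarray(r1_s, dtype=float)
    if np.any(r1 <= 0):
        raise ValueError("R1 must be strictly positive (s^-1)")
    out = 1000.0 / r1
    return float(out) if np.isscalar(r1_s) else out


@dataclass(frozen=True)
class ContrastAgentSpec:
    """Physical constants of the contrast agent formulation.

    Defaults describe ferumoxytol: relaxivity 18 mM^-1 s^-1 at 1.5 T in
    blood, 30 mg elemental iron per ml of formulation, iron molar mass
    55.845 g/mol.
    """

    r1: float = 18.0                          # mM^-1 s^-1
    formulation_concentration: float = 30.0   # mg elemental iron / ml
    molar_mass: float = 55.845                # g/mol

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.formulation_concentration <= 0 or self.molar_mass <= 0:
            raise ValueError("all ContrastAgentSpec fields must be strictly positive")


@dataclass
class SaturationRecoverySeries:
    """A saturation-recovery acquisition: signal vs saturation time.

    ``saturation_times_ms`` uses :data:`EQUILIBRIUM` (infinity) for the
    unsaturated equilibrium image.  ``replicates`` gives the number of
    independent acquisitions represented by each entry; replicate points
    enter the fit as independent observations rather than being averaged.
    """

    saturation_times_ms: np.ndarray
    signals: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.saturation_times_ms = np.asarray(self.saturation_times_ms, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.saturation_times_ms.shape != self.signals.shape:
            raise ValueError("saturation times and signals must have equal length")
        finite = np.isfinite(self.saturation_times_ms)
        if np.any(self.saturation_times_ms[finite] <= 0):
            raise ValueError("finite saturation times must be strictly positive")
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative")
        if self.replicates is None:
            self.replicates = np.ones_like(self.signals, dtype=int)
        else:
            self.replicates = np.asarray(self.replicates, dtype=int)
            if self.replicates.shape != self.signals.shape:
                raise ValueError("replicates must match series length")
            if np.any(self.replicates < 1):
                raise ValueError("replicate counts must be >= 1")
        if len(np.unique(self.saturation_times_ms)) < 2:
            raise ValueError("need at least 2 distinct saturation times "
                             "(equilibrium counts as one)")

    def expanded(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, signals) with each point repeated per its replicate count."""
        return (np.repeat(self.saturation_times_ms, self.replicates),
                np.repeat(self.signals, self.replicates))


@dataclass(frozen=True)
class T1Estimate:
    """Result of a two-parameter saturation-recovery fit."""

    t1: float             # ms
    amplitude: float      # signal units (equilibrium magnetization A)
    residual_norm: float  # ||residuals|| / ||signals||, dimensionless
    converged: bool


def saturation_recovery_signal(ts_ms, t1_ms: float, amplitude: float):
    """Ideal two-parameter saturation-recovery signal A*(1 - exp(-TS/T1)).

    ``EQUILIBRIUM`` (infinite TS) maps to the amplitude itself.
    """
    ts = np.asarray(ts_ms, dtype=float)
    with np.errstate(over="ignore"):
        rec = 1.0 - np.exp(-ts / float(t1_ms))
    out = amplitude * np.where(np.isinf(ts), 1.0, rec)
    return float(out) if np.isscalar(ts_ms) else out


def _initial_guess(times: np.ndarray, signals: np.ndarray) -> tuple[float, float]:
    eq = np.isinf(times)
    if eq.any():
        a0 = float(np.mean(signals[eq]))
    else:
        a0 = float(np.max(signals)) * 1.05
    a0 = max(a0, 1e-12)
    finite = ~eq
    valid = finite & (signals > 0) & (signals < a0)
    if valid.any():
        # one-point closed-form inversion per valid sample; median for robustness
        t1_0 = float(np.median(-times[valid] / np.log1p(-signals[valid] / a0)))
        t1_0 = min(max(t1_0, _T1_LOWER * 2), _T1_UPPER / 2)
    else:
        t1_0 = 1000.0
    return a0, t1_0


def fit_saturation_recovery(series: SaturationRecoverySeries) -> T1Estimate:
    """Least-squares two-parameter T1 fit of a saturation-recovery series.

    The equilibrium image is modelled as infinite saturation time (S = A),
    so only amplitude and T1 are free.  Initialisation is deterministic:
    A from the equilibrium signal, T1 from the closed-form single-point
    inversion.  A degenerate series (no decay information: the optimizer
    pinned at a T1 bound, or a failed solve) is reported with
    ``converged=False`` rather than raising.
    """
    times, signals = series.expanded()

    # Degenerate series: equal signal at every distinct saturation time
    # carries no decay information (any sufficiently small T1 fits), so
    # flag non-convergence instead of returning an arbitrary minimiser.
    group_means = np.array([signals[times == t].mean() for t in np.unique(times)])
    spread = np.ptp(group_means)
    if spread <= 1e-12 * max(float(np.abs(group_means).max()), 1e-300):
        return T1Estimate(t1=float("nan"), amplitude=float(group_means.mean()),
                          residual_norm=0.0, converged=False)

    a0, t1_0 = _initial_guess(times, signals)

    def model(ts, amplitude, t1):
        return saturation_recovery_signal(ts, t1, amplitude)

    try:
        popt, _ = optimize.curve_fit(
            model, times, signals, p0=[a0, t1_0],
            bounds=([0.0, _T1_LOWER], [np.inf, _T1_UPPER]),
            maxfev=10000, check_finite=False,  # equilibrium time is inf by design
        )
    except (RuntimeError, ValueError):
        return T1Estimate(t1=float("nan"), amplitude=float("nan"),
                          residual_norm=float("nan"), converged=False)

    amplitude, t1 = float(popt[0]), float(popt[1])
    resid = signals - model(times, amplitude, t1)
    denom = float(np.linalg.norm(signals))
    residual_norm = float(np.linalg.norm(resid)) / denom if denom > 0 else float("nan")
    at_bound = (t1 <= _T1_LOWER * (1 + 1e-6)) or (t1 >= _T1_UPPER * (1 - 1e-6))
    converged = np.isfinite(t1) and not at_bound
    return T1Estimate(t1=t1, amplitude=amplitude,
                      residual_norm=residual_norm, converged=converged)


@dataclass(frozen=True)
class RelaxivityCalibration:
    """Linear relaxivity calibration R1 = intercept + r1 * [CA]."""

    r1: float          # slope, mM^-1 s^-1
    intercept: float   # native relaxation rate R1 at zero agent, s^-1
    r_squared: float

    def predicted_r1(self, concentration_mm):
        return self.intercept + self.r1 * np.asarray(concentration_mm, dtype=float)


def calibrate_relaxivity(concentrations_mm: Sequence[float],
                         r1_rates_s: Sequence[float]) -> RelaxivityCalibration:
    """Fit relaxivity by ordinary least squares of R1 against concentration.

    The slope estimates the agent relaxivity r1 and the intercept the
    native (pre-contrast) relaxation rate.  Requires at least two
    distinct concentrations.
    """
    conc = np.asarray(concentrations_mm, dtype=float)
    rates = np.asarray(r1_rates_s, dtype=float)
    if conc.shape != rates.shape:
        raise ValueError("concentrations and rates must have equal length")
    if conc.size < 2 or np.ptp(conc) == 0:
        raise ValueError("need >= 2 distinct concentrations to calibrate a slope")
    res = sstats.linregress(conc, rates)
    return RelaxivityCalibration(r1=float(res.slope), intercept=float(res.intercept),
                                 r_squared=float(res.rvalue ** 2))


def calibrate_relaxivity_from_t1(concentrations_mm: Sequence[float],
                                 t1_values_ms: Sequence[float]) -> RelaxivityCalibration:
    """Convenience wrapper: convert dilution-series T1 (ms) to R1 and calibrate."""
    return calibrate_relaxivity(concentrations_mm, t1_to_r1(np.asarray(t1_values_ms, float)))
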