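"""Tracer-dilution plasma and blood volume estimation.

The indicator-dilution principle: after injecting n_Fe millimoles of a
blood-pool contrast agent with relaxivity r1, the blood concentration is
read out through the change in longitudinal relaxation rate,
dR1(t) = R1(t) - R1_native = r1 * [CA](t), giving an apparent
distribution volume

    V'(t) = r1 * n_Fe / dR1(t)     [mM^-1 s^-1 * mmol / s^-1 = L]

which grows exponentially as the agent is eliminated,
V'(t) = V_plasma * exp(t / tau).  A log-linear ordinary least squares
fit of log V'(t) against time therefore yields the plasma volume from
the intercept (extrapolation to t = 0, the end of infusion) and the
elimination time constant tau from the slope; the half-life is
t_1/2 = tau * ln 2.  Blood volume follows from the hematocrit:
V_blood = V_plasma / (1 - Hct).

The model/results pair (:class:`DilutionModel`, :class:`DilutionFitResult`)
is the primary interface; :func:`fit_elimination` is a functional wrapper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .relaxometry import ContrastAgentSpec, t1_to_r1

__all__ = [
    "SubjectRecord",
    "DoseRecord",
    "T1Series",
    "DilutionFitResult",
    "DilutionModel",
    "iron_amount",
    "apparent_volume",
    "sensitivity",
    "blood_volume",
    "blood_volume_per_kg",
    "fit_elimination",
    "DEFAULT_FIT_WINDOW",
]

#: Default elimination-fit window in minutes after the end of infusion.
#: The first 20 min are excluded because contrast extraction is not yet
#: mono-exponential there (transient physiological response).
DEFAULT_FIT_WINDOW: tuple[float, float] = (20.0, 60.0)

#: Compartments treated as blood pool (post-contrast T1 must undercut baseline).
BLOOD_COMPARTMENTS = ("LV", "RV")


@dataclass(frozen=True)
class SubjectRecord:
    """Subject covariates needed to convert plasma to blood volume."""

    weight_kg: float
    hematocrit: float                      # red-cell volume fraction, [0, 1)
    hemoglobin_g_per_l: float | None = None

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError("weight must be positive")
        if not 0.0 <= self.hematocrit < 1.0:
            raise ValueError("hematocrit must lie in [0, 1)")
        if self.hemoglobin_g_per_l is not None and self.hemoglobin_g_per_l <= 0:
            raise ValueError("hemoglobin must be positive when given")


@dataclass(frozen=True)
class DoseRecord:
    """An administered volume of contrast formulation."""

    injected_volume_ml: float
    agent: ContrastAgentSpec = field(default_factory=ContrastAgentSpec)

    def __post_init__(self) -> None:
        if self.injected_volume_ml <= 0:
            raise ValueError("injected volume must be positive")


def iron_amount(dose: DoseRecord) -> float:
    """Millimoles of elemental iron in a dose.

    volume [ml] x formulation concentration [mg/ml] / molar mass [g/mol]
    -> mg / (g/mol) = mmol.
    """
    agent = dose.agent
    return dose.injected_volume_ml * agent.formulation_concentration / agent.molar_mass


def apparent_volume(n_fe_mmol: float, r1: float, t1_ms, t1_baseline_ms) -> float | np.ndarray:
    """Apparent tracer distribution volume V' = r1 * n_Fe / dR1, in liters.

    Requires positive enhancement (post-contrast T1 below baseline);
    otherwise no volume is defined and a ``ValueError`` is raised.
    Vectorized over ``t1_ms``.
    """
    dr1 = t1_to_r1(t1_ms) - t1_to_r1(t1_baseline_ms)
    if np.any(np.asarray(dr1) <= 0):
        raise ValueError("post-contrast T1 must be below baseline (positive dR1)")
    out = r1 * n_fe_mmol / dr1
    return float(out) if np.isscalar(t1_ms) else out


def sensitivity(t1_ms: float, t1_baseline_ms: float) -> tuple[float, float]:
    """Relative-error amplification factors of the apparent volume.

    Returns ``(s_post, s_baseline)``: a relative error ``e`` in the
    post-contrast T1 produces a relative volume error ``s_post * e``,
    and likewise for the baseline T1.  From V' = r1*n/(R1 - R1_native):

        s_post     = R1 / dR1
        s_baseline = R1_native / dR1

    As baseline -> infinity, dR1 -> R1 and s_post -> 1.
    """
    r1_post = t1_to_r1(t1_ms)
    r1_base = t1_to_r1(t1_baseline_ms)
    dr1 = r1_post - r1_base
    if dr1 <= 0:
        raise ValueError("post-contrast T1 must be below baseline (positive dR1)")
    return r1_post / dr1, r1_base / dr1


def blood_volume(v_plasma_l: float, subject: SubjectRecord) -> float:
    """Total blood volume V_plasma / (1 - Hct), in liters."""
    return v_plasma_l / (1.0 - subject.hematocrit)


def blood_volume_per_kg(v_plasma_l: float, subject: SubjectRecord) -> float:
    """Weight-normalized blood volume in ml/kg."""
    return blood_volume(v_plasma_l, subject) * 1000.0 / subject.weight_kg


@dataclass
class T1Series:
    """Timestamped compartmental T1 measurements from one imaging session.

    Times are minutes since the end of contrast infusion (t = 0).
    ``baseline_ms`` holds the pre-contrast T1 per compartment (the average
    of pre-contrast replicate maps).  ``sd_ms`` optionally carries the
    intra-ROI standard deviation per time point.
    """

    times_min: np.ndarray
    t1_ms: Mapping[str, np.ndarray]
    baseline_ms: Mapping[str, float]
    sd_ms: Mapping[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        self.t1_ms = {k: np.asarray(v, dtype=float) for k, v in self.t1_ms.items()}
        for comp, vals in self.t1_ms.items():
            if vals.shape != self.times_min.shape:
                raise ValueError(f"compartment {comp!r}: length mismatch with times")
            if np.any(vals <= 0):
                raise ValueError(f"compartment {comp!r}: T1 must be positive")
            base = self.baseline_ms.get(comp)
            if base is None or base <= 0:
                raise ValueError(f"compartment {comp!r}: missing/invalid baseline T1")
            if comp in BLOOD_COMPARTMENTS and np.any(vals >= base):
                raise ValueError(
                    f"compartment {comp!r}: post-contrast T1 must stay below baseline")

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(self.t1_ms)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "T1Series":
        """Build from long-format rows (time_min, compartment, t1_ms[, sd_ms]).

        Rows with negative ``time_min`` are pre-contrast replicates; their
        per-compartment average becomes the baseline.
        """
        required = {"time_min", "compartment", "t1_ms"}
        if not required.issubset(df.columns):
            raise ValueError(f"series table needs columns {sorted(required)}")
        pre = df[df["time_min"] < 0]
        post = df[df["time_min"] >= 0].sort_values("time_min")
        if pre.empty or post.empty:
            raise ValueError("need pre-contrast (time_min < 0) and post-contrast rows")
        baseline = pre.groupby("compartment")["t1_ms"].mean().to_dict()
        t1: dict[str, np.ndarray] = {}
        sd: dict[str, np.ndarray] = {}
        times_ref = None
        for comp, grp in post.groupby("compartment"):
            times = grp["time_min"].to_numpy(dtype=float)
            if times_ref is None:
                times_ref = times
            elif not np.array_equal(times, times_ref):
                raise ValueError("all compartments must share the same time grid")
            t1[comp] = grp["t1_ms"].to_numpy(dtype=float)
            if "sd_ms" in grp and grp["sd_ms"].notna().all():
                sd[comp] = grp["sd_ms"].to_numpy(dtype=float)
        return cls(times_min=times_ref, t1_ms=t1, baseline_ms=baseline,
                   sd_ms=sd or None)

    @classmethod
    def from_csv(cls, path) -> "T1Series":
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for comp in self.compartments:
            rows.append(pd.DataFrame({
                "time_min": [-1.0], "compartment": [comp],
                "t1_ms": [self.baseline_ms[comp]], "sd_ms": [np.nan]}))
            sd = (self.sd_ms or {}).get(comp)
            rows.append(pd.DataFrame({
                "time_min": self.times_min, "compartment": comp,
                "t1_ms": self.t1_ms[comp],
                "sd_ms": sd if sd is not None else np.nan}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class DilutionFitResult:
    """Results of the log-linear elimination fit.

    ``v_plasma_ci_frac`` is the fractional 95% confidence half-width of
    the plasma volume, obtained by the delta method from the intercept
    standard error of the log-linear fit (NaN when the fit has no
    residual degrees of freedom).  ``positive_elimination`` is False when
    the fitted slope is non-positive (apparent volume not growing), in
    which case tau and the half-life are not physically meaningful.
    """

    v_plasma_l: float
    tau_min: float
    t_half_h: float
    r_squared: float
    v_plasma_ci_frac: float
    fit_window: tuple[float, float]
    n_points: int
    compartment: str
    positive_elimination: bool
    intercept_se: float
    times_min: np.ndarray | None = None
    apparent_volumes_l: np.ndarray | None = None
    v_blood_l: float | None = None
    v_blood_ml_per_kg: float | None = None

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "Ferumoxytol dilution fit",
            "=" * 44,
            f"compartment            {self.compartment}",
            f"fit window [min]       {self.fit_window[0]:g} - {self.fit_window[1]:g}",
            f"n points               {self.n_points}",
            f"V_plasma [L]           {self.v_plasma_l:.4f}",
            f"  95% CI half-width    {100 * self.v_plasma_ci_frac:.2f}%"
            if np.isfinite(self.v_plasma_ci_frac) else
            "  95% CI half-width    n/a (saturated fit)",
            f"tau [min]              {self.tau_min:.2f}",
            f"half-life [h]          {self.t_half_h:.3f}",
            f"r^2                    {self.r_squared:.4f}",
            f"positive elimination   {self.positive_elimination}",
        ]
        if self.v_blood_l is not None:
            lines.append(f"V_blood [L]            {self.v_blood_l:.4f}")
        if self.v_blood_ml_per_kg is not None:
            lines.append(f"V_blood [ml/kg]        {self.v_blood_ml_per_kg:.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "compartment": self.compartment,
            "v_plasma_l": self.v_plasma_l,
            "tau_min": self.tau_min,
            "t_half_h": self.t_half_h,
            "r_squared": self.r_squared,
            "v_plasma_ci_frac": self.v_plasma_ci_frac,
            "fit_window_min": list(self.fit_window),
            "n_points": self.n_points,
            "positive_elimination": self.positive_elimination,
        }
        if self.v_blood_l is not None:
            d["v_blood_l"] = self.v_blood_l
        if self.v_blood_ml_per_kg is not None:
            d["v_blood_ml_per_kg"] = self.v_blood_ml_per_kg
        return d

    def plot(self, ax=None):
        """Plot apparent volume vs time with the fitted exponential."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.times_min is not None and self.apparent_volumes_l is not None:
            ax.plot(self.times_min, self.apparent_volumes_l, "o", label="V'(t)")
            tt = np.linspace(0.0, float(self.times_min.max()), 200)
            ax.plot(tt, self.v_plasma_l * np.exp(tt / self.tau_min), "-",
                    label="fit (extrapolated to t=0)")
        ax.axhline(self.v_plasma_l, ls=":", color="gray")
        ax.set_xlabel("time since end of infusion [min]")
        ax.set_ylabel("apparent volume V' [L]")
        ax.legend()
        return ax


class DilutionModel:
    """Log-linear elimination model for one compartment of a T1 series.

    Parameters
    ----------
    series : T1Series
        Timestamped post-contrast T1 values with pre-contrast baseline.
    dose : DoseRecord
        Injected formulation volume and agent constants.
    subject : SubjectRecord, optional
        When given, the results also carry blood volume (hematocrit
        corrected) and its weight-normalized value.
    compartment : str
        Which compartment to fit; the left-ventricular blood pool by
        default (largest ROI, smallest variation).
    window : (float, float)
        Inclusive fit window in minutes.
    """

    def __init__(self, series: T1Series, dose: DoseRecord,
                 subject: SubjectRecord | None = None,
                 compartment: str = "LV",
                 window: tuple[float, float] = DEFAULT_FIT_WINDOW) -> None:
        if compartment not in series.t1_ms:
            raise ValueError(f"series has no compartment {compartment!r}")
        if window[0] >= window[1]:
            raise ValueError("window must satisfy t_start < t_end")
        self.series = series
        self.dose = dose
        self.subject = subject
        self.compartment = compartment
        self.window = (float(window[0]), float(window[1]))

    @classmethod
    def from_csv(cls, path, dose: DoseRecord, **kwargs) -> "DilutionModel":
        return cls(T1Series.from_csv(path), dose, **kwargs)

    def fit(self) -> DilutionFitResult:
        t = self.series.times_min
        t1 = self.series.t1_ms[self.compartment]
        base = self.series.baseline_ms[self.compartment]
        in_window = (t >= self.window[0]) & (t <= self.window[1])
        usable = in_window & (t1 < base)
        if usable.sum() < 2:
            raise ValueError("need >= 2 usable points (T1 below baseline) in window")

        n_fe = iron_amount(self.dose)
        tt = t[usable]
        vprime = apparent_volume(n_fe, self.dose.agent.r1, t1[usable], base)
        y = np.log(vprime)
        ols = sm.OLS(y, sm.add_constant(tt)).fit()
        intercept, slope = float(ols.params[0]), float(ols.params[1])
        intercept_se = float(ols.bse[0]) if ols.df_resid > 0 else float("nan")
        r2 = float(ols.rsquared)

        v_plasma = math.exp(intercept)
        positive = slope > 0
        tau = 1.0 / slope if slope != 0 else float("inf")
        t_half = tau * math.log(2) / 60.0
        result = DilutionFitResult(
            v_plasma_l=v_plasma, tau_min=tau, t_half_h=t_half, r_squared=r2,
            v_plasma_ci_frac=1.96 * intercept_se,
            fit_window=self.window, n_points=int(usable.sum()),
            compartment=self.compartment, positive_elimination=positive,
            intercept_se=intercept_se, times_min=tt, apparent_volumes_l=vprime,
        )
        if self.subject is not None:
            result.v_blood_l = blood_volume(v_plasma, self.subject)
            result.v_blood_ml_per_kg = blood_volume_per_kg(v_plasma, self.subject)
        return result


def fit_elimination(series: T1Series, dose: DoseRecord, compartment: str = "LV",
                    window: tuple[float, float] = DEFAULT_FIT_WINDOW,
                    subject: SubjectRecord | None = None) -> DilutionFitResult:
    """Functional wrapper: build a :class:`DilutionModel` and fit it."""
    return DilutionModel(series, dose, subject=subject,
                         compartment=compartment, window=window).fit()
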