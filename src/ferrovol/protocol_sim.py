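"""Monte Carlo simulation of abbreviated T1 sampling protocols.

Forward model: a mono-exponential blood-pool tracer with baseline T1
1600 ms, immediate post-contrast T1 230 ms, elimination half-life 3.4 h,
1.0 ml of ferumoxytol (r1 = 18 mM^-1 s^-1) — values representative of a
0.7 mg/kg dose in swine.  Those inputs jointly imply the true plasma
volume through the dilution equation, and the concentration decays as
[CA](t) = (n_Fe / V_plasma) * exp(-t / tau), so

    R1(t) = R1_native + r1 * [CA](t),     T1(t) = 1000 / R1(t).

Each Monte Carlo replicate draws one noisy baseline T1 and one noisy T1
per post-contrast sample time (independent multiplicative Gaussian noise,
0.6% CV by default), estimates the plasma volume with the protocol's
estimator, and the ensemble spread/bias quantifies protocol precision.

Estimators:

- ``log_linear``: per-replicate OLS of log apparent volume vs time
  (slope -> tau, intercept -> V_plasma);
- ``single_point``: the apparent volume at the single sample time with
  no elimination correction.  At 4 min this carries a deterministic
  relative bias of exp(4/tau) - 1 (about +1.4% at defaults), which is a
  property of the protocol and is deliberately not corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .dilution import DoseRecord, apparent_volume, iron_amount
from .relaxometry import ContrastAgentSpec, r1_to_t1, t1_to_r1

__all__ = [
    "ForwardModelParams",
    "SamplingProtocol",
    "MCSummary",
    "ImpliedTruth",
    "implied_truth",
    "forward_t1",
    "simulate_protocol",
    "sweep_protocols",
    "full_protocol",
    "protocol_1",
    "protocol_2",
    "protocol_3",
    "human_protocol",
]

_MAX_RESAMPLE_ROUNDS = 1000


@dataclass(frozen=True)
class ForwardModelParams:
    """Ground truth and noise model for the Monte Carlo simulations."""

    t1_baseline_ms: float = 1600.0
    t1_post_ms: float = 230.0       # immediately after infusion (t = 0)
    half_life_h: float = 3.4
    v_fe_ml: float = 1.0            # injected formulation volume
    r1: float = 18.0                # mM^-1 s^-1
    noise_cv: float = 0.006         # fractional SD of multiplicative T1 noise
    n_reps: int = 10_000
    seed: int = 0
    agent: ContrastAgentSpec | None = None

    def __post_init__(self) -> None:
        if self.t1_post_ms >= self.t1_baseline_ms:
            raise ValueError("post-contrast T1 must be below baseline")
        if min(self.t1_post_ms, self.half_life_h, self.v_fe_ml, self.r1) <= 0:
            raise ValueError("model parameters must be strictly positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.agent is None:
            object.__setattr__(
                self, "agent", ContrastAgentSpec(r1=self.r1))
        elif self.agent.r1 != self.r1:
            raise ValueError("agent.r1 must match params.r1")


class ImpliedTruth(NamedTuple):
    v_plasma_l: float
    tau_min: float
    n_fe_mmol: float


def implied_truth(params: ForwardModelParams) -> ImpliedTruth:
    """Plasma volume, elimination time constant and iron dose implied
    by the forward-model anchors (dose + immediate post-contrast T1)."""
    n_fe = iron_amount(DoseRecord(params.v_fe_ml, params.agent))
    v_plasma = apparent_volume(n_fe, params.r1, params.t1_post_ms,
                               params.t1_baseline_ms)
    tau_min = params.half_life_h * 60.0 / math.log(2)
    return ImpliedTruth(float(v_plasma), tau_min, n_fe)


def forward_t1(t_min, params: ForwardModelParams) -> float | np.ndarray:
    """Noise-free blood-pool T1 (ms) at time t (min) after infusion end."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    truth = implied_truth(params)
    dr1_0 = t1_to_r1(params.t1_post_ms) - t1_to_r1(params.t1_baseline_ms)
    r1_t = t1_to_r1(params.t1_baseline_ms) + dr1_0 * np.exp(-t / truth.tau_min)
    out = r1_to_t1(r1_t)
    return float(out) if np.isscalar(t_min) else out


@dataclass(frozen=True)
class SamplingProtocol:
    """An abbreviated acquisition design: when to sample, how to estimate."""

    name: str
    post_times_min: tuple[float, ...]
    estimator: Literal["single_point", "log_linear"] = "log_linear"
    baseline_samples: int = 1

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.post_times_min)
        object.__setattr__(self, "post_times_min", times)
        if not times or any(t <= 0 for t in times):
            raise ValueError("post times must be positive and non-empty")
        if any(b >= a for a, b in zip(times[1:], times[:-1])):
            raise ValueError("post times must be strictly increasing")
        if self.estimator not in ("single_point", "log_linear"):
            raise ValueError("unknown estimator")
        if self.estimator == "log_linear" and len(times) < 2:
            raise ValueError("log_linear estimator needs >= 2 post times")
        if self.estimator == "single_point" and len(times) != 1:
            raise ValueError("single_point estimator needs exactly 1 post time")
        if self.baseline_samples < 1:
            raise ValueError("need at least one baseline sample")


def full_protocol() -> SamplingProtocol:
    """Reference sampling: every 2 min from 20 to 60 min, log-linear fit."""
    return SamplingProtocol("full", tuple(np.arange(20.0, 60.0 + 1, 2.0)))


def protocol_1(time_min: float = 4.0) -> SamplingProtocol:
    """Single post-contrast measurement (default 4 min), no elimination fit."""
    return SamplingProtocol("protocol1", (time_min,), estimator="single_point")


def protocol_2(n_samples: int = 5) -> SamplingProtocol:
    """Sequential measurements at 2-min spacing from 20 min (default 20-28)."""
    if n_samples < 2:
        raise ValueError("protocol 2 needs >= 2 samples")
    return SamplingProtocol(
        "protocol2", tuple(20.0 + 2.0 * np.arange(n_samples)))


def protocol_3(anchor_min: float = 40.0) -> SamplingProtocol:
    """Three early measurements (20, 22, 24 min) plus one delayed anchor."""
    if anchor_min <= 24.0:
        raise ValueError("anchor must lie after the 24-min sample")
    return SamplingProtocol("protocol3", (20.0, 22.0, 24.0, float(anchor_min)))


def human_protocol(up_to_min: float = 6.0) -> SamplingProtocol:
    """Acute sampling every 2 min from 2 min up to ``up_to_min``."""
    if up_to_min < 4.0:
        raise ValueError("human protocol needs at least samples at 2 and 4 min")
    return SamplingProtocol("human", tuple(np.arange(2.0, up_to_min + 1e-9, 2.0)))


@dataclass(frozen=True)
class MCSummary:
    """Ensemble summary of one simulated protocol."""

    protocol: str
    sigma_vplasma_pct: float        # 100 * SD / mean of the estimates
    bias_l: float                   # mean estimate - implied truth
    mean_r_squared: float | None    # log_linear only
    mean_vplasma_l: float
    sd_vplasma_l: float
    truth_vplasma_l: float
    n_reps: int
    n_rejected: int                 # replicates redrawn for non-positive dR1
    seed: int

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "sigma_vplasma_pct": self.sigma_vplasma_pct,
            "bias_l": self.bias_l,
            "mean_r_squared": self.mean_r_squared,
            "mean_vplasma_l": self.mean_vplasma_l,
            "sd_vplasma_l": self.sd_vplasma_l,
            "truth_vplasma_l": self.truth_vplasma_l,
            "n_reps": self.n_reps,
            "n_rejected": self.n_rejected,
            "seed": self.seed,
        }


def _draw_noisy(rng: np.random.Generator, clean: np.ndarray, cv: float,
                shape: tuple[int, ...]) -> np.ndarray:
    if cv == 0:
        return np.broadcast_to(clean, shape).copy()
    return clean * (1.0 + cv * rng.standard_normal(shape))


def simulate_protocol(protocol: SamplingProtocol, params: ForwardModelParams,
                      rng: np.random.Generator | None = None) -> MCSummary:
    """Monte Carlo evaluation of a sampling protocol under the forward model.

    Replicates in which any sample yields non-positive enhancement
    (noisy post T1 at or above the noisy baseline) are rejected, counted
    and redrawn, since no apparent volume is defined for them.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    truth = implied_truth(params)
    t = np.asarray(protocol.post_times_min)
    t1_clean = np.atleast_1d(forward_t1(t, params))
    n = params.n_reps

    base = _draw_noisy(rng, np.asarray(params.t1_baseline_ms), params.noise_cv,
                       (n, protocol.baseline_samples)).mean(axis=1)
    post = _draw_noisy(rng, t1_clean, params.noise_cv, (n, t.size))
    dr1 = 1000.0 / post - (1000.0 / base)[:, None]

    n_rejected = 0
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = (dr1 <= 0).any(axis=1)
        if not bad.any():
            break
        n_bad = int(bad.sum())
        n_rejected += n_bad
        base_new = _draw_noisy(rng, np.asarray(params.t1_baseline_ms),
                               params.noise_cv,
                               (n_bad, protocol.baseline_samples)).mean(axis=1)
        post_new = _draw_noisy(rng, t1_clean, params.noise_cv, (n_bad, t.size))
        post[bad] = post_new
        base[bad] = base_new
        dr1[bad] = 1000.0 / post_new - (1000.0 / base_new)[:, None]
    else:
        raise RuntimeError("resampling failed to produce positive enhancement")

    scale = params.r1 * truth.n_fe_mmol
    vprime = scale / dr1                              # (n, n_times), liters

    mean_r2: float | None
    if protocol.estimator == "single_point":
        estimates = vprime[:, 0]
        mean_r2 = None
    else:
        y = np.log(vprime)
        xm = t.mean()
        sxx = float(((t - xm) ** 2).sum())
        ym = y.mean(axis=1)
        slope = ((t - xm) * (y - ym[:, None])).sum(axis=1) / sxx
        intercept = ym - slope * xm
        estimates = np.exp(intercept)
        fitted = intercept[:, None] + slope[:, None] * t
        ss_res = ((y - fitted) ** 2).sum(axis=1)
        ss_tot = ((y - ym[:, None]) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
        mean_r2 = float(np.mean(r2))

    mean_v = float(estimates.mean())
    sd_v = float(estimates.std(ddof=1)) if n > 1 else 0.0
    return MCSummary(
        protocol=protocol.name,
        sigma_vplasma_pct=100.0 * sd_v / mean_v,
        bias_l=mean_v - truth.v_plasma_l,
        mean_r_squared=mean_r2,
        mean_vplasma_l=mean_v,
        sd_vplasma_l=sd_v,
        truth_vplasma_l=truth.v_plasma_l,
        n_reps=n,
        n_rejected=n_rejected,
        seed=params.seed,
    )


def _sweep_designs(family: str) -> list[tuple[float, SamplingProtocol]]:
    if family == "extend_protocol2":
        return [(20.0 + 2.0 * (k - 1), protocol_2(k)) for k in range(2, 22)]
    if family == "anchor_protocol3":
        return [(a, protocol_3(a)) for a in np.arange(30.0, 60.0 + 1, 2.0)]
    if family == "human":
        return [(up, human_protocol(up)) for up in np.arange(4.0, 20.0 + 1, 2.0)]
    raise ValueError(f"unknown sweep family {family!r}")


def sweep_protocols(family: Literal["extend_protocol2", "anchor_protocol3", "human"],
                    params: ForwardModelParams) -> pd.DataFrame:
    """Precision-vs-design curves for one protocol family.

    - ``extend_protocol2``: grow the sequential block 20, 22, 24, ... one
      2-min sample at a time (design variable: time of the last sample);
    - ``anchor_protocol3``: fix samples at 20/22/24 min and move a single
      anchor from 30 to 60 min (design variable: anchor time);
    - ``human``: acute sampling every 2 min from 2 min up to the design
      variable (4 to 20 min).

    Each row is simulated with an independent child seed spawned from
    ``params.seed`` so rows are statistically independent yet reproducible.
    """
    designs = _sweep_designs(family)
    child_seeds = np.random.SeedSequence(params.seed).generate_state(len(designs))
    rows = []
    for (design_value, proto), child in zip(designs, child_seeds):
        seed = int(child) % (2**31)
        summary = simulate_protocol(proto, replace(params, seed=seed))
        rows.append({
            "family": family,
            "design_value": design_value,
            "n_post_samples": len(proto.post_times_min),
            "sigma_vplasma_pct": summary.sigma_vplasma_pct,
            "bias_l": summary.bias_l,
            "mean_r_squared": summary.mean_r_squared,
            "n_rejected": summary.n_rejected,
            "seed": seed,
        })
    return pd.DataFrame(rows)


def plot_sweep(table: pd.DataFrame, ax=None):
    """Plot a sweep table: protocol precision against the design variable."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(table["design_value"], table["sigma_vplasma_pct"], "o-")
    for level in (3.0, 2.0, 1.0):
        ax.axhline(level, ls=":", color="gray", lw=0.8)
    ax.set_xlabel(f"design variable ({table['family'].iloc[0]})")
    ax.set_ylabel(r"$\sigma_{V_{plasma}}$ [%]")
    return ax
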