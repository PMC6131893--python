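"""Carbon-monoxide rebreathing reference blood volume.

A known volume of CO is rebreathed from a closed bag/spirometer circuit;
CO binds circulating hemoglobin and the rise in carboxyhemoglobin
(delta %COHb) between baseline and post-administration samples reads out
the circulating hemoglobin mass, hence blood volume:

    V_blood [L] = V_CO,eff [ml] * K * 100 / ([Hb] g/L * d%COHb * n_H)

with Hufner's number n_H = 1.31 ml CO per g Hb and K a Boyle's-law
correction of the administered gas volume to standard temperature and
pressure.  (Dimensionally: ml / (ml/g) = g of CO-bound Hb; scaling by
100/d% gives total Hb in g; dividing by [Hb] in g/L yields liters.)

Three systematic losses reduce the administered CO volume to the
effective dose V_CO,eff:

1. a fixed 1% loss to non-circulating binding (CO affinity loss);
2. CO remnant in the apparatus (bag + spirometer + lungs) at the
   residual concentration measured after the maneuver;
3. CO expired to air during the measurement, predicted from the
   post-administration COHb level via the empirical relation
   expired CO = 5.09 * [COHb%] + 2.34 ppm, scaled by the alveolar
   ventilation rate and the measurement time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CO_AFFINITY_LOSS",
    "CORebreathingRecord",
    "k_stpd_from_ambient",
    "delta_cohb",
    "effective_vco",
    "vco_correction_terms",
    "blood_volume_co",
]

#: Fractional loss of administered CO to non-circulating binding, applied
#: to the administered volume before the remnant/expired subtractions.
CO_AFFINITY_LOSS = 0.01

#: Empirical expired-CO model: concentration [ppm] = A * COHb% + B.
_EXPIRED_SLOPE_PPM_PER_PCT = 5.09
_EXPIRED_OFFSET_PPM = 2.34


def k_stpd_from_ambient(temperature_c: float, pressure_mmhg: float) -> float:
    """Boyle's-law STPD correction factor from ambient conditions.

    K = (273 / (273 + T_C)) * (P_mmHg / 760).
    """
    if temperature_c <= -273 or pressure_mmhg <= 0:
        raise ValueError("non-physical ambient conditions")
    return (273.0 / (273.0 + temperature_c)) * (pressure_mmhg / 760.0)


@dataclass(frozen=True)
class CORebreathingRecord:
    """One CO-rebreathing maneuver with its apparatus constants.

    Volumes of the circuit are liters; CO gas volumes are ml; the
    residual concentration is ppm (volume fraction x 1e-6).  Defaults
    follow the standard apparatus: 2.7 L bag, 0.04 L spirometer, 1 L
    assumed lung volume, 5 L/min alveolar ventilation, 7 min measurement
    time (the mean of 6/7/8-min blood sampling), Hufner 1.31 ml/g.
    """

    baseline_cohb_pct: tuple[float, ...]
    post_cohb_pct: tuple[float, ...]
    hemoglobin_g_per_l: float
    vco_administered_ml: float
    post_times_min: tuple[float, ...] | None = None
    bag_volume_l: float = 2.7
    spirometer_volume_l: float = 0.04
    lung_volume_l: float = 1.0
    residual_co_ppm: float = 0.0
    k_stpd: float = 1.0
    huefner_ml_per_g: float = 1.31
    ventilation_rate_l_min: float = 5.0
    measurement_time_min: float = 7.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "baseline_cohb_pct", tuple(self.baseline_cohb_pct))
        object.__setattr__(self, "post_cohb_pct", tuple(self.post_cohb_pct))
        if not self.baseline_cohb_pct or not self.post_cohb_pct:
            raise ValueError("need at least one baseline and one post COHb sample")
        if self.post_times_min is not None:
            times = tuple(self.post_times_min)
            object.__setattr__(self, "post_times_min", times)
            if len(times) != len(self.post_cohb_pct):
                raise ValueError("post sample times must match post samples")
            if any(t <= 0 for t in times):
                raise ValueError("post sample times must be positive")
        if self.hemoglobin_g_per_l <= 0:
            raise ValueError("hemoglobin must be positive")
        for name in ("vco_administered_ml", "bag_volume_l", "spirometer_volume_l",
                     "lung_volume_l", "residual_co_ppm", "ventilation_rate_l_min",
                     "measurement_time_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k_stpd <= 0 or self.huefner_ml_per_g <= 0:
            raise ValueError("k_stpd and Hufner's number must be positive")


def delta_cohb(record: CORebreathingRecord) -> float:
    """Rise in %COHb: mean(post samples) - mean(baseline samples).

    Raises if the rise is non-positive (no measurable CO uptake).
    """
    delta = float(np.mean(record.post_cohb_pct) - np.mean(record.baseline_cohb_pct))
    if delta <= 0:
        raise ValueError("post COHb does not exceed baseline: no CO uptake measurable")
    return delta


def vco_correction_terms(record: CORebreathingRecord) -> dict[str, float]:
    """Per-term breakdown of the CO dose corrections, all in ml."""
    affinity_loss = record.vco_administered_ml * CO_AFFINITY_LOSS
    apparatus_l = record.bag_volume_l + record.spirometer_volume_l + record.lung_volume_l
    remnant = apparatus_l * record.residual_co_ppm * 1e-6 * 1000.0
    expired_ppm = (_EXPIRED_SLOPE_PPM_PER_PCT * float(np.mean(record.post_cohb_pct))
                   + _EXPIRED_OFFSET_PPM)
    expired = (expired_ppm * 1e-6
               * record.ventilation_rate_l_min * record.measurement_time_min * 1000.0)
    return {
        "administered_ml": record.vco_administered_ml,
        "affinity_loss_ml": affinity_loss,
        "apparatus_remnant_ml": remnant,
        "expired_ml": expired,
    }


def effective_vco(record: CORebreathingRecord) -> float:
    """Effective CO volume (ml) after the three systematic-loss corrections."""
    terms = vco_correction_terms(record)
    eff = (terms["administered_ml"] - terms["affinity_loss_ml"]
           - terms["apparatus_remnant_ml"] - terms["expired_ml"])
    if eff <= 0:
        raise ValueError("CO loss corrections exceed the administered dose")
    return eff


def blood_volume_co(record: CORebreathingRecord) -> float:
    """Reference total blood volume (L) from a CO rebreathing record."""
    return (effective_vco(record) * record.k_stpd * 100.0
            / (record.hemoglobin_g_per_l * delta_cohb(record)
               * record.huefner_ml_per_g))
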