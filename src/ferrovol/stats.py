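"""Repeatability and agreement statistics.

Coefficient of variation (100 * sd / mean), the repeatability
coefficient (1.96 * sd expressed as % of the mean — the value below
which 95% of test-retest differences are expected to fall), and
Bland-Altman agreement analysis.  Sample (n-1) standard deviations are
used throughout.  Nonparametric paired/unpaired tests are exposed as
thin wrappers over scipy for study replication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats

__all__ = [
    "PairedMeasurements",
    "BlandAltmanResult",
    "coefficient_of_variation",
    "repeatability_coefficient",
    "bland_altman",
    "wilcoxon_paired",
    "mann_whitney",
]


def _as_values(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-D sequence of >= 2 values")
    return arr


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Coefficient of variation in %: 100 * sample SD / mean.

    Requires a non-zero mean.  Scale-invariant by construction.
    """
    arr = _as_values(values)
    mean = arr.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return 100.0 * arr.std(ddof=1) / mean


def repeatability_coefficient(values: Sequence[float]) -> float:
    """Repeatability coefficient in % of the mean: 1.96 * sample SD * 100 / mean."""
    return 1.96 * coefficient_of_variation(values)


@dataclass(frozen=True)
class PairedMeasurements:
    """Two methods (or sessions) measured on the same subjects."""

    method_a: tuple[float, ...]
    method_b: tuple[float, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a = tuple(float(x) for x in self.method_a)
        b = tuple(float(x) for x in self.method_b)
        object.__setattr__(self, "method_a", a)
        object.__setattr__(self, "method_b", b)
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("need equal-length sequences of >= 2 pairs")
        if self.labels is not None and len(self.labels) != len(a):
            raise ValueError("labels must match the number of pairs")

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.method_a) - np.asarray(self.method_b)


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    limits_of_agreement: tuple[float, float]  # mean +/- 1.96 * SD
    n: int


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bland-Altman agreement summary of paired measurements (a - b)."""
    d = pairs.differences
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean, sd_diff=sd,
        limits_of_agreement=(mean - 1.96 * sd, mean + 1.96 * sd),
        n=d.size)


def wilcoxon_paired(pairs: PairedMeasurements):
    """Wilcoxon signed-rank test on the paired differences (scipy wrapper)."""
    return sstats.wilcoxon(pairs.method_a, pairs.method_b)


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]):
    """Mann-Whitney U test between two independent samples (scipy wrapper)."""
    return sstats.mannwhitneyu(sample_a, sample_b)
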