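"""Inverse-variance pooling, heterogeneity, failsafe-N and power planning.

Fixed-effect pooling weights each study by 1/v_i; the DerSimonian–Laird
random-effects model adds a method-of-moments between-study variance tau^2
to every weight.  Cochran's Q, I^2 and tau^2 quantify heterogeneity.
Rosenberg's weighted failsafe-N and a normal-approximation sample-size
planner round out the classical toolbox the bias audit builds on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .study_io import MetaSample, StudyValidationError

__all__ = [
    "MetaEstimate",
    "HeterogeneityStats",
    "fixed_effect",
    "heterogeneity",
    "random_effects",
    "failsafe_n_rosenberg",
    "power_sample_size",
]

Z_95 = float(stats.norm.ppf(0.975))  # 1.959964...


@dataclass(frozen=True)
class MetaEstimate:
    """A pooled standardized mean difference with its inference."""

    model: str  # "fixed" | "random"
    theta: float
    se_theta: float
    ci_low: float
    ci_high: float
    z_stat: float
    p_value: float
    weights: np.ndarray
    k: int
    tau2: float = 0.0

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "theta": self.theta,
            "se": self.se_theta,
            "ci": [self.ci_low, self.ci_high],
            "z": self.z_stat,
            "p": self.p_value,
            "tau2": self.tau2,
            "k": self.k,
        }


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q with its derived I^2 and DerSimonian–Laird tau^2."""

    Q: float
    df: int
    I2: float  # percent, 0–100
    tau2: float
    Q_pvalue: float
    degenerate: bool = False  # k == 1

    def to_dict(self) -> dict:
        return {"Q": self.Q, "df": self.df, "I2": self.I2, "tau2": self.tau2, "Q_p": self.Q_pvalue}


def _pool(d: np.ndarray, w: np.ndarray, model: str, tau2: float = 0.0) -> MetaEstimate:
    sw = w.sum()
    theta = float(np.sum(w * d) / sw)
    se = float(1.0 / math.sqrt(sw))
    z = theta / se
    return MetaEstimate(
        model=model,
        theta=theta,
        se_theta=se,
        ci_low=theta - Z_95 * se,
        ci_high=theta + Z_95 * se,
        z_stat=z,
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        weights=w,
        k=len(d),
        tau2=tau2,
    )


def fixed_effect(sample: MetaSample) -> MetaEstimate:
    """Fixed-effect (common-effect) inverse-variance pooled estimate."""
    v = sample.variance
    if np.any(v <= 0):
        raise StudyValidationError("all sampling variances must be positive")
    return _pool(sample.d, 1.0 / v, "fixed")


def heterogeneity(sample: MetaSample, fe: MetaEstimate | None = None) -> HeterogeneityStats:
    """Cochran's Q about the fixed-effect mean, with I^2 and DL tau^2.

    I^2 = max(0, (Q - df)/Q) * 100;
    tau^2_DL = max(0, (Q - df) / (sum w - sum w^2 / sum w)).
    A single-study sample is degenerate: Q = 0, df = 0, I^2 = 0, tau^2 = 0.
    """
    if fe is None:
        fe = fixed_effect(sample)
    k = sample.k
    if k == 1:
        return HeterogeneityStats(Q=0.0, df=0, I2=0.0, tau2=0.0, Q_pvalue=1.0, degenerate=True)
    w = 1.0 / sample.variance
    Q = float(np.sum(w * (sample.d - fe.theta) ** 2))
    df = k - 1
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    c = w.sum() - np.sum(w**2) / w.sum()
    tau2 = max(0.0, (Q - df) / c)
    return HeterogeneityStats(
        Q=Q, df=df, I2=I2, tau2=tau2, Q_pvalue=float(stats.chi2.sf(Q, df))
    )


def random_effects(sample: MetaSample, het: HeterogeneityStats | None = None) -> MetaEstimate:
    """DerSimonian–Laird random-effects pooled estimate.

    Weights are 1/(v_i + tau^2).  When tau^2 = 0 the result coincides with
    the fixed-effect estimate exactly.
    """
    if sample.k < 2:
        raise StudyValidationError("random-effects pooling needs at least 2 studies")
    if het is None:
        het = heterogeneity(sample)
    w = 1.0 / (sample.variance + het.tau2)
    return _pool(sample.d, w, "random", tau2=het.tau2)


def failsafe_n_rosenberg(
    sample: MetaSample, alpha: float = 0.05, *, one_tailed: bool = False
) -> int:
    """Rosenberg's weighted failsafe-N under the fixed-effect model.

    The smallest number of hypothetical null-result studies, each carrying
    the sample's mean weight, whose addition drives the fixed-effect
    combined test below the alpha critical value.  Returns 0 when the
    observed combined test is already non-significant.
    """
    w = 1.0 / sample.variance
    swd = float(np.sum(w * sample.d))
    sw = float(w.sum())
    z_crit = float(stats.norm.ppf(1.0 - alpha) if one_tailed else stats.norm.ppf(1.0 - alpha / 2.0))
    if abs(swd) / math.sqrt(sw) <= z_crit:
        return 0
    w_bar = sw / sample.k
    n = math.ceil((swd**2 / z_crit**2 - sw) / w_bar)
    return max(0, n)


def _power_two_sample(delta: float, n_per_condition: float, alpha: float) -> float:
    """Normal-approximation power of a two-sided two-sample test, equal n."""
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    shift = abs(delta) / math.sqrt(2.0 / n_per_condition)
    return float(stats.norm.sf(z_crit - shift) + stats.norm.cdf(-z_crit - shift))


def power_sample_size(
    delta: float, power_target: float = 0.80, alpha: float = 0.05
) -> int:
    """Smallest per-condition n reaching ``power_target`` for effect ``delta``.

    Uses the closed-form normal approximation to seed an integer scan, so the
    returned n is the exact smallest integer satisfying the power model.
    """
    if not 0.0 < power_target < 1.0:
        raise StudyValidationError("power_target must be in (0, 1)")
    if delta == 0:
        raise StudyValidationError("power never exceeds alpha when delta = 0")
    z_a = float(stats.norm.ppf(1.0 - alpha / 2.0))
    z_b = float(stats.norm.ppf(power_target))
    n = max(2, int(2.0 * ((z_a + z_b) / abs(delta)) ** 2) - 2)
    while _power_two_sample(delta, n, alpha) < power_target:
        n += 1
    while n > 2 and _power_two_sample(delta, n - 1, alpha) >= power_target:
        n -= 1
    return n
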