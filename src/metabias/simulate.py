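"""Synthetic meta-analytic literatures with known truth and known censoring.

Each simulated experiment is a two-condition study: per-subject outcomes are
unit-variance normals whose means differ by the true standardized effect
delta.  Cohen's d is computed from the group means and the pooled SD, so its
sampling distribution (scaled noncentral t) is exact, not approximated.

Publication censoring is one-sided, mimicking a field that expects positive
effects: a study is always published when it is significant *in the
expected direction*; every other study (non-significant, or significant the
"wrong" way) is published with probability pi.  Studies are generated and
filtered until the target published count is reached, with full bookkeeping
of how many were attempted and suppressed.

Two researcher-degrees-of-freedom distortions are available: optional
stopping (test early, top up the sample until significance or a cap) and
multiple correlated outcomes with selective reporting of the strongest.

Per-condition sample sizes follow a discretized lognormal calibrated to the
ego-depletion literature's reported moments (mean ~27 per condition,
inter-quartile range ~17-31); alternatively the (n_treat, n_ctrl) pairs of
a supplied study table can be resampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .study_io import MetaSample, StudyRecord, StudyValidationError, variance_of_d

__all__ = [
    "SampleSizeLaw",
    "OptionalStopping",
    "MultipleOutcomes",
    "SimulationConfig",
    "SimulatedLiterature",
    "simulate_study",
    "simulate_literature",
]

# Lognormal parameters for per-condition n: sigma fixes the IQR spread,
# mu = ln(mean) - sigma^2/2 pins the mean at exactly 27 before rounding.
# Implied quartiles ~ (17.0, 33.4) vs the literature's reported ~ (17, 31);
# the upper quartile inherits the lognormal's heavy right tail.
N_MEAN_DEFAULT = 27.0
N_SIGMA_DEFAULT = 0.5


@dataclass(frozen=True)
class SampleSizeLaw:
    """Discretized-lognormal law for per-condition sample sizes.

    ``resample_from`` overrides the lognormal: (n_treat, n_ctrl) pairs are
    drawn uniformly from the supplied sample's rows instead.
    """

    mean: float = N_MEAN_DEFAULT
    sigma: float = N_SIGMA_DEFAULT
    n_min: int = 5
    resample_from: MetaSample | None = None

    @property
    def mu(self) -> float:
        return math.log(self.mean) - self.sigma**2 / 2.0

    def draw_pairs(self, size: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        if self.resample_from is not None:
            idx = rng.integers(0, self.resample_from.k, size)
            return self.resample_from.n_treat[idx], self.resample_from.n_ctrl[idx]
        raw = rng.lognormal(self.mu, self.sigma, size=(2, size))
        n = np.maximum(np.round(raw).astype(int), self.n_min)
        return n[0], n[1]


@dataclass(frozen=True)
class OptionalStopping:
    """Peek at n_start per condition, top up by n_step until significant or n_max."""

    n_start: int = 20
    n_step: int = 10
    n_max: int = 100


@dataclass(frozen=True)
class MultipleOutcomes:
    """Measure m equicorrelated outcomes, report the one with the largest |z|."""

    m: int = 3
    rho: float = 0.5


Qrp = OptionalStopping | MultipleOutcomes | None


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated literature."""

    delta_true: float = 0.0
    k_published: int = 198
    publish_prob_nonsig: float = 0.05  # pi
    n_dist: SampleSizeLaw = field(default_factory=SampleSizeLaw)
    qrp: Qrp = None
    alpha: float = 0.05
    seed: int = 0
    direction: Literal[1, -1] = 1  # sign of the "expected" effect
    apply_hedges: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.publish_prob_nonsig <= 1.0:
            raise StudyValidationError("publish_prob_nonsig must lie in [0, 1]")
        if self.k_published < 1:
            raise StudyValidationError("k_published must be >= 1")


@dataclass
class SimulatedLiterature:
    """A censored literature plus the bookkeeping needed to audit the audit."""

    published: MetaSample
    attempted_count: int
    suppressed_count: int
    truth: float
    config: SimulationConfig
    qrp_inflated: list[bool] = field(default_factory=list)

    @property
    def suppression_rate(self) -> float:
        return self.suppressed_count / self.attempted_count if self.attempted_count else 0.0


def _d_from_groups(x_treat: np.ndarray, x_ctrl: np.ndarray) -> float:
    """Cohen's d with pooled SD; positive when the treatment mean is higher."""
    n1, n2 = len(x_treat), len(x_ctrl)
    s2 = ((n1 - 1) * x_treat.var(ddof=1) + (n2 - 1) * x_ctrl.var(ddof=1)) / (n1 + n2 - 2)
    return float((x_treat.mean() - x_ctrl.mean()) / math.sqrt(s2))


def _is_significant(d: float, n1: int, n2: int, alpha: float) -> bool:
    v = variance_of_d(d, n1, n2)
    return 2.0 * stats.norm.sf(abs(d) / math.sqrt(v)) < alpha


def simulate_study(
    delta_true: float,
    n1: int,
    n2: int,
    qrp: Qrp = None,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    *,
    study_id: str = "sim",
    apply_hedges: bool = False,
) -> tuple[StudyRecord, bool]:
    """Simulate one two-group experiment; returns (record, qrp_inflated).

    Outcomes are unit-variance normals, mean ``delta_true`` in the treatment
    condition.  Under optional stopping the test runs at n_start and every
    n_step subjects per condition until significance or n_max, and the
    reported d uses the data at stopping; under multiple outcomes the
    outcome with the largest |z| is reported.  ``qrp_inflated`` is True when
    the reported result is significant but the distortion-free reference
    (first look / first outcome) is not.
    """
    if rng is None:
        rng = np.random.default_rng()

    if isinstance(qrp, OptionalStopping):
        n_cap = qrp.n_max
        xt = rng.normal(delta_true, 1.0, n_cap)
        xc = rng.normal(0.0, 1.0, n_cap)
        looks = list(range(qrp.n_start, qrp.n_max + 1, qrp.n_step))
        if looks[-1] != qrp.n_max:
            looks.append(qrp.n_max)
        first_look_sig: bool | None = None
        for n_look in looks:
            d = _d_from_groups(xt[:n_look], xc[:n_look])
            sig = _is_significant(d, n_look, n_look, alpha)
            if first_look_sig is None:
                first_look_sig = sig
            if sig:
                rec = StudyRecord.from_summary(
                    study_id, d, n_look, n_look, alpha=alpha, apply_hedges=apply_hedges
                )
                return rec, rec.is_significant and not first_look_sig
        rec = StudyRecord.from_summary(
            study_id, d, qrp.n_max, qrp.n_max, alpha=alpha, apply_hedges=apply_hedges
        )
        return rec, False

    if isinstance(qrp, MultipleOutcomes):
        m, rho = qrp.m, qrp.rho
        if not 0.0 <= rho < 1.0:
            raise StudyValidationError("outcome correlation rho must lie in [0, 1)")
        # equicorrelated outcomes via a shared component
        shared_t = rng.normal(0.0, 1.0, (n1, 1))
        shared_c = rng.normal(0.0, 1.0, (n2, 1))
        own_t = rng.normal(0.0, 1.0, (n1, m))
        own_c = rng.normal(0.0, 1.0, (n2, m))
        xt = delta_true + math.sqrt(rho) * shared_t + math.sqrt(1.0 - rho) * own_t
        xc = math.sqrt(rho) * shared_c + math.sqrt(1.0 - rho) * own_c
        ds = np.array([_d_from_groups(xt[:, j], xc[:, j]) for j in range(m)])
        zs = np.abs(ds) / np.sqrt([variance_of_d(d, n1, n2) for d in ds])
        best = int(np.argmax(zs))
        rec = StudyRecord.from_summary(
            study_id, ds[best], n1, n2, alpha=alpha, apply_hedges=apply_hedges
        )
        first_sig = _is_significant(float(ds[0]), n1, n2, alpha)
        return rec, rec.is_significant and not first_sig

    xt = rng.normal(delta_true, 1.0, n1)
    xc = rng.normal(0.0, 1.0, n2)
    d = _d_from_groups(xt, xc)
    rec = StudyRecord.from_summary(study_id, d, n1, n2, alpha=alpha, apply_hedges=apply_hedges)
    return rec, False


def _draw_d_batch(
    delta: float, n1: np.ndarray, n2: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized exact draw of Cohen's d via its sufficient statistics.

    The group-mean difference is N(delta, 1/n1 + 1/n2) and the pooled
    variance is an independent chi-square on n1 + n2 - 2 df scaled to mean
    one; their ratio has exactly the distribution of d computed from
    per-subject normals.  Used on the undistorted path where per-subject
    data are never needed.
    """
    df = n1 + n2 - 2
    md = rng.normal(delta, np.sqrt(1.0 / n1 + 1.0 / n2))
    s2 = rng.chisquare(df) / df
    return md / np.sqrt(s2)


def simulate_literature(config: SimulationConfig) -> SimulatedLiterature:
    """Generate studies until ``k_published`` survive the censoring rule.

    Deterministic given ``config.seed``.  With pi = 0 and delta_true = 0
    roughly 1/alpha' attempts are needed per published study (alpha' being
    the one-sided supportive rate), which is allowed but slow by design.
    """
    rng = np.random.default_rng(config.seed)
    published: list[StudyRecord] = []
    inflated: list[bool] = []
    attempted = 0
    alpha = config.alpha
    sgn = float(config.direction)

    if config.qrp is None:
        batch = max(256, 2 * config.k_published)
        while len(published) < config.k_published:
            n1, n2 = config.n_dist.draw_pairs(batch, rng)
            d = _draw_d_batch(config.delta_true, n1, n2, rng)
            if config.apply_hedges:
                d = d * (1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0))
            v = (n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2))
            p = 2.0 * stats.norm.sf(np.abs(d) / np.sqrt(v))
            supportive = (p < alpha) & (sgn * d > 0)
            publish = supportive | (rng.random(batch) < config.publish_prob_nonsig)
            attempted += batch
            for i in np.flatnonzero(publish):
                if len(published) >= config.k_published:
                    attempted -= batch - i  # un-count draws never examined
                    break
                published.append(
                    StudyRecord(
                        study_id=f"sim{len(published) + 1:04d}",
                        d=float(d[i]),
                        n_treat=int(n1[i]),
                        n_ctrl=int(n2[i]),
                        variance=float(v[i]),
                        se=float(math.sqrt(v[i])),
                        z=float(d[i] / math.sqrt(v[i])),
                        p_two_sided=float(p[i]),
                        is_significant=bool(p[i] < alpha),
                    )
                )
                inflated.append(False)
    else:
        while len(published) < config.k_published:
            n1, n2 = config.n_dist.draw_pairs(1, rng)
            rec, was_inflated = simulate_study(
                config.delta_true,
                int(n1[0]),
                int(n2[0]),
                config.qrp,
                alpha,
                rng,
                study_id=f"sim{len(published) + 1:04d}",
                apply_hedges=config.apply_hedges,
            )
            attempted += 1
            supportive = rec.is_significant and sgn * rec.d > 0
            if supportive or rng.random() < config.publish_prob_nonsig:
                published.append(rec)
                inflated.append(was_inflated)

    sample = MetaSample(studies=published, label="simulated", alpha=alpha)
    return SimulatedLiterature(
        published=sample,
        attempted_count=attempted,
        suppressed_count=attempted - config.k_published,
        truth=config.delta_true,
        config=config,
        qrp_inflated=inflated,
    )
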