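"""Duval–Tweedie trim-and-fill correction for funnel-plot asymmetry.

The number of studies "missing" from one side of the funnel is estimated
from the signed ranks of deviations about the pooled mean (L0 or R0
estimator), the most extreme same-side studies are iteratively trimmed
until the estimate stabilises, and mirror-image counterparts of the trimmed
studies are imputed before re-pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .meta_core import MetaEstimate, fixed_effect, heterogeneity, random_effects
from .study_io import MetaSample, StudyRecord, StudyValidationError, two_sided_p

__all__ = ["TrimFillResult", "rank_asymmetry_estimators", "trim_and_fill", "detect_side"]


@dataclass(frozen=True)
class TrimFillResult:
    estimator: str  # "L0" | "R0"
    side: str  # "left" | "right"
    n_filled: int
    iterations: int
    converged: bool
    filled_sample: MetaSample
    fe_corrected: MetaEstimate
    re_corrected: MetaEstimate

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "side": self.side,
            "n_filled": self.n_filled,
            "iterations": self.iterations,
            "converged": self.converged,
            "fe": self.fe_corrected.to_dict(),
            "re": self.re_corrected.to_dict(),
        }


def rank_asymmetry_estimators(sample: MetaSample, theta: float) -> tuple[int, int]:
    """(L0, R0) estimates of the missing-study count for the right side.

    Deviations c_i = d_i - theta are ranked by absolute size (average ranks
    on ties).  L0 is the linear rank estimator round((4S - k(k+1))/(2k-1))
    with S the rank-sum of positive deviations; R0 counts the run of
    consecutive top ranks that are all positive minus one.  Both are floored
    at zero.  For the left side, call with the sample's effects negated.
    """
    k = sample.k
    if k < 3:
        raise StudyValidationError("rank asymmetry estimators need at least 3 studies")
    c = sample.d - theta
    ranks = stats.rankdata(np.abs(c))
    S = float(ranks[c > 0].sum())
    L0 = max(0, round((4.0 * S - k * (k + 1)) / (2.0 * k - 1.0)))
    order = np.argsort(-ranks)  # descending |c| rank
    gamma = 0
    for idx in order:
        if c[idx] > 0:
            gamma += 1
        else:
            break
    R0 = max(0, gamma - 1)
    return int(L0), int(R0)


def detect_side(sample: MetaSample) -> str:
    """Funnel side carrying the surplus of studies, via Kendall's tau(d, se).

    A positive rank correlation between effect size and standard error means
    small (imprecise) studies report larger effects: the surplus sits on the
    right and any suppressed counterparts would lie on the left.
    """
    tau = stats.kendalltau(sample.d, sample.se).statistic
    return "right" if (tau is None or np.isnan(tau) or tau >= 0) else "left"


def _mirror(record: StudyRecord, theta: float, alpha: float) -> StudyRecord:
    """Mirror image of ``record`` about ``theta``; variance inherited unchanged."""
    d_new = 2.0 * theta - record.d
    p = two_sided_p(d_new, record.se)
    return replace(
        record,
        study_id=f"fill:{record.study_id}",
        d=d_new,
        z=d_new / record.se,
        p_two_sided=p,
        is_significant=p < alpha,
        imputed=True,
    )


def trim_and_fill(
    sample: MetaSample,
    estimator: str = "L0",
    side: str = "auto",
    pool_model: str = "fixed",
    max_iter: int = 50,
) -> TrimFillResult:
    """Estimate and impute funnel-missing studies, then re-pool FE and RE.

    Iterates: pool the trimmed set, recompute deviations of the *full* set
    about that pooled mean, re-estimate the missing count, trim that many
    most-extreme same-side studies — until the count stabilises or
    ``max_iter`` passes.  The trimmed studies' mirror images (same variance)
    are then added back and both models re-estimated on the augmented
    sample; the random-effects tau^2 is re-estimated on the filled sample.
    """
    if estimator not in ("L0", "R0"):
        raise StudyValidationError(f"unknown trim-and-fill estimator {estimator!r}")
    if pool_model not in ("fixed", "random"):
        raise StudyValidationError(f"unknown pool model {pool_model!r}")
    if side == "auto":
        side = detect_side(sample)
    if side not in ("left", "right"):
        raise StudyValidationError(f"unknown side {side!r}")
    flip = -1.0 if side == "left" else 1.0

    work = sample
    if flip < 0:
        work = sample.with_studies(
            [replace(s, d=-s.d, z=-s.z) for s in sample.studies]
        )

    k = work.k
    order = np.argsort(work.d)  # ascending; extreme right-side studies last

    def pooled_theta(n_trim: int) -> float:
        kept = [work.studies[i] for i in order[: k - n_trim]]
        trimmed_sample = work.with_studies(kept)
        est = (
            fixed_effect(trimmed_sample)
            if pool_model == "fixed"
            else random_effects(trimmed_sample)
        )
        return est.theta

    n0 = 0
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        theta = pooled_theta(n0)
        L0, R0 = rank_asymmetry_estimators(work, theta)
        n_new = min(L0 if estimator == "L0" else R0, k - 2)
        if n_new == n0:
            converged = True
            break
        n0 = n_new

    theta_final = pooled_theta(n0)
    fill_src = [work.studies[i] for i in order[k - n0 :]] if n0 > 0 else []
    filled = [_mirror(s, theta_final, sample.alpha) for s in fill_src]

    augmented_flipped = list(work.studies) + filled
    if flip < 0:
        augmented = [replace(s, d=-s.d, z=-s.z) for s in augmented_flipped]
    else:
        augmented = augmented_flipped
    filled_sample = sample.with_studies(augmented)

    fe = fixed_effect(filled_sample)
    het = heterogeneity(filled_sample, fe)
    re = random_effects(filled_sample, het) if filled_sample.k >= 2 else fe
    return TrimFillResult(
        estimator=estimator,
        side=side,
        n_filled=len(filled),
        iterations=iterations,
        converged=converged,
        filled_sample=filled_sample,
        fe_corrected=fe,
        re_corrected=re,
    )
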