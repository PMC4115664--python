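"""Egger-type WLS regressions: PET, PEESE, and the conditional PET-PEESE.

Regressing effect size on its standard error (weights 1/se^2) yields the
classical Egger asymmetry test as the slope; the intercept extrapolates to
a hypothetical infinitely precise study and is read as a bias-corrected
effect (the precision-effect test, PET).  Substituting the variance for the
standard error gives PEESE, the less biased intercept when the true effect
is non-zero.  PET-PEESE branches between the two on PET's intercept test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .study_io import MetaSample, StudyValidationError

__all__ = [
    "RegressionResult",
    "ConditionalEstimate",
    "wls_fit",
    "pet",
    "peese",
    "pet_peese",
    "significance_stars",
]

#: Funnel-asymmetry slope tests are conventionally read at this level.
ASYMMETRY_ALPHA = 0.10


@dataclass(frozen=True)
class RegressionResult:
    """A two-coefficient WLS fit: intercept b0 and slope b1 with t inference."""

    model: str  # "PET" | "PEESE" | "WLS"
    b0: float
    b1: float
    se_b0: float
    se_b1: float
    ci_b0: tuple[float, float]
    ci_b1: tuple[float, float]
    t_b0: float
    t_b1: float
    p_b0: float
    p_b1: float
    k: int
    sigma2: float  # multiplicative dispersion (weighted residual mean square)

    @property
    def df(self) -> int:
        return self.k - 2

    def asymmetry_significant(self, alpha: float = ASYMMETRY_ALPHA) -> bool:
        """Funnel-plot asymmetry verdict from the slope test."""
        return self.p_b1 < alpha

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "b0": self.b0,
            "b1": self.b1,
            "se_b0": self.se_b0,
            "se_b1": self.se_b1,
            "ci_b0": list(self.ci_b0),
            "ci_b1": list(self.ci_b1),
            "t_b0": self.t_b0,
            "t_b1": self.t_b1,
            "p_b0": self.p_b0,
            "p_b1": self.p_b1,
            "k": self.k,
        }


@dataclass(frozen=True)
class ConditionalEstimate:
    """The PET-PEESE verdict: which intercept to trust and its value."""

    chosen_model: str  # "PET" | "PEESE"
    final_b0: float
    ci: tuple[float, float]
    rationale_p: float  # PET's intercept p-value that drove the branch
    pet: RegressionResult
    peese: RegressionResult

    def to_dict(self) -> dict:
        return {
            "chosen_model": self.chosen_model,
            "final_b0": self.final_b0,
            "ci": list(self.ci),
            "rationale_p": self.rationale_p,
        }


def wls_fit(
    y: np.ndarray, x: np.ndarray, w: np.ndarray, model: str = "WLS"
) -> RegressionResult:
    """Closed-form weighted least squares of y on [1, x].

    The coefficient covariance uses a multiplicative dispersion estimated
    from the weighted residual mean square on k - 2 degrees of freedom, so
    rescaling all weights by a constant changes nothing.  Inference is
    t-based with k - 2 df.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    k = len(y)
    if k <= 2:
        raise StudyValidationError(f"WLS needs at least 3 studies, got {k}")
    if np.ptp(x) == 0:
        raise StudyValidationError("predictor is constant across studies (collinear with intercept)")
    if np.any(w <= 0):
        raise StudyValidationError("weights must be positive")

    X = np.column_stack([np.ones(k), x])
    A = X.T @ (X * w[:, None])
    b = np.linalg.solve(A, X.T @ (w * y))
    resid = y - X @ b
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    t = b / se
    df = k - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    ci0 = (float(b[0] - tcrit * se[0]), float(b[0] + tcrit * se[0]))
    ci1 = (float(b[1] - tcrit * se[1]), float(b[1] + tcrit * se[1]))
    return RegressionResult(
        model=model,
        b0=float(b[0]),
        b1=float(b[1]),
        se_b0=float(se[0]),
        se_b1=float(se[1]),
        ci_b0=ci0,
        ci_b1=ci1,
        t_b0=float(t[0]),
        t_b1=float(t[1]),
        p_b0=float(p[0]),
        p_b1=float(p[1]),
        k=k,
        sigma2=sigma2,
    )


def pet(sample: MetaSample) -> RegressionResult:
    """Precision-effect test: d_i on se_i, weights 1/se_i^2."""
    se = sample.se
    res = wls_fit(sample.d, se, 1.0 / se**2, model="PET")
    return res


def peese(sample: MetaSample) -> RegressionResult:
    """Precision-effect estimate with SE: d_i on se_i^2, weights 1/se_i^2."""
    se = sample.se
    return wls_fit(sample.d, se**2, 1.0 / se**2, model="PEESE")


def pet_peese(
    sample: MetaSample,
    decision_alpha: float = 0.05,
    *,
    one_tailed: bool = False,
) -> ConditionalEstimate:
    """Conditional estimator: PEESE's intercept iff PET rejects b0 = 0.

    The branch is two-sided at ``decision_alpha`` by default (equivalent to
    checking whether PET's 95% CI excludes zero at the default level); the
    one-tailed variant additionally requires PET's intercept to be positive.
    """
    pet_res = pet(sample)
    peese_res = peese(sample)
    if one_tailed:
        p_branch = stats.t.sf(pet_res.t_b0, pet_res.df)
    else:
        p_branch = pet_res.p_b0
    use_peese = p_branch < decision_alpha
    chosen = peese_res if use_peese else pet_res
    return ConditionalEstimate(
        chosen_model=chosen.model,
        final_b0=chosen.b0,
        ci=chosen.ci_b0,
        rationale_p=float(p_branch),
        pet=pet_res,
        peese=peese_res,
    )


def significance_stars(p: float) -> str:
    """Footnote markers at the conventional 0.10/0.05/0.01/0.001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "†"
    return ""
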