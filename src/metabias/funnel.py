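"""Contour-enhanced funnel plot geometry and rendering.

A funnel plot scatters effect size (horizontal) against standard error
(vertical, increasing downward).  The contour enhancement shades the region
where a study's two-sided test is non-significant, |d| < z_{1-alpha/2}*se,
so that asymmetry caused by missing non-significant studies is visible at a
glance.  Pseudo-confidence bounds theta_FE +/- z*se show where 95% of
studies should fall absent heterogeneity; vertical reference lines mark the
fixed-effect (solid) and random-effects (dashed) pooled estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .meta_core import MetaEstimate, fixed_effect, heterogeneity, random_effects
from .study_io import MetaSample, StudyValidationError

__all__ = ["FunnelGeometry", "build_funnel_geometry", "render_funnel"]


@dataclass(frozen=True)
class FunnelGeometry:
    """Everything needed to draw (or export) one contour-enhanced funnel."""

    label: str
    points: pd.DataFrame  # columns: d, se, significant, imputed
    alpha: float
    z_crit: float
    ref_fixed: float
    ref_random: float
    se_axis_max: float

    def sig_boundary(self, se: np.ndarray) -> np.ndarray:
        """|d| at which a study with standard error ``se`` is exactly borderline."""
        return self.z_crit * np.asarray(se, dtype=float)

    def funnel_bounds(self, se: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pseudo-95% bounds about the fixed-effect estimate."""
        se = np.asarray(se, dtype=float)
        return self.ref_fixed - self.z_crit * se, self.ref_fixed + self.z_crit * se

    def to_frame(self) -> pd.DataFrame:
        """Plain-table export for external plotting tools."""
        df = self.points.copy()
        df["label"] = self.label
        df["ref_fixed"] = self.ref_fixed
        df["ref_random"] = self.ref_random
        df["sig_boundary"] = self.sig_boundary(df["se"].to_numpy())
        return df


def build_funnel_geometry(
    sample: MetaSample,
    fe: MetaEstimate | None = None,
    re: MetaEstimate | None = None,
    alpha: float | None = None,
) -> FunnelGeometry:
    """Assemble funnel geometry for a sample, reusing estimates if given."""
    if alpha is None:
        alpha = sample.alpha
    if fe is None:
        fe = fixed_effect(sample)
    if re is None:
        re = random_effects(sample, heterogeneity(sample, fe)) if sample.k >= 2 else fe
    z_crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    points = pd.DataFrame(
        {
            "d": sample.d,
            "se": sample.se,
            "significant": [s.is_significant for s in sample.studies],
            "imputed": [s.imputed for s in sample.studies],
        }
    )
    return FunnelGeometry(
        label=sample.label,
        points=points,
        alpha=alpha,
        z_crit=z_crit,
        ref_fixed=fe.theta,
        ref_random=re.theta,
        se_axis_max=float(points["se"].max()) * 1.1,
    )


#: Multi-band contour levels offered as an option (two-sided p thresholds).
MULTI_BAND_LEVELS = (0.10, 0.05, 0.01)


def render_funnel(
    geometry: FunnelGeometry,
    path: str | Path,
    *,
    multi_band: bool = False,
    dpi: int = 150,
) -> Path:
    """Write the funnel plot to ``path`` (format from the extension: svg/png/pdf).

    Shaded region = statistically non-significant at the geometry's alpha
    (lighter bands for 0.10/0.05/0.01 when ``multi_band``); solid angled
    lines = pseudo-95% bounds about the fixed-effect estimate; solid
    vertical = fixed-effect estimate; dashed vertical = random-effects
    estimate; imputed studies get a distinct filled marker.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if len(geometry.points) == 0:
        raise StudyValidationError("cannot render a funnel with no studies")
    path = Path(path)

    se_grid = np.linspace(0.0, geometry.se_axis_max, 200)
    fig, ax = plt.subplots(figsize=(5.0, 4.5))

    if multi_band:
        shades = ["0.92", "0.82", "0.72"]
        prev = np.zeros_like(se_grid)
        for level, shade in zip(sorted(MULTI_BAND_LEVELS, reverse=True), shades):
            zc = stats.norm.ppf(1.0 - level / 2.0)
            ax.fill_betweenx(se_grid, -zc * se_grid, zc * se_grid, color=shade, zorder=0)
    else:
        bound = geometry.sig_boundary(se_grid)
        ax.fill_betweenx(se_grid, -bound, bound, color="0.85", zorder=0)

    lo, hi = geometry.funnel_bounds(se_grid)
    ax.plot(lo, se_grid, color="black", lw=1.0)
    ax.plot(hi, se_grid, color="black", lw=1.0)
    ax.axvline(geometry.ref_fixed, color="black", lw=1.2, label="fixed effect")
    ax.axvline(geometry.ref_random, color="black", lw=1.2, ls="--", label="random effects")

    pts = geometry.points
    observed = pts[~pts["imputed"]]
    imputed = pts[pts["imputed"]]
    ax.scatter(
        observed["d"], observed["se"], s=18, facecolors="none",
        edgecolors="black", linewidths=0.8, label="observed",
    )
    if len(imputed):
        ax.scatter(
            imputed["d"], imputed["se"], s=22, marker="D",
            facecolors="black", edgecolors="black", label="imputed",
        )

    ax.set_ylim(geometry.se_axis_max, 0.0)  # se increases downward
    ax.set_xlabel("standardized mean difference (d)")
    ax.set_ylabel("standard error")
    ax.set_title(geometry.label)
    ax.legend(loc="upper left", fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path
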