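"""Run the full publication-bias audit over a sample and its subgroups.

One "block" per analysis sample (the full table plus one per subgroup
label): fixed- and random-effects pooling, heterogeneity, the three-basis
excess-significance battery, trim-and-fill, PET/PEESE with the conditional
estimate, failsafe-N, and funnel geometry.  Formatting helpers emit the
three canonical summary tables (pooled models + binomial tests; trim-and-
fill; PET-PEESE) in a delimited, round-trippable layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .excess_significance import POWER_BASES, PowerAnalysis, excess_significance_test
from .funnel import FunnelGeometry, build_funnel_geometry, render_funnel
from .meta_core import (
    HeterogeneityStats,
    MetaEstimate,
    failsafe_n_rosenberg,
    fixed_effect,
    heterogeneity,
    random_effects,
)
from .pet_peese import ConditionalEstimate, pet_peese, significance_stars
from .study_io import MetaSample, StudyValidationError
from .trim_fill import TrimFillResult, trim_and_fill

__all__ = ["BatteryConfig", "SampleBlock", "BatteryReport", "run_battery", "format_tables"]

logger = logging.getLogger("metabias")

#: Subsamples smaller than this carry a caution flag on funnel-based methods.
SMALL_K_THRESHOLD = 10


@dataclass(frozen=True)
class BatteryConfig:
    alpha: float = 0.05
    asymmetry_alpha: float = 0.10
    decision_alpha: float = 0.05
    tf_estimator: str = "L0"
    tf_side: str = "auto"
    tf_pool_model: str = "fixed"
    power_bases: tuple[str, ...] = POWER_BASES
    seed: int | None = None  # echoed into the report; the analysis path is deterministic

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "asymmetry_alpha": self.asymmetry_alpha,
            "decision_alpha": self.decision_alpha,
            "tf_estimator": self.tf_estimator,
            "tf_side": self.tf_side,
            "tf_pool_model": self.tf_pool_model,
            "power_bases": list(self.power_bases),
            "seed": self.seed,
        }


@dataclass
class SampleBlock:
    """All audit results for one analysis sample."""

    label: str
    k: int
    fe: MetaEstimate
    re: MetaEstimate
    het: HeterogeneityStats
    power: dict[str, PowerAnalysis]
    trimfill: TrimFillResult | None
    pet_peese: ConditionalEstimate | None
    funnel: FunnelGeometry
    failsafe_n: int
    small_k_caution: bool

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "k": self.k,
            "fe": self.fe.to_dict(),
            "re": self.re.to_dict(),
            "heterogeneity": self.het.to_dict(),
            "power": {b: p.to_dict() for b, p in self.power.items()},
            "trimfill": self.trimfill.to_dict() if self.trimfill else None,
            "pet": self.pet_peese.pet.to_dict() if self.pet_peese else None,
            "peese": self.pet_peese.peese.to_dict() if self.pet_peese else None,
            "pet_peese": self.pet_peese.to_dict() if self.pet_peese else None,
            "failsafe_n": self.failsafe_n,
            "small_k_caution": self.small_k_caution,
        }


@dataclass
class BatteryReport:
    blocks: list[SampleBlock]
    config: BatteryConfig

    def block(self, label: str) -> SampleBlock:
        for b in self.blocks:
            if b.label == label:
                return b
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {"config": self.config.to_dict(), "blocks": [b.to_dict() for b in self.blocks]}


def _analyse_one(sample: MetaSample, config: BatteryConfig) -> SampleBlock:
    logger.info("analysing sample %r (k=%d)", sample.label, sample.k)
    fe = fixed_effect(sample)
    het = heterogeneity(sample, fe)
    re = random_effects(sample, het) if sample.k >= 2 else fe

    power: dict[str, PowerAnalysis] = {}
    for basis in config.power_bases:
        power[basis] = excess_significance_test(sample, basis, config.alpha)

    trimfill = pet = None
    if sample.k >= 3:
        trimfill = trim_and_fill(
            sample,
            estimator=config.tf_estimator,
            side=config.tf_side,
            pool_model=config.tf_pool_model,
        )
        try:
            pet = pet_peese(sample, config.decision_alpha)
        except StudyValidationError as exc:
            logger.warning("PET-PEESE unavailable for %r: %s", sample.label, exc)
    else:
        logger.warning("sample %r has k=%d < 3: funnel-based corrections skipped", sample.label, sample.k)

    small_k = sample.k < SMALL_K_THRESHOLD
    if small_k:
        logger.warning(
            "sample %r has fewer than %d studies; funnel-based results are unreliable",
            sample.label,
            SMALL_K_THRESHOLD,
        )
    return SampleBlock(
        label=sample.label,
        k=sample.k,
        fe=fe,
        re=re,
        het=het,
        power=power,
        trimfill=trimfill,
        pet_peese=pet,
        funnel=build_funnel_geometry(sample, fe, re, config.alpha),
        failsafe_n=failsafe_n_rosenberg(sample, config.alpha),
        small_k_caution=small_k,
    )


def run_battery(
    sample: MetaSample,
    by_subgroup: bool = True,
    config: BatteryConfig | None = None,
) -> BatteryReport:
    """Audit the full sample and, when labels exist, each subgroup separately.

    Every subgroup is re-analysed from scratch (its own tau^2, its own
    trim-and-fill, its own regressions) — subsamples share nothing with the
    full-sample fit.  Studies without a label appear only in the full block.
    """
    if config is None:
        config = BatteryConfig(alpha=sample.alpha)
    blocks = [_analyse_one(sample, config)]
    if by_subgroup:
        labels: list[str] = []
        for s in sample.studies:
            if s.subgroup is not None and s.subgroup not in labels:
                labels.append(s.subgroup)
        for label in labels:
            sub = sample.subsample(label, [s for s in sample.studies if s.subgroup == label])
            blocks.append(_analyse_one(sub, config))
    return BatteryReport(blocks=blocks, config=config)


def _fmt_est(est: MetaEstimate, mask_na: bool = False) -> str:
    if mask_na:
        return "NA"
    return f"{est.theta:.2f} ({est.ci_low:.2f}, {est.ci_high:.2f})"


def _fmt_p(p: float) -> str:
    return f"{p:.2e}" if p < 0.001 else f"{p:.3f}"


def format_tables(report: BatteryReport) -> dict[str, pd.DataFrame]:
    """The three canonical summary tables as DataFrames.

    Estimates are rounded to two decimals, p-values below 0.001 rendered in
    scientific notation, and random-effects cells display "NA" in
    homogeneous samples (tau^2 = 0) even though the underlying records keep
    the computed values.
    """
    t1_rows, t2_rows, t3_rows = [], [], []
    for b in report.blocks:
        mask_re = b.het.tau2 == 0.0
        row1 = {
            "sample": b.label,
            "fe": _fmt_est(b.fe),
            "re": _fmt_est(b.re, mask_na=mask_re),
            "heterogeneity": f"{b.het.Q:.2f}; {b.het.I2:.1f}%",
            "k_significant": int(b.funnel.points["significant"].sum()),
        }
        for basis in ("individual", "fixed", "random"):
            if basis in b.power:
                pa = b.power[basis]
                cell = f"{pa.mean_power:.2f} ({_fmt_p(pa.binom_p)})"
            else:
                cell = "NA"
            if basis == "random" and mask_re:
                cell = "NA"
            row1[f"pow_{basis}"] = cell
        t1_rows.append(row1)

        if b.trimfill is not None:
            t2_rows.append(
                {
                    "sample": b.label,
                    "filled": b.trimfill.n_filled,
                    "fe": _fmt_est(b.trimfill.fe_corrected),
                    "re": _fmt_est(
                        b.trimfill.re_corrected, mask_na=b.trimfill.re_corrected.tau2 == 0.0
                    ),
                }
            )
        if b.pet_peese is not None:
            pt, ps = b.pet_peese.pet, b.pet_peese.peese
            t3_rows.append(
                {
                    "sample": b.label,
                    "pet_b0": f"{pt.b0:.2f} ({pt.ci_b0[0]:.2f}, {pt.ci_b0[1]:.2f})",
                    "pet_b1": f"{pt.b1:.2f}{significance_stars(pt.p_b1)}",
                    "peese_b0": f"{ps.b0:.2f} ({ps.ci_b0[0]:.2f}, {ps.ci_b0[1]:.2f})",
                    "peese_b1": f"{ps.b1:.2f}{significance_stars(ps.p_b1)}",
                    "chosen": b.pet_peese.chosen_model,
                }
            )
    return {
        "models_and_binomial": pd.DataFrame(t1_rows),
        "trim_and_fill": pd.DataFrame(t2_rows),
        "pet_peese": pd.DataFrame(t3_rows),
    }


def write_report(
    report: BatteryReport, out_dir: str | Path, *, plots: bool = False
) -> dict[str, Path]:
    """Write the three tables (TSV) and optionally one funnel plot per block."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in format_tables(report).items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written[name] = p
    if plots:
        for b in report.blocks:
            p = out / f"funnel_{b.label}.png"
            render_funnel(b.funnel, p)
            written[f"funnel_{b.label}"] = p
    return written
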