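"""Study-level data model for meta-analyses of standardized mean differences.

A study contributes a Cohen's *d* (positive = the focal/"depletion" condition
performs worse) together with the per-condition sample sizes.  Everything the
downstream estimators need — the sampling variance of *d*, its standard
error, the *z* statistic and two-sided *p*-value, and a significance flag —
is derived here once so that every stage of the audit uses one consistent
significance criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudyValidationError",
    "StudyRecord",
    "MetaSample",
    "variance_of_d",
    "two_sided_p",
    "hedges_correction",
    "read_study_table",
    "write_study_table",
]

#: Default two-sided significance level used throughout the package.
DEFAULT_ALPHA = 0.05

REQUIRED_COLUMNS = ("study_id", "d", "n_treat", "n_ctrl")


class StudyValidationError(ValueError):
    """Raised when a study table or a single study fails validation.

    ``errors`` collects one human-readable message per offending row so a
    malformed table is reported in a single pass rather than one row at a
    time.
    """

    def __init__(self, errors: Sequence[str] | str):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def _check_group_size(n: object, label: str, study: str) -> int:
    """Validate one per-condition sample size (integral, >= 2)."""
    if isinstance(n, bool):
        raise StudyValidationError(f"study {study!r}: {label} must be a count, got {n!r}")
    try:
        nf = float(n)
    except (TypeError, ValueError):
        raise StudyValidationError(f"study {study!r}: {label} is non-numeric ({n!r})") from None
    if not math.isfinite(nf) or nf != int(nf):
        raise StudyValidationError(f"study {study!r}: {label} must be an integer, got {n!r}")
    if nf < 2:
        raise StudyValidationError(f"study {study!r}: {label} must be >= 2, got {int(nf)}")
    return int(nf)


def variance_of_d(d: float, n_treat: int, n_ctrl: int, *, study: str = "<anon>") -> float:
    """Large-sample sampling variance of Cohen's d for a two-group design.

    var(d) = (n1 + n2)/(n1 * n2) + d^2 / (2 * (n1 + n2))

    The first term is the variance of a mean difference in pooled-SD units;
    the second reflects the uncertainty of the pooled SD itself.  Symmetric
    in the two groups and invariant to the sign of ``d``.
    """
    n1 = _check_group_size(n_treat, "n_treat", study)
    n2 = _check_group_size(n_ctrl, "n_ctrl", study)
    big_n = n1 + n2
    return big_n / (n1 * n2) + d * d / (2.0 * big_n)


def two_sided_p(d: float, se: float) -> float:
    """Two-sided normal p-value for H0: effect = 0, i.e. 2*(1 - Phi(|d|/se))."""
    if not se > 0:
        raise StudyValidationError(f"standard error must be positive, got {se!r}")
    return float(2.0 * stats.norm.sf(abs(d) / se))


def hedges_correction(d: float, n_treat: int, n_ctrl: int) -> float:
    """Small-sample (Hedges' g) correction factor applied to d.

    J = 1 - 3/(4*df - 1) with df = n1 + n2 - 2.  Off by default in the
    reading path (coded effect sizes are taken as-is); the simulator can opt
    in when emulating literatures coded as g.
    """
    df = n_treat + n_ctrl - 2
    return d * (1.0 - 3.0 / (4.0 * df - 1.0))


@dataclass(frozen=True)
class StudyRecord:
    """One experiment's effect size with its derived sampling quantities."""

    study_id: str
    d: float
    n_treat: int
    n_ctrl: int
    variance: float
    se: float
    z: float
    p_two_sided: float
    is_significant: bool
    subgroup: str | None = None
    imputed: bool = False

    @classmethod
    def from_summary(
        cls,
        study_id: str,
        d: float,
        n_treat: int,
        n_ctrl: int,
        *,
        alpha: float = DEFAULT_ALPHA,
        subgroup: str | None = None,
        apply_hedges: bool = False,
        imputed: bool = False,
    ) -> "StudyRecord":
        """Build a record from (d, n_treat, n_ctrl), deriving the rest."""
        try:
            d = float(d)
        except (TypeError, ValueError):
            raise StudyValidationError(
                f"study {study_id!r}: effect size is non-numeric ({d!r})"
            ) from None
        if not math.isfinite(d):
            raise StudyValidationError(f"study {study_id!r}: effect size is not finite ({d!r})")
        if apply_hedges:
            _check_group_size(n_treat, "n_treat", study_id)
            _check_group_size(n_ctrl, "n_ctrl", study_id)
            d = hedges_correction(d, int(n_treat), int(n_ctrl))
        variance = variance_of_d(d, n_treat, n_ctrl, study=study_id)
        se = math.sqrt(variance)
        z = d / se
        p = two_sided_p(d, se)
        return cls(
            study_id=str(study_id),
            d=d,
            n_treat=int(n_treat),
            n_ctrl=int(n_ctrl),
            variance=variance,
            se=se,
            z=z,
            p_two_sided=p,
            is_significant=p < alpha,
            subgroup=None if subgroup is None else str(subgroup),
            imputed=imputed,
        )

    @property
    def n_total(self) -> int:
        return self.n_treat + self.n_ctrl


@dataclass
class MetaSample:
    """An ordered collection of studies analysed as one meta-analytic sample."""

    studies: list[StudyRecord]
    label: str = "Full"
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if len(self.studies) < 1:
            raise StudyValidationError(f"sample {self.label!r} is empty")
        ids = [s.study_id for s in self.studies if not s.imputed]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise StudyValidationError(f"sample {self.label!r}: duplicate study_id(s) {dupes}")

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.studies)

    @property
    def k(self) -> int:
        return len(self.studies)

    @property
    def d(self) -> np.ndarray:
        return np.array([s.d for s in self.studies], dtype=float)

    @property
    def variance(self) -> np.ndarray:
        return np.array([s.variance for s in self.studies], dtype=float)

    @property
    def se(self) -> np.ndarray:
        return np.array([s.se for s in self.studies], dtype=float)

    @property
    def n_treat(self) -> np.ndarray:
        return np.array([s.n_treat for s in self.studies], dtype=int)

    @property
    def n_ctrl(self) -> np.ndarray:
        return np.array([s.n_ctrl for s in self.studies], dtype=int)

    @property
    def significant_count(self) -> int:
        return sum(s.is_significant for s in self.studies)

    @classmethod
    def from_summaries(
        cls,
        rows: Iterable[tuple],
        *,
        label: str = "Full",
        alpha: float = DEFAULT_ALPHA,
        apply_hedges: bool = False,
    ) -> "MetaSample":
        """Build a sample from (study_id, d, n_treat, n_ctrl[, subgroup]) tuples."""
        studies = []
        errors: list[str] = []
        for row in rows:
            sub = row[4] if len(row) > 4 else None
            try:
                studies.append(
                    StudyRecord.from_summary(
                        row[0], row[1], row[2], row[3],
                        alpha=alpha, subgroup=sub, apply_hedges=apply_hedges,
                    )
                )
            except StudyValidationError as exc:
                errors.extend(exc.errors)
        if errors:
            raise StudyValidationError(errors)
        return cls(studies=studies, label=label, alpha=alpha)

    def subsample(self, label: str, studies: Sequence[StudyRecord]) -> "MetaSample":
        return MetaSample(studies=list(studies), label=label, alpha=self.alpha)

    def with_studies(self, studies: Sequence[StudyRecord], label: str | None = None) -> "MetaSample":
        return MetaSample(
            studies=list(studies), label=self.label if label is None else label, alpha=self.alpha
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with all derived columns appended."""
        return pd.DataFrame(
            {
                "study_id": [s.study_id for s in self.studies],
                "d": self.d,
                "n_treat": self.n_treat,
                "n_ctrl": self.n_ctrl,
                "subgroup": [s.subgroup for s in self.studies],
                "variance": self.variance,
                "se": self.se,
                "z": [s.z for s in self.studies],
                "p_two_sided": [s.p_two_sided for s in self.studies],
                "significant": [s.is_significant for s in self.studies],
                "imputed": [s.imputed for s in self.studies],
            }
        )


def _sniff_delimiter(path: Path) -> str:
    header = path.read_text(encoding="utf-8").splitlines()[0] if path.stat().st_size else ""
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_study_table(
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    label: str | None = None,
    delimiter: str | None = None,
) -> MetaSample:
    """Read a delimited study table (comma or tab, header row) into a sample.

    Required columns: ``study_id, d, n_treat, n_ctrl``; a ``subgroup`` column
    is picked up when present.  ``column_map`` renames file columns to these
    canonical names, e.g. ``{"effect": "d"}``.  All rows failing validation
    are reported together.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype={0: str}, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StudyValidationError([f"missing required column {c!r}" for c in missing])
    has_subgroup = "subgroup" in df.columns

    rows = []
    for _, r in df.iterrows():
        sub = r["subgroup"] if has_subgroup and pd.notna(r["subgroup"]) else None
        rows.append((r["study_id"], r["d"], r["n_treat"], r["n_ctrl"], sub))
    return MetaSample.from_summaries(
        rows, label=label if label is not None else path.stem, alpha=alpha
    )


def write_study_table(sample: MetaSample, path: str | Path, *, delimiter: str = ",") -> None:
    """Write the sample with derived columns appended (round-trip safe).

    Floats are written with shortest round-trip precision so re-reading
    reproduces the derived fields bit-for-bit.
    """
    df = sample.to_frame()
    df.to_csv(path, sep=delimiter, index=False)
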