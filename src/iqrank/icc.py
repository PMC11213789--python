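"""Agreement statistics: two-way random absolute-agreement ICC.

The intraclass correlation coefficient used throughout observer studies
of this kind is the two-way random-effects, absolute-agreement ICC
(McGraw & Wong's ICC(A,1) and ICC(A,k); SPSS's "two-way random,
absolute agreement").  Both the subjects (scans) and the raters
(observers) are treated as random samples, and systematic rater offsets
count against agreement — which is exactly what distinguishes rank data
(offset-free by construction) from Likert data (offset-prone).

Estimates come from the classical two-way ANOVA decomposition of an
n_subjects x k_raters matrix with one observation per cell:

    single:  (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))
    average: (MSR - MSE) / (MSR + (MSC - MSE)/n)

with MSR/MSC/MSE the subject, rater and residual mean squares.  95%
confidence intervals follow the F-based construction with a
Satterthwaite-approximated denominator df for the single-measures case;
the average-measures interval is the Spearman-Brown transform of the
single-measures bounds.  This matches the convention of the standard
statistical packages, so published ICC tables are reproducible given
the same ratings matrix.

Raw estimates may be negative; report tables conventionally floor them
at 0, so :class:`ICCResult` keeps the raw values and exposes a clamped
view for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedEstimateError, ValidationError

__all__ = [
    "RatingsMatrix",
    "ICCResult",
    "anova_mean_squares",
    "icc_agreement",
    "confusion_matrix",
]


@dataclass(frozen=True)
class RatingsMatrix:
    """n_subjects x k_raters scores (ranks or Likert), complete design."""

    values: np.ndarray
    subject_ids: tuple
    rater_ids: tuple

    def __init__(self, values, subject_ids=None, rater_ids=None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("ratings must be a 2-D subjects x raters array")
        n, k = values.shape
        if n < 2 or k < 2:
            raise ValidationError(
                f"need at least 2 subjects and 2 raters, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError(
                "ratings contain missing or non-finite cells; the design must "
                "be complete — handle incomplete cases upstream"
            )
        if subject_ids is None:
            subject_ids = [f"s{i+1}" for i in range(n)]
        if rater_ids is None:
            rater_ids = [f"r{j+1}" for j in range(k)]
        if len(subject_ids) != n or len(rater_ids) != k:
            raise ValidationError("label lengths do not match the matrix shape")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subject_ids", tuple(subject_ids))
        object.__setattr__(self, "rater_ids", tuple(rater_ids))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.subject_ids), columns=list(self.rater_ids)
        ).rename_axis("subject_id")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RatingsMatrix":
        return cls(df.to_numpy(dtype=float), df.index.tolist(), df.columns.tolist())

    @classmethod
    def from_csv(cls, path) -> "RatingsMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))


class MeanSquares(NamedTuple):
    ms_rows: float
    ms_cols: float
    ms_error: float
    df_rows: int
    df_cols: int
    df_error: int


def anova_mean_squares(m: RatingsMatrix) -> MeanSquares:
    """Two-way ANOVA decomposition (one observation per cell).

    SS_total = SS_rows + SS_cols + SS_error with df (n-1), (k-1),
    (n-1)(k-1); mean squares are SS/df.
    """
    x = m.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_error = ss_total - ss_rows - ss_cols
    df_rows, df_cols = n - 1, k - 1
    df_error = df_rows * df_cols
    return MeanSquares(
        ss_rows / df_rows, ss_cols / df_cols, ss_error / df_error,
        df_rows, df_cols, df_error,
    )


@dataclass(frozen=True)
class ICCResult:
    """One agreement analysis: estimate, 95% CI and its ANOVA backing."""

    estimate: float
    ci_low: float
    ci_high: float
    measures: str  # "single" or "average"
    model: str
    ms_rows: float
    ms_cols: float
    ms_error: float
    df_rows: int
    df_cols: int
    df_error: int
    alpha: float

    @property
    def clamped_display(self) -> tuple[float, float, float]:
        """(estimate, ci_low, ci_high) with negatives floored at 0."""
        return (max(0.0, self.estimate), max(0.0, self.ci_low), max(0.0, self.ci_high))

    def to_dict(self) -> dict:
        out = {f: getattr(self, f) for f in (
            "estimate", "ci_low", "ci_high", "measures", "model",
            "ms_rows", "ms_cols", "ms_error",
            "df_rows", "df_cols", "df_error", "alpha",
        )}
        est, lo, hi = self.clamped_display
        out["clamped_display"] = {"estimate": est, "ci_low": lo, "ci_high": hi}
        return out


def icc_agreement(
    m: RatingsMatrix, measures: str = "single", alpha: float = 0.05
) -> ICCResult:
    """Two-way random, absolute-agreement ICC with a 95% (1-alpha) CI.

    ``measures="single"`` gives the reliability of one rater's scores
    (ICC(A,1), the intraobserver convention); ``measures="average"``
    gives the reliability of the k-rater mean (ICC(A,k), the
    interobserver convention).
    """
    if measures not in ("single", "average"):
        raise ValidationError(f"measures must be 'single' or 'average', got {measures!r}")
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha!r}")

    ms = anova_mean_squares(m)
    msr, msc, mse = ms.ms_rows, ms.ms_cols, ms.ms_error
    n, k = m.n_subjects, m.n_raters

    if msr == 0.0 and mse == 0.0:
        raise UndefinedEstimateError(
            "ratings matrix is constant (no subject and no residual variance); "
            "the agreement coefficient is undefined"
        )

    single = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    average = (msr - mse) / (msr + (msc - mse) / n)

    # Perfect agreement: both rater and residual variance vanish.
    if msc == 0.0 and mse == 0.0:
        lo1 = hi1 = 1.0
    else:
        # McGraw & Wong F interval for ICC(A,1), Satterthwaite df.
        r = single
        a = k * r / (n * (1.0 - r)) if r != 1.0 else np.inf
        b = 1.0 + k * r * (n - 1.0) / (n * (1.0 - r)) if r != 1.0 else np.inf
        if np.isfinite(a):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_up = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_lo = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo1 = n * (msr - f_up * mse) / (
                f_up * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi1 = n * (f_lo * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_lo * msr
            )
        else:  # estimate exactly 1 but some rater variance: degenerate
            lo1 = hi1 = 1.0

    if measures == "single":
        est, lo, hi = single, lo1, hi1
    else:
        # Spearman-Brown step applied to the single-measures bounds
        def sb(x: float) -> float:
            return k * x / (1.0 + (k - 1.0) * x)

        est, lo, hi = average, sb(lo1), sb(hi1)

    return ICCResult(
        estimate=float(est), ci_low=float(lo), ci_high=float(hi),
        measures=measures, model="two-way random, absolute agreement",
        ms_rows=msr, ms_cols=msc, ms_error=mse,
        df_rows=ms.df_rows, df_cols=ms.df_cols, df_error=ms.df_error,
        alpha=alpha,
    )


def confusion_matrix(
    a: Sequence[int],
    b: Sequence[int],
    levels: Iterable[int] = range(1, 6),
) -> pd.DataFrame:
    """Cross-tabulate two raters' ordinal scores over the same subjects.

    Cell (i, j) counts subjects scored level_i by ``a`` and level_j by
    ``b``; a diagonal table means perfect agreement.
    """
    levels = list(levels)
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("score vectors must be 1-D and of equal length")
    for name, v in (("a", a), ("b", b)):
        bad = set(v.tolist()) - set(levels)
        if bad:
            raise ValidationError(f"scores in {name} outside levels {levels}: {sorted(bad)}")
    tab = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    return tab.reindex(index=levels, columns=levels, fill_value=0)
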