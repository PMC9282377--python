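"""Precision statistics: CV, precision error, least significant change, ICC.

A measurement campaign is a subjects x repetitions matrix per parameter.
The precision error (PE) is the root mean square of the per-subject
coefficients of variation; the least significant change is
LSC = PE * Z * sqrt(1/n1 + 1/n2) with Z = 1.96 (two-tailed 95%), n1
baseline measures and n2 follow-up measures. Reliability is the
intraclass correlation coefficient of the two-way random-effects model,
absolute agreement, single measures (ICC(A,1) / ICC(2,1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MeasurementMatrix:
    """subjects (rows) x repetitions (columns) values of one parameter."""

    parameter: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x repetitions)")
        m, k = self.values.shape
        if m < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 repetitions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in {self.parameter!r}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_repetitions(self) -> int:
        return self.values.shape[1]


@dataclass
class PrecisionResult:
    parameter: str
    cv_per_subject: np.ndarray
    pe_pct: float
    lsc_pct: float
    icc: float
    z: float = 1.96
    n1: int = 1
    n2: int = 2


def cv(values: np.ndarray, ddof: int = 1) -> float:
    """Coefficient of variation: sample SD / mean (one subject's repeats)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least two values")
    mu = values.mean()
    if mu == 0:
        raise ValueError("CV undefined for zero mean")
    return float(values.std(ddof=ddof) / mu)


def precision_error(matrix: MeasurementMatrix, ddof: int = 1) -> float:
    """PE in percent: 100 * sqrt(mean of squared per-subject CVs).

    A subject whose repeats are all identical contributes CV = 0 even when
    the common value is 0 (no observed variability); a zero mean with
    non-zero spread is still an error.
    """
    cvs = []
    for j in range(matrix.n_subjects):
        row = matrix.values[j]
        if row.std(ddof=ddof) == 0.0:
            cvs.append(0.0)
            continue
        try:
            cvs.append(cv(row, ddof=ddof))
        except ValueError as e:
            raise ValueError(f"subject {j} of {matrix.parameter!r}: {e}") from e
    return 100.0 * float(np.sqrt(np.mean(np.square(cvs))))


def lsc(pe_pct: float, z: float = 1.96, n1: int = 1, n2: int = 2) -> float:
    """Least significant change in percent."""
    if pe_pct < 0:
        raise ValueError("PE must be >= 0")
    if n1 < 1 or n2 < 1:
        raise ValueError("n1, n2 must be >= 1")
    return pe_pct * z * float(np.sqrt(1.0 / n1 + 1.0 / n2))


def icc_two_way_random_absolute_single(matrix: MeasurementMatrix) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    From the two-way ANOVA mean squares (rows = subjects, columns = raters):
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/m)(MSC - MSE)).
    """
    x = matrix.values
    m, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = m * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (m - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((m - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / m) * (msc - mse)
    if ss_total == 0 or denom == 0:
        raise ValueError("zero total variance: ICC undefined")
    return float((msr - mse) / denom)


def precision_summary(
    matrix: MeasurementMatrix,
    z: float = 1.96,
    n1: int = 1,
    n2: int = 2,
    ddof: int = 1,
) -> PrecisionResult:
    """CV/PE/LSC/ICC bundle for one parameter."""
    cvs = np.array([cv(matrix.values[j], ddof=ddof)
                    for j in range(matrix.n_subjects)])
    pe = 100.0 * float(np.sqrt(np.mean(cvs**2)))
    return PrecisionResult(
        parameter=matrix.parameter,
        cv_per_subject=cvs,
        pe_pct=pe,
        lsc_pct=lsc(pe, z, n1, n2),
        icc=icc_two_way_random_absolute_single(matrix),
        z=z, n1=n1, n2=n2,
    )


@dataclass
class EffectResult:
    """Per-subject relative change between baseline and follow-up, percent."""

    parameter: str
    per_subject_pct: np.ndarray
    mean_pct: float = field(init=False)
    sd_pct: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_subject_pct = np.asarray(self.per_subject_pct, dtype=float)
        self.mean_pct = float(self.per_subject_pct.mean())
        self.sd_pct = float(self.per_subject_pct.std(ddof=1))


def relative_change(
    follow: np.ndarray,
    base: np.ndarray,
    parameter: str = "",
) -> EffectResult:
    """Per-subject 100*(follow - base)/base with mean and sample SD."""
    follow = np.asarray(follow, dtype=float)
    base = np.asarray(base, dtype=float)
    if follow.shape != base.shape:
        raise ValueError("baseline and follow-up must be paired")
    if np.any(base == 0):
        raise ValueError("zero baseline value")
    return EffectResult(parameter, 100.0 * (follow - base) / base)
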