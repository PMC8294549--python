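"""Test–retest reliability of the benchmark: ICC, Cronbach's alpha, SEM.

The benchmark is repeated (e.g. the manual marker-center selection is done
twice on the same captures), giving k >= 2 error values per measurement unit
(here: per landmark).  Agreement between the repeats is quantified with the
intraclass correlation coefficient from the two-way ANOVA variance
decomposition, with an exact F-distribution 95% confidence interval,
Cronbach's alpha as the internal-consistency reliability, and the standard
error of measurement SEM = SD * sqrt(1 - alpha).

Two single-measurement ICC forms are provided:

``absolute_agreement`` (default)
    (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n); sensitive to
    systematic trial-to-trial shifts.  Point estimate of ICC(2,1) and
    ICC(A,1), which coincide.
``consistency``
    (MSR - MSE) / (MSR + (k-1) MSE); invariant to a constant added to one
    trial.  ICC(3,1) / ICC(C,1).

with MSR/MSC/MSE the row (unit), column (trial) and error mean squares.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .metrics import ErrorRecord, records_to_frame

__all__ = [
    "TrialMatrix",
    "ReliabilityResult",
    "DegenerateVarianceError",
    "icc",
    "cronbach_alpha",
    "sem",
    "classify_icc",
    "pooled_sd",
    "trial_matrix_from_records",
    "reliability_report",
    "ICC_FORMS",
]

logger = logging.getLogger(__name__)

ICC_FORMS = ("absolute_agreement", "consistency")
_FORM_LABELS = {
    "absolute_agreement": "two-way mixed effects, absolute agreement, single measurement (ICC(A,1)/ICC(2,1))",
    "consistency": "two-way mixed effects, consistency, single measurement (ICC(C,1)/ICC(3,1))",
}

DEGENERATE_STATUS = "degenerate: no between-unit variance"


class DegenerateVarianceError(ValueError):
    """Raised when a reliability statistic is undefined for lack of variance."""


@dataclass(frozen=True)
class TrialMatrix:
    """Complete units x trials matrix of measurements (cm).

    Rows are measurement units (the landmarks' error values), columns the
    repeated trials (k >= 2).  No missing cells.
    """

    values: np.ndarray
    units: tuple[str, ...] = ()
    trials: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        x = np.array(self.values, dtype=float)
        if x.ndim != 2:
            raise ValueError("trial matrix must be 2-D (units x trials)")
        n, k = x.shape
        if n < 2 or k < 2:
            raise ValueError(f"need >= 2 units and >= 2 trials, got {n}x{k}")
        if not np.all(np.isfinite(x)):
            raise ValueError("trial matrix must be complete (finite values only)")
        units = tuple(self.units) or tuple(f"u{i + 1}" for i in range(n))
        trials = tuple(self.trials) or tuple(f"trial{j + 1}" for j in range(k))
        if len(units) != n or len(trials) != k:
            raise ValueError("row/column labels do not match matrix shape")
        x.setflags(write=False)
        object.__setattr__(self, "values", x)
        object.__setattr__(self, "units", units)
        object.__setattr__(self, "trials", trials)

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ReliabilityResult:
    """ICC point estimate with 95% CI, Cronbach's alpha, SEM and category.

    ``status`` is ``"ok"`` or an explicit degenerate marker (then the numeric
    fields are NaN).  ``anova`` carries the mean squares the estimate was
    built from.
    """

    icc: float
    ci95: tuple[float, float]
    alpha: float
    sem: float
    category: str | None
    icc_form: str
    status: str = "ok"
    anova: Mapping[str, float] = field(default_factory=dict)


def _mean_squares(x: np.ndarray) -> dict[str, float]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    return {
        "n": n,
        "k": k,
        "msr": ssr / (n - 1),
        "msc": ssc / (k - 1),
        "mse": sse / ((n - 1) * (k - 1)),
        "ssr": ssr,
        "ssc": ssc,
        "sse": sse,
        "sst": sst,
    }


def icc(
    matrix: TrialMatrix,
    form: str = "absolute_agreement",
    confidence: float = 0.95,
) -> ReliabilityResult:
    """ICC of a units x trials matrix, with CI, alpha, SEM and category.

    The confidence interval uses the exact F-distribution limits for the
    consistency form and the Satterthwaite-approximated F limits for absolute
    agreement — the classical closed-form ICC intervals.

    A matrix with no between-unit variance (all rows equal) has an undefined
    ICC; the result then carries ``status = 'degenerate: no between-unit
    variance'`` and NaN estimates instead of a misleading number.
    """
    if form not in ICC_FORMS:
        raise ValueError(f"unknown ICC form {form!r}; expected one of {ICC_FORMS}")
    ms = _mean_squares(matrix.values)
    n, k = matrix.n_units, matrix.n_trials
    msr, msc, mse = ms["msr"], ms["msc"], ms["mse"]

    # Degenerate when rows carry no variance: either relative to the total
    # variation, or absolutely (sub-nano-cm spread is numerical noise, e.g.
    # the float residue of an exactly-recovered zero-noise session).
    scale = max(ms["sst"], np.finfo(float).tiny)
    total_sd = np.sqrt(ms["sst"] / (n * k - 1))
    if (
        ms["ssr"] <= 1e-12 * scale
        or ms["sst"] == 0.0
        or total_sd <= 1e-9 * max(1.0, abs(matrix.values.mean()))
    ):
        return ReliabilityResult(
            icc=float("nan"),
            ci95=(float("nan"), float("nan")),
            alpha=float("nan"),
            sem=float("nan"),
            category=None,
            icc_form=_FORM_LABELS[form],
            status=DEGENERATE_STATUS,
            anova=ms,
        )

    a2 = (1.0 - confidence) / 2.0
    if form == "consistency":
        point = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0.0:
            low = high = 1.0
        else:
            F = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = F / f_dist.ppf(1 - a2, df1, df2)
            fu = F * f_dist.ppf(1 - a2, df2, df1)
            low = (fl - 1) / (fl + k - 1)
            high = (fu - 1) / (fu + k - 1)
    else:
        point = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        if mse == 0.0 and msc == 0.0:
            low = high = 1.0
        else:
            # Satterthwaite df for the denominator linear combination
            a = k * point / (n * (1 - point)) if point < 1 else np.inf
            b = 1 + k * point * (n - 1) / (n * (1 - point)) if point < 1 else np.inf
            if not np.isfinite(a):
                low = high = 1.0
            else:
                num = (a * msc + b * mse) ** 2
                den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                v = num / den if den > 0 else 1.0
                f1 = f_dist.ppf(1 - a2, n - 1, v)
                f2 = f_dist.ppf(1 - a2, v, n - 1)
                low = n * (msr - f1 * mse) / (
                    f1 * (k * msc + (k * n - k - n) * mse) + n * msr
                )
                high = n * (f2 * msr - mse) / (
                    k * msc + (k * n - k - n) * mse + n * f2 * msr
                )

    try:
        alpha_val = cronbach_alpha(matrix)
    except DegenerateVarianceError:
        alpha_val = float("nan")
    sd = pooled_sd(matrix)
    sem_val = sem(sd, alpha_val) if np.isfinite(alpha_val) else float("nan")
    low = min(low, point)
    high = max(high, point)
    return ReliabilityResult(
        icc=float(point),
        ci95=(float(low), float(high)),
        alpha=float(alpha_val),
        sem=float(sem_val),
        category=classify_icc(point),
        icc_form=_FORM_LABELS[form],
        status="ok",
        anova=ms,
    )


def cronbach_alpha(matrix: TrialMatrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of trial variances / total-score variance)."""
    x = matrix.values
    k = matrix.n_trials
    total_var = float(x.sum(axis=1).var(ddof=1))
    if total_var == 0.0:
        raise DegenerateVarianceError("degenerate: zero total-score variance")
    item_var = float(x.var(axis=0, ddof=1).sum())
    return k / (k - 1) * (1.0 - item_var / total_var)


def sem(sd: float, alpha: float) -> float:
    """Standard error of measurement: SD * sqrt(1 - alpha).

    ``alpha`` outside [0, 1] (negative alphas can occur with anticorrelated
    trials) is clamped with a warning so the square root stays defined.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if not 0.0 <= alpha <= 1.0:
        warnings.warn(
            f"alpha={alpha:.4g} outside [0, 1]; clamping for SEM", stacklevel=2
        )
        alpha = min(max(alpha, 0.0), 1.0)
    return float(sd * np.sqrt(1.0 - alpha))


def classify_icc(value: float) -> str:
    """Qualitative agreement band: poor < 0.5 <= moderate < 0.75 <= good <= 0.9 < excellent."""
    if not np.isfinite(value):
        raise ValueError("ICC must be finite to classify")
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


def pooled_sd(matrix: TrialMatrix) -> float:
    """Sample SD of all cells pooled (the SD used in the SEM by default)."""
    return float(matrix.values.ravel().std(ddof=1))


def trial_matrix_from_records(
    records: Sequence[ErrorRecord],
    value: str = "er",
    average_subjects: bool = True,
) -> TrialMatrix:
    """Build the units x trials matrix from benchmark error records.

    ``value`` is one of ``er``, ``ax_x``, ``ax_y``, ``ax_z``.  With
    ``average_subjects=True`` (default) rows are landmarks and each cell is
    the mean over subjects for that trial; otherwise rows are
    (subject, landmark) pairs.
    """
    df = records_to_frame(records)
    if value not in ("er", "ax_x", "ax_y", "ax_z"):
        raise ValueError(f"unknown value column {value!r}")
    rows = ["landmark"] if average_subjects else ["subject", "landmark"]
    wide = df.pivot_table(index=rows, columns="trial", values=value, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("incomplete design: some (unit, trial) cells are missing")
    units = tuple(
        str(i) if isinstance(i, str) else "/".join(map(str, i)) for i in wide.index
    )
    return TrialMatrix(
        wide.to_numpy(),
        units=units,
        trials=tuple(f"trial{t}" for t in wide.columns),
    )


def reliability_report(
    records: Sequence[ErrorRecord],
    form: str = "absolute_agreement",
    average_subjects: bool = True,
) -> pd.DataFrame:
    """Per-metric reliability table (rows Er, x, y, z; ICC, CI, SEM columns)."""
    rows = []
    for label, col in (("Er", "er"), ("x-axis", "ax_x"), ("y-axis", "ax_y"), ("z-axis", "ax_z")):
        m = trial_matrix_from_records(records, value=col, average_subjects=average_subjects)
        r = icc(m, form=form)
        rows.append(
            {
                "metric": label,
                "icc": r.icc,
                "ci95_low": r.ci95[0],
                "ci95_high": r.ci95[1],
                "sem": r.sem,
                "alpha": r.alpha,
                "category": r.category,
                "status": r.status,
            }
        )
    out = pd.DataFrame(rows).set_index("metric")
    out.attrs["icc_form"] = _FORM_LABELS[form]
    return out
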