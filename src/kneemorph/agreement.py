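"""Multi-rater agreement statistics for crossed measurement designs.

The study design is a complete crossed table: ``n`` subjects measured by
``m`` observers at ``r`` occasions.  This module provides the two-way
random-effects machinery built on it:

* crossed-design ANOVA mean squares and method-of-moments variance
  components;
* absolute-agreement intraclass correlation (single- and average-measures
  forms) with F-based confidence intervals using Satterthwaite degrees of
  freedom;
* limits of agreement with the mean (LOAM) for multiple observers;
* extended Bland-Altman plot data (difference from the subject mean against
  the subject mean);
* the repeatability coefficient for a single observer with repeated
  occasions;
* an aggregated :class:`AgreementReport` with deterministic JSON
  serialization.

Only method-of-moments estimation is used (no likelihood fitting), matching
the classical constructions these statistics come from.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from ._version import __version__
from .errors import (
    IncompleteDesignError,
    InsufficientReplicatesError,
    LoamUndefinedError,
    UndefinedIccError,
)

__all__ = [
    "MeasurementTable",
    "MeanSquares",
    "VarianceComponents",
    "IccResult",
    "RepeatabilityResult",
    "AgreementReport",
    "ReportConfig",
    "mean_squares",
    "variance_components",
    "icc_absolute",
    "loam",
    "extended_ba_plot_data",
    "repeatability_coefficient",
    "agreement_report",
]

_DEFAULT_Z = 1.96


@dataclass
class MeasurementTable:
    """Complete crossed subjects x observers x occasions table of one angle.

    ``values`` has shape ``(n, m, r)``; axis labels are kept for reporting.
    """

    angle_name: str
    values: np.ndarray
    subjects: list[str] = field(default_factory=list)
    observers: list[str] = field(default_factory=list)
    occasions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise IncompleteDesignError(
                f"values must be (n, m, r) or (n, m); got shape {self.values.shape}"
            )
        n, m, r = self.values.shape
        if not self.subjects:
            self.subjects = [f"S{i + 1}" for i in range(n)]
        if not self.observers:
            self.observers = [f"O{j + 1}" for j in range(m)]
        if not self.occasions:
            self.occasions = list(range(1, r + 1))
        if (len(self.subjects), len(self.observers), len(self.occasions)) != (n, m, r):
            raise IncompleteDesignError("axis labels do not match the value shape")
        if n < 2:
            raise IncompleteDesignError(f"need at least 2 subjects, got {n}")
        if m < 2 and r < 2:
            raise IncompleteDesignError("need m >= 2 observers or r >= 2 occasions")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise IncompleteDesignError(
                f"missing/non-finite cell at subject={self.subjects[bad[0]]}, "
                f"observer={self.observers[bad[1]]}, occasion={self.occasions[bad[2]]}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def r(self) -> int:
        return self.values.shape[2]

    @classmethod
    def from_long(cls, df: pd.DataFrame, angle_name: str = "value", value_col: str = "value") -> "MeasurementTable":
        """Build from a long table with subject_id / observer_id / occasion / value columns.

        The design must be complete; a missing cell raises
        :class:`IncompleteDesignError` naming it.
        """
        required = {"subject_id", "observer_id", "occasion", value_col}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise IncompleteDesignError(f"long table is missing columns: {sorted(missing_cols)}")
        subjects = list(dict.fromkeys(df["subject_id"].astype(str)))
        observers = list(dict.fromkeys(df["observer_id"].astype(str)))
        occasions = sorted(set(int(o) for o in df["occasion"]))
        n, m, r = len(subjects), len(observers), len(occasions)
        values = np.full((n, m, r), np.nan)
        si = {s: i for i, s in enumerate(subjects)}
        oi = {o: j for j, o in enumerate(observers)}
        ki = {k: k_idx for k_idx, k in enumerate(occasions)}
        for row in df.itertuples(index=False):
            i = si[str(row.subject_id)]
            j = oi[str(row.observer_id)]
            k = ki[int(row.occasion)]
            if not math.isnan(values[i, j, k]):
                raise IncompleteDesignError(
                    f"duplicate cell subject={row.subject_id}, observer={row.observer_id}, "
                    f"occasion={row.occasion}"
                )
            values[i, j, k] = getattr(row, value_col)
        if np.isnan(values).any():
            i, j, k = np.argwhere(np.isnan(values))[0]
            raise IncompleteDesignError(
                f"incomplete design: missing cell subject={subjects[i]}, "
                f"observer={observers[j]}, occasion={occasions[k]}"
            )
        return cls(angle_name, values, subjects, observers, occasions)

    def occasions_as_observers(self) -> "MeasurementTable":
        """Swap the observer and occasion axes (intra-rater convention)."""
        return MeasurementTable(
            self.angle_name,
            np.swapaxes(self.values, 1, 2),
            subjects=list(self.subjects),
            observers=[f"occ{k}" for k in self.occasions],
            occasions=list(range(1, self.m + 1)),
        )


@dataclass(frozen=True)
class MeanSquares:
    """Crossed two-way ANOVA mean squares.

    With a single occasion (r = 1) the interaction and pure-error strata are
    not separable: ``ms_interaction`` is ``None`` and ``ms_error`` holds the
    merged residual mean square on (n-1)(m-1) degrees of freedom.
    """

    ms_rows: float
    ms_cols: float
    ms_interaction: Optional[float]
    ms_error: float
    df_rows: int
    df_cols: int
    df_interaction: Optional[int]
    df_error: int


@dataclass(frozen=True)
class VarianceComponents:
    """Method-of-moments variance components (degrees squared).

    Truncated components are clipped at zero; the raw (possibly negative)
    solutions are retained alongside.
    """

    sigma2_subject: float
    sigma2_observer: float
    sigma2_interaction: float
    sigma2_residual: float
    raw_subject: float
    raw_observer: float
    raw_interaction: float
    raw_residual: float


@dataclass(frozen=True)
class IccResult:
    """Absolute-agreement intraclass correlation with its confidence interval."""

    form: str  # "single" or "average"
    estimate: float
    ci_low: float
    ci_high: float
    alpha: float


@dataclass(frozen=True)
class RepeatabilityResult:
    """Repeatability coefficient (within-subject) plus a between-subject analog.

    ``rc`` is z * sqrt(2) * s_w with s_w the pooled within-subject SD across
    occasions.  ``rc_between`` applies the same multiplier to the SD of the
    per-subject means, exposed because "inter-subject repeatability" is an
    ambiguous label.
    """

    rc: float
    s_within: float
    rc_between: float
    s_between: float
    z: float


def mean_squares(table: MeasurementTable) -> MeanSquares:
    """Crossed-design ANOVA mean squares of a complete (n, m, r) table."""
    y = table.values
    n, m, r = y.shape
    if np.ptp(y) == 0.0:
        # exactly constant table: avoid cancellation noise in the sums of squares
        zero = MeanSquares(0.0, 0.0, None if r == 1 else 0.0, 0.0,
                           n - 1, m - 1, None if r == 1 else (n - 1) * (m - 1),
                           (n - 1) * (m - 1) if r == 1 else n * m * (r - 1))
        return zero
    grand = y.mean()
    row_means = y.mean(axis=(1, 2))
    col_means = y.mean(axis=(0, 2))
    cell_means = y.mean(axis=2)

    ss_rows = m * r * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * r * float(np.sum((col_means - grand) ** 2))
    ss_inter = r * float(
        np.sum((cell_means - row_means[:, None] - col_means[None, :] + grand) ** 2)
    )
    ss_err = float(np.sum((y - cell_means[:, :, None]) ** 2))

    df_rows, df_cols, df_inter = n - 1, m - 1, (n - 1) * (m - 1)
    ms_rows = ss_rows / df_rows
    ms_cols = ss_cols / df_cols if df_cols > 0 else 0.0
    if r == 1:
        # interaction and error merge into one residual stratum
        return MeanSquares(
            ms_rows=ms_rows,
            ms_cols=ms_cols,
            ms_interaction=None,
            ms_error=ss_inter / df_inter if df_inter > 0 else 0.0,
            df_rows=df_rows,
            df_cols=df_cols,
            df_interaction=None,
            df_error=df_inter,
        )
    df_err = n * m * (r - 1)
    return MeanSquares(
        ms_rows=ms_rows,
        ms_cols=ms_cols,
        ms_interaction=ss_inter / df_inter if df_inter > 0 else 0.0,
        ms_error=ss_err / df_err,
        df_rows=df_rows,
        df_cols=df_cols,
        df_interaction=df_inter,
        df_error=df_err,
    )


def variance_components(ms: MeanSquares, n: int, m: int, r: int) -> VarianceComponents:
    """Method-of-moments variance components from crossed-design mean squares.

    For r = 1 the interaction is not estimable and is reported as zero, with
    the residual absorbing it.  Negative raw solutions are truncated to zero
    in the primary fields.
    """
    if r == 1:
        raw_e = ms.ms_error
        raw_ab = 0.0
        raw_b = (ms.ms_cols - ms.ms_error) / n
        raw_a = (ms.ms_rows - ms.ms_error) / m
    else:
        assert ms.ms_interaction is not None
        raw_e = ms.ms_error
        raw_ab = (ms.ms_interaction - ms.ms_error) / r
        raw_b = (ms.ms_cols - ms.ms_interaction) / (n * r)
        raw_a = (ms.ms_rows - ms.ms_interaction) / (m * r)
    return VarianceComponents(
        sigma2_subject=max(raw_a, 0.0),
        sigma2_observer=max(raw_b, 0.0),
        sigma2_interaction=max(raw_ab, 0.0),
        sigma2_residual=max(raw_e, 0.0),
        raw_subject=raw_a,
        raw_observer=raw_b,
        raw_interaction=raw_ab,
        raw_residual=raw_e,
    )


def _two_way_flat(table: MeasurementTable) -> tuple[np.ndarray, int, int]:
    """Flatten observers x occasions into k columns for the ICC computation."""
    y = table.values
    n, m, r = y.shape
    return y.reshape(n, m * r), n, m * r


def icc_absolute(
    table: MeasurementTable, form: str = "average", alpha: float = 0.05
) -> IccResult:
    """Two-way random-effects absolute-agreement intraclass correlation.

    ``form="single"`` is the reliability of one measurement; ``"average"``
    (default, matching a multiple-raters design) is the reliability of the
    mean over all k columns.  When r > 1 the observer and occasion axes are
    flattened into k = m * r measurement columns.

    Confidence bounds use the F-based construction with Satterthwaite
    degrees of freedom; average-form bounds are the Spearman-Brown transform
    of the single-form bounds.

    Raises
    ------
    UndefinedIccError
        If the table has zero total variance.
    """
    if form not in ("single", "average"):
        raise ValueError(f"form must be 'single' or 'average', got {form!r}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    flat, n, k = _two_way_flat(table)
    if np.ptp(flat) == 0.0:
        raise UndefinedIccError("table has zero total variance; ICC undefined")
    sub = MeasurementTable(table.angle_name, flat[:, :, None])
    ms = mean_squares(sub)
    msr, msc, mse = ms.ms_rows, ms.ms_cols, ms.ms_error
    if msr <= 0.0 and msc <= 0.0 and mse <= 0.0:
        raise UndefinedIccError("table has zero total variance; ICC undefined")

    den_single = msr + (k - 1) * mse + (k / n) * (msc - mse)
    den_avg = msr + (msc - mse) / n
    if den_single <= 0.0 or den_avg <= 0.0:
        raise UndefinedIccError("degenerate mean squares; ICC denominator non-positive")
    icc1 = (msr - mse) / den_single
    icck = (msr - mse) / den_avg

    lo1, hi1 = _icc_a1_ci(msr, msc, mse, n, k, icc1, alpha)
    if form == "single":
        est, lo, hi = icc1, lo1, hi1
    else:
        est = icck
        lo, hi = (_spearman_brown(lo1, k), _spearman_brown(hi1, k))
    lo, hi = min(lo, est), max(hi, est)
    return IccResult(form=form, estimate=est, ci_low=lo, ci_high=hi, alpha=alpha)


def _spearman_brown(rho: float, k: int) -> float:
    den = 1.0 + (k - 1) * rho
    if den <= 0.0:
        return -1.0
    return k * rho / den


def _icc_a1_ci(
    msr: float, msc: float, mse: float, n: int, k: int, icc1: float, alpha: float
) -> tuple[float, float]:
    """F-based CI for the single-measure absolute-agreement ICC."""
    if mse <= 0.0:
        # no residual variance: estimate is exact up to the column stratum
        return icc1, icc1
    fj = msc / mse
    num = (k - 1) * (n - 1) * (k * icc1 * fj + n * (1 + (k - 1) * icc1) - k * icc1) ** 2
    den = (n - 1) * k**2 * icc1**2 * fj**2 + (n * (1 + (k - 1) * icc1) - k * icc1) ** 2
    v = num / den if den > 0 else 1.0
    v = max(v, 1.0)
    f2u = f_dist.ppf(1 - alpha / 2, n - 1, v)
    f2l = f_dist.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f2u * mse) / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2l * msr)
    return lower, upper


def loam(
    table: MeasurementTable, z: float = _DEFAULT_Z
) -> tuple[float, VarianceComponents]:
    """Limits-of-agreement-with-the-mean halfwidth for multiple observers.

    For one occasion per observer the halfwidth is
    ``z * sqrt(((m-1)/m) * (sigma2_observer + sigma2_residual))`` — the SD of
    one observer's measurement around the all-observer subject mean.  With
    replicate occasions the interaction joins the observer term and the
    residual is scaled by (m*r - 1)/(m*r), i.e. the exact variance of
    ``y_ijk - mean_i``.

    Raises
    ------
    LoamUndefinedError
        If the table has a single observer (use the repeatability
        coefficient instead).
    """
    if table.m < 2:
        raise LoamUndefinedError("LOAM needs >= 2 observers; use repeatability_coefficient")
    n, m, r = table.n, table.m, table.r
    vc = variance_components(mean_squares(table), n, m, r)
    if r == 1:
        var_dev = (m - 1) / m * (vc.sigma2_observer + vc.sigma2_residual)
    else:
        var_dev = (m - 1) / m * (vc.sigma2_observer + vc.sigma2_interaction) + (
            m * r - 1
        ) / (m * r) * vc.sigma2_residual
    return z * math.sqrt(max(var_dev, 0.0)), vc


def extended_ba_plot_data(
    table: MeasurementTable, z: float = _DEFAULT_Z
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Extended Bland-Altman plot data: difference from the subject mean vs the mean.

    Returns one point per cell ``(subject_mean, difference, observer_id,
    occasion)`` and the horizontal reference lines (zero and +/- the LOAM
    halfwidth).
    """
    y = table.values
    subj_mean = y.mean(axis=(1, 2))
    rows = []
    for i, s in enumerate(table.subjects):
        for j, o in enumerate(table.observers):
            for k_idx, k in enumerate(table.occasions):
                rows.append(
                    {
                        "subject_id": s,
                        "subject_mean": subj_mean[i],
                        "difference": y[i, j, k_idx] - subj_mean[i],
                        "observer_id": o,
                        "occasion": k,
                    }
                )
    halfwidth, _ = loam(table, z=z)
    lines = {"center": 0.0, "lower": -halfwidth, "upper": halfwidth}
    return pd.DataFrame(rows), lines


def repeatability_coefficient(
    table: MeasurementTable, z: float = _DEFAULT_Z
) -> RepeatabilityResult:
    """Repeatability coefficient for one observer with repeated occasions.

    ``rc = z * sqrt(2) * s_w`` where ``s_w**2`` is the pooled within-subject
    variance across occasions (the one-way ANOVA residual).  A
    between-subject analog (same multiplier on the SD of subject means) is
    returned alongside.

    Raises
    ------
    InsufficientReplicatesError
        If there are fewer than two occasions or more than one observer.
    """
    if table.m != 1:
        raise InsufficientReplicatesError(
            f"repeatability coefficient needs a single observer, got m={table.m}"
        )
    if table.r < 2:
        raise InsufficientReplicatesError(
            f"repeatability coefficient needs r >= 2 occasions, got r={table.r}"
        )
    y = table.values[:, 0, :]  # (n, r)
    n, r = y.shape
    subj_means = y.mean(axis=1)
    s_w2 = float(np.sum((y - subj_means[:, None]) ** 2)) / (n * (r - 1))
    s_b = float(np.std(subj_means, ddof=1))
    s_w = math.sqrt(s_w2)
    return RepeatabilityResult(
        rc=z * math.sqrt(2.0) * s_w,
        s_within=s_w,
        rc_between=z * math.sqrt(2.0) * s_b,
        s_between=s_b,
        z=z,
    )


@dataclass
class ReportConfig:
    """Configuration of :func:`agreement_report`."""

    icc_form: str = "average"
    alpha: float = 0.05
    z: float = _DEFAULT_Z
    seed: Optional[int] = None
    angle_decimals: int = 1
    icc_decimals: int = 3


@dataclass
class AgreementReport:
    """Aggregated agreement statistics for one measurement table."""

    angle_name: str
    n: int
    m: int
    r: int
    per_observer_summary: list[dict]
    components: VarianceComponents
    icc_single: Optional[IccResult]
    icc_average: Optional[IccResult]
    icc_undefined: bool
    loam_halfwidth: Optional[float]
    ba_plot_points: pd.DataFrame
    ba_plot_lines: Optional[dict]
    repeatability: Optional[RepeatabilityResult]
    config: ReportConfig
    version: str = __version__
    schema_version: int = 1

    def to_dict(self) -> dict:
        """Stable, JSON-ready representation (full precision + printed block)."""
        d_ang = self.config.angle_decimals
        d_icc = self.config.icc_decimals

        def icc_block(res: Optional[IccResult]) -> Optional[dict]:
            if res is None:
                return None
            return {
                "form": res.form,
                "estimate": res.estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "alpha": res.alpha,
            }

        out = {
            "schema_version": self.schema_version,
            "software_version": self.version,
            "angle_name": self.angle_name,
            "design": {"n_subjects": self.n, "m_observers": self.m, "r_occasions": self.r},
            "seed": self.config.seed,
            "per_observer_summary": self.per_observer_summary,
            "variance_components": {
                "sigma2_subject": self.components.sigma2_subject,
                "sigma2_observer": self.components.sigma2_observer,
                "sigma2_interaction": self.components.sigma2_interaction,
                "sigma2_residual": self.components.sigma2_residual,
                "raw": {
                    "subject": self.components.raw_subject,
                    "observer": self.components.raw_observer,
                    "interaction": self.components.raw_interaction,
                    "residual": self.components.raw_residual,
                },
            },
            "icc": {
                "undefined": self.icc_undefined,
                "single": icc_block(self.icc_single),
                "average": icc_block(self.icc_average),
                "default_form": self.config.icc_form,
            },
            "loam_halfwidth": self.loam_halfwidth,
            "z": self.config.z,
            "repeatability": None,
            "printed": {},
        }
        if self.repeatability is not None:
            out["repeatability"] = {
                "rc": self.repeatability.rc,
                "s_within": self.repeatability.s_within,
                "rc_between": self.repeatability.rc_between,
                "s_between": self.repeatability.s_between,
            }
        printed: dict = {
            "per_observer": [
                {
                    "observer_id": s["observer_id"],
                    "mean": round(s["mean"], d_ang),
                    "sd": round(s["sd"], 2),
                }
                for s in self.per_observer_summary
            ],
        }
        if self.loam_halfwidth is not None:
            printed["loam_halfwidth"] = round(self.loam_halfwidth, d_ang)
        if not self.icc_undefined:
            chosen = self.icc_average if self.config.icc_form == "average" else self.icc_single
            if chosen is not None:
                printed["icc"] = {
                    "form": chosen.form,
                    "estimate": round(chosen.estimate, d_icc),
                    "ci": [round(chosen.ci_low, d_icc), round(chosen.ci_high, d_icc)],
                }
        if self.repeatability is not None:
            printed["rc"] = round(self.repeatability.rc, d_ang)
        out["printed"] = printed
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, allow_nan=True)


def agreement_report(
    table: MeasurementTable, config: Optional[ReportConfig] = None
) -> AgreementReport:
    """Populate an :class:`AgreementReport` for one measurement table.

    A single-observer table with repeated occasions (the intra-rater design)
    is analyzed with occasions in the observer slot for the ICC/LOAM part,
    and additionally yields the repeatability coefficient.
    """
    config = config or ReportConfig()
    intra = table.m == 1 and table.r >= 2
    work = table.occasions_as_observers() if intra else table

    per_obs = []
    for j, obs in enumerate(table.observers if not intra else work.observers):
        vals = work.values[:, j, :].ravel()
        per_obs.append(
            {
                "observer_id": obs,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)),
                "n": int(vals.size),
            }
        )

    vc = variance_components(mean_squares(work), work.n, work.m, work.r)

    icc_undefined = False
    icc_s: Optional[IccResult] = None
    icc_a: Optional[IccResult] = None
    try:
        icc_s = icc_absolute(work, form="single", alpha=config.alpha)
        icc_a = icc_absolute(work, form="average", alpha=config.alpha)
    except UndefinedIccError:
        icc_undefined = True

    halfwidth: Optional[float] = None
    points = pd.DataFrame()
    lines: Optional[dict] = None
    try:
        halfwidth, _ = loam(work, z=config.z)
        points, lines = extended_ba_plot_data(work, z=config.z)
    except LoamUndefinedError:
        pass

    rep: Optional[RepeatabilityResult] = None
    if intra:
        rep = repeatability_coefficient(table, z=config.z)

    return AgreementReport(
        angle_name=table.angle_name,
        n=table.n,
        m=table.m,
        r=table.r,
        per_observer_summary=per_obs,
        components=vc,
        icc_single=icc_s,
        icc_average=icc_a,
        icc_undefined=icc_undefined,
        loam_halfwidth=halfwidth,
        ba_plot_points=points,
        ba_plot_lines=lines,
        repeatability=rep,
        config=config,
    )
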