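"""Cohort-level statistics for core-limb thermography studies.

Covers the clinical-comparison and statistics layer: the axillary-to-core
equivalence adjustment (+0.5 degC), median/IQR summaries, fixed-width
histogram binning of gradients and ratios, Spearman rank correlation (with
average-rank tie handling and an exact permutation p-value at small n), and
group comparisons of a metric against binary clinical flags.

Correlating a metric against a 0/1 clinical flag via Spearman reduces to a
rank-biserial-style statistic; that is how flag "correlations" are reported.
No multiple-testing correction is applied; reports annotate the number of
tests performed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DomainError,
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)
from .profile import core_limb_gradient, core_limb_ratio

#: Offset added to an axillary reading to approximate a rectal core reading.
AXILLARY_OFFSET_C = 0.5

EXCLUSION_REASONS = ("distortion", "calibration_error", "limbs_not_visible", "none")

#: Largest n for which the exact permutation p-value is enumerated.
EXACT_PERMUTATION_MAX_N = 8


@dataclass
class PatientRecord:
    """Per-subject temperatures, derived metrics and clinical covariates."""

    patient_id: str
    theta_c: float
    theta_l: float
    clinical_reference_temp: float = math.nan
    reference_site: str = "rectal"
    clinical_flags: dict = field(default_factory=dict)
    usable: bool = True
    exclusion_reason: str = "none"
    gradient: float = field(default=None)  # type: ignore[assignment]
    ratio: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.reference_site not in ("rectal", "axillary"):
            raise DomainError("reference_site must be 'rectal' or 'axillary'")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise DomainError(
                f"exclusion_reason must be one of {EXCLUSION_REASONS}")
        if self.usable and self.exclusion_reason != "none":
            raise DomainError("usable records cannot carry an exclusion reason")
        if self.gradient is None:
            self.gradient = core_limb_gradient(self.theta_c, self.theta_l)
        if self.ratio is None:
            self.ratio = core_limb_ratio(self.theta_c, self.theta_l)

    @property
    def core_equivalent_reference(self) -> float:
        """Clinical reference temperature on the rectal-equivalent scale."""
        return adjust_reference_temperature(self.clinical_reference_temp,
                                            self.reference_site)


@dataclass
class CorrelationReport:
    """Spearman coefficient with its p-value and provenance."""

    rho: float
    p_value: float
    n: int
    method: str  # 't_approximation' or 'exact_permutation'


def axillary_to_core_equivalent(t_axillary: float) -> float:
    """Add the +0.5 degC clinical equivalence offset to an axillary reading."""
    if not math.isfinite(t_axillary):
        raise DomainError("axillary temperature must be finite")
    return t_axillary + AXILLARY_OFFSET_C


def adjust_reference_temperature(t: float, site: str) -> float:
    """Axillary readings get the +0.5 degC offset; rectal pass through."""
    if site == "axillary":
        return axillary_to_core_equivalent(t)
    if site == "rectal":
        return t
    raise DomainError("site must be 'rectal' or 'axillary'")


# ---------------------------------------------------------------------------
# Spearman correlation

def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return float((rx * ry).sum() / denom)


def spearman(x, y) -> CorrelationReport:
    """Spearman rank correlation with a two-sided p-value.

    Ranks use average-rank (mid-rank) tie handling; rho is the Pearson
    correlation of the ranks.  The p-value is computed by exhaustive
    permutation enumeration for n <= 8 and by the t-approximation with
    n - 2 degrees of freedom otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")

    rho = _spearman_rho(x, y)
    if n <= EXACT_PERMUTATION_MAX_N:
        hits = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(y):
            total += 1
            if abs(_spearman_rho(x, np.asarray(perm))) >= target:
                hits += 1
        return CorrelationReport(rho=rho, p_value=hits / total, n=n,
                                 method="exact_permutation")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationReport(rho=rho, p_value=min(max(p, 0.0), 1.0), n=n,
                             method="t_approximation")


# ---------------------------------------------------------------------------
# Summaries

def median_iqr(values, method: str = "linear") -> tuple[float, float, float]:
    """(median, Q1, Q3) via linear interpolation of the order statistics.

    ``method`` is passed through to numpy's quantile machinery; the default
    'linear' is the type-7 convention.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DomainError("median_iqr of an empty list")
    q1, med, q3 = np.percentile(values, [25, 50, 75], method=method)
    return float(med), float(q1), float(q3)


def format_median_iqr(values, unit: str = "", decimals: int = 2) -> str:
    """Render as ``median [q1-q3]``, e.g. ``33.88 [32.74-34.19]``."""
    med, q1, q3 = median_iqr(values)
    u = unit and f" {unit}"
    return f"{med:.{decimals}f}{u} [{q1:.{decimals}f}-{q3:.{decimals}f}]"


def histogram_bins(values, bin_width: float, origin: float = 0.0,
                   ) -> list[tuple[tuple[float, float], int]]:
    """Fixed-width half-open bins ``[origin + k*w, origin + (k+1)*w)``.

    Returns ordered ``((lo, hi), count)`` pairs spanning the data range;
    counts sum to the number of values.  Empty input yields an empty list.
    """
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return []
    k = np.floor((values - origin) / bin_width).astype(int)
    bins = []
    for kk in range(k.min(), k.max() + 1):
        lo = origin + kk * bin_width
        bins.append(((lo, lo + bin_width), int((k == kk).sum())))
    return bins


@dataclass
class GroupSummary:
    """Per-group mean +/- SD of a metric plus its flag correlation."""

    metric: str
    flag: str
    n_flagged: int
    mean_flagged: float
    sd_flagged: float
    n_unflagged: int
    mean_unflagged: float
    sd_unflagged: float
    correlation: CorrelationReport | None


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) >= 2 else math.nan
    return mean, sd


def group_summary(records, flag: str, metric: str = "gradient") -> GroupSummary:
    """Mean +/- sample SD of a metric per binary-flag group, with Spearman.

    Unusable records are excluded.  The Spearman correlation of the metric
    against the 0/1 flag (a rank-biserial-style statistic) is None when
    either group is empty.
    """
    if metric not in ("gradient", "ratio"):
        raise DomainError("metric must be 'gradient' or 'ratio'")
    usable = [r for r in records if r.usable]
    try:
        flags = np.array([bool(r.clinical_flags[flag]) for r in usable])
    except KeyError as exc:
        raise KeyError(f"unknown clinical flag {flag!r}") from exc
    values = np.array([getattr(r, metric) for r in usable], dtype=float)
    in_group = values[flags]
    out_group = values[~flags]
    corr = None
    if len(in_group) and len(out_group):
        try:
            corr = spearman(values, flags.astype(float))
        except UndefinedCorrelationError:
            corr = None
    mean_in, sd_in = _mean_sd(in_group) if len(in_group) else (math.nan, math.nan)
    mean_out, sd_out = (_mean_sd(out_group) if len(out_group)
                        else (math.nan, math.nan))
    return GroupSummary(metric=metric, flag=flag,
                        n_flagged=len(in_group), mean_flagged=mean_in,
                        sd_flagged=sd_in,
                        n_unflagged=len(out_group), mean_unflagged=mean_out,
                        sd_unflagged=sd_out, correlation=corr)


def apply_usability_filter(records) -> tuple[list, dict[str, int]]:
    """Partition records into usable ones and an exclusion tally by reason."""
    usable = [r for r in records if r.usable]
    tally = {reason: 0 for reason in EXCLUSION_REASONS if reason != "none"}
    for r in records:
        if not r.usable:
            tally[r.exclusion_reason] += 1
    return usable, tally


# ---------------------------------------------------------------------------
# CSV interface and report

_BASE_COLUMNS = ("patient_id", "theta_c", "theta_l", "clinical_reference_temp",
                 "reference_site", "usable", "exclusion_reason")


def records_to_dataframe(records) -> pd.DataFrame:
    flag_names = sorted({name for r in records for name in r.clinical_flags})
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id, "theta_c": r.theta_c,
            "theta_l": r.theta_l, "gradient": r.gradient, "ratio": r.ratio,
            "clinical_reference_temp": r.clinical_reference_temp,
            "reference_site": r.reference_site, "usable": r.usable,
            "exclusion_reason": r.exclusion_reason,
        }
        for name in flag_names:
            row[name] = int(bool(r.clinical_flags.get(name, False)))
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_csv(records, path: str | Path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def records_from_csv(path: str | Path) -> list[PatientRecord]:
    """Load patient records, validating each row; flags are the extra columns."""
    df = pd.read_csv(path)
    missing = set(_BASE_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValidationError(f"records CSV missing columns {sorted(missing)}")
    flag_names = [c for c in df.columns
                  if c not in _BASE_COLUMNS + ("gradient", "ratio")]
    records = []
    for i, row in df.iterrows():
        for col in ("theta_c", "theta_l"):
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"row {i}: column {col!r} is not numeric "
                    f"(got {row[col]!r})") from None
            if not math.isfinite(float(row[col])):
                raise ValidationError(f"row {i}: column {col!r} is not finite")
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]),
            theta_c=float(row["theta_c"]),
            theta_l=float(row["theta_l"]),
            clinical_reference_temp=float(
                row.get("clinical_reference_temp", math.nan)),
            reference_site=str(row.get("reference_site", "rectal")),
            usable=bool(row.get("usable", True)),
            exclusion_reason=str(row.get("exclusion_reason", "none")),
            clinical_flags={name: bool(row[name]) for name in flag_names},
        ))
    return records


def cohort_report(records, flags=(), metrics=("gradient", "ratio")) -> str:
    """Human-readable cohort report: summaries plus per-flag group tables."""
    usable, tally = apply_usability_filter(records)
    lines = [f"Cohort: {len(records)} records, {len(usable)} usable"]
    excluded = {k: v for k, v in tally.items() if v}
    if excluded:
        lines.append("Excluded: " + ", ".join(
            f"{reason} (n = {n})" for reason, n in excluded.items()))
    theta_c = [r.theta_c for r in usable]
    theta_l = [r.theta_l for r in usable]
    lines.append(f"theta_c: {format_median_iqr(theta_c, 'degC')}")
    lines.append(f"theta_l: {format_median_iqr(theta_l, 'degC')}")
    lines.append(f"gradient: {format_median_iqr([r.gradient for r in usable], 'degC')}")
    lines.append(f"ratio: {format_median_iqr([r.ratio for r in usable])}")
    if len(usable) >= 3:
        try:
            rep = spearman(theta_c, theta_l)
            lines.append(f"Spearman theta_c vs theta_l: rho = {rep.rho:.2f}, "
                         f"p = {rep.p_value:.2g} (n = {rep.n}, {rep.method})")
        except UndefinedCorrelationError:
            lines.append("Spearman theta_c vs theta_l: undefined "
                         "(constant vector)")
        refs = [(r.theta_c, r.core_equivalent_reference) for r in usable
                if math.isfinite(r.clinical_reference_temp)]
        if len(refs) >= 3:
            a = np.array(refs)
            try:
                rep = spearman(a[:, 0], a[:, 1])
                lines.append(
                    f"Spearman theta_c vs clinical reference: "
                    f"rho = {rep.rho:.2f}, p = {rep.p_value:.2g} "
                    f"(n = {rep.n}, {rep.method})")
            except UndefinedCorrelationError:
                lines.append("Spearman theta_c vs clinical reference: "
                             "undefined (constant vector)")
    n_tests = 0
    for metric in metrics:
        for flag in flags:
            g = group_summary(records, flag, metric)
            corr = g.correlation
            corr_txt = (f"rho = {corr.rho:.2f}, p = {corr.p_value:.2g}"
                        if corr else "correlation undefined")
            lines.append(
                f"{metric} vs {flag}: with (n = {g.n_flagged}) "
                f"{g.mean_flagged:.2f} +/- {g.sd_flagged:.2f}; "
                f"without (n = {g.n_unflagged}) "
                f"{g.mean_unflagged:.2f} +/- {g.sd_unflagged:.2f}; {corr_txt}")
            n_tests += corr is not None
    if n_tests:
        lines.append(f"({n_tests} hypothesis tests performed; "
                     f"p-values are unadjusted)")
    return "\n".join(lines)
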