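"""Correlation, regression and comparison statistics for the ablation study.

Conventions follow the source study's analysis:

* Pearson's r and Spearman's r_s with two-sided p-values from the exact
  Student-t transform ``t = r * sqrt(n-2) / sqrt(1-r^2)`` on n-2 degrees
  of freedom.  Spearman is Pearson on average-ranked data (tie-corrected),
  with the same t transform.
* Correlation strength is labelled with Evans's verbal bands on |r|:
  0.00-0.19 very weak, 0.20-0.39 weak, 0.40-0.59 moderate, 0.60-0.79
  strong, 0.80-1.0 very strong; exactly 0 means no correlation.
* Force-vs-measurement correlations are computed at the replicate level
  (n = 240) without the raw data, using the balanced-design identity:
  with the predictor constant inside each cell and equal replicates n_c,
  the raw cross-product equals n_c times the between-cell cross-product
  and the raw response sum of squares equals n_c * SS_between plus
  sum((n_c - 1) * SD_cell^2).
* Model fits are ordinary least squares, either linear in the predictor
  or linear in its natural log, ranked by R^2 = 1 - SS_res / SS_tot.
* Group comparisons use the pooled-variance two-sample Student t-test at
  the 0.05 level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .study_data import AblationCondition, ConditionTable

EVANS_BANDS = (
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (1.0 + 1e-12, "very strong"),
)


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    coefficient: float
    n: int
    p_two_sided: float
    evans_label: str


@dataclass(frozen=True)
class FitResult:
    form: str  # "linear": y = a*x + b | "log": y = a*ln(x) + b
    a: float
    b: float
    r_squared: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        t = np.log(x) if self.form == "log" else x
        return self.a * t + self.b


@dataclass(frozen=True)
class ModelComparison:
    log_r2: float
    linear_r2: float
    behavior: str  # "Log" | "Linear"
    log_fit: FitResult
    linear_fit: FitResult


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    t_statistic: float
    p_two_sided: float
    significant: bool


def evans_label(coefficient: float) -> str:
    """Verbal correlation strength for a coefficient in [-1, 1]."""
    c = abs(float(coefficient))
    if not c <= 1:
        raise ValueError(f"|coefficient| = {c} exceeds 1")
    if c == 0:
        return "none"
    for upper, label in EVANS_BANDS:
        if c < upper:
            return label
    raise AssertionError("unreachable")


def _t_transform_p(r: float, n: int) -> float:
    """Two-sided p for a correlation coefficient via the exact t distribution."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def _as_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    return x, y


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-distribution p-value."""
    x, y = _as_pairs(x, y)
    dx, dy = x - x.mean(), y - y.mean()
    sxx, syy = np.dot(dx, dx), np.dot(dy, dy)
    if sxx == 0 or syy == 0:
        raise ValueError("correlation undefined: zero variance input")
    r = float(np.dot(dx, dy) / np.sqrt(sxx * syy))
    r = min(1.0, max(-1.0, r))
    return CorrelationResult("pearson", r, x.size, _t_transform_p(r, x.size), evans_label(r))


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Rank correlation: Pearson on average ranks, same p-value transform."""
    x, y = _as_pairs(x, y)
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("rank correlation undefined: constant ranks")
    res = pearson(rx, ry)
    return CorrelationResult("spearman", res.coefficient, res.n, res.p_two_sided, res.evans_label)


def pearson_balanced_raw(
    cells: ConditionTable,
    predictor: str | Mapping[AblationCondition, float] | Callable[[AblationCondition], float],
) -> CorrelationResult:
    """Replicate-level Pearson correlation reconstructed from cell summaries.

    The predictor (e.g. contact force) is constant within each condition,
    so the full-data correlation over all sum(n_cell) replicates is exactly
    computable from the 40 cell means, cell SDs and the common replicate
    count.  ``predictor`` may be a field name ("force_gf" / "angle_deg"),
    a mapping, or a callable on conditions.
    """
    conds = cells.conditions()
    if isinstance(predictor, str):
        z = np.array([getattr(c, predictor) for c in conds], dtype=float)
    elif callable(predictor):
        z = np.array([predictor(c) for c in conds], dtype=float)
    else:
        z = np.array([predictor[c] for c in conds], dtype=float)
    m = cells.means()
    s = cells.sds()
    ns = np.array([cells.cells[c].n for c in conds])
    if np.any(ns < 1):
        raise ValueError("balanced-raw correlation requires replicate counts")
    if len(set(ns.tolist())) != 1:
        raise ValueError("design is not balanced: unequal cell n")
    if np.any(np.isnan(s)):
        raise ValueError("balanced-raw correlation requires cell SDs")
    n_cell = int(ns[0])
    dz, dm = z - z.mean(), m - m.mean()
    sxy = n_cell * np.dot(dz, dm)
    sxx = n_cell * np.dot(dz, dz)
    syy = n_cell * np.dot(dm, dm) + np.sum((n_cell - 1) * s**2)
    if sxx == 0 or syy == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(sxy / np.sqrt(sxx * syy))
    n_total = n_cell * len(conds)
    return CorrelationResult("pearson", r, n_total, _t_transform_p(r, n_total), evans_label(r))


def _ols(t: np.ndarray, y: np.ndarray, form: str) -> FitResult:
    design = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("degenerate response: zero variance")
    r2 = float(1.0 - np.sum(resid**2) / ss_tot)
    return FitResult(form, float(coef[0]), float(coef[1]), r2, t.size)


def fit_linear(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """OLS fit y = a*x + b with R^2."""
    x, y = _as_pairs(x, y)
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: constant x")
    return _ols(x, y, "linear")


def fit_log(z: Sequence[float], y: Sequence[float]) -> FitResult:
    """OLS fit y = a*ln(z) + b with R^2; requires z > 0."""
    z, y = _as_pairs(z, y)
    if np.any(z <= 0):
        raise ValueError("log fit requires strictly positive predictor")
    if np.ptp(z) == 0:
        raise ValueError("degenerate predictor: constant z")
    return _ols(np.log(z), y, "log")


def compare_fits(z: Sequence[float], y: Sequence[float]) -> ModelComparison:
    """Fit both the log and the linear model and rank them by R^2.

    Ties go to "Linear" (the simpler model).
    """
    logf = fit_log(z, y)
    linf = fit_linear(z, y)
    behavior = "Log" if logf.r_squared > linf.r_squared else "Linear"
    return ModelComparison(logf.r_squared, linf.r_squared, behavior, logf, linf)


def lesion_contact_ratio(area_mm2: float, contact_area_mm2: float) -> float:
    """Dimensionless lesion-area / contact-area ratio."""
    if not contact_area_mm2 > 0:
        raise ValueError(f"contact area must be positive, got {contact_area_mm2}")
    return float(area_mm2) / float(contact_area_mm2)


def students_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    alpha: float = 0.05,
) -> PairwiseComparison:
    """Two-sample pooled-variance Student t-test, two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # identical constant groups: zero pooled variance but a well-defined null
        return PairwiseComparison(labels[0], labels[1], 0.0, 1.0, False)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):
        raise ValueError("zero pooled variance: t-test undefined")
    return PairwiseComparison(labels[0], labels[1], float(t), float(p), bool(p < alpha))


def moment_matched_expansion(mean: float, sd: float, n: int) -> np.ndarray:
    """Deterministic n-point sample with exactly the given mean and sample SD.

    Half the points sit at mean - c*sd and half at mean + c*sd with
    c = sqrt((n-1)/n), so the ddof=1 SD is exact.  Odd n places one point
    at the mean and scales c accordingly.  Used to reconstruct groups for
    t-tests when only cell summaries are available.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    half, odd = divmod(n, 2)
    if odd:
        c = np.sqrt((n - 1) / (2.0 * half))  # the 2*half off-centre points carry all variance
        vals = np.concatenate([[0.0], np.full(half, -c), np.full(half, c)])
    else:
        c = np.sqrt((n - 1) / float(n))
        vals = np.concatenate([np.full(half, -c), np.full(half, c)])
    return mean + sd * vals


def angle_group_values(table: ConditionTable, angle_deg: int) -> np.ndarray:
    """All moment-matched replicate values for one contact angle (8 forces x n)."""
    vals = []
    for cond in table.conditions():
        if cond.angle_deg == angle_deg:
            cell = table.cells[cond]
            vals.append(moment_matched_expansion(cell.mean, cell.sd, cell.n))
    return np.concatenate(vals)
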