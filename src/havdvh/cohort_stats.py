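"""Cohort-level statistics for symptomatic radiation pneumonitis.

The analysis is deliberately univariate, mirroring how dose constraints
are used in the clinic: for each dose-volume parameter separately, a
logistic regression of the binary outcome (pneumonitis grade >= 2) on
the parameter, the ROC AUC as a ranking score, and an optimal decision
threshold chosen to maximize sensitivity + specificity (the Youden
criterion) over the observed parameter values with the "positive iff
value >= t" orientation — every parameter here is risk-increasing in
dose, so no auto-flipping is done.  Between-cohort comparability of a
parameter is measured by the absolute difference of its per-cohort
optimal thresholds.

Group-comparison utilities (Fisher exact incl. the Freeman-Halton r x 2
extension, Wilcoxon rank-sum) cover the baseline-characteristics tables.
No multiplicity correction is applied; p-values are reported per test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import gammaln
import statsmodels.api as sm

__all__ = [
    "PatientRecord",
    "Cohort",
    "LogisticFit",
    "RocSummary",
    "ThresholdComparison",
    "fit_univariate_logistic",
    "roc_auc",
    "youden_threshold",
    "rank_parameters_by_auc",
    "compare_cohort_thresholds",
    "fisher_exact",
    "wilcoxon_rank_sum",
]

COVARIATE_COLUMNS = ["age", "sex", "stage", "histology", "chemo",
                     "smoking", "pack_years", "bmi", "ild"]


@dataclass
class PatientRecord:
    """One patient's DVH parameters, clinical covariates and RP grade."""

    dvh_row: dict
    rp_grade: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rp_grade not in range(6):
            raise ValueError(f"rp_grade must be 0..5, got {self.rp_grade}")

    def outcome(self, grade_threshold: int = 2) -> int:
        return int(self.rp_grade >= grade_threshold)


@dataclass
class Cohort:
    """A labeled patient table with a binary symptomatic-RP outcome.

    ``table`` needs an ``rp_grade`` column; ``outcome`` is derived as
    grade >= grade_threshold (CTCAE symptomatic cut, default 2).
    """

    label: str
    table: pd.DataFrame
    grade_threshold: int = 2

    def __post_init__(self) -> None:
        if "rp_grade" not in self.table.columns:
            raise ValueError("cohort table needs an 'rp_grade' column")
        if not (1 <= self.grade_threshold <= 5):
            raise ValueError("grade_threshold must be in 1..5")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_records(cls, label: str, records: list[PatientRecord],
                     grade_threshold: int = 2) -> "Cohort":
        rows = []
        for r in records:
            row = dict(r.dvh_row)
            row.update(r.covariates)
            row["rp_grade"] = r.rp_grade
            rows.append(row)
        return cls(label=label, table=pd.DataFrame(rows),
                   grade_threshold=grade_threshold)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def outcome(self) -> np.ndarray:
        return (self.table["rp_grade"].to_numpy() >= self.grade_threshold).astype(int)

    def parameter_values(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Finite values of one parameter with matching outcomes (listwise)."""
        x = pd.to_numeric(self.table[name], errors="coerce").to_numpy(dtype=float)
        y = self.outcome
        keep = np.isfinite(x)
        return x[keep], y[keep]


@dataclass
class LogisticFit:
    parameter: str
    beta0: float
    beta1: float
    se_beta1: float
    wald_p: float
    converged: bool
    separation: bool

    @property
    def odds_ratio_per_unit(self) -> float:
        return math.exp(self.beta1)


@dataclass
class RocSummary:
    parameter: str
    auc: float
    optimal_threshold: float
    sensitivity_at_threshold: float
    specificity_at_threshold: float


@dataclass
class ThresholdComparison:
    parameter: str
    threshold_cohort_a: float
    threshold_cohort_b: float
    is_hav_family: bool
    counterpart: str | None = None

    @property
    def abs_difference(self) -> float:
        return abs(self.threshold_cohort_a - self.threshold_cohort_b)


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")


# ---------------------------------------------------------------------------
# Logistic regression


def fit_univariate_logistic(cohort: Cohort, parameter: str) -> LogisticFit:
    """Maximum-likelihood logistic fit of the outcome on one parameter.

    Newton/IRLS with log-likelihood tolerance 1e-8 and at most 100
    iterations.  Quasi-complete separation (a monotone split of the
    classes, or |beta1|*sd(x) > 15) is flagged; the estimates are still
    reported but their standard errors are not meaningful.
    """
    x, y = cohort.parameter_values(parameter)
    _check_two_classes(y)
    if np.unique(x).size < 2:
        raise ValueError(f"parameter {parameter!r} is constant")

    monotone = float(x[y == 1].min()) >= float(x[y == 0].max()) or \
        float(x[y == 1].max()) <= float(x[y == 0].min())

    X = sm.add_constant(x)
    import warnings as _w

    with np.errstate(all="ignore"), _w.catch_warnings():
        _w.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8,
                                     disp=0)
        except np.linalg.LinAlgError:
            # singular Hessian under (quasi-)complete separation: a
            # gradient method still yields finite (diverging) estimates
            res = sm.Logit(y, X).fit(method="bfgs", maxiter=200, disp=0)
    beta0, beta1 = (float(b) for b in res.params)
    with np.errstate(all="ignore"):
        se = float(res.bse[1])
        p = float(res.pvalues[1])
    separation = bool(monotone or abs(beta1) * float(np.std(x)) > 15)
    if separation:
        _w.warn(f"separation detected for {parameter!r}; estimates are "
                "unstable and standard errors are not meaningful", stacklevel=2)
    return LogisticFit(
        parameter=parameter, beta0=beta0, beta1=beta1, se_beta1=se,
        wald_p=p, converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation,
    )


# ---------------------------------------------------------------------------
# ROC / thresholds


def roc_auc(values: np.ndarray, outcomes: np.ndarray) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 P(pos == neg) over all pairs.

    Computed from midranks, so ties contribute 1/2; identical to the
    trapezoidal area under the empirical ROC curve.
    """
    values = np.asarray(values, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    _check_two_classes(outcomes)
    n_pos = int(outcomes.sum())
    n_neg = int(len(outcomes) - n_pos)
    ranks = scipy.stats.rankdata(values)
    rank_sum_pos = float(ranks[outcomes == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def youden_threshold(values: np.ndarray,
                     outcomes: np.ndarray) -> tuple[float, float, float]:
    """Optimal decision threshold maximizing sensitivity + specificity.

    The classifier is "positive iff value >= t"; candidate thresholds are
    the distinct observed values; ties in J are broken by the smallest t.
    Returns ``(threshold, sensitivity, specificity)``.
    """
    values = np.asarray(values, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    _check_two_classes(outcomes)
    candidates = np.unique(values)
    if candidates.size < 2:
        raise ValueError("all parameter values are equal; threshold is degenerate")
    pos = values[outcomes == 1]
    neg = values[outcomes == 0]
    # sens(t) = P(pos >= t), spec(t) = P(neg < t), vectorized over candidates
    sens = (pos[None, :] >= candidates[:, None]).mean(axis=1)
    spec = (neg[None, :] < candidates[:, None]).mean(axis=1)
    j = sens + spec
    best = int(np.argmax(j))  # argmax takes the first = smallest candidate on ties
    return float(candidates[best]), float(sens[best]), float(spec[best])


def rank_parameters_by_auc(cohort: Cohort,
                           parameters: list[str]) -> list[RocSummary]:
    """Per-parameter ROC summaries sorted by descending AUC.

    Ties in AUC are broken alphabetically by parameter name.
    """
    out = []
    for name in parameters:
        x, y = cohort.parameter_values(name)
        auc = roc_auc(x, y)
        thr, sens, spec = youden_threshold(x, y)
        out.append(RocSummary(parameter=name, auc=auc, optimal_threshold=thr,
                              sensitivity_at_threshold=sens,
                              specificity_at_threshold=spec))
    return sorted(out, key=lambda s: (-s.auc, s.parameter))


def compare_cohort_thresholds(cohort_a: Cohort, cohort_b: Cohort,
                              parameters: list[str]) -> list[ThresholdComparison]:
    """Per-parameter optimal thresholds in two cohorts and their |difference|.

    Each high-attenuation parameter is paired with its conventional
    counterpart (MHALD with MLD, HAVx% with Vx) so the report can be read
    pairwise.
    """
    from .dvh import HAV_COUNTERPARTS

    out = []
    for name in parameters:
        ta, *_ = youden_threshold(*cohort_a.parameter_values(name))
        tb, *_ = youden_threshold(*cohort_b.parameter_values(name))
        out.append(ThresholdComparison(
            parameter=name, threshold_cohort_a=ta, threshold_cohort_b=tb,
            is_hav_family=name in HAV_COUNTERPARTS,
            counterpart=HAV_COUNTERPARTS.get(name),
        ))
    return out


# ---------------------------------------------------------------------------
# Classical tests for the baseline tables


def _freeman_halton_rx2(table: np.ndarray) -> float:
    """Exact conditional p for an r x 2 table by full enumeration.

    Sums the multivariate-hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (within a 1e-9 relative tolerance for floating-point ties).
    """
    row_sums = table.sum(axis=1)
    col1 = int(table[:, 0].sum())

    def log_prob(first_col: tuple[int, ...]) -> float:
        lp = 0.0
        for a, r in zip(first_col, row_sums):
            lp += gammaln(r + 1) - gammaln(a + 1) - gammaln(r - a + 1)
        return lp

    norm = gammaln(row_sums.sum() + 1) - gammaln(col1 + 1) \
        - gammaln(row_sums.sum() - col1 + 1)
    obs_lp = log_prob(tuple(int(v) for v in table[:, 0])) - norm

    total = 0.0
    stack = [((), col1)]
    r = len(row_sums)
    while stack:
        prefix, remaining = stack.pop()
        i = len(prefix)
        if i == r - 1:
            if remaining <= row_sums[i]:
                lp = log_prob(prefix + (remaining,)) - norm
                if lp <= obs_lp + 1e-9:
                    total += math.exp(lp)
            continue
        lo = max(0, remaining - int(row_sums[i + 1:].sum()))
        hi = min(int(row_sums[i]), remaining)
        for a in range(lo, hi + 1):
            stack.append((prefix + (a,), remaining - a))
    return min(1.0, total)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for an r x 2 contingency table (r <= 5).

    2 x 2 tables use the hypergeometric tail sum; larger tables use the
    Freeman-Halton generalization by full enumeration.
    """
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table != np.floor(table)) or np.any(table < 0):
            raise ValueError("cells must be non-negative integers")
        table = table.astype(int)
    if table.ndim != 2 or table.shape[1] != 2 or not 2 <= table.shape[0] <= 5:
        raise ValueError(f"expected an r x 2 table with 2 <= r <= 5, got {table.shape}")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    if table.shape[0] == 2:
        return float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])
    return _freeman_halton_rx2(table)


def wilcoxon_rank_sum(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when min(n) <= 10 and there are no ties;
    otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                   use_continuity=True)
    return float(res.pvalue)
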