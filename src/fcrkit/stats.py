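"""Cohort statistical battery.

Spearman rank correlation (average ranks for ties, two-tailed p via the
t approximation), the classical paired t-test, the interaction F of a
2x2 fully-within-subject ANOVA, Bonferroni-style multiplicity correction
capped at 1, and forward stepwise linear regression on partial F tests.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass(frozen=True)
class StatResult:
    """One inferential result with raw and (optionally) corrected p."""

    statistic_name: str        # {"rho", "t", "F", "beta"}
    value: float
    df: float | tuple[float, float]
    p_raw: float
    n: int
    p_corrected: float | None = None

    def __post_init__(self) -> None:
        if self.statistic_name == "rho" and not -1 <= self.value <= 1:
            raise ValueError("rho outside [-1, 1]")
        if self.statistic_name == "F" and self.value < 0:
            raise ValueError("F must be >= 0")
        if not 0 <= self.p_raw <= 1:
            raise ValueError("p_raw outside [0, 1]")
        if self.p_corrected is not None and self.p_corrected < self.p_raw:
            raise ValueError("p_corrected must be >= p_raw")

    def corrected(self, family_size: int) -> "StatResult":
        return StatResult(
            self.statistic_name, self.value, self.df, self.p_raw, self.n,
            p_corrected=correct_p(self.p_raw, family_size),
        )


def _finite_pair(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < min_n:
        raise ValueError(f"need n >= {min_n}, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    return x, y


def spearman(x, y) -> StatResult:
    """Two-tailed Spearman rank correlation.

    Ties receive average ranks; rho is the Pearson correlation of the two
    rank vectors and the p-value uses the t approximation with n-2 df
    (adequate at the cohort sizes this battery targets; an exact
    permutation test is not attempted).
    """
    x, y = _finite_pair(x, y, min_n=3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman rho undefined")
    rho, p = sps.spearmanr(x, y)
    return StatResult("rho", float(rho), df=float(x.size - 2),
                      p_raw=float(min(p, 1.0)), n=int(x.size))


def paired_t(x, y) -> StatResult:
    """Classical two-tailed paired-samples t-test, df = n - 1."""
    x, y = _finite_pair(x, y, min_n=2)
    d = x - y
    if np.ptp(d) == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    t, p = sps.ttest_rel(x, y)
    return StatResult("t", float(t), df=float(x.size - 1),
                      p_raw=float(p), n=int(x.size))


def rm_anova_2x2(cells: np.ndarray | pd.DataFrame) -> StatResult:
    """Interaction F of a 2x2 fully-within-subject ANOVA.

    ``cells`` is an (n_subjects, 4) array whose columns are the four
    factor-combination cells in the order (A1B1, A1B2, A2B1, A2B2) — here
    (leg, side of stimulation). Computed by the explicit sums-of-squares
    decomposition; for this design the interaction F with df (1, n-1)
    equals the squared paired t on each subject's difference of
    differences.
    """
    arr = np.asarray(cells, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("expect an (n_subjects, 4) cell table")
    if not np.isfinite(arr).all():
        raise ValueError("missing cell: every subject needs all 4 cells")
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    data = arr.reshape(n, 2, 2)  # (subject, A, B)

    grand = data.mean()
    subj_mean = data.mean(axis=(1, 2))
    a_mean = data.mean(axis=(0, 2))
    b_mean = data.mean(axis=(0, 1))
    ab_mean = data.mean(axis=0)

    ss_ab = n * np.sum((ab_mean - a_mean[:, None] - b_mean[None, :] + grand) ** 2)
    # interaction error: cell - subject mean - A-within-subject dev - B-within-subject dev
    as_mean = data.mean(axis=2)  # (subject, A)
    bs_mean = data.mean(axis=1)  # (subject, B)
    resid = (data
             - as_mean[:, :, None] - bs_mean[:, None, :]
             - ab_mean[None, :, :]
             + a_mean[None, :, None] + b_mean[None, None, :]
             + subj_mean[:, None, None] - grand)
    ss_err = np.sum(resid ** 2)

    df1, df2 = 1.0, float(n - 1)
    if ss_ab == 0:
        f, p = 0.0, 1.0           # no interaction signal, whatever the error
    elif ss_err == 0:
        f, p = np.inf, 0.0
    else:
        f = float(ss_ab / df1 / (ss_err / df2))
        p = float(sps.f.sf(f, df1, df2))
    return StatResult("F", f, df=(df1, df2), p_raw=p, n=n)


def correct_p(p_raw: float, family_size: int) -> float:
    """Bonferroni multiplicity correction with capping at 1."""
    if not 0 <= p_raw <= 1:
        raise ValueError("p_raw outside [0, 1]")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return min(1.0, p_raw * family_size)


@dataclass(frozen=True)
class StepwiseStep:
    entered: str
    coefficients: dict[str, float]
    r_squared: float
    partial_f_p: float


@dataclass(frozen=True)
class StepwiseSummary:
    """Forward-selection model: entry order, per-step coefficients, R^2."""

    steps: tuple[StepwiseStep, ...]
    dropped_aliased: tuple[str, ...] = ()

    @property
    def entered(self) -> tuple[str, ...]:
        return tuple(s.entered for s in self.steps)

    @property
    def r_squared(self) -> float:
        return self.steps[-1].r_squared if self.steps else 0.0


def _ols(X: pd.DataFrame, y: np.ndarray):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_regression(
    predictors: pd.DataFrame,
    outcome,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> StepwiseSummary:
    """Forward stepwise OLS on partial F tests.

    At each step the candidate with the smallest partial-F p-value enters
    if p < ``entry_p``; already-entered predictors whose partial p rises
    above ``removal_p`` are removed. Exactly collinear candidates are
    dropped with a warning before selection starts.
    """
    y = np.asarray(outcome, dtype=float)
    X = predictors.astype(float).copy()
    if len(X) != y.size:
        raise ValueError("predictor table and outcome length differ")

    dropped: list[str] = []
    keep: list[str] = []
    for col in X.columns:
        trial_cols = keep + [col]
        mat = np.column_stack([np.ones(len(X)), X[trial_cols].to_numpy()])
        if np.linalg.matrix_rank(mat) < mat.shape[1]:
            dropped.append(col)
            warnings.warn(f"dropping aliased predictor {col!r}", stacklevel=2)
        else:
            keep.append(col)
    X = X[keep]

    if len(X) <= len(X.columns) + 1:
        raise ValueError("need n > number of candidate predictors + 1")

    selected: list[str] = []
    steps: list[StepwiseStep] = []
    while True:
        remaining = [c for c in X.columns if c not in selected]
        best: tuple[float, str] | None = None
        for cand in remaining:
            fit = _ols(X[selected + [cand]], y)
            p = float(fit.pvalues[cand])
            if best is None or p < best[0]:
                best = (p, cand)
        if best is None or best[0] >= entry_p:
            break
        selected.append(best[1])

        # backward pass at the removal threshold
        while True:
            fit = _ols(X[selected], y)
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] > removal_p and len(selected) > 1:
                selected.remove(worst)
            else:
                break

        fit = _ols(X[selected], y)
        steps.append(StepwiseStep(
            entered=best[1],
            coefficients={k: float(v) for k, v in fit.params.items()},
            r_squared=float(fit.rsquared),
            partial_f_p=best[0],
        ))
        if len(selected) == len(X.columns):
            break
    return StepwiseSummary(steps=tuple(steps), dropped_aliased=tuple(dropped))
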