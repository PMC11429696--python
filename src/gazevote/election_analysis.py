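"""Relating gaze and facial metrics to vote share and election outcomes.

Correlations (Pearson or Spearman) are reported with Fisher-z 95% confidence
intervals and two-sided p-values. Partial correlation residualizes both variables
on a single control (the analyses control one variable at a time). The joint
appearance model is an ordinary least-squares fit of two-party vote share on jaw
prominence and perceived competence. State partisan lean is classified from the
nearest presidential margin (positive = Republican): swing iff |margin| < 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataValidationError, DegenerateInputError
from .gaze_io import CandidateRecord, RaceRecord  # noqa: F401  (data-layer types re-exported)
from .gaze_scoring import paired_gaze_test, unpaired_gaze_test

STATE_LEANS = ("blue", "swing", "red")
SWING_MARGIN_PCT = 10.0


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    n: int
    method: str

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


@dataclass(frozen=True)
class JointModelResult:
    """OLS fit of vote share on intercept + jaw prominence + competence."""

    intercept: float
    coef_jaw: float
    coef_competence: float
    r_squared: float
    n: int
    ci_jaw: tuple[float, float]
    ci_competence: tuple[float, float]
    p_jaw: float
    p_competence: float


def _fisher_ci(r: float, n: int, extra_controls: int = 0) -> tuple[float, float]:
    """95% CI via the Fisher z-transform; df shrink by one per control."""
    denom = n - 3 - extra_controls
    if denom <= 0 or abs(r) >= 1.0:
        return (r, r)
    z = np.arctanh(r)
    half = 1.959963984540054 / np.sqrt(denom)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Correlation coefficient with Fisher-z 95% CI and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataValidationError("correlate requires equal-length vectors")
    n = x.size
    if n < 3:
        raise DataValidationError("correlate requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("constant vector passed to correlate")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    r = float(res.statistic)
    lo, hi = _fisher_ci(r, n)
    return CorrelationResult(r, lo, hi, float(res.pvalue), n, method)


def partial_correlate(x, y, control) -> CorrelationResult:
    """Partial Pearson correlation of x and y given one control variable.

    Both variables are residualized on the control by simple linear regression
    and the residuals correlated; the p-value uses n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(control, dtype=float)
    if not (x.shape == y.shape == c.shape):
        raise DataValidationError("partial_correlate requires equal-length vectors")
    n = x.size
    if n < 4:
        raise DataValidationError("partial_correlate requires n >= 4")
    if np.std(c) == 0:
        raise DegenerateInputError("constant control variable")
    design = np.column_stack([np.ones(n), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    tol = 1e-12 * max(np.var(x), 1.0)
    if np.var(rx) <= tol or np.var(ry) <= tol:
        raise DegenerateInputError("control is collinear with x or y")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    t = r * np.sqrt(df / max(1.0 - r * r, np.finfo(float).tiny))
    p = float(2.0 * stats.t.sf(abs(t), df))
    lo, hi = _fisher_ci(r, n, extra_controls=1)
    return CorrelationResult(r, lo, hi, p, n, "partial-pearson")


def fit_joint_model(vote_share, jaw_prominence, competence) -> JointModelResult:
    """OLS of vote share on intercept + jaw prominence + competence (unadjusted R^2)."""
    y = np.asarray(vote_share, dtype=float)
    X = np.column_stack([
        np.asarray(jaw_prominence, dtype=float),
        np.asarray(competence, dtype=float),
    ])
    if y.size < 4:
        raise DataValidationError("fit_joint_model requires n >= 4")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise DegenerateInputError("collinear predictors in fit_joint_model")
    fit = sm.OLS(y, Xc).fit()
    ci = fit.conf_int(alpha=0.05)
    return JointModelResult(
        intercept=float(fit.params[0]),
        coef_jaw=float(fit.params[1]),
        coef_competence=float(fit.params[2]),
        r_squared=float(fit.rsquared),
        n=int(y.size),
        ci_jaw=(float(ci[1, 0]), float(ci[1, 1])),
        ci_competence=(float(ci[2, 0]), float(ci[2, 1])),
        p_jaw=float(fit.pvalues[1]),
        p_competence=float(fit.pvalues[2]),
    )


def fit_vote_difference_model(diff_frame: pd.DataFrame) -> dict:
    """Race-level OLS of the within-race vote-share difference on feature differences.

    ``diff_frame`` has one row per race with column ``d_vote`` (share of the first
    listed candidate minus the second) and any subset of the predictor columns
    ``d_jaw``, ``d_competence``, ``d_incumbent``, ``d_age_decades``. Because the
    two candidates' shares sum to 100, race-level differences have independent
    errors — unlike the candidate-level table — so the coefficient confidence
    intervals are valid for parameter-recovery checks.
    """
    predictors = [c for c in ("d_jaw", "d_competence", "d_incumbent", "d_age_decades")
                  if c in diff_frame.columns]
    if not predictors:
        raise DataValidationError("no predictor columns in diff_frame")
    y = diff_frame["d_vote"].to_numpy(dtype=float)
    X = sm.add_constant(diff_frame[predictors].to_numpy(dtype=float), has_constant="add")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    out = {"n": int(y.size), "r_squared": float(fit.rsquared),
           "intercept": float(fit.params[0])}
    for i, name in enumerate(predictors, start=1):
        out[name] = {"coef": float(fit.params[i]),
                     "ci95": (float(ci[i, 0]), float(ci[i, 1])),
                     "p": float(fit.pvalues[i])}
    return out


def candidate_age(birth_year: int, election_year: int) -> int:
    """Candidate age in years: election year minus birth year."""
    age = int(election_year) - int(birth_year)
    if age < 0:
        raise DataValidationError(
            f"birth year {birth_year} is after election year {election_year}"
        )
    return age


def classify_state_lean(margin_pct: float) -> str:
    """Classify a signed presidential margin (positive = Republican).

    swing iff |margin| < 10; red iff margin >= 10; blue iff margin <= -10.
    """
    m = float(margin_pct)
    if not np.isfinite(m):
        raise DataValidationError("state margin must be finite")
    if abs(m) < SWING_MARGIN_PCT:
        return "swing"
    return "red" if m > 0 else "blue"


def stratified_summary(values, groups) -> dict:
    """Per-group mean +/- SEM with rank-test (2 groups) or ANOVA + Tukey (>= 3).

    Returns a dict with a per-group table and pairwise contrasts. Raw p-values
    are reported; the Tukey honestly-significant-difference adjustment applies
    only within an ANOVA family (no global multiplicity correction).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise DataValidationError("values and groups must align")
    labels = list(pd.unique(groups))
    samples = {g: values[groups == g] for g in labels}
    for g, v in samples.items():
        if v.size == 0:
            raise DataValidationError(f"empty group {g!r}")
    table = pd.DataFrame({
        "group": labels,
        "n": [samples[g].size for g in labels],
        "mean": [samples[g].mean() for g in labels],
        "sem": [stats.sem(samples[g]) if samples[g].size > 1 else np.nan for g in labels],
    })
    out: dict = {"groups": table, "anova_p": None, "contrasts": None}
    contrasts = []
    if len(labels) == 2:
        g1, g2 = labels
        contrasts.append({"group_a": g1, "group_b": g2,
                          "p": unpaired_gaze_test(samples[g1], samples[g2]),
                          "adjusted": False})
    elif len(labels) >= 3:
        out["anova_p"] = float(stats.f_oneway(*[samples[g] for g in labels]).pvalue)
        tukey = stats.tukey_hsd(*[samples[g] for g in labels])
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                contrasts.append({"group_a": labels[i], "group_b": labels[j],
                                  "p": float(tukey.pvalue[i, j]), "adjusted": True})
    out["contrasts"] = pd.DataFrame(contrasts) if contrasts else None
    return out
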