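"""Psychometric evaluation: internal consistency, inter-rater agreement,
and diagnosis-symptom convergent validity.

* :func:`cronbach_alpha` — internal consistency of a multi-item scale,
  ``alpha = k/(k-1) * (1 - sum(var_i) / var_total)`` with sample (n-1)
  variances.
* :func:`weighted_kappa` — chance-corrected ordinal agreement,
  ``kappa = 1 - sum(w*O) / sum(w*E)`` with quadratic (default) or linear
  disagreement weights and chance expectation from the margin products.
* :func:`c_statistic` — probability a random case outranks a random
  control (ties count half); identical to the area under the ROC curve.
* :func:`convergent_validity` — logistic regression of a diagnosis flag
  on banded scale scores; odds ratios with Wald 95% CIs per band against
  the zero/reference band, plus the model c-statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import UndefinedStatisticError


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha of an items-by-persons score matrix (rows = persons).

    Complete cases only; sample variances (n-1 divisor).  Alpha is at most
    1 and may be negative for incoherent item sets.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise UndefinedStatisticError("alpha needs at least 2 items (columns)")
    if m.shape[0] < 2:
        raise UndefinedStatisticError("alpha needs at least 2 persons (rows)")
    if np.isnan(m).any():
        raise UndefinedStatisticError("alpha requires complete cases (no missing cells)")
    k = m.shape[1]
    item_vars = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedStatisticError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def weighted_kappa(table, weights: str = "quadratic") -> float:
    """Weighted kappa from a k-by-k rater-A x rater-B contingency table.

    Disagreement weights are ``((i-j)/(k-1))**2`` (quadratic) or
    ``|i-j|/(k-1)`` (linear); expected counts come from the margin
    products.  Equals 1 iff all mass is on the diagonal.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1] or t.shape[0] < 2:
        raise UndefinedStatisticError("kappa needs a square table with k >= 2")
    if (t < 0).any() or t.sum() <= 0:
        raise UndefinedStatisticError("kappa needs non-negative counts with positive total")
    k = t.shape[0]
    i, j = np.indices((k, k))
    d = np.abs(i - j) / (k - 1)
    if weights == "quadratic":
        w = d**2
    elif weights == "linear":
        w = d
    else:
        raise ValueError(f"unknown weights {weights!r}")
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    expected_disagreement = (w * expected).sum()
    if expected_disagreement == 0:
        raise UndefinedStatisticError(
            "expected disagreement is zero (degenerate margins); kappa undefined"
        )
    return float(1.0 - (w * t).sum() / expected_disagreement)


def c_statistic(outcome, score) -> float:
    """Concordance statistic: P(score_case > score_control) + 0.5 P(tie).

    Computed by the rank formulation (equivalent to exhaustive pair
    counting, and to the area under the ROC curve).
    """
    y = np.asarray(outcome).astype(int)
    s = np.asarray(score, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("outcome and score must be equal-length 1-d vectors")
    n_case = int(y.sum())
    n_ctrl = int(len(y) - n_case)
    if n_case == 0 or n_ctrl == 0:
        raise UndefinedStatisticError("c-statistic needs both cases and controls")
    ranks = rankdata(s)  # midranks handle ties
    return float((ranks[y == 1].sum() - n_case * (n_case + 1) / 2) / (n_case * n_ctrl))


@dataclass(frozen=True)
class BandEstimate:
    band: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class ValidityResult:
    outcome: str
    reference_band: str
    estimates: tuple[BandEstimate, ...]
    c: float
    n: int
    separation_flag: bool = False
    dropped_bands: tuple[str, ...] = ()
    coefficients: dict = field(default_factory=dict)


def band_label(edges: tuple[int, int]) -> str:
    lo, hi = edges
    return str(lo) if lo == hi else f"{lo}-{hi}"


def assign_bands(values, bands: Sequence[tuple[int, int]]) -> pd.Series:
    """Map numeric values onto labelled closed-interval bands."""
    v = pd.Series(values)
    labels = pd.Series(index=v.index, dtype=object)
    for lo, hi in bands:
        labels[(v >= lo) & (v <= hi)] = band_label((lo, hi))
    if labels.isna().any():
        bad = sorted(v[labels.isna()].unique().tolist())
        raise ValueError(f"values {bad[:5]} fall outside the declared bands")
    return labels


def convergent_validity(
    data: pd.DataFrame,
    outcome: str,
    banding: Mapping[str, Sequence[tuple[int, int]]],
    extra_covariates: Sequence[str] = (),
) -> ValidityResult:
    """Fit a logistic model of a binary diagnosis flag on banded covariates.

    ``banding`` maps each covariate column to its ordered band edges; the
    first band is the reference (odds ratio identically 1).  Odds ratios
    are exponentiated coefficients with Wald 95% CIs; the c-statistic is
    computed from the fitted probabilities.  Complete cases only; empty
    bands are dropped with a record in ``dropped_bands``.
    """
    import statsmodels.api as sm

    cols = [outcome, *banding.keys(), *extra_covariates]
    df = data[cols].dropna()
    n = len(df)
    y = df[outcome].astype(int).to_numpy()
    if y.min() == y.max():
        raise UndefinedStatisticError(f"outcome {outcome!r} has a single class")

    design = {}
    dropped: list[str] = []
    band_columns: list[tuple[str, str, int]] = []  # (column key, band label, n)
    reference = ""
    for cov, bands in banding.items():
        labels = assign_bands(df[cov].to_numpy(), list(bands))
        ref = band_label(tuple(bands[0]))
        if not reference:
            reference = f"{cov}={ref}"
        for edges in bands[1:]:
            lbl = band_label(tuple(edges))
            indicator = (labels == lbl).astype(float).to_numpy()
            count = int(indicator.sum())
            key = f"{cov}[{lbl}]"
            if count == 0:
                dropped.append(key)
                continue
            design[key] = indicator
            band_columns.append((key, lbl, count))
    for cov in extra_covariates:
        design[cov] = df[cov].astype(float).to_numpy()

    X = sm.add_constant(pd.DataFrame(design, index=df.index), has_constant="add")
    separation = False
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params, conf = fit.params, fit.conf_int()
    except Exception:
        separation = True
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        params, conf = fit.params, fit.conf_int()
    if not separation and not getattr(fit.mle_retvals, "get", lambda *_: True)("converged", True):
        separation = True

    estimates = []
    for key, lbl, count in band_columns:
        beta = params[key]
        lo, hi = conf.loc[key]
        if abs(beta) > 15:  # effectively unbounded: perfect separation
            separation = True
        estimates.append(
            BandEstimate(
                band=key,
                odds_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(lo)),
                ci_high=float(np.exp(hi)),
                n=count,
            )
        )
    fitted = np.asarray(fit.predict(X), dtype=float)
    return ValidityResult(
        outcome=outcome,
        reference_band=reference,
        estimates=tuple(estimates),
        c=c_statistic(y, fitted),
        n=n,
        separation_flag=separation,
        dropped_bands=tuple(dropped),
        coefficients={k: float(v) for k, v in params.items()},
    )
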