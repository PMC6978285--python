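"""Risk-adjusted mental-health quality indicators (MHQIs).

Two outcome families over admission -> follow-up scale pairs:

* **improvement** — among persons with a non-zero scale value at
  admission, the share whose follow-up score is lower;
* **failure** (failure to improve or worsening) — among persons below the
  scale maximum at admission, the share whose follow-up score is at or
  above the admission score.

Follow-up is the 90-day reassessment, or the discharge assessment if
discharge happens within 90 days of admission.  Risk adjustment is
indirect standardization: a pooled logistic model of the event on baseline
covariates gives each stratum an expected rate, and
``adjusted = observed / expected * pooled``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, UndefinedStatisticError
from .registry import AssessmentRecord
from .scales import ScaleDef, score_all

FOLLOWUP_WINDOW_DAYS = 90  # inclusive day counting


@dataclass(frozen=True)
class QIPair:
    person_id: str
    scale: str
    baseline: int
    followup: int
    baseline_covariates: Mapping
    period: int  # calendar year of admission
    scale_max: int


@dataclass
class PairingLog:
    paired: int = 0
    no_followup: int = 0
    incomplete_scores: int = 0
    episode_errors: list[str] = field(default_factory=list)


def pair_followups(
    records: Iterable[AssessmentRecord],
    scale_defs: Mapping[str, ScaleDef],
    scales: Sequence[str] | None = None,
) -> tuple[list[QIPair], PairingLog]:
    """Pair each admission with its earliest eligible follow-up assessment.

    Eligible follow-ups are reviews or discharges dated within 90 days
    (inclusive) of the admission.  Admissions without one are excluded and
    counted; episodes with non-monotone dates are skipped with a log entry.
    One pair per admission episode and tracked scale.
    """
    wanted = list(scales) if scales is not None else list(scale_defs)
    by_person: dict[str, list[AssessmentRecord]] = {}
    for rec in records:
        by_person.setdefault(rec.person_id, []).append(rec)

    pairs: list[QIPair] = []
    log = PairingLog()
    for person_id in sorted(by_person):
        recs = by_person[person_id]  # stored order; regressions are episode errors
        i = 0
        while i < len(recs):
            rec = recs[i]
            if rec.reason != "admission":
                i += 1
                continue
            window_end = rec.date + _dt.timedelta(days=FOLLOWUP_WINDOW_DAYS)
            candidates = []
            broken = False
            prev_date = rec.date
            for nxt in recs[i + 1 :]:
                if nxt.reason == "admission":
                    break
                if nxt.date < prev_date:
                    log.episode_errors.append(
                        f"{person_id}: {nxt.reason} on {nxt.date} precedes {prev_date}"
                    )
                    broken = True
                    break
                prev_date = nxt.date
                if nxt.reason in ("review", "discharge") and nxt.date <= window_end:
                    candidates.append(nxt)
            if broken:
                i += 1
                continue
            if not candidates:
                log.no_followup += 1
                i += 1
                continue
            followup_rec = min(candidates, key=lambda r: (r.date, r.reason != "review"))
            base_scores = score_all(rec, scale_defs)
            fu_scores = score_all(followup_rec, scale_defs)
            paired_any = False
            for name in wanted:
                b, f = base_scores.get(name), fu_scores.get(name)
                if b is None or f is None or b.value is None or f.value is None:
                    log.incomplete_scores += 1
                    continue
                pairs.append(
                    QIPair(
                        person_id=person_id,
                        scale=name,
                        baseline=b.value,
                        followup=f.value,
                        baseline_covariates=dict(rec.covariates),
                        period=rec.date.year,
                        scale_max=scale_defs[name].out_max,
                    )
                )
                paired_any = True
            if paired_any:
                log.paired += 1
            i += 1
    return pairs, log


def _event(pair: QIPair, indicator: str, strict_worsening: bool = False) -> bool | None:
    """Event status for one pair, or None if the pair is out of denominator."""
    if indicator == "improvement":
        if pair.baseline <= 0:
            return None
        return pair.followup < pair.baseline
    if indicator == "failure":
        if pair.baseline >= pair.scale_max:
            return None
        if strict_worsening:
            return pair.followup > pair.baseline
        return pair.followup >= pair.baseline
    raise ConfigError(f"unknown indicator {indicator!r}")


def compute_qi(
    pairs: Sequence[QIPair],
    indicator: str,
    stratifier: str | None = None,
    *,
    strict_worsening: bool = False,
) -> pd.DataFrame:
    """Numerators/denominators (and rates) per stratum for one indicator.

    All pairs must belong to a single scale.  With no stratifier a single
    pooled row is returned (stratum ``"all"``).  An empty denominator
    yields an undefined (NaN) rate, flagged, never 0.
    """
    scales = {p.scale for p in pairs}
    if len(scales) > 1:
        raise ConfigError(f"pairs mix scales {sorted(scales)}; compute per scale")
    rows: dict[object, list[bool]] = {}
    for p in pairs:
        ev = _event(p, indicator, strict_worsening)
        if ev is None:
            continue
        stratum = p.baseline_covariates.get(stratifier) if stratifier else "all"
        rows.setdefault(stratum, []).append(ev)
    if stratifier is None and not rows:
        rows["all"] = []
    out = []
    for stratum in sorted(rows, key=str):
        events = rows[stratum]
        denom = len(events)
        num = int(sum(events))
        out.append(
            {
                "indicator": indicator,
                "stratum": stratum,
                "numerator": num,
                "denominator": denom,
                "rate": num / denom if denom else float("nan"),
                "undefined": denom == 0,
            }
        )
    return pd.DataFrame(out)


DEFAULT_ADJUSTMENT = ("age_band", "sex", "baseline_band", "homeless")


def _design_matrix(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    import statsmodels.api as sm

    parts = []
    for cov in covariates:
        col = df[cov]
        if col.dtype == bool or pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).rename(cov))
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            parts.append(dummies.astype(float))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)
    return sm.add_constant(X, has_constant="add")


def _prepare_frame(pairs: Sequence[QIPair], indicator: str, strict: bool) -> pd.DataFrame:
    rows = []
    for p in pairs:
        ev = _event(p, indicator, strict)
        if ev is None:
            continue
        row = {"event": bool(ev), "period": p.period, **dict(p.baseline_covariates)}
        row["baseline_band"] = _baseline_band(p)
        row["age_band"] = _age_band(row.get("age"))
        rows.append(row)
    return pd.DataFrame(rows)


def _baseline_band(p: QIPair) -> str:
    third = max(p.scale_max / 3.0, 1.0)
    if p.baseline <= third:
        return "low"
    if p.baseline <= 2 * third:
        return "mid"
    return "high"


def _age_band(age) -> str:
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return "unknown"
    age = float(age)
    if age < 25:
        return "18-24"
    if age < 45:
        return "25-44"
    if age < 65:
        return "45-64"
    return "65+"


def risk_adjust(
    pairs: Sequence[QIPair],
    indicator: str,
    stratifier: str,
    covariates: Sequence[str] = DEFAULT_ADJUSTMENT,
    *,
    strict_worsening: bool = False,
) -> pd.DataFrame:
    """Indirectly standardized rates per stratum.

    A logistic model of the event on baseline covariates is fit on the
    pooled sample; the stratum's expected rate is its mean fitted
    probability and ``adjusted = observed / expected * pooled``, clipped
    into [0, 1] with a flag.  With no usable covariates (or a degenerate
    model) the adjusted rate falls back to the observed rate, flagged.
    """
    import statsmodels.api as sm

    df = _prepare_frame(pairs, indicator, strict_worsening)
    if df.empty:
        raise UndefinedStatisticError("no pairs in the indicator denominator")
    if stratifier not in df.columns:
        raise KeyError(f"stratifier {stratifier!r} missing from baseline covariates")
    # the reporting stratum must never adjust itself away
    usable = [
        c for c in covariates if c != stratifier and c in df.columns and df[c].notna().all()
    ]
    n_excluded = 0
    for c in covariates:
        if c in df.columns and df[c].isna().any():
            keep = df[c].notna()
            n_excluded += int((~keep).sum())
            df = df[keep]
    y = df["event"].astype(float).to_numpy()
    pooled = float(y.mean())

    degenerate = pooled in (0.0, 1.0) or not usable
    if not degenerate:
        X = _design_matrix(df, usable)
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            df = df.assign(_expected=np.asarray(fit.predict(X), dtype=float))
        except Exception:
            degenerate = True
    if degenerate:
        df = df.assign(_expected=pooled)

    out = []
    for stratum, grp in df.groupby(stratifier, sort=True):
        denom = len(grp)
        num = int(grp["event"].sum())
        observed = num / denom
        expected = float(grp["_expected"].mean())
        if expected > 0:
            adjusted = observed / expected * pooled
        else:
            adjusted = observed
        clipped = not (0.0 <= adjusted <= 1.0)
        out.append(
            {
                "indicator": indicator,
                "stratum": stratum,
                "numerator": num,
                "denominator": denom,
                "observed_rate": observed,
                "expected_rate": expected,
                "adjusted_rate": float(min(max(adjusted, 0.0), 1.0)),
                "clipped": clipped,
                "degenerate_model": degenerate,
                "n_excluded_missing_covariates": n_excluded,
            }
        )
    return pd.DataFrame(out)


def qi_trend(
    pairs: Sequence[QIPair],
    indicator: str,
    stratifier: str,
    covariates: Sequence[str] = DEFAULT_ADJUSTMENT,
) -> pd.DataFrame:
    """Adjusted rates by period (calendar year) x stratum, tidy for plotting."""
    periods = sorted({p.period for p in pairs})
    frames = []
    for period in periods:
        subset = [p for p in pairs if p.period == period]
        res = risk_adjust(subset, indicator, stratifier, covariates)
        res.insert(0, "period", period)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
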