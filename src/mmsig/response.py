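"""Treatment-response labeling and score-based response stratification.

Patients with any clinical response (CR, PR, MR) are responders; the
relation between signature score and response is quantified by
multivariable logistic regression, by grouping patients at fixed score
cutoffs (0.5 and 1 by default) with Fisher's exact test between groups,
and by a hazard-ratio sweep comparing the top-f% of scores against the
rest across a grid of f values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .survival import cox_fit, stratify_top_quantile

__all__ = [
    "RESPONDER_CODES",
    "KNOWN_CODES",
    "LogisticResult",
    "label_responders",
    "logistic_fit",
    "score_groups",
    "fisher_2x2",
    "response_rates",
    "hr_sweep",
]

RESPONDER_CODES = frozenset({"CR", "PR", "MR"})
KNOWN_CODES = frozenset({"CR", "PR", "MR", "NC", "PD", "other"})


@dataclass
class LogisticResult:
    """Logistic-regression odds ratios with Wald CIs; no estimates under separation."""

    summary: pd.DataFrame | None  # index term; columns coef, or, ci_low, ci_high, pvalue
    separation: bool = False


def label_responders(codes) -> pd.Series:
    """Binary responder labels: CR/PR/MR -> 1, NC/PD/other -> 0.

    Codes outside the known vocabulary are excluded with a warning.
    """
    s = pd.Series(codes, dtype=object)
    if len(s) == 0:
        raise ValueError("empty response-code list")
    unknown = ~s.isin(KNOWN_CODES)
    if unknown.any():
        warnings.warn(
            f"excluding {int(unknown.sum())} samples with unknown response codes: "
            f"{sorted(set(s[unknown]))}"
        )
        s = s[~unknown]
    return s.isin(RESPONDER_CODES).astype(int).rename("responder")


def logistic_fit(labels, score, covariates: pd.DataFrame | None = None) -> LogisticResult:
    """Maximum-likelihood logistic regression of responder status on score.

    The score enters with any additional covariates; Wald P-values and 95%
    CIs on the odds-ratio scale. Complete separation is flagged and no
    estimate is returned.
    """
    y = np.asarray(labels, dtype=float)
    score = np.asarray(score, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both responder classes must be present")
    if np.ptp(score) == 0:
        raise ValueError("score is constant")
    X = pd.DataFrame({"score": score})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    if len(y) <= X.shape[1] + 10:
        raise ValueError("too few samples for the number of parameters")
    X = sm.add_constant(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError):
        return LogisticResult(summary=None, separation=True)
    ci = fit.conf_int()
    summary = pd.DataFrame(
        {
            "coef": fit.params,
            "or": np.exp(fit.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "pvalue": fit.pvalues,
        }
    )
    return LogisticResult(summary=summary, separation=False)


def score_groups(scores, cutoffs: tuple[float, float] = (0.5, 1.0)) -> pd.Series:
    """Partition scores into low (< c1), medium (c1 <= s < c2), high (>= c2)."""
    c1, c2 = cutoffs
    if not c1 < c2:
        raise ValueError(f"cutoffs must satisfy c1 < c2: {cutoffs}")
    s = pd.Series(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    group = np.where(s < c1, "low", np.where(s < c2, "medium", "high"))
    return pd.Series(group, index=s.index, name="group")


def fisher_2x2(table) -> float:
    """Exact two-sided Fisher P for a 2x2 table (probability-mass rule).

    A table with a zero margin carries no information; P = 1 by convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; P = 1 by convention")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def response_rates(groups: pd.Series, labels: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group responder fractions and pairwise rate ratios with Fisher P.

    Returns (rates, comparisons); pairs involving an empty group are
    skipped, and a rate ratio is NaN when the reference rate is zero.
    """
    df = pd.DataFrame({"group": groups, "label": labels}).dropna()
    rates = df.groupby("group")["label"].agg(n="size", responders="sum", rate="mean")
    comparisons = []
    names = list(rates.index)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            na, nb = int(rates.loc[a, "n"]), int(rates.loc[b, "n"])
            if na == 0 or nb == 0:
                continue
            ra, rb = float(rates.loc[a, "rate"]), float(rates.loc[b, "rate"])
            ka, kb = int(rates.loc[a, "responders"]), int(rates.loc[b, "responders"])
            p = fisher_2x2([[ka, na - ka], [kb, nb - kb]])
            ratio = ra / rb if rb > 0 else np.nan
            comparisons.append((a, b, ra, rb, ratio, p))
    comp = pd.DataFrame(
        comparisons, columns=["group_a", "group_b", "rate_a", "rate_b", "rate_ratio", "fisher_p"]
    )
    return rates.reset_index(), comp


def hr_sweep(
    scores: pd.Series,
    survival: pd.DataFrame,
    f_grid,
    min_events: int = 5,
    duration_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Hazard ratio of the top-f% score group vs the rest over a grid of f.

    Each f dichotomizes at the (1 - f) score quantile with the >= rule —
    identical to :func:`mmsig.survival.stratify_top_quantile` at q = 1 - f —
    and fits a two-group Cox model. Grid points without min_events events in
    both groups are skipped with a warning.
    """
    scores = pd.Series(scores, dtype=float)
    surv = survival.loc[scores.index]
    rows = []
    for f in f_grid:
        if not (0.0 < f <= 0.5):
            raise ValueError(f"f must lie in (0, 0.5]: {f}")
        groups = stratify_top_quantile(scores, q=1.0 - f)
        high = (groups == "high").astype(int)
        ev = surv[event_col].groupby(high).sum()
        if len(ev) < 2 or (ev < min_events).any():
            warnings.warn(f"skipping f={f}: fewer than {min_events} events in a group")
            continue
        data = pd.DataFrame(
            {"high": high, duration_col: surv[duration_col], event_col: surv[event_col]}
        )
        res = cox_fit(data, ["high"], duration_col=duration_col, event_col=event_col)
        s = res.summary.loc["high"]
        rows.append((f, int(high.sum()), s["hr"], s["ci_low"], s["ci_high"], s["pvalue"]))
    if not rows:
        raise ValueError("no f in the grid yielded enough events in both groups")
    return pd.DataFrame(rows, columns=["f", "n_high", "hr", "ci_low", "ci_high", "pvalue"])
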