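"""Kaplan-Meier estimation, log-rank tests, and the Monte-Carlo U test.

Risk-group curves are compared with the standard two-group log-rank test
after truncating follow-up at 90 months.  Whether one risk model separates
the curves *better than another* is judged with a simulated-null U test:
U = |chi2_A - chi2_B|, referred to the Monte-Carlo distribution of the
absolute difference of two independent chi-squared(1) variables.  The
independence assumption between the two models' statistics is inherited
from the protocol being reproduced, not endorsed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .evaluation import ContrastData, FittedModel, _equal_split, fit_half
from .lsr_model import DEFAULT_DELTA_GRID

TRUNCATION_MONTHS = 90.0
DEFAULT_U_DRAWS = 10_000_000


@dataclass
class KMCurve:
    """Product-limit estimate truncated at ``truncation_time`` months."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    truncation_time: float

    def survival_at(self, t: float) -> float:
        """S(t); step function, right-continuous."""
        if t < 0:
            raise ValueError("time must be non-negative")
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class UTestResult:
    chi2_a: float
    chi2_b: float
    U: float
    n_draws: int
    p: float
    seed: int | None


def _truncate(
    times: Sequence[float], events: Sequence[int], truncation: float
) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(t < 0):
        raise ValueError("negative follow-up time")
    over = t > truncation
    t = np.where(over, truncation, t)
    e = np.where(over, 0, e)  # anything beyond truncation is censored there
    return t, e


def km_estimate(
    times: Sequence[float],
    events: Sequence[int],
    truncation: float = TRUNCATION_MONTHS,
) -> KMCurve:
    """Kaplan-Meier curve with follow-up truncated at ``truncation`` months."""
    t, e = _truncate(times, events, truncation)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return KMCurve(times=grid, survival=surv, at_risk=at_risk, truncation_time=truncation)


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
    truncation: float = TRUNCATION_MONTHS,
) -> tuple[float, float]:
    """Two-group log-rank chi-squared (1 df) and p-value after truncation."""
    ta, ea = _truncate(times_a, events_a, truncation)
    tb, eb = _truncate(times_b, events_b, truncation)
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def u_test(
    chi2_a: float,
    chi2_b: float,
    n_draws: int = DEFAULT_U_DRAWS,
    seed: int | None = None,
) -> UTestResult:
    """Monte-Carlo p for U = |chi2_a - chi2_b| against the null of two
    independent chi-squared(1) statistics; plus-one corrected so p > 0."""
    if min(chi2_a, chi2_b) < 0:
        raise ValueError("chi-squared statistics must be non-negative")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    U = abs(chi2_a - chi2_b)
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = 10_000_000
    remaining = n_draws
    while remaining > 0:
        m = min(chunk, remaining)
        diff = np.abs(rng.chisquare(1, m) - rng.chisquare(1, m))
        exceed += int(np.count_nonzero(diff >= U))
        remaining -= m
    p = (exceed + 1) / (n_draws + 1)
    return UTestResult(
        chi2_a=float(chi2_a), chi2_b=float(chi2_b), U=U, n_draws=n_draws, p=p, seed=seed
    )


def u_null_survival(u: float) -> float:
    """Exact P(|X - Y| >= u) for independent chi-squared(1) X, Y.

    X - Y = (Z1 - Z2)(Z1 + Z2) with Z1 - Z2 and Z1 + Z2 independent
    N(0, 2), so X - Y is distributed as twice the product of two standard
    normals, whose density is K0(|x|)/pi; hence
    P(|X - Y| >= u) = (2/pi) * integral_{u/2}^inf K0(w) dw.
    """
    from scipy.integrate import quad
    from scipy.special import k0

    if u <= 0:
        return 1.0
    val, _ = quad(k0, u / 2.0, np.inf)
    return float(2.0 * val / np.pi)


def merged_cv_groups(
    data: ContrastData,
    modalities: Iterable[str],
    seed: int | np.random.SeedSequence,
    delta_grid: Sequence[float] = DEFAULT_DELTA_GRID,
) -> pd.Series:
    """Cross-fitted risk-group call per patient from one two-fold split.

    Each patient is predicted by the model trained on the half *not*
    containing them, so every patient receives exactly one call.  The
    Gleason single-modality model is the exception: it is a fixed global
    threshold (> 7) applied to all samples without cross-fitting.
    """
    mods = tuple(m for m in "LNFG" if m in set(modalities))
    if mods == ("G",):
        from .covariates import encode_gleason

        calls = {
            sid: encode_gleason(rec.gleason) for sid, rec in data.records.items()
        }
        return pd.Series(calls, name="predicted", dtype=int)
    rng = np.random.default_rng(seed)
    half_a, half_b = _equal_split(data.sample_ids, data.labels, rng)
    calls: dict[str, int] = {}
    for train_ids, test_ids in ((half_a, half_b), (half_b, half_a)):
        model = fit_half(data, train_ids, mods, delta_grid)
        pred = model.predict(data, test_ids)
        calls.update(dict(zip(test_ids, (int(v) for v in pred))))
    series = pd.Series(calls, name="predicted", dtype=int)
    return series.loc[data.sample_ids]


def km_by_group(
    data: ContrastData,
    groups: pd.Series,
    truncation: float = TRUNCATION_MONTHS,
) -> tuple[dict[int, KMCurve], float, float]:
    """KM curves per predicted risk group plus the log-rank (chi2, p).

    Event = recurrence; time = recurrence time for recurrent patients,
    censoring time otherwise.
    """
    times = {0: [], 1: []}
    events = {0: [], 1: []}
    for sid, g in groups.items():
        rec = data.records[sid]
        times[int(g)].append(rec.followup_months)
        events[int(g)].append(int(rec.recurrent))
    if not times[0] or not times[1]:
        raise ValueError("both risk groups must be non-empty")
    curves = {
        g: km_estimate(times[g], events[g], truncation) for g in (0, 1)
    }
    chi2, p = logrank(times[0], events[0], times[1], events[1], truncation)
    return curves, chi2, p
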