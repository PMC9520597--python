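"""Survival-analysis primitives.

Kaplan-Meier (product-limit) estimation, the two-group Mantel-Haenszel
log-rank test (including a gene-vectorized variant used by transcriptome-wide
screening), fixed-horizon dead/alive tables, and the continuity-corrected
chi-square statistic for 2x2 tables.

Clinical tables are plain :class:`pandas.DataFrame` objects with columns
``sample_id``, ``time_days`` (non-negative follow-up in days), ``event``
(boolean, ``True`` = death), ``treatment``, ``cancer_type`` and ``subtype``.

Notes
-----
The log-rank statistic is the 1-df Mantel-Haenszel form with hypergeometric
variance,

.. math:: X^2 = (O_A - E_A)^2 / V,

with :math:`O_A`, :math:`E_A` the observed and expected deaths in group A
summed over distinct event times and :math:`V` the summed hypergeometric
variance. Samples censored at an event time are counted at risk at that time.

The 2x2 chi-square applies the Yates continuity correction with the
corrected deviation floored at zero,

.. math:: X^2 = \\sum \\max(|O - E| - 0.5,\\, 0)^2 / E,

which is the convention that reproduces published horizon-table statistics;
it differs from SciPy's correction, which shifts each observed count half a
unit toward its expectation even when the deviation is below one half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .exceptions import UndefinedTestError, ValidationError

logger = logging.getLogger(__name__)

#: Columns a clinical table must carry.
CLINICAL_COLUMNS = ("sample_id", "time_days", "event", "treatment",
                    "cancer_type", "subtype")

#: Follow-up horizons (days) for 1/3/5-year outcome tables.
DEFAULT_HORIZONS = (365, 1095, 1825)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (half-up), not banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check schema and basic invariants of a clinical table."""
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns: {missing}")
    t = pd.to_numeric(clinical["time_days"], errors="coerce")
    if t.isna().any():
        bad = clinical.loc[t.isna(), "sample_id"].tolist()[:5]
        raise ValidationError(f"non-numeric follow-up times for samples {bad}")
    if (t < 0).any():
        raise ValidationError("negative follow-up times present")
    if clinical["sample_id"].duplicated().any():
        dup = clinical.loc[clinical["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample id: {dup!r}")
    return clinical


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve.

    Attributes
    ----------
    event_times : ndarray
        Distinct times with at least one death, ascending.
    survival : ndarray
        S(t) immediately after each event time; non-increasing, in [0, 1].
    at_risk : ndarray
        Number at risk just before each event time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, times) -> np.ndarray:
        """Step-function evaluation of S(t); S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, np.asarray(times, dtype=float),
                              side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


def _check_time_event(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValidationError("empty survival input")
    if time.shape != event.shape:
        raise ValidationError("time and event must have identical shape")
    if not np.isfinite(time).all():
        raise ValidationError("non-finite follow-up times")
    return time, event


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survivor function.

    Parameters
    ----------
    time : array-like
        Observed follow-up times (days).
    event : array-like of bool
        True where the follow-up ended in death, False where censored.
    """
    time, event = _check_time_event(time, event)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = t.size
    first = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    deaths = np.add.reduceat(e.astype(float), first)
    at_risk = (n - first).astype(float)
    has_death = deaths > 0
    d, r = deaths[has_death], at_risk[has_death]
    surv = np.cumprod(1.0 - d / r)
    return KMCurve(event_times=t[first][has_death], survival=surv, at_risk=r)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogRankResult:
    """Mantel-Haenszel log-rank test result (1 df)."""

    statistic: float
    p_value: float
    direction: int  #: sign of (observed - expected) deaths in group A

    #: observed minus expected deaths in group A (signed effect size)
    o_minus_e: float = field(default=0.0)


def logrank_screen(time, event, in_group) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Mantel-Haenszel log-rank over many group assignments.

    All rows of ``in_group`` share the same follow-up data; each row is one
    membership indicator (e.g. one gene's high-expression group). This is the
    workhorse behind transcriptome-wide screening: a 5,000-gene screen is a
    single pass over the sorted risk sets.

    Parameters
    ----------
    time, event : array-like, shape (n_samples,)
    in_group : array-like of bool, shape (n_tests, n_samples)

    Returns
    -------
    statistic, p_value, o_minus_e : ndarray, shape (n_tests,)
        ``o_minus_e`` is observed minus expected deaths in the indicated
        group; its sign is the test direction.
    """
    time, event = _check_time_event(time, event)
    G = np.atleast_2d(np.asarray(in_group, dtype=bool))
    if G.shape[1] != time.size:
        raise ValidationError("in_group columns must match number of samples")
    if not event.any():
        raise UndefinedTestError("log-rank test undefined with zero events")

    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(float)
    g = G[:, order].astype(float)
    n = t.size

    # at-risk counts in the indicated group, counting from each index to the end
    n1_from = np.cumsum(g[:, ::-1], axis=1)[:, ::-1]
    first = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    d = np.add.reduceat(e, first)              # deaths at each distinct time
    d1 = np.add.reduceat(g * e, first, axis=1)  # ... in the indicated group
    n_at = (n - first).astype(float)
    n1 = n1_from[:, first]

    mask = d > 0
    dm, nm = d[mask], n_at[mask]
    n1m, d1m = n1[:, mask], d1[:, mask]
    frac = n1m / nm
    expected = dm * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        var = dm * frac * (1.0 - frac) * (nm - dm) / np.maximum(nm - 1.0, 1.0)

    o_minus_e = d1m.sum(axis=1) - expected.sum(axis=1)
    v = var.sum(axis=1)
    stat = np.zeros(G.shape[0])
    ok = v > 0
    stat[ok] = o_minus_e[ok] ** 2 / v[ok]
    p = _chi2_dist.sf(stat, 1)
    p[~ok] = 1.0
    return stat, p, o_minus_e


def logrank_test(time_a, event_a, time_b, event_b) -> LogRankResult:
    """Two-group Mantel-Haenszel log-rank test.

    ``direction`` is the sign of observed-minus-expected deaths in group A:
    negative means group A saw fewer deaths than expected (better survival).
    """
    ta, ea = _check_time_event(time_a, event_a)
    tb, eb = _check_time_event(time_b, event_b)
    time = np.concatenate([ta, tb])
    event = np.concatenate([ea, eb])
    in_a = np.zeros(time.size, dtype=bool)
    in_a[: ta.size] = True
    stat, p, oe = logrank_screen(time, event, in_a[None, :])
    return LogRankResult(statistic=float(stat[0]), p_value=float(p[0]),
                         direction=int(np.sign(oe[0])), o_minus_e=float(oe[0]))


# ---------------------------------------------------------------------------
# Horizon tables and the continuity-corrected chi-square
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HorizonTable:
    """Dead/alive counts at a fixed follow-up horizon, per group.

    A sample counts as dead when its event occurred at or before the horizon;
    every other sample -- including those censored before the horizon --
    counts as alive, which keeps group totals constant across horizons.
    """

    horizon: float
    groups: tuple[str, str]
    deaths: dict
    alive: dict
    survival_pct: dict

    def counts(self) -> np.ndarray:
        """2x2 array ((deaths_A, alive_A), (deaths_B, alive_B))."""
        return np.array([[self.deaths[g], self.alive[g]] for g in self.groups])


def horizon_table(clinical: pd.DataFrame, groups: Sequence[str],
                  horizon: float, group_col: str = "treatment") -> HorizonTable:
    """Tabulate deaths/alive at ``horizon`` days for two groups.

    Parameters
    ----------
    clinical : DataFrame
        Clinical table (see module docstring).
    groups : pair of labels
        Values of ``group_col`` defining the two groups.
    horizon : float
        Follow-up horizon in days (> 0).
    """
    if horizon <= 0:
        raise ValidationError("horizon must be positive")
    if len(groups) != 2:
        raise ValidationError("exactly two group labels required")
    deaths, alive, pct = {}, {}, {}
    for g in groups:
        sub = clinical[clinical[group_col] == g]
        if len(sub) == 0:
            raise ValidationError(f"empty group {g!r}")
        dead = int((sub["event"].astype(bool) & (sub["time_days"] <= horizon)).sum())
        deaths[g] = dead
        alive[g] = len(sub) - dead
        pct[g] = round_half_up(100.0 * alive[g] / len(sub), 2)
    return HorizonTable(horizon=float(horizon), groups=tuple(groups),
                        deaths=deaths, alive=alive, survival_pct=pct)


def chi2_contingency_cc(table) -> tuple[float, float]:
    """Continuity-corrected chi-square for a 2x2 table, deviation floored at 0.

    Returns the unrounded statistic and its 1-df upper-tail p-value. Raises
    :class:`UndefinedTestError` when a row or column margin is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("a 2x2 table is required")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValidationError("counts must be non-negative and finite")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise UndefinedTestError("zero row or column margin")
    expected = np.outer(rows, cols) / t.sum()
    dev = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    stat = float((dev ** 2 / expected).sum())
    return stat, float(_chi2_dist.sf(stat, 1))


def table1_report(clinical: pd.DataFrame, groups: Sequence[str] = ("5-FU", "none"),
                  horizons: Sequence[float] = DEFAULT_HORIZONS,
                  group_col: str = "treatment",
                  by: str | None = "subtype") -> pd.DataFrame:
    """Horizon survival report: one row per (stratum, horizon, group).

    For every stratum (all samples plus each level of ``by``) and horizon,
    reports group totals, deaths, alive, the survival percentage, and the
    continuity-corrected chi-square comparing the two groups with its star
    annotation.
    """
    validate_clinical(clinical)
    strata: list[tuple[str, pd.DataFrame]] = [("all", clinical)]
    if by is not None:
        for level, sub in clinical.groupby(by, sort=True):
            strata.append((str(level), sub))
    rows = []
    for name, sub in strata:
        present = all((sub[group_col] == g).any() for g in groups)
        if not present:
            logger.info("table1: stratum %r lacks one of the groups, skipped", name)
            continue
        for h in horizons:
            ht = horizon_table(sub, groups, h, group_col=group_col)
            try:
                stat, p = chi2_contingency_cc(ht.counts())
                stat, stars = round_half_up(stat, 2), significance_stars(p)
            except UndefinedTestError:
                stat, p, stars = float("nan"), float("nan"), "NA"
            for g in groups:
                rows.append({
                    "stratum": name, "horizon_days": h, "group": g,
                    "total": ht.deaths[g] + ht.alive[g],
                    "deaths": ht.deaths[g], "alive": ht.alive[g],
                    "survival_pct": ht.survival_pct[g],
                    "chi2": stat, "p_value": p, "stars": stars,
                })
    return pd.DataFrame(rows)
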