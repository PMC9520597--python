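"""Transcriptome-wide survival screening of Pro/Con gene cohorts.

Every gene is dichotomized at its cohort median ("high" strictly above,
"low" at or below), the high and low groups are compared with the
Mantel-Haenszel log-rank test, and genes passing the significance cutoff are
classified by direction: a *Pro* gene is one whose high-expression group saw
fewer deaths than expected (high expression beneficial), a *Con* gene the
reverse. No multiple-testing correction is applied: the raw per-gene cutoff
is deliberate and is the convention this screen reproduces.

The estimator follows the scikit-learn protocol: ``X`` is samples x genes and
``y`` is the survival outcome, given as a ``(time, event)`` pair of arrays, a
structured array with ``time``/``event`` fields, or a DataFrame with
``time_days``/``event`` (or ``time``/``event``) columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .exceptions import (AlignmentError, DegenerateSplitError,
                         ValidationError)
from .survival import logrank_screen

logger = logging.getLogger(__name__)

#: Annotation tag marking a secreted protein in a subcellular-location table.
SECRETED_TAG = "secreted"


@dataclass(frozen=True)
class GeneScreenResult:
    """Outcome of screening one gene."""

    gene: str
    p_value: float
    direction: str  #: one of {"pro", "con", "ns", "skipped"}


@dataclass(frozen=True)
class ProConPanel:
    """Disjoint Pro and Con gene lists with the screening alpha."""

    pro_genes: tuple[str, ...]
    con_genes: tuple[str, ...]
    alpha: float = 0.01

    def __post_init__(self):
        if set(self.pro_genes) & set(self.con_genes):
            raise ValidationError("pro and con lists must be disjoint")
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.pro_genes) + tuple(self.con_genes)

    def __len__(self) -> int:
        return len(self.pro_genes) + len(self.con_genes)


def _as_survival(y) -> tuple[np.ndarray, np.ndarray]:
    """Coerce the supported survival-outcome representations."""
    if isinstance(y, tuple) and len(y) == 2:
        time, event = y
    elif isinstance(y, pd.DataFrame):
        tcol = "time_days" if "time_days" in y.columns else "time"
        if tcol not in y.columns or "event" not in y.columns:
            raise ValidationError("survival frame needs time(_days) and event columns")
        time, event = y[tcol], y["event"]
    elif isinstance(y, np.ndarray) and y.dtype.names:
        names = y.dtype.names
        tname = "time_days" if "time_days" in names else "time"
        time, event = y[tname], y["event"]
    else:
        raise ValidationError("y must be (time, event), a structured array, or "
                              "a DataFrame with time and event columns")
    return np.asarray(time, dtype=float), np.asarray(event, dtype=bool)


def dichotomize_by_median(values) -> np.ndarray:
    """Label each value 'high' (strictly above the median) or 'low'.

    Ties at the median go low. Raises :class:`DegenerateSplitError` when all
    values are identical or one side of the split is empty.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("at least two samples required")
    high = v > np.median(v)
    if not high.any() or high.all():
        raise DegenerateSplitError("median split leaves one side empty")
    return np.where(high, "high", "low")


class ProConScreener(BaseEstimator):
    """Per-gene survival screen with median dichotomization.

    Parameters
    ----------
    alpha : float, default 0.01
        Raw per-gene significance cutoff (no multiplicity correction).
    drop_zero_time_censored : bool, default True
        Exclude records with zero follow-up and no event before screening.

    Attributes
    ----------
    results_ : DataFrame
        Per gene: ``p_value``, ``o_minus_e`` (observed minus expected deaths
        in the high group) and ``direction`` in {pro, con, ns, skipped}.
    pro_genes_, con_genes_ : tuple of str
    skipped_genes_ : tuple of str
        Genes with a degenerate split (constant values or a majority tied at
        the median).
    """

    def __init__(self, alpha: float = 0.01, drop_zero_time_censored: bool = True):
        self.alpha = alpha
        self.drop_zero_time_censored = drop_zero_time_censored

    def fit(self, X, y):
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")
        time, event = _as_survival(y)
        if isinstance(X, pd.DataFrame):
            genes = np.asarray(X.columns, dtype=str)
            M = X.to_numpy(dtype=float)
        else:
            M = np.asarray(X, dtype=float)
            genes = np.array([f"g{i}" for i in range(M.shape[1])])
        if M.ndim != 2 or M.shape[0] != time.size:
            raise AlignmentError("X rows must match the survival records")
        if M.shape[0] < 2:
            raise ValidationError("at least two samples required")

        keep = np.ones(time.size, dtype=bool)
        if self.drop_zero_time_censored:
            keep = ~((time == 0) & ~event)
            if (~keep).any():
                logger.info("screen: excluded %d zero-follow-up censored records",
                            int((~keep).sum()))
        M, time, event = M[keep], time[keep], event[keep]
        n = M.shape[0]

        med = np.median(M, axis=0, keepdims=True)
        high = (M > med).T  # genes x samples
        n_high = high.sum(axis=1)
        n_at_med = (M == med).sum(axis=0)
        testable = (n_high > 0) & (n_high < n) & (n_at_med <= n / 2)

        p = np.full(genes.size, np.nan)
        oe = np.full(genes.size, np.nan)
        if testable.any():
            _, p_t, oe_t = logrank_screen(time, event, high[testable])
            p[testable], oe[testable] = p_t, oe_t

        direction = np.where(testable, "ns", "skipped").astype(object)
        sig = testable & (p < self.alpha)
        direction[sig & (oe < 0)] = "pro"   # high group: fewer deaths than expected
        direction[sig & (oe > 0)] = "con"
        self.results_ = pd.DataFrame(
            {"p_value": p, "o_minus_e": oe, "direction": direction}, index=genes)
        self.pro_genes_ = tuple(genes[direction == "pro"])
        self.con_genes_ = tuple(genes[direction == "con"])
        self.skipped_genes_ = tuple(genes[~testable])
        self.n_features_in_ = genes.size
        if self.skipped_genes_:
            logger.info("screen: skipped %d degenerate genes", len(self.skipped_genes_))
        logger.info("screen: %d pro, %d con of %d genes at alpha=%g",
                    len(self.pro_genes_), len(self.con_genes_), genes.size, self.alpha)
        return self

    def get_panel(self) -> ProConPanel:
        check_is_fitted(self, "results_")
        return ProConPanel(self.pro_genes_, self.con_genes_, alpha=self.alpha)


def screen_gene(expr_row, time, event, alpha: float = 0.01,
                gene: str = "gene") -> GeneScreenResult:
    """Screen a single gene; degenerate splits yield direction 'skipped'."""
    v = np.atleast_2d(np.asarray(expr_row, dtype=float)).T  # samples x 1
    s = ProConScreener(alpha=alpha).fit(
        pd.DataFrame(v, columns=[gene]), (time, event))
    row = s.results_.iloc[0]
    return GeneScreenResult(gene=gene, p_value=float(row["p_value"]),
                            direction=str(row["direction"]))


def build_panel(expression: pd.DataFrame, clinical: pd.DataFrame,
                alpha: float = 0.01) -> ProConPanel:
    """Screen every gene of a genes x samples matrix against a clinical table.

    The matrix columns and clinical ``sample_id`` must contain the same
    samples (any order); a mismatch raises :class:`AlignmentError`.
    """
    ids = clinical["sample_id"].astype(str)
    if set(expression.columns) != set(ids):
        raise AlignmentError("expression samples and clinical sample ids differ")
    X = expression[list(ids)].T  # samples x genes, clinical order
    screener = ProConScreener(alpha=alpha).fit(
        X, (clinical["time_days"], clinical["event"]))
    return screener.get_panel()


def filter_secreted(panel: ProConPanel, locations: Mapping[str, str] | pd.Series,
                    tag: str = SECRETED_TAG) -> ProConPanel:
    """Keep only panel genes whose location annotation contains ``tag``.

    Matching is case-insensitive substring search, so compound annotations
    like ``"Secreted;Cytosol"`` are retained. Genes absent from the table are
    dropped and logged.
    """
    if isinstance(locations, pd.Series):
        locations = locations.to_dict()
    if not locations:
        raise ValidationError("empty location table")
    tag = tag.lower()

    def keep(genes: Sequence[str]) -> tuple[str, ...]:
        kept, missing = [], []
        for g in genes:
            if g not in locations:
                missing.append(g)
            elif tag in str(locations[g]).lower():
                kept.append(g)
        if missing:
            logger.info("filter_secreted: %d genes missing from the location "
                        "table were dropped", len(missing))
        return tuple(kept)

    return ProConPanel(keep(panel.pro_genes), keep(panel.con_genes),
                       alpha=panel.alpha)
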