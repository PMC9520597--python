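"""Z-score drug-response signature and its ROC evaluation.

The signature score of sample *s* is

    score_s = mean_{g in Pro} z_gs - mean_{g in Con} z_gs,

where ``z`` is the per-gene standardization of expression within the
evaluated cohort (sample sd, n-1 denominator). Means rather than sums keep
the score invariant to panel-size imbalance. Treated samples are labeled
*benefit* when their observed survival time exceeds the treated cohort's
median and *futile* otherwise (ties at the median are futile); the AUC is
the rank-based (Mann-Whitney) probability that a benefit sample outscores a
futile one.

``evaluate_grid`` repeats score/label/AUC per (cancer type, subtype, drug)
cohort and reports NA for cells with fewer than ``min_samples`` labeled
samples or a single label class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from .exceptions import ValidationError
from .screen import ProConPanel

logger = logging.getLogger(__name__)

BENEFIT, FUTILE = "benefit", "futile"


def zscore_genes(expression: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene (row) to mean 0, sample sd 1 across samples.

    Zero-variance genes map to all-zero rows (logged), so they contribute
    nothing to downstream signature means.
    """
    if expression.shape[1] < 2:
        raise ValidationError("at least two samples required for z-scoring")
    mu = expression.mean(axis=1)
    sd = expression.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.info("zscore: %d zero-variance genes set to 0", int(flat.sum()))
    z = expression.sub(mu, axis=0).div(sd.where(~flat, 1.0), axis=0)
    z[flat] = 0.0
    return z


class SignatureScorer(TransformerMixin, BaseEstimator):
    """Pro-minus-Con z-score signature as a scikit-learn transformer.

    ``fit`` learns per-gene means and sds on the evaluated cohort (samples x
    genes); ``transform`` returns the signature score as an ``(n, 1)`` column,
    ``score_samples`` as a flat vector. Panel genes absent from the matrix
    are dropped with a warning, mirroring signatures applied to platforms
    that lack part of the panel; an empty overlap is an error.
    """

    def __init__(self, panel: ProConPanel = None):
        self.panel = panel

    def fit(self, X, y=None):
        if self.panel is None or len(self.panel) == 0:
            raise ValidationError("a non-empty ProConPanel is required")
        X = self._frame(X)
        if X.shape[0] < 2:
            raise ValidationError("at least two samples required")
        present = set(X.columns)
        self.pro_used_ = tuple(g for g in self.panel.pro_genes if g in present)
        self.con_used_ = tuple(g for g in self.panel.con_genes if g in present)
        dropped = len(self.panel) - len(self.pro_used_) - len(self.con_used_)
        if dropped:
            logger.warning("scorer: %d panel genes missing from the matrix", dropped)
        if not self.pro_used_ and not self.con_used_:
            raise ValidationError("no panel gene present in the matrix")
        used = list(self.pro_used_) + list(self.con_used_)
        sub = X[used].to_numpy(dtype=float)
        self.mean_ = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        self.flat_ = sd == 0
        self.scale_ = np.where(self.flat_, 1.0, sd)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def score_samples(self, X) -> np.ndarray:
        check_is_fitted(self, "mean_")
        X = self._frame(X)
        used = list(self.pro_used_) + list(self.con_used_)
        missing = [g for g in used if g not in X.columns]
        if missing:
            raise ValidationError(f"matrix lacks fitted panel genes: {missing[:5]}")
        Z = (X[used].to_numpy(dtype=float) - self.mean_) / self.scale_
        Z[:, self.flat_] = 0.0
        k = len(self.pro_used_)
        pro = Z[:, :k].mean(axis=1) if k else np.zeros(len(X))
        con = Z[:, k:].mean(axis=1) if len(self.con_used_) else np.zeros(len(X))
        return pro - con

    def transform(self, X) -> np.ndarray:
        return self.score_samples(X)[:, None]

    @staticmethod
    def _frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        raise ValidationError("X must be a samples x genes DataFrame with "
                              "gene names as columns")


def score_samples(zmatrix: pd.DataFrame, panel: ProConPanel) -> pd.Series:
    """Signature scores from a pre-standardized genes x samples matrix."""
    pro = [g for g in panel.pro_genes if g in zmatrix.index]
    con = [g for g in panel.con_genes if g in zmatrix.index]
    dropped = len(panel) - len(pro) - len(con)
    if dropped:
        logger.warning("score: %d panel genes missing from the matrix", dropped)
    if not pro and not con:
        raise ValidationError("no panel gene present in the matrix")
    pro_part = zmatrix.loc[pro].mean(axis=0) if pro else 0.0
    con_part = zmatrix.loc[con].mean(axis=0) if con else 0.0
    score = pro_part - con_part
    score.name = "score"
    return score


def label_response(clinical: pd.DataFrame, drug: str) -> pd.Series:
    """Benefit/futile labels for drug-treated samples.

    Restricted to rows with ``treatment == drug``; the cohort median of the
    *observed* time (deaths and censored alike) is the threshold: strictly
    above is benefit, at or below is futile.
    """
    treated = clinical[clinical["treatment"] == drug]
    if len(treated) < 2:
        raise ValidationError(f"fewer than two samples treated with {drug!r}")
    med = treated["time_days"].median()
    labels = np.where(treated["time_days"] > med, BENEFIT, FUTILE)
    return pd.Series(labels, index=treated["sample_id"].to_numpy(), name="label")


def roc_auc(scores, labels) -> float:
    """Rank-based AUC of scores for benefit vs futile; NaN if one class only.

    Equivalent to the Mann-Whitney statistic: concordant pairs plus half the
    tied pairs, over all benefit x futile pairs.
    """
    y = np.asarray(labels) == BENEFIT
    s = np.asarray(scores, dtype=float)
    if y.size != s.size:
        raise ValidationError("scores and labels must align")
    if y.all() or not y.any():
        return float("nan")
    return float(roc_auc_score(y, s))


class Cohort(NamedTuple):
    """One grid cell: a cohort with aligned expression and survival."""

    cancer_type: str
    subtype: str
    drug: str
    expression: pd.DataFrame  #: genes x samples
    clinical: pd.DataFrame


@dataclass(frozen=True)
class AUCGridCell:
    cancer_type: str
    subtype: str
    drug: str
    n: int
    auc: float  #: NaN encodes NA


def evaluate_grid(cohorts: Iterable[Cohort], panel: ProConPanel,
                  min_samples: int = 6) -> pd.DataFrame:
    """AUC of the signature per (cancer type, subtype, drug) cohort.

    Within each cell the drug-treated samples are z-scored, scored and
    labeled; the AUC is NA when fewer than ``min_samples`` samples carry a
    label or one label class is empty.
    """
    rows = []
    for c in cohorts:
        treated = c.clinical[c.clinical["treatment"] == c.drug]
        n = len(treated)
        auc = float("nan")
        if n >= max(min_samples, 2):
            ids = treated["sample_id"].astype(str)
            expr = c.expression[list(ids)]
            labels = label_response(treated, c.drug)
            try:
                z = zscore_genes(expr)
                scores = score_samples(z, panel)
                auc = roc_auc(scores[labels.index], labels)
            except ValidationError as exc:
                logger.warning("grid cell (%s, %s, %s): %s",
                               c.cancer_type, c.subtype, c.drug, exc)
        else:
            logger.info("grid cell (%s, %s, %s): NA with n=%d < %d",
                        c.cancer_type, c.subtype, c.drug, n, min_samples)
        rows.append(AUCGridCell(c.cancer_type, c.subtype, c.drug, n, auc))
    return pd.DataFrame([r.__dict__ for r in rows],
                        columns=["cancer_type", "subtype", "drug", "n", "auc"])
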