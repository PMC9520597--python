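"""Reference-based bulk deconvolution and group proportion comparisons.

Cell-type proportions of a bulk expression profile are estimated by
non-negative least squares against per-type mean reference profiles,

    min_w || b - R w ||^2   s.t.  w >= 0,

followed by renormalization of ``w`` onto the simplex, which also makes the
estimate invariant to rescaling the bulk sample. The reference is the
per-gene mean over the cells of each type, taken after the standard cell
quality filter (200-2,500 unique features inclusive, mitochondrial fraction
strictly below 15%). Group differences in estimated proportions are tested
with a two-tailed Welch t-test and annotated with the usual significance
stars (0.05 / 0.01 / 0.001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import ttest_ind
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .exceptions import EstimationError, ValidationError
from .survival import significance_stars

logger = logging.getLogger(__name__)

#: Inclusive feature-count bounds and strict mitochondrial bound of the QC rule.
QC_FEATURE_BOUNDS = (200, 2500)
QC_MAX_MITO = 0.15


def qc_filter_cells(cells: ad.AnnData,
                    feature_bounds: tuple[int, int] = QC_FEATURE_BOUNDS,
                    max_mito: float = QC_MAX_MITO,
                    feature_key: str = "n_features",
                    mito_key: str = "mito_fraction") -> ad.AnnData:
    """Retain cells with in-range feature counts and sub-threshold mito load.

    Keeps cell *c* iff ``lo <= n_features_c <= hi`` (inclusive bounds) and
    ``mito_fraction_c < max_mito`` (strict). Missing metric columns raise
    :class:`ValidationError`.
    """
    for key in (feature_key, mito_key):
        if key not in cells.obs.columns:
            raise ValidationError(f"per-cell metric {key!r} missing from .obs")
    nf = cells.obs[feature_key].to_numpy()
    mito = cells.obs[mito_key].to_numpy()
    if np.isnan(nf.astype(float)).any() or np.isnan(mito.astype(float)).any():
        raise ValidationError("per-cell QC metrics contain missing values")
    lo, hi = feature_bounds
    keep = (nf >= lo) & (nf <= hi) & (mito < max_mito)
    logger.info("qc_filter_cells: retained %d / %d cells", int(keep.sum()), cells.n_obs)
    return cells[keep].copy()


def build_reference(cells: ad.AnnData, label_key: str = "cell_type") -> pd.DataFrame:
    """Per-type mean expression profiles (genes x types) from labeled cells."""
    if label_key not in cells.obs.columns:
        raise ValidationError(f"cell label column {label_key!r} missing from .obs")
    col = cells.obs[label_key]
    # a categorical's declared vocabulary may exceed the observed labels
    types = (sorted(map(str, col.cat.categories))
             if isinstance(col.dtype, pd.CategoricalDtype)
             else sorted(col.astype(str).unique()))
    labels = col.astype(str)
    if any((labels == t).sum() == 0 for t in types):
        raise ValidationError("every cell type needs at least one cell")
    X = np.asarray(cells.X, dtype=float)
    profiles = {t: X[(labels == t).to_numpy()].mean(axis=0) for t in types}
    return pd.DataFrame(profiles, index=cells.var_names)


class NNLSDeconvolver(BaseEstimator):
    """Cell-type proportion estimator with a scikit-learn fit/predict surface.

    ``fit(X, y)`` builds the per-type reference from labeled single cells
    (``X``: cells x genes, ``y``: type label per cell); alternatively
    :meth:`from_reference` wraps precomputed profiles. ``predict`` solves one
    NNLS problem per bulk sample on the shared genes and renormalizes.

    Attributes
    ----------
    reference_ : DataFrame, genes x types
    classes_ : ndarray of type labels
    """

    def __init__(self, min_genes_per_type: int = 2):
        self.min_genes_per_type = min_genes_per_type

    def fit(self, X, y):
        if isinstance(X, ad.AnnData):
            adata = X.copy()
            if y is not None:
                adata.obs["cell_type"] = np.asarray(y, dtype=str)
        else:
            Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
            var = (pd.DataFrame(index=X.columns) if isinstance(X, pd.DataFrame)
                   else pd.DataFrame(index=[f"g{i}" for i in range(Xv.shape[1])]))
            adata = ad.AnnData(X=Xv, obs=pd.DataFrame(
                {"cell_type": np.asarray(y, dtype=str)}), var=var)
        self.reference_ = build_reference(adata)
        self.classes_ = np.asarray(self.reference_.columns)
        return self

    @classmethod
    def from_reference(cls, reference: pd.DataFrame) -> "NNLSDeconvolver":
        """Wrap a precomputed genes x types reference as a fitted estimator."""
        if reference.shape[1] < 2:
            raise ValidationError("at least two cell types required")
        if reference.columns.duplicated().any():
            raise ValidationError("duplicate cell-type labels in reference")
        est = cls()
        est.reference_ = reference
        est.classes_ = np.asarray(reference.columns)
        return est

    def predict(self, X) -> np.ndarray:
        """Proportions (n_samples, n_types) for bulk profiles (samples x genes)."""
        check_is_fitted(self, "reference_")
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("bulk input must be a samples x genes DataFrame")
        shared = self.reference_.index.intersection(X.columns)
        k = len(self.classes_)
        if len(shared) == 0:
            raise EstimationError("no genes shared between bulk and reference")
        if len(shared) < self.min_genes_per_type * k:
            logger.warning("deconvolution: only %d shared genes for %d types",
                           len(shared), k)
        R = self.reference_.loc[shared].to_numpy(dtype=float)
        B = X[shared].to_numpy(dtype=float)
        out = np.empty((B.shape[0], k))
        for i, b in enumerate(B):
            w, _ = nnls(R, b)
            total = w.sum()
            if total <= 0:
                raise EstimationError(f"all-zero NNLS solution for sample {i}")
            out[i] = w / total
        return out

    def predict_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Like :meth:`predict`, with sample index and type columns."""
        return pd.DataFrame(self.predict(X), index=X.index, columns=self.classes_)


def estimate_proportions(bulk, reference: pd.DataFrame) -> pd.Series | pd.DataFrame:
    """Functional wrapper: proportions of one bulk profile or many.

    ``bulk`` may be a per-gene Series (one sample) or a genes x samples
    DataFrame; ``reference`` is genes x types.
    """
    est = NNLSDeconvolver.from_reference(reference)
    if isinstance(bulk, pd.Series):
        res = est.predict_frame(bulk.to_frame().T)
        return res.iloc[0]
    return est.predict_frame(bulk.T)


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample t-test with star annotation."""

    t_statistic: float
    p_value: float
    stars: str


def compare_proportions(group_a, group_b) -> GroupComparison:
    """Two-tailed Welch t-test between two sets of proportion values."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least two values")
    res = ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    return GroupComparison(t_statistic=t, p_value=p, stars=significance_stars(p))
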