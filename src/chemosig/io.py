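"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices travel as TSV (first column the gene id, header row of
sample ids) or as MatrixMarket coordinate files with ``<stem>.rows.txt`` /
``<stem>.cols.txt`` sidecar name files. Clinical tables are TSV with the
columns documented in :mod:`chemosig.survival`. Gene panels use the standard
GMT dialect (set name, description, then tab-separated gene ids) with two
records named ``PRO`` and ``CON``. Subcellular-location annotations are
two-column TSV (gene, location).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import AlignmentError, ValidationError
from .screen import ProConPanel
from .survival import validate_clinical

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def write_expression_tsv(expression: pd.DataFrame, path) -> None:
    """Write a genes x samples matrix as TSV (gene id in the first column)."""
    expression.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValidationError("duplicate gene ids in expression matrix")
    if df.columns.duplicated().any():
        raise ValidationError("duplicate sample ids in expression matrix")
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        raise ValidationError(f"non-numeric expression values in columns {list(bad)[:3]}")
    return df.astype(float)


def write_expression_mtx(expression: pd.DataFrame, path) -> None:
    """Write as MatrixMarket coordinate format plus row/col name sidecars."""
    path = Path(path)
    scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(expression.to_numpy()))
    stem = path.with_suffix("") if path.suffix == ".mtx" else path
    Path(f"{stem}.rows.txt").write_text("\n".join(map(str, expression.index)) + "\n")
    Path(f"{stem}.cols.txt").write_text("\n".join(map(str, expression.columns)) + "\n")


def read_expression_mtx(path) -> pd.DataFrame:
    path = Path(path)
    mat = scipy.io.mmread(str(path)).toarray()
    stem = path.with_suffix("") if path.suffix == ".mtx" else path
    rows = Path(f"{stem}.rows.txt").read_text().splitlines()
    cols = Path(f"{stem}.cols.txt").read_text().splitlines()
    return pd.DataFrame(mat, index=rows, columns=cols)


def read_expression(path) -> pd.DataFrame:
    """Dispatch on suffix: ``.mtx`` MatrixMarket, otherwise TSV."""
    return (read_expression_mtx(path) if str(path).endswith(".mtx")
            else read_expression_tsv(path))


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

def write_clinical_tsv(clinical: pd.DataFrame, path) -> None:
    validate_clinical(clinical).to_csv(path, sep="\t", index=False,
                                       float_format="%.10g")


def read_clinical_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "event" in df.columns:
        df["event"] = df["event"].astype(bool)
    return validate_clinical(df)


# ---------------------------------------------------------------------------
# Panels (GMT) and annotations
# ---------------------------------------------------------------------------

def write_panel_gmt(panel: ProConPanel, path) -> None:
    """Two-record GMT: PRO and CON, with alpha recorded in the description."""
    desc = f"alpha={panel.alpha:g}"
    with open(path, "w") as fh:
        fh.write("\t".join(["PRO", desc, *panel.pro_genes]) + "\n")
        fh.write("\t".join(["CON", desc, *panel.con_genes]) + "\n")


def read_panel_gmt(path) -> ProConPanel:
    sets: dict[str, list[str]] = {}
    alpha = 0.01
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, desc, *genes = line.rstrip("\n").split("\t")
        sets[name.upper()] = [g for g in genes if g]
        if desc.startswith("alpha="):
            alpha = float(desc.split("=", 1)[1])
    if "PRO" not in sets or "CON" not in sets:
        raise ValidationError("panel GMT must contain PRO and CON records")
    return ProConPanel(tuple(sets["PRO"]), tuple(sets["CON"]), alpha=alpha)


def read_locations_tsv(path) -> pd.Series:
    """Gene -> subcellular-location mapping from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("location table needs two columns (gene, location)")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy())
    if len(s) == 0:
        raise ValidationError("empty location table")
    return s


def write_reference_tsv(reference: pd.DataFrame, path) -> None:
    reference.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_reference_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(float)


# ---------------------------------------------------------------------------
# Cohort loading
# ---------------------------------------------------------------------------

def load_cohort(expression_path, clinical_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and align an expression matrix with its clinical table.

    The cohort is the intersection of the two sample-id sets (mismatches are
    logged with counts); duplicate ids and zero overlap are errors.
    """
    expression = read_expression(expression_path)
    clinical = read_clinical_tsv(clinical_path)
    expr_ids = set(map(str, expression.columns))
    clin_ids = set(clinical["sample_id"])
    shared = expr_ids & clin_ids
    if not shared:
        raise AlignmentError("no sample ids shared between expression and clinical")
    if shared != expr_ids or shared != clin_ids:
        logger.info("load_cohort: intersection keeps %d samples "
                    "(%d expression-only, %d clinical-only dropped)",
                    len(shared), len(expr_ids - shared), len(clin_ids - shared))
    clinical = clinical[clinical["sample_id"].isin(shared)].reset_index(drop=True)
    expression = expression[list(clinical["sample_id"])]
    return expression, clinical


def write_grid_tsv(grid: pd.DataFrame, path) -> None:
    """AUC grid as TSV with NA emitted literally for undefined cells."""
    out = grid.copy()
    out["auc"] = out["auc"].map(lambda a: "NA" if pd.isna(a) else f"{a:.4f}")
    out.to_csv(path, sep="\t", index=False)


def read_grid_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
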