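"""End-to-end orchestration: screen -> score -> label -> AUC -> deconvolve.

``run_pipeline`` wires the stages over files on disk and writes a result
bundle (panel GMT, per-sample scores, AUC grid, horizon survival report,
optional proportions) plus a JSON manifest recording the configuration and
per-stage counts. The manifest contains no timestamps, so a rerun with the
same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__, io
from .deconv import NNLSDeconvolver
from .exceptions import ChemosigError, ValidationError
from .score import Cohort, evaluate_grid, label_response, score_samples, zscore_genes
from .screen import build_panel, filter_secreted
from .survival import DEFAULT_HORIZONS, round_half_up, table1_report

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File paths and knobs for one pipeline run."""

    expression: str
    clinical: str
    output_dir: str
    reference: str | None = None   #: genes x types TSV enabling deconvolution
    locations: str | None = None   #: gene -> location TSV enabling the secreted filter
    alpha: float = 0.01
    horizons: tuple = DEFAULT_HORIZONS
    drug: str = "5-FU"
    min_samples_for_auc: int = 6
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a YAML (or JSON) mapping of the dataclass fields."""
        import yaml
        data = yaml.safe_load(Path(path).read_text())
        return cls(**{k: (tuple(v) if k == "horizons" else v)
                      for k, v in data.items()})


def _single_group_horizons(clinical: pd.DataFrame, horizons) -> pd.DataFrame:
    rows = []
    n = len(clinical)
    for h in horizons:
        dead = int((clinical["event"].astype(bool) & (clinical["time_days"] <= h)).sum())
        rows.append({"stratum": "all", "horizon_days": h, "group": "all",
                     "total": n, "deaths": dead, "alive": n - dead,
                     "survival_pct": round_half_up(100.0 * (n - dead) / n, 2),
                     "chi2": float("nan"), "p_value": float("nan"), "stars": "NA"})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dictionary.

    Any stage failure is re-raised annotated with the stage name.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "chemosig", "version": __version__,
        "config": {**dataclasses.asdict(config), "horizons": list(config.horizons)},
        "stages": {},
    }
    stage = "load"
    try:
        expression, clinical = io.load_cohort(config.expression, config.clinical)
        manifest["stages"]["load"] = {"n_genes": int(expression.shape[0]),
                                      "n_samples": int(expression.shape[1])}

        stage = "screen"
        treated = clinical[clinical["treatment"] == config.drug]
        panel = build_panel(expression[list(treated["sample_id"])], treated,
                            alpha=config.alpha)
        io.write_panel_gmt(panel, out / "panel.gmt")
        manifest["stages"]["screen"] = {"n_pro": len(panel.pro_genes),
                                        "n_con": len(panel.con_genes),
                                        "alpha": config.alpha}
        if config.locations:
            loc = io.read_locations_tsv(config.locations)
            secreted = filter_secreted(panel, loc)
            io.write_panel_gmt(secreted, out / "panel_secreted.gmt")
            manifest["stages"]["screen"]["n_secreted"] = len(secreted)

        stage = "score"
        z = zscore_genes(expression[list(treated["sample_id"])])
        scores = score_samples(z, panel)
        scores.rename_axis("sample_id").to_frame().to_csv(
            out / "scores.tsv", sep="\t", float_format="%.10g")
        manifest["stages"]["score"] = {"n_scored": int(scores.size)}

        stage = "label"
        labels = label_response(clinical, config.drug)
        manifest["stages"]["label"] = {
            "n_benefit": int((labels == "benefit").sum()),
            "n_futile": int((labels == "futile").sum())}

        stage = "auc"
        cohorts = [Cohort(ct, "all", config.drug,
                          expression[list(sub["sample_id"])], sub)
                   for ct, sub in clinical.groupby("cancer_type")]
        cohorts += [Cohort(ct, st, config.drug,
                           expression[list(sub["sample_id"])], sub)
                    for (ct, st), sub in clinical.groupby(["cancer_type", "subtype"])]
        grid = evaluate_grid(cohorts, panel, min_samples=config.min_samples_for_auc)
        io.write_grid_tsv(grid, out / "auc_grid.tsv")
        manifest["stages"]["auc"] = {"n_cells": int(len(grid)),
                                     "n_na": int(grid["auc"].isna().sum())}

        stage = "table1"
        others = [t for t in clinical["treatment"].unique() if t != config.drug]
        if others:
            counterpart = clinical.loc[clinical["treatment"] != config.drug,
                                       "treatment"].mode().iloc[0]
            report = table1_report(clinical, groups=(config.drug, counterpart),
                                   horizons=config.horizons)
        else:
            report = _single_group_horizons(clinical, config.horizons)
        report.to_csv(out / "table1.tsv", sep="\t", index=False,
                      float_format="%.6g")
        manifest["stages"]["table1"] = {"n_rows": int(len(report))}

        if config.reference:
            stage = "deconvolve"
            reference = io.read_reference_tsv(config.reference)
            est = NNLSDeconvolver.from_reference(reference)
            props = est.predict_frame(expression.T)
            props.rename_axis("sample_id").to_csv(
                out / "proportions.tsv", sep="\t", float_format="%.10g")
            manifest["stages"]["deconvolve"] = {
                "n_types": int(reference.shape[1]),
                "n_samples": int(props.shape[0])}
    except ChemosigError as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: outputs in %s", out)
    return manifest
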