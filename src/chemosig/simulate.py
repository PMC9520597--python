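"""Synthetic cohorts with planted survival effects, and labeled single-cell
references with bulk mixtures of known composition.

The bulk generator emulates a drug-treated tumor cohort: log-scale normalized
expression for each gene is Gaussian around a gene-specific mean, and each
sample's death hazard is constant in time (exponential survival) with

    log h = log(baseline_hazard) + sum_g beta_g * I(expr_g > median_g),

where ``beta_g = +log(hazard_ratio)`` for planted Con genes (high expression
harmful), ``-log(hazard_ratio)`` for planted Pro genes (high expression
protective), and 0 for all other genes. Censoring is independent exponential.
Hazards act on the dichotomized (above/below median) expression, mirroring
the median classifier used downstream in screening.

The single-cell generator draws per-type mean profiles with distinct marker
blocks, samples cells with negative-binomial (gamma-Poisson) noise, attaches
per-cell QC metrics (feature count, mitochondrial fraction) of which a
configurable share violates the standard QC bounds, and mixes the type
profiles into bulk samples at known proportions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import anndata as ad
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

#: Lauren-subtype labels and their frequencies among treated gastric-cancer
#: samples (13 diffuse / 51 intestinal / 18 not specified).
SUBTYPE_LABELS = ("diffuse", "intestinal", "not specified")
SUBTYPE_PROBS = (13 / 82, 51 / 82, 18 / 82)

_MARKER_FOLD = 8.0  # expression fold-change of a marker gene in its own type


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Parameters
    ----------
    n_samples, n_genes : int
        Bulk cohort dimensions. The default 300 x 5,000 is a reduced
        protein-coding transcriptome at a realistic treated-cohort size.
    n_pro, n_con : int
        Numbers of planted protective / harmful genes.
    hazard_ratio : float
        Per-gene hazard ratio of the high- vs low-expression group (> 1);
        Pro genes use its reciprocal.
    baseline_hazard : float
        Death hazard per day with no planted effects. The default
        ``log(2)/500`` puts baseline median survival at 500 days.
    censoring_rate : float
        Independent exponential censoring hazard per day; the default yields
        roughly 30% censoring under the default planted effects.
    gene_mean_location, gene_mean_scale : float
        Normal law for per-gene mean log-expression.
    noise_sd : float
        Per-sample Gaussian sd around the gene mean (log scale).
    n_cell_types, cells_per_type : int
        Single-cell reference dimensions.
    nb_dispersion : float
        Negative-binomial dispersion of single-cell counts; variance is
        ``mu + mu^2 / nb_dispersion``, so large values approach Poisson.
    mito_fraction_range : (float, float)
        Support of simulated per-cell mitochondrial fractions.
    qc_violation_rate : float
        Share of cells drawn to violate the QC bounds (feature count outside
        200-2,500 or mitochondrial fraction at/above 15%).
    bulk_noise_fraction : float
        Gaussian noise sd on bulk mixtures, as a fraction of the mean
        reference signal; 0 gives exact mixtures.
    seed : int
        Fixes every draw of both generators.
    """

    n_samples: int = 300
    n_genes: int = 5000
    n_pro: int = 20
    n_con: int = 20
    hazard_ratio: float = 3.0
    baseline_hazard: float = math.log(2) / 500.0
    censoring_rate: float = 4e-4
    gene_mean_location: float = 3.0
    gene_mean_scale: float = 1.0
    noise_sd: float = 1.0
    n_cell_types: int = 5
    cells_per_type: int = 200
    nb_dispersion: float = 2.0
    mito_fraction_range: tuple[float, float] = (0.0, 0.30)
    qc_violation_rate: float = 0.2
    bulk_noise_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("n_samples", "n_genes", "n_cell_types", "cells_per_type"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("n_pro", "n_con"):
            if int(getattr(self, name)) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_pro + self.n_con > self.n_genes:
            raise ConfigurationError("n_pro + n_con may not exceed n_genes")
        if not self.hazard_ratio > 1:
            raise ConfigurationError("hazard_ratio must exceed 1")
        for name in ("baseline_hazard", "censoring_rate", "nb_dispersion"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.noise_sd < 0 or self.bulk_noise_fraction < 0:
            raise ConfigurationError("noise levels must be non-negative")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError("mito_fraction_range must be within [0, 1]")
        if not 0 <= self.qc_violation_rate <= 1:
            raise ConfigurationError("qc_violation_rate must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted by a generator run."""

    pro_genes: tuple[str, ...]
    con_genes: tuple[str, ...]
    beta: dict = field(default_factory=dict)  #: per-gene log hazard ratio
    true_proportions: np.ndarray | None = None  #: (n_mixtures, n_types) or None

    def __post_init__(self):
        if set(self.pro_genes) & set(self.con_genes):
            raise ValidationError("pro and con gene lists must be disjoint")
        if self.true_proportions is not None:
            p = np.asarray(self.true_proportions, dtype=float)
            if (p < 0).any() or np.abs(p.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValidationError("proportion vectors must lie on the simplex")

    def to_json(self, path) -> None:
        payload = {
            "pro_genes": list(self.pro_genes),
            "con_genes": list(self.con_genes),
            "beta": {g: float(b) for g, b in self.beta.items()},
        }
        if self.true_proportions is not None:
            payload["true_proportions"] = np.asarray(self.true_proportions).tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


class CohortSimulation(NamedTuple):
    expression: pd.DataFrame  #: genes x samples, log-scale values
    clinical: pd.DataFrame
    truth: SyntheticTruth


class ReferenceSimulation(NamedTuple):
    cells: ad.AnnData          #: cells x genes counts with QC metrics in .obs
    reference: pd.DataFrame    #: genes x types mean profiles (ground truth)
    bulk: pd.DataFrame         #: genes x mixtures
    truth: SyntheticTruth


def simulate_cohort(config: SimulationConfig,
                    treatment: str = "5-FU",
                    cancer_type: str = "STAD") -> CohortSimulation:
    """Draw a treated cohort with censored survival tied to planted genes.

    Returns log-scale expression (genes x samples), a clinical table and the
    planted truth. Identical config (including seed) reproduces the draw
    exactly.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_genes
    genes = np.array([f"G{i:05d}" for i in range(m)])
    samples = np.array([f"S{i:04d}" for i in range(n)])

    means = rng.normal(config.gene_mean_location, config.gene_mean_scale, size=m)
    X = means[:, None] + rng.normal(0.0, config.noise_sd, size=(m, n))

    planted = rng.choice(m, size=config.n_pro + config.n_con, replace=False)
    pro_idx, con_idx = planted[: config.n_pro], planted[config.n_pro:]
    beta = np.zeros(m)
    beta[pro_idx] = -math.log(config.hazard_ratio)
    beta[con_idx] = math.log(config.hazard_ratio)

    high = X > np.median(X, axis=1, keepdims=True)
    log_hazard = math.log(config.baseline_hazard) + beta @ high
    t_event = rng.exponential(np.exp(-log_hazard))
    t_censor = rng.exponential(1.0 / config.censoring_rate, size=n)
    observed = np.minimum(t_event, t_censor)
    event = t_event <= t_censor

    clinical = pd.DataFrame({
        "sample_id": samples,
        "time_days": observed,
        "event": event,
        "treatment": treatment,
        "cancer_type": cancer_type,
        "subtype": rng.choice(SUBTYPE_LABELS, size=n, p=SUBTYPE_PROBS),
    })
    expression = pd.DataFrame(X, index=genes, columns=samples)
    truth = SyntheticTruth(
        pro_genes=tuple(genes[np.sort(pro_idx)]),
        con_genes=tuple(genes[np.sort(con_idx)]),
        beta={genes[i]: float(beta[i]) for i in np.sort(planted)},
    )
    return CohortSimulation(expression, clinical, truth)


def _check_proportions(proportions, n_types: int) -> np.ndarray:
    p = np.atleast_2d(np.asarray(proportions, dtype=float))
    if p.shape[1] != n_types:
        raise ValidationError(
            f"proportion vectors have length {p.shape[1]}, expected {n_types}")
    if (p < 0).any() or np.abs(p.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValidationError("each proportion vector must be non-negative "
                              "and sum to 1 within 1e-9")
    return p


def simulate_reference_and_mixtures(config: SimulationConfig,
                                    proportions) -> ReferenceSimulation:
    """Draw a labeled single-cell reference and bulk mixtures of known makeup.

    Half of the genes are partitioned into per-type marker blocks elevated
    ``8x`` in their own type; cells carry gamma-Poisson count noise around
    their type profile plus simulated QC metrics. Bulk sample ``b`` equals
    ``sum_k p_bk * mu_k`` plus Gaussian noise with sd
    ``bulk_noise_fraction * mean(reference)``.
    """
    P = _check_proportions(proportions, config.n_cell_types)
    rng = np.random.default_rng(config.seed)
    m, k = config.n_genes, config.n_cell_types
    genes = np.array([f"G{i:05d}" for i in range(m)])
    types = np.array([f"T{j}" for j in range(k)])

    base = rng.lognormal(mean=1.0, sigma=0.5, size=m)
    profiles = np.tile(base[:, None], (1, k))
    block = max(1, (m // 2) // k)
    for j in range(k):
        profiles[j * block: (j + 1) * block, j] *= _MARKER_FOLD
    reference = pd.DataFrame(profiles, index=genes, columns=types)

    n_cells = k * config.cells_per_type
    labels = np.repeat(types, config.cells_per_type)
    mu = profiles[:, np.repeat(np.arange(k), config.cells_per_type)]  # m x cells
    lam = rng.gamma(shape=config.nb_dispersion, scale=mu / config.nb_dispersion)
    counts = rng.poisson(lam).astype(np.int32).T  # cells x genes

    violate = rng.random(n_cells) < config.qc_violation_rate
    lo, hi = config.mito_fraction_range
    features = rng.integers(200, 2501, size=n_cells)
    mito = rng.uniform(lo, min(hi, 0.1499), size=n_cells)
    mode = rng.integers(0, 3, size=n_cells)
    features = np.where(violate & (mode == 0), rng.integers(0, 200, size=n_cells), features)
    features = np.where(violate & (mode == 1), rng.integers(2501, 6000, size=n_cells), features)
    mito = np.where(violate & (mode == 2),
                    rng.uniform(0.15, max(hi, 0.2), size=n_cells), mito)

    obs = pd.DataFrame({
        "cell_type": labels,
        "n_features": features.astype(int),
        "mito_fraction": mito,
    }, index=[f"C{i:05d}" for i in range(n_cells)])
    cells = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=genes))

    clean = profiles @ P.T
    noise_sd = config.bulk_noise_fraction * float(profiles.mean())
    bulk_vals = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
    bulk = pd.DataFrame(bulk_vals, index=genes,
                        columns=[f"B{i:04d}" for i in range(P.shape[0])])
    truth = SyntheticTruth(pro_genes=(), con_genes=(), true_proportions=P)
    return ReferenceSimulation(cells, reference, bulk, truth)


def random_proportions(n_mixtures: int, n_types: int, rng=None,
                       concentration: float = 1.0) -> np.ndarray:
    """Dirichlet draws of mixture proportions (rows on the simplex)."""
    rng = np.random.default_rng(rng)
    return rng.dirichlet(np.full(n_types, concentration), size=n_mixtures)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["mito_fraction_range"] = list(d["mito_fraction_range"])
    return d
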