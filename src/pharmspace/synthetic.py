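"""Seeded generators for every input the pipeline consumes.

These emulate (at desk scale) the two data worlds the method lives in:
a cell-line training panel in which drug response and expression share a
low-dimensional latent structure, and heterogeneous "patients" made of
transcriptomically distinct clones.  Ground truth is returned alongside
each dataset so recovery can be measured exactly.  All generators are
pure functions of their arguments plus a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import (CellClusterTable, ClonalComposition, ExpressionMatrix,
                         ResponsePanel, ValidationError)
from .dose_response import DoseResponseCurve, MixtureCurve


@dataclass
class SyntheticPanelTruth:
    """Ground truth behind a generated training panel."""

    sample_factors: np.ndarray   # n_lines x f_true latent positions P
    gene_loadings: np.ndarray    # f_true x n_genes emission loadings
    Q: np.ndarray                # n_drugs x f_true
    b_Q: np.ndarray
    s_true: np.ndarray           # noiseless drugs x lines sensitivity
    sigma_response: float
    seed: int


def generate_panel(
    n_lines: int = 60,
    n_drugs: int = 8,
    n_genes: int = 500,
    f_true: int = 5,
    sigma_response: float = 0.3,
    missing_rate: float = 0.1,
    seed: int = 0,
    sigma_expression: float = 0.1,
    max_dose_quantile: float = 0.5,
):
    """A latent-factor cell-line panel with known ground truth.

    Each cell line sits at a latent position p_u; expression is emitted
    through a shared gene-loading matrix (plus a per-gene baseline and
    noise) so that expression similarity reflects latent proximity — the
    premise that makes correlation-kernel features informative.  True
    sensitivity is s = b_Q + Q P^T; the observed panel adds Gaussian
    noise and masks entries at ``missing_rate``.  The per-drug maximum
    dose sits at a quantile of the true scores so both response classes
    are populated.

    Returns (ExpressionMatrix log_normalized, ResponsePanel, SyntheticPanelTruth).
    """
    if f_true > min(n_lines, n_drugs):
        raise ValidationError("f_true must not exceed min(n_lines, n_drugs)")
    if not (0 <= missing_rate < 1):
        raise ValidationError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        P = rng.normal(size=(n_lines, f_true))
        G = rng.normal(size=(f_true, n_genes)) / np.sqrt(f_true)
        baseline = rng.normal(5.0, 1.0, size=n_genes)
        expr_vals = baseline[None, :] + P @ G \
            + sigma_expression * rng.normal(size=(n_lines, n_genes))
        Q = rng.normal(size=(n_drugs, f_true))
        b_Q = rng.normal(size=n_drugs)
        s_true = b_Q[:, None] + Q @ P.T
        s_obs = s_true + sigma_response * rng.normal(size=s_true.shape)
        observed = rng.random(s_true.shape) >= missing_rate
        o = np.quantile(s_true, max_dose_quantile, axis=1)
        sens = (s_obs > o[:, None]) & observed
        insens = (s_obs <= o[:, None]) & observed
        if np.all(sens.any(axis=1) & insens.any(axis=1)):
            break
        warnings.warn("a drug came out single-class; regenerating")
    else:
        raise ValidationError("could not generate a two-class panel; adjust parameters")

    gene_ids = [f"G{k:04d}" for k in range(n_genes)]
    line_ids = [f"CL{u:03d}" for u in range(n_lines)]
    drug_ids = [f"D{i:02d}" for i in range(n_drugs)]
    expr = ExpressionMatrix(gene_ids, line_ids, expr_vals.T, "log_normalized")
    panel = ResponsePanel(drug_ids, line_ids, np.where(observed, s_obs, np.nan),
                          observed, o)
    truth = SyntheticPanelTruth(P, G, Q, b_Q, s_true, sigma_response, seed)
    return expr, panel, truth


def generate_heterogeneous_patient(
    n_clusters: int = 3,
    cells_per_cluster: int = 50,
    base_profiles: np.ndarray | None = None,
    noise: float = 0.1,
    dropout_rate: float = 0.0,
    n_genes: int = 200,
    seed: int = 0,
    patient_id: str = "P1",
):
    """A patient as a mixture of transcriptomic clones (TPM-scale cells).

    Every cell is its cluster's base profile plus non-negative-clipped
    Gaussian noise, with optional dropout zeroing.  Returns the cell
    matrix, the cluster-assignment table and the ground-truth clonal
    composition (base profiles as cluster means).
    """
    if n_clusters < 1:
        raise ValidationError("need at least one cluster")
    rng = np.random.default_rng(seed)
    if base_profiles is None:
        base_profiles = rng.lognormal(mean=2.0, sigma=1.0, size=(n_clusters, n_genes))
    else:
        base_profiles = np.asarray(base_profiles, dtype=float)
        n_clusters, n_genes = base_profiles.shape
    if cells_per_cluster is None or np.isscalar(cells_per_cluster):
        counts = [int(cells_per_cluster)] * n_clusters
    else:
        counts = [int(c) for c in cells_per_cluster]
    cell_vals, cell_ids, cluster_ids = [], [], []
    for j in range(n_clusters):
        cells = base_profiles[j][None, :] + noise * rng.normal(size=(counts[j], n_genes))
        cells = np.clip(cells, 0.0, None)
        if dropout_rate > 0:
            cells = np.where(rng.random(cells.shape) < dropout_rate, 0.0, cells)
        for k in range(counts[j]):
            cell_ids.append(f"{patient_id}_c{j}_{k:03d}")
            cluster_ids.append(f"K{j}")
        cell_vals.append(cells)
    values = np.vstack(cell_vals).T  # genes x cells
    gene_ids = [f"G{k:04d}" for k in range(n_genes)]
    expr = ExpressionMatrix(gene_ids, cell_ids, values, "tpm")
    table = CellClusterTable(cell_ids, cluster_ids, [patient_id] * len(cell_ids))
    total = sum(counts)
    truth = ClonalComposition(
        patient_id, gene_ids,
        [(f"K{j}", counts[j] / total, base_profiles[j]) for j in range(n_clusters)],
    )
    return expr, table, truth


def generate_mixture_curves(k: int, seed: int = 0) -> MixtureCurve:
    """Random clone mixture: Dirichlet weights, m ~ U[-6, 6], b ~ U[0.5, 3]."""
    if k < 1:
        raise ValidationError("need at least one component")
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(k))
    m = rng.uniform(-6.0, 6.0, size=k)
    b = rng.uniform(0.5, 3.0, size=k)
    return MixtureCurve([(w[i], DoseResponseCurve(m[i], b[i])) for i in range(k)])
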