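"""Kernel featurization: expression profiles -> correlation features x_u.

A query sample is represented by its Pearson correlation, over a panel of
essential genes, between its log-expression fold-change (relative to the
*frozen* training-cohort mean) and each training cell line's fold-change.
Correlation against a fixed reference makes the feature vector of a single
unseen sample well-defined and independent of whatever batch it arrives in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import ExpressionMatrix, ValidationError


@dataclass
class ReferenceBasis:
    """Frozen training-side state needed to featurize any future query."""

    gene_ids: list
    reference_mean: np.ndarray            # per-gene mean log expression over training lines
    essential_gene_ids: list              # realized intersection with the training matrix
    reference_sample_ids: list
    reference_fold_change: np.ndarray     # essential genes x reference cell lines

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.essential_gene_ids = [str(g) for g in self.essential_gene_ids]
        self.reference_sample_ids = [str(s) for s in self.reference_sample_ids]
        self.reference_mean = np.asarray(self.reference_mean, dtype=float)
        self.reference_fold_change = np.asarray(self.reference_fold_change, dtype=float)
        if not set(self.essential_gene_ids) <= set(self.gene_ids):
            raise ValidationError("essential genes must be a subset of basis genes")
        if self.reference_fold_change.shape != (
            len(self.essential_gene_ids), len(self.reference_sample_ids)
        ):
            raise ValidationError("reference_fold_change shape mismatch")
        if np.any(self.reference_fold_change.std(axis=0) == 0):
            raise ValidationError("reference fold-change has a constant column "
                                  "(correlation undefined)")

    @property
    def n_reference(self) -> int:
        return len(self.reference_sample_ids)


@dataclass
class KernelMatrix:
    """Query x reference Pearson-correlation features (entries in [-1, 1])."""

    query_sample_ids: list
    reference_sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.query_sample_ids), len(self.reference_sample_ids)):
            raise ValidationError("kernel shape mismatch")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValidationError("kernel entries must lie in [-1, 1]")


def fit_reference_basis(train_expr: ExpressionMatrix, essential_genes) -> ReferenceBasis:
    """Freeze per-gene reference means and essential-gene fold-changes.

    Fold-change of each gene is its log expression minus the gene's mean
    across the training cell lines; only essential genes actually present
    in the matrix enter the correlation panel (a warning is raised when
    coverage drops below half the requested list).
    """
    if train_expr.scale != "log_normalized":
        raise ValidationError("reference basis expects log-scale expression")
    if train_expr.n_samples < 2:
        raise ValidationError("need at least 2 training samples to define fold-changes")
    essential_genes = [str(g) for g in essential_genes]
    present = [g for g in essential_genes if g in set(train_expr.gene_ids)]
    if len(present) < 2:
        raise ValidationError("fewer than 2 essential genes present in the training matrix")
    if len(present) < 0.5 * len(essential_genes):
        warnings.warn(
            f"only {len(present)}/{len(essential_genes)} essential genes present "
            "in the training matrix"
        )
    elif len(present) < len(essential_genes):
        warnings.warn(
            f"{len(essential_genes) - len(present)} essential genes absent from the "
            "training matrix were dropped"
        )
    ref_mean = train_expr.values.mean(axis=1)
    sub = train_expr.select_genes(present)
    fc = sub.values - ref_mean[[train_expr.gene_ids.index(g) for g in present]][:, None]
    return ReferenceBasis(train_expr.gene_ids, ref_mean, present,
                          train_expr.sample_ids, fc)


def fold_change(expr: ExpressionMatrix, basis: ReferenceBasis) -> ExpressionMatrix:
    """Per-gene log fold-change of ``expr`` against the frozen reference mean."""
    if expr.scale != "log_normalized":
        raise ValidationError("fold_change expects log-scale expression")
    shared = [g for g in expr.gene_ids if g in set(basis.gene_ids)]
    if not shared:
        raise ValidationError("no genes shared with the reference basis")
    pos = {g: i for i, g in enumerate(basis.gene_ids)}
    sub = expr.select_genes(shared)
    fc = sub.values - basis.reference_mean[[pos[g] for g in shared]][:, None]
    return ExpressionMatrix(shared, expr.sample_ids, fc, "log2_fold_change")


def compute_kernel(query_expr: ExpressionMatrix, basis: ReferenceBasis) -> KernelMatrix:
    """Pearson-correlation features of queries against the reference lines.

    Correlations are taken over the essential genes shared by the query
    matrix and the basis; a constant query fold-change vector has no
    defined correlation and raises, naming the offending sample.
    """
    if query_expr.scale != "log_normalized":
        raise ValidationError("compute_kernel expects log-scale expression")
    qset = set(query_expr.gene_ids)
    shared = [g for g in basis.essential_gene_ids if g in qset]
    if len(shared) < 2:
        raise ValidationError("query shares fewer than 2 essential genes with the basis")
    if len(shared) < 0.5 * len(basis.essential_gene_ids):
        warnings.warn(
            f"query covers only {len(shared)}/{len(basis.essential_gene_ids)} "
            "essential genes"
        )
    gpos = {g: i for i, g in enumerate(basis.gene_ids)}
    epos = {g: i for i, g in enumerate(basis.essential_gene_ids)}
    q = query_expr.select_genes(shared).values \
        - basis.reference_mean[[gpos[g] for g in shared]][:, None]
    r = basis.reference_fold_change[[epos[g] for g in shared], :]

    qc = q - q.mean(axis=0)
    rc = r - r.mean(axis=0)
    qn = np.linalg.norm(qc, axis=0)
    rn = np.linalg.norm(rc, axis=0)
    flat = np.flatnonzero(qn == 0)
    if flat.size:
        raise ValidationError(
            f"constant fold-change vector for sample {query_expr.sample_ids[flat[0]]!r}: "
            "correlation undefined"
        )
    if np.any(rn == 0):
        raise ValidationError("constant reference fold-change column: correlation undefined")
    corr = (qc / qn).T @ (rc / rn)
    np.clip(corr, -1.0, 1.0, out=corr)
    return KernelMatrix(list(query_expr.sample_ids), list(basis.reference_sample_ids), corr)
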