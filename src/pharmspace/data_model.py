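"""Domain containers and readers for expression, response and clustering data.

Conventions used throughout the package:

* expression matrices are genes x samples, with a ``scale`` tag recording
  the unit (``tpm``, ``log_normalized`` or ``log2_fold_change``);
* drug sensitivity is carried as s = -log2(IC50 in uM), so larger s means
  a more sensitive sample; the per-drug maximum tested dosage is stored on
  the same scale as o = -log2(max dose uM);
* all dosages are in micromolar at ingest and log2-uM internally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("pharmspace")

EXPRESSION_SCALES = ("tpm", "log_normalized", "log2_fold_change")


class ValidationError(ValueError):
    """An input violated a structural invariant."""


class ParseError(ValueError):
    """A file could not be interpreted as the expected table."""


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with named axes and a scale tag."""

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    scale: str

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in EXPRESSION_SCALES:
            raise ValidationError(f"unknown expression scale {self.scale!r}")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.scale == "tpm" and np.any(self.values < 0):
            raise ValidationError("tpm-scale expression must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: str) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), scale)

    def select_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, list(sample_ids), self.values[:, idx], self.scale)

    def select_genes(self, gene_ids) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.sample_ids, self.values[idx, :], self.scale)

    def log2p1(self) -> "ExpressionMatrix":
        """log2(TPM + 1) transform, the conventional bridge to log scale."""
        if self.scale != "tpm":
            raise ValidationError("log2p1 expects a tpm-scale matrix")
        return ExpressionMatrix(
            self.gene_ids, self.sample_ids, np.log2(self.values + 1.0), "log_normalized"
        )


@dataclass
class ResponsePanel:
    """Drug x sample sensitivity scores with an observation mask.

    ``s[i, u] = -log2(IC50 uM)`` where observed; unobserved entries are
    ignored by every downstream computation.  ``max_dose_log2[i]`` is the
    per-drug o_i = -log2(max tested dose uM) separating sensitive (s > o)
    from insensitive samples.
    """

    drug_ids: list
    sample_ids: list
    s: np.ndarray
    observed: np.ndarray
    max_dose_log2: np.ndarray

    def __post_init__(self):
        self.drug_ids = [str(d) for d in self.drug_ids]
        self.sample_ids = [str(u) for u in self.sample_ids]
        self.s = np.asarray(self.s, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        self.max_dose_log2 = np.asarray(self.max_dose_log2, dtype=float)
        _check_unique(self.drug_ids, "drug ids")
        _check_unique(self.sample_ids, "sample ids")
        shape = (len(self.drug_ids), len(self.sample_ids))
        if self.s.shape != shape or self.observed.shape != shape:
            raise ValidationError("response matrix shape mismatch")
        if self.max_dose_log2.shape != (len(self.drug_ids),):
            raise ValidationError("max_dose_log2 must have one entry per drug")
        if not np.all(np.isfinite(self.max_dose_log2)):
            raise ValidationError("max_dose_log2 must be finite for every drug")
        if np.any(~np.isfinite(self.s[self.observed])):
            raise ValidationError("observed sensitivity scores must be finite")

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def select_samples(self, sample_ids) -> "ResponsePanel":
        idx = [self.sample_ids.index(u) for u in sample_ids]
        return ResponsePanel(
            self.drug_ids, list(sample_ids), self.s[:, idx], self.observed[:, idx],
            self.max_dose_log2,
        )

    def select_drugs(self, drug_ids) -> "ResponsePanel":
        pos = {d: i for i, d in enumerate(self.drug_ids)}
        idx = [pos[d] for d in drug_ids]
        return ResponsePanel(
            list(drug_ids), self.sample_ids, self.s[idx, :], self.observed[idx, :],
            self.max_dose_log2[idx],
        )


@dataclass
class CellClusterTable:
    """Per-cell cluster and patient assignments (clustering is an input)."""

    cell_ids: list
    cluster_ids: list
    patient_ids: list

    def __post_init__(self):
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.cluster_ids = [str(c) for c in self.cluster_ids]
        self.patient_ids = [str(p) for p in self.patient_ids]
        if not (len(self.cell_ids) == len(self.cluster_ids) == len(self.patient_ids)):
            raise ValidationError("cell/cluster/patient columns must have equal length")
        _check_unique(self.cell_ids, "cell ids")
        if any(c == "" for c in self.cluster_ids):
            raise ValidationError("cluster labels must be non-empty strings")

    def cells_of_patient(self, patient_id) -> list:
        patient_id = str(patient_id)
        return [c for c, p in zip(self.cell_ids, self.patient_ids) if p == patient_id]

    def cluster_of(self, cell_id) -> str:
        return self.cluster_ids[self.cell_ids.index(str(cell_id))]

    @property
    def patients(self) -> list:
        return sorted(set(self.patient_ids))


@dataclass
class ClonalComposition:
    """A patient's cell clusters: (cluster id, cell fraction, mean TPM profile)."""

    patient_id: str
    gene_ids: list
    clusters: list  # list of (cluster_id: str, fraction: float, mean_profile: np.ndarray)

    def __post_init__(self):
        self.patient_id = str(self.patient_id)
        self.gene_ids = [str(g) for g in self.gene_ids]
        clean = []
        for cid, w, prof in self.clusters:
            prof = np.asarray(prof, dtype=float)
            if prof.shape != (len(self.gene_ids),):
                raise ValidationError("cluster mean_profile length mismatch with gene axis")
            if not (0.0 < w <= 1.0):
                raise ValidationError(f"cluster fraction {w} outside (0, 1]")
            clean.append((str(cid), float(w), prof))
        self.clusters = clean
        total = sum(w for _, w, _ in self.clusters)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"cluster fractions sum to {total}, expected 1")

    @property
    def cluster_ids(self) -> list:
        return [cid for cid, _, _ in self.clusters]

    @property
    def fractions(self) -> np.ndarray:
        return np.array([w for _, w, _ in self.clusters])

    @property
    def profiles(self) -> np.ndarray:
        """Genes x clusters matrix of mean profiles."""
        return np.column_stack([prof for _, _, prof in self.clusters])

    def pseudo_bulk(self) -> np.ndarray:
        """Fraction-weighted mean of cluster profiles == mean over all cells."""
        return self.profiles @ self.fractions


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. BioCarta pathways) for activity scoring."""

    set_names: list
    members: dict = field(default_factory=dict)

    def __post_init__(self):
        self.set_names = [str(n) for n in self.set_names]
        _check_unique(self.set_names, "gene-set names")
        for name in self.set_names:
            genes = [str(g) for g in self.members[name]]
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            _check_unique(genes, f"members of set {name!r}")
            self.members[name] = genes


# ---------------------------------------------------------------------------
# Readers / writers


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_expression_matrix(path, scale: str) -> ExpressionMatrix:
    """Read a genes x samples delimited table (first column = gene id).

    Duplicate gene rows are collapsed by their mean with a warning, a
    behaviour chosen because public matrices routinely carry duplicated
    symbols.
    """
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty expression table") from exc
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: cannot parse expression table: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: expression table has no sample columns")
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        bad = [c for c, t in df.dtypes.items() if not np.issubdtype(t, np.number)]
        raise ParseError(f"{path}: non-numeric sample columns {bad}")
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        warnings.warn(f"{path}: {n_dup} duplicated gene rows collapsed by mean")
        df = df.groupby(level=0, sort=False).mean()
    df.index = df.index.map(str)
    return ExpressionMatrix.from_frame(df, scale)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_response_panel(path, max_dose_table, ic50_units: str = "uM") -> ResponsePanel:
    """Read a long-format IC50 table plus a per-drug maximum-dose table.

    The IC50 table has columns (drug_id, sample_id, ic50_uM); unobserved
    drug-sample pairs are simply absent.  Scores are s = -log2(IC50 uM);
    thresholds are o = -log2(max dose uM).
    """
    if ic50_units != "uM":
        raise ValidationError(f"unsupported IC50 units {ic50_units!r}; use uM")
    try:
        long = pd.read_csv(path, sep=_sep_for(path))
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty response table") from exc
    needed = {"drug_id", "sample_id", "ic50_uM"}
    if not needed.issubset(long.columns):
        raise ParseError(f"{path}: expected columns {sorted(needed)}, got {list(long.columns)}")
    if np.any(long["ic50_uM"].to_numpy(dtype=float) <= 0):
        raise ValidationError(f"{path}: IC50 values must be positive")
    doses = pd.read_csv(max_dose_table, sep=_sep_for(max_dose_table))
    if not {"drug_id", "max_dose_uM"}.issubset(doses.columns):
        raise ParseError(f"{max_dose_table}: expected columns drug_id, max_dose_uM")
    dose_map = dict(zip(doses["drug_id"].astype(str), doses["max_dose_uM"].astype(float)))

    long["drug_id"] = long["drug_id"].astype(str)
    long["sample_id"] = long["sample_id"].astype(str)
    drug_ids = sorted(long["drug_id"].unique())
    sample_ids = sorted(long["sample_id"].unique())
    missing = [d for d in drug_ids if d not in dose_map]
    if missing:
        raise ValidationError(f"drugs missing from max-dose table: {missing}")

    wide = long.pivot_table(index="drug_id", columns="sample_id", values="ic50_uM",
                            aggfunc="mean")
    wide = wide.reindex(index=drug_ids, columns=sample_ids)
    ic50 = wide.to_numpy(dtype=float)
    observed = np.isfinite(ic50)
    s = np.where(observed, -np.log2(np.where(observed, ic50, 1.0)), np.nan)
    o = -np.log2(np.array([dose_map[d] for d in drug_ids]))
    return ResponsePanel(drug_ids, sample_ids, s, observed, o)


def read_cluster_table(path) -> CellClusterTable:
    df = pd.read_csv(path, sep=_sep_for(path))
    needed = {"cell_id", "patient_id", "cluster_id"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(needed)}")
    return CellClusterTable(
        list(df["cell_id"].astype(str)),
        list(df["cluster_id"].astype(str)),
        list(df["patient_id"].astype(str)),
    )


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, members...)."""
    names, members = [], {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            names.append(parts[0])
            members[parts[0]] = [g for g in parts[2:] if g]
    if not names:
        raise ParseError(f"{path}: no gene sets found")
    return GeneSetCollection(names, members)


# ---------------------------------------------------------------------------
# Single-cell QC and summarisation


def qc_filter_cells(
    expr: ExpressionMatrix,
    read_counts,
    mito_fraction,
    min_reads: float = 10_000,
    max_mito: float = 0.25,
    max_genes: int | None = None,
) -> ExpressionMatrix:
    """Remove poor-quality cells.

    A cell is removed when its total read count is strictly below
    ``min_reads``, or its mitochondrial read fraction is at or above
    ``max_mito`` (a high fraction indicates a damaged cell).  ``max_genes``
    optionally removes suspected doublets with more expressed genes than
    the threshold; it has no default.
    """
    reads = pd.Series(read_counts)
    mito = pd.Series(mito_fraction)
    missing = [c for c in expr.sample_ids if c not in reads.index or c not in mito.index]
    if missing:
        raise ValidationError(f"cells missing QC metrics: {missing[:5]}")
    keep, removed = [], []
    n_expressed = (expr.values > 0).sum(axis=0)
    for j, cell in enumerate(expr.sample_ids):
        bad = reads[cell] < min_reads or mito[cell] >= max_mito
        if max_genes is not None and n_expressed[j] > max_genes:
            bad = True
        (removed if bad else keep).append(cell)
    if removed:
        logger.info("qc_filter_cells removed %d cells: %s", len(removed), removed)
    return expr.select_samples(keep)


def qc_filter_genes(expr: ExpressionMatrix, min_cell_fraction: float = 0.05) -> ExpressionMatrix:
    """Keep genes expressed (value > 0) in at least ``min_cell_fraction`` of cells."""
    if expr.n_samples < 1:
        raise ValidationError("gene filter needs at least one cell")
    frac = (expr.values > 0).mean(axis=1)
    keep = [g for g, f in zip(expr.gene_ids, frac) if f >= min_cell_fraction]
    return expr.select_genes(keep)


def build_clonal_composition(
    expr: ExpressionMatrix, clusters: CellClusterTable, patient_id
) -> ClonalComposition:
    """Summarise a patient's cells into per-cluster fractions and mean TPM profiles."""
    cells = clusters.cells_of_patient(patient_id)
    if not cells:
        raise ValidationError(f"patient {patient_id!r} has no cells")
    missing = [c for c in cells if c not in expr.sample_ids]
    if missing:
        raise ValidationError(f"cells of patient {patient_id!r} absent from matrix: {missing[:5]}")
    sub = expr.select_samples(cells)
    labels = [clusters.cluster_of(c) for c in cells]
    out = []
    for cid in sorted(set(labels)):
        idx = [j for j, lab in enumerate(labels) if lab == cid]
        w = len(idx) / len(cells)
        mean_profile = sub.values[:, idx].mean(axis=1)
        out.append((cid, w, mean_profile))
    return ClonalComposition(str(patient_id), expr.gene_ids, out)


def pseudo_bulk(expr: ExpressionMatrix, cell_ids=None) -> np.ndarray:
    """Per-gene mean over cells — the bulk proxy for a patient profile."""
    sub = expr if cell_ids is None else expr.select_samples(cell_ids)
    if sub.n_samples < 1:
        raise ValidationError("pseudo_bulk needs at least one cell")
    return sub.values.mean(axis=1)
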