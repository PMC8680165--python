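"""Intra-tumor transcriptomic heterogeneity (ITTH) scores.

ITTH of a tumor is the Shannon entropy (natural log) of its cell-type or
cell-cluster composition, after excluding types below a 5% frequency
floor (classification noise) and renormalizing the survivors.  Samples
are classed low / medium / high by the first and third quartiles of the
cohort's scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CellClusterTable, ValidationError


@dataclass
class CompositionVector:
    """Cell-type (or cluster) fractions of one sample; sums to 1."""

    labels: list
    fractions: np.ndarray

    def __post_init__(self):
        self.labels = [str(x) for x in self.labels]
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(self.labels),):
            raise ValidationError("composition labels/fractions length mismatch")
        if np.any(self.fractions < 0):
            raise ValidationError("composition fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValidationError(f"fractions sum to {self.fractions.sum()}, expected 1")


def itth_score(comp: CompositionVector, min_fraction: float = 0.05) -> float:
    """Entropy (nats) of the composition after the frequency filter.

    Entries with fraction < ``min_fraction`` are dropped and the survivors
    renormalized so the entropy is that of a proper distribution over the
    dominant types; a single surviving type scores exactly 0.
    """
    keep = comp.fractions[comp.fractions >= min_fraction]
    if keep.size == 0:
        raise ValidationError("all composition entries fall below the frequency floor")
    p = keep / keep.sum()
    if p.size == 1:
        return 0.0
    return float(-(p * np.log(p)).sum())


def sc_itth_score(clusters: CellClusterTable, patient_id,
                  min_fraction: float = 0.05) -> float:
    """ITTH from single-cell cluster assignments (fractions by counting)."""
    cells = clusters.cells_of_patient(patient_id)
    if not cells:
        raise ValidationError(f"patient {patient_id!r} has no cells")
    labels = [clusters.cluster_of(c) for c in cells]
    uniq = sorted(set(labels))
    counts = np.array([labels.count(u) for u in uniq], dtype=float)
    return itth_score(CompositionVector(uniq, counts / counts.sum()), min_fraction)


def itth_tertiles(scores) -> np.ndarray:
    """Class labels from cohort quartiles: low < Q1, high > Q3, else medium.

    Quartiles use linear interpolation; a score exactly equal to a
    quartile is classed medium (deterministic tie rule).
    """
    arr = np.asarray(list(scores.values()) if isinstance(scores, dict) else scores,
                     dtype=float)
    if arr.size < 4:
        raise ValidationError("quartile classification needs at least 4 samples")
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    labels = np.where(arr < q1, "low", np.where(arr > q3, "high", "medium"))
    if isinstance(scores, dict):
        return dict(zip(scores.keys(), labels))
    return labels


def read_fraction_table(path) -> dict:
    """Sample x cell-type proportion CSV -> {sample_id: CompositionVector}."""
    df = pd.read_csv(path, index_col=0)
    out = {}
    for sample, row in df.iterrows():
        vals = row.to_numpy(dtype=float)
        out[str(sample)] = CompositionVector(list(df.columns), vals)
    return out
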