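"""Patient-level monotherapy and combination-therapy predictions.

The pharmacogenomic model yields a sensitivity score s_hat (hence an IC50
of 2^{-s_hat} uM) for any transcriptomic profile — a single cell, a
cluster mean or a patient pseudo-bulk.  At a stated dosage each unit's
cell-death fraction follows its sigmoid curve (slope 1 by default), and
patient response is the cell average, the cluster-fraction-weighted
average, or the pseudo-bulk profile's own death fraction, depending on
the aggregation level.

Two drugs combined are modelled as acting independently: within a clone
the combined kill is h_i + h_j - h_i h_j (the product being the cells hit
by both).  A combination's utility is its improvement in patient-level
kill over the better of its two monotherapies; under independent action
this improvement is never negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (CellClusterTable, ClonalComposition, ExpressionMatrix,
                         ValidationError)
from .dose_response import DoseResponseCurve, cell_death_fraction
from .model import PharmacogenomicModel, predict_scores_from_expression

LEVELS = ("cell", "cluster", "patient")


@dataclass
class MonotherapyPrediction:
    patient_id: str
    drug_id: str
    dose_log2: float
    cluster_ids: list
    cluster_death: np.ndarray
    patient_death: float

    def __post_init__(self):
        self.cluster_death = np.asarray(self.cluster_death, dtype=float)
        if np.any((self.cluster_death < 0) | (self.cluster_death > 1)):
            raise ValidationError("death fractions must lie in [0, 1]")
        if not (0.0 <= self.patient_death <= 1.0):
            raise ValidationError("patient death fraction must lie in [0, 1]")


@dataclass
class CombinationPrediction:
    patient_id: str
    drug_i: str
    drug_j: str
    dose_i_log2: float
    dose_j_log2: float
    cluster_ids: list
    cluster_combo_death: np.ndarray
    patient_combo_death: float
    patient_mono_i: float
    patient_mono_j: float

    @property
    def improvement(self) -> float:
        return self.patient_combo_death - max(self.patient_mono_i, self.patient_mono_j)


def _drug_index(model: PharmacogenomicModel, drug_id) -> int:
    try:
        return model.drug_ids.index(str(drug_id))
    except ValueError:
        raise ValidationError(f"unknown drug {drug_id!r}") from None


def _death_from_profiles(model, profiles: ExpressionMatrix, drug_idx: int,
                         dose_log2: float, slope: float,
                         log_transform: bool) -> np.ndarray:
    """Per-profile kill fraction: TPM -> log2(TPM+1) -> kernel -> s_hat -> curve."""
    if log_transform and profiles.scale == "tpm":
        expr = profiles.log2p1()
    elif profiles.scale == "tpm":
        # caller vouches the values are already log-like; relabel for the kernel
        expr = ExpressionMatrix(profiles.gene_ids, profiles.sample_ids,
                                profiles.values, "log_normalized")
    else:
        expr = profiles
    s_hat = predict_scores_from_expression(model, expr)[drug_idx]
    return np.array([
        cell_death_fraction(DoseResponseCurve(m=-s, b=slope), dose_log2) for s in s_hat
    ])


def predict_patient_response(
    model: PharmacogenomicModel,
    composition: ClonalComposition,
    drug_id,
    dose_log2: float,
    level: str = "cluster",
    cells: ExpressionMatrix | None = None,
    cluster_table: CellClusterTable | None = None,
    slope: float = 1.0,
    log_transform: bool = True,
) -> MonotherapyPrediction:
    """Kill fraction for one patient and drug at a dosage (log2 uM).

    ``level`` picks the profile granularity: per-cell predictions averaged
    (requires ``cells`` and ``cluster_table``), per-cluster predictions
    weighted by cell fractions, or a single pseudo-bulk profile.
    """
    if level not in LEVELS:
        raise ValidationError(f"level must be one of {LEVELS}")
    if not np.isfinite(dose_log2):
        raise ValidationError("dose must be finite")
    idx = _drug_index(model, drug_id)
    w = composition.fractions
    cluster_ids = composition.cluster_ids

    if level == "cluster":
        profiles = ExpressionMatrix(composition.gene_ids, cluster_ids,
                                    composition.profiles, "tpm")
        h = _death_from_profiles(model, profiles, idx, dose_log2, slope, log_transform)
        patient = float(np.dot(w, h))
    elif level == "cell":
        if cells is None or cluster_table is None:
            raise ValidationError("cell-level prediction needs cells and cluster_table")
        cell_ids = cluster_table.cells_of_patient(composition.patient_id)
        sub = cells.select_samples(cell_ids)
        per_cell = _death_from_profiles(model, sub, idx, dose_log2, slope, log_transform)
        labels = [cluster_table.cluster_of(c) for c in cell_ids]
        h = np.array([
            per_cell[[j for j, lab in enumerate(labels) if lab == cid]].mean()
            for cid in cluster_ids
        ])
        patient = float(per_cell.mean())
    else:  # patient level: pseudo-bulk profile
        bulk = ExpressionMatrix(composition.gene_ids, [composition.patient_id],
                                composition.pseudo_bulk()[:, None], "tpm")
        hb = _death_from_profiles(model, bulk, idx, dose_log2, slope, log_transform)
        h = np.full(len(cluster_ids), hb[0])
        patient = float(hb[0])

    return MonotherapyPrediction(composition.patient_id, str(drug_id),
                                 float(dose_log2), cluster_ids, h, patient)


def combine_independent(h_i, h_j):
    """Independent-action combined kill: h_i + h_j - h_i h_j."""
    h_i = np.asarray(h_i, dtype=float)
    h_j = np.asarray(h_j, dtype=float)
    if np.any((h_i < 0) | (h_i > 1)) or np.any((h_j < 0) | (h_j > 1)):
        raise ValidationError("kill fractions must lie in [0, 1]")
    out = h_i + h_j - h_i * h_j
    return float(out) if out.ndim == 0 else out


def predict_combination(
    model: PharmacogenomicModel,
    composition: ClonalComposition,
    drug_i, dose_i_log2: float,
    drug_j, dose_j_log2: float,
    slope: float = 1.0,
    log_transform: bool = True,
) -> CombinationPrediction:
    """Independent-action combination response at cluster resolution."""
    if str(drug_i) == str(drug_j):
        warnings.warn(f"combining drug {drug_i!r} with itself; "
                      "combined kill is 1 - (1 - h)^2 per cluster")
    mono_i = predict_patient_response(model, composition, drug_i, dose_i_log2,
                                      level="cluster", slope=slope,
                                      log_transform=log_transform)
    mono_j = predict_patient_response(model, composition, drug_j, dose_j_log2,
                                      level="cluster", slope=slope,
                                      log_transform=log_transform)
    combo = combine_independent(mono_i.cluster_death, mono_j.cluster_death)
    patient = float(np.dot(composition.fractions, combo))
    return CombinationPrediction(
        composition.patient_id, str(drug_i), str(drug_j),
        float(dose_i_log2), float(dose_j_log2),
        mono_i.cluster_ids, np.atleast_1d(combo), patient,
        mono_i.patient_death, mono_j.patient_death,
    )


def rank_combinations(model, compositions, pairs, doses,
                      slope: float = 1.0, log_transform: bool = True) -> pd.DataFrame:
    """Rank candidate drug pairs by improvement over best monotherapy.

    ``compositions`` is an iterable of ClonalComposition (one per patient),
    ``pairs`` a list of (drug_i, drug_j), ``doses`` a mapping drug ->
    dose (log2 uM).  Rows sorted by improvement descending; ties broken
    by lexicographic pair, then patient.
    """
    if not pairs:
        raise ValidationError("no candidate drug pairs supplied")
    rows = []
    for comp in compositions:
        for di, dj in pairs:
            pred = predict_combination(model, comp, di, doses[str(di)],
                                       dj, doses[str(dj)], slope=slope,
                                       log_transform=log_transform)
            rows.append({
                "patient_id": comp.patient_id,
                "drug_i": str(di), "drug_j": str(dj),
                "dose_i_uM": float(2.0 ** pred.dose_i_log2),
                "dose_j_uM": float(2.0 ** pred.dose_j_log2),
                "combo_death": pred.patient_combo_death,
                "mono_i_death": pred.patient_mono_i,
                "mono_j_death": pred.patient_mono_j,
                "best_mono_death": max(pred.patient_mono_i, pred.patient_mono_j),
                "improvement": pred.improvement,
            })
    df = pd.DataFrame(rows)
    df = df.sort_values(["improvement", "drug_i", "drug_j", "patient_id"],
                        ascending=[False, True, True, True], kind="mergesort")
    return df.reset_index(drop=True)


def prioritize_pairs(ranked: pd.DataFrame, cv_accuracy: dict | None = None,
                     min_accuracy: float = 0.7,
                     min_improvement: float = 0.0) -> pd.DataFrame:
    """Screening filter for experimental follow-up: keep pairs whose drugs
    both predicted reliably in cross-validation and that improve over
    monotherapy in at least one patient."""
    df = ranked
    if cv_accuracy is not None:
        ok = {d for d, a in cv_accuracy.items() if np.isfinite(a) and a >= min_accuracy}
        df = df[df["drug_i"].isin(ok) & df["drug_j"].isin(ok)]
    improving = df.groupby(["drug_i", "drug_j"])["improvement"].transform("max")
    return df[improving > min_improvement].reset_index(drop=True)
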