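"""Drug-pathway association: pathway activity vs predicted response.

A sample's activity for a pathway is the sum of its member genes' log2
expression fold-changes; the association of a drug with a pathway is the
Pearson correlation between that activity and the drug's predicted kill
fraction across samples (positive r: high activity tracks sensitivity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionMatrix, GeneSetCollection, ValidationError


@dataclass
class PathwayActivityMatrix:
    set_names: list
    sample_ids: list
    values: np.ndarray          # sets x samples; NaN row when no member present
    coverage: dict              # set name -> number of member genes present

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.set_names), len(self.sample_ids)):
            raise ValidationError("activity matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.set_names, columns=self.sample_ids)


def pathway_activity(fc: ExpressionMatrix, sets: GeneSetCollection) -> PathwayActivityMatrix:
    """Sum of member-gene log2 fold-changes per (pathway, sample)."""
    if fc.scale != "log2_fold_change":
        raise ValidationError("pathway activity expects log2_fold_change expression")
    pos = {g: i for i, g in enumerate(fc.gene_ids)}
    values = np.full((len(sets.set_names), fc.n_samples), np.nan)
    coverage = {}
    any_present = False
    for k, name in enumerate(sets.set_names):
        idx = [pos[g] for g in sets.members[name] if g in pos]
        coverage[name] = len(idx)
        if not idx:
            warnings.warn(f"gene set {name!r} has no member present; activity missing")
            continue
        any_present = True
        values[k] = fc.values[idx, :].sum(axis=0)
    if not any_present:
        raise ValidationError("no gene set has any member present in the matrix")
    return PathwayActivityMatrix(list(sets.set_names), list(fc.sample_ids),
                                 values, coverage)


def drug_pathway_association(activity: PathwayActivityMatrix,
                             predicted_death: pd.DataFrame,
                             bh_correct: bool = False) -> pd.DataFrame:
    """Pearson r between pathway activity and predicted kill, per (drug, pathway).

    ``predicted_death`` is drugs x samples (kill fractions, higher = more
    sensitive).  Constant vectors yield a missing r.  ``bh_correct`` adds
    Benjamini-Hochberg adjusted p-values (off by default).
    """
    shared = [s for s in activity.sample_ids if s in set(predicted_death.columns)]
    if len(shared) < 3:
        raise ValidationError("association needs at least 3 shared samples")
    act = activity.to_frame()[shared]
    death = predicted_death[shared]
    rows = []
    for drug in death.index:
        y = death.loc[drug].to_numpy(dtype=float)
        for name in activity.set_names:
            x = act.loc[name].to_numpy(dtype=float)
            if not np.all(np.isfinite(x)) or np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            rows.append({"drug_id": drug, "pathway": name, "r": r, "p_value": p,
                         "n_samples": len(shared),
                         "coverage": activity.coverage[name]})
    df = pd.DataFrame(rows)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        ok = df["p_value"].notna()
        adj = np.full(len(df), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
        df["p_adj_bh"] = adj
    return df
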