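"""Symptom-burden analysis of the ordinal symptom table.

Subjects answer a battery of symptom questions on a 4-point ordinal scale
(0 absent, 1 mild, 2 moderate, 3 severe; missing allowed).  Variables are
screened by the ratio of relative mean ordinal intensity between severe
ME/CFS and the MS disease-control reference (inclusion at fold >= 1.5),
and tested by a two-sided Fisher exact test on presence/absence (entry
>= 1) in severe ME vs MS, with Benjamini-Hochberg false-discovery-rate
adjustment (significance at adjusted p < 0.05).  Missing entries are
excluded pairwise per variable.

A small pseudo-count (epsilon = 0.05 ordinal units) stabilizes fold
ratios when the reference mean is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SymptomTable",
    "mean_ordinal_intensity",
    "select_symptoms",
    "fisher_bh",
    "symptom_selection",
    "heatmap_matrix",
]

GROUP_ORDER = ("HC", "MildME", "ModME", "SevME", "MS")


@dataclass
class SymptomTable:
    """subjects x variables matrix (values 0-3 or NaN) + group labels."""

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 3))
        if not ok.all():
            raise ValueError("symptom entries must be in {0,1,2,3} or missing")
        if not self.data.index.equals(self.groups.index):
            self.groups = self.groups.loc[self.data.index]

    def group_rows(self, group: str) -> pd.DataFrame:
        return self.data.loc[self.groups == group]


def mean_ordinal_intensity(table: SymptomTable, group: str, variable: str) -> float:
    """Mean of non-missing entries; NaN when all entries are missing."""
    if variable not in table.data.columns:
        raise KeyError(f"variable {variable!r} not in table")
    col = table.group_rows(group)[variable]
    return float(col.mean()) if col.notna().any() else float("nan")


def select_symptoms(table: SymptomTable, group_a: str = "SevME",
                    group_b: str = "MS", fold_min: float = 1.5,
                    eps: float = 0.05) -> pd.DataFrame:
    """Fold screen: fold = (mean_a + eps) / (mean_b + eps), include >= fold_min."""
    present = set(table.groups)
    for g in (group_a, group_b):
        if g not in present:
            raise ValueError(f"group {g!r} absent from table")
    rows = []
    for var in table.data.columns:
        means = {g: mean_ordinal_intensity(table, g, var)
                 for g in GROUP_ORDER if g in present}
        ma, mb = means[group_a], means[group_b]
        fold = (ma + eps) / (mb + eps) if np.isfinite(ma) and np.isfinite(mb) else np.nan
        rows.append({
            "variable": var, **{f"mean_{g}": m for g, m in means.items()},
            "mean_a": ma, "mean_b": mb, "fold": fold,
            "included": bool(np.isfinite(fold) and fold >= fold_min),
        })
    return pd.DataFrame(rows).set_index("variable")


def fisher_bh(table: SymptomTable, group_a: str = "SevME", group_b: str = "MS",
              presence_cut: float = 1.0) -> pd.DataFrame:
    """Per-variable two-sided Fisher exact (presence x group) + BH adjustment.

    Presence = entry >= presence_cut; missing entries excluded.  Variables
    with zero non-missing subjects in either group get NaN and do not
    count toward the number of tests m.
    """
    a_rows = table.group_rows(group_a)
    b_rows = table.group_rows(group_b)
    pvals, variables = [], []
    na_vars = []
    for var in table.data.columns:
        a = a_rows[var].dropna()
        b = b_rows[var].dropna()
        if a.empty or b.empty:
            na_vars.append(var)
            continue
        a_pos, a_neg = int((a >= presence_cut).sum()), int((a < presence_cut).sum())
        b_pos, b_neg = int((b >= presence_cut).sum()), int((b < presence_cut).sum())
        _, p = fisher_exact([[a_pos, a_neg], [b_pos, b_neg]], alternative="two-sided")
        pvals.append(p)
        variables.append(var)
    adj = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    out = pd.DataFrame(
        {"p": pvals, "p_adj": adj, "significant": [q < 0.05 for q in adj]},
        index=pd.Index(variables, name="variable"),
    )
    for var in na_vars:
        out.loc[var] = [np.nan, np.nan, False]
    return out.reindex(table.data.columns)


def symptom_selection(table: SymptomTable, group_a: str = "SevME",
                      group_b: str = "MS", fold_min: float = 1.5,
                      eps: float = 0.05, presence_cut: float = 1.0) -> pd.DataFrame:
    """Combined fold screen + Fisher/BH test table."""
    sel = select_symptoms(table, group_a, group_b, fold_min, eps)
    tests = fisher_bh(table, group_a, group_b, presence_cut)
    return sel.join(tests)


def heatmap_matrix(selection: pd.DataFrame, table: SymptomTable):
    """Included variables x subjects matrix, heatmap-ready.

    Variables descend by fold; subjects are ordered HC, MildME, ModME,
    SevME, MS.  Missing entries stay NaN (render distinctly, e.g. gray).
    Returns (matrix, subject_groups).
    """
    inc = selection.loc[selection["included"]].sort_values("fold", ascending=False)
    subj_order = [
        s for g in GROUP_ORDER for s in table.data.index[table.groups == g]
    ]
    matrix = table.data.loc[subj_order, list(inc.index)].T
    return matrix, table.groups.loc[subj_order]
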