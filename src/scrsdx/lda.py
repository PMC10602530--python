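"""Supervised LDA views of SCRS: clustering, feature selection, confounders.

Linear discriminant analysis on the 1019-channel spectra serves two
distinct purposes: (i) low-dimensional visualization of 3/4/5-group
separation at the cell and the subject level, with per-axis
explained-variance fractions, and (ii) feature selection -- ranking
wavenumbers by the magnitude of their discriminant coefficients.

With ~1019 channels and far fewer cells per class, the within-class
scatter matrix is singular; the eigen solver therefore uses Ledoit-Wolf
shrinkage regularization of the within-class covariance (scikit-learn's
``solver="eigen", shrinkage="auto"``).

The confounder screen computes Pearson correlations between LD
coordinates and clinical/technical covariates and flags |r| > 0.75
(conventional threshold for a high correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core import SpectralAxis

__all__ = ["LDAModel", "ConfounderReport", "fit_lda", "top_features", "confounder_scan"]


@dataclass
class LDAModel:
    classes: list
    directions: np.ndarray                 # (n_features, n_axes)
    explained_variance_ratio: np.ndarray   # sums to 1
    class_means_ld: pd.DataFrame           # class x LD axis
    level: str = "cell"
    wavenumbers: np.ndarray | None = field(default=None, repr=False)
    _xbar: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_axes(self) -> int:
        return self.directions.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self._xbar) @ self.directions


def _subject_average(X: np.ndarray, labels: np.ndarray, subject_ids: np.ndarray):
    subjects = pd.unique(subject_ids)
    Xs, ys = [], []
    for s in subjects:
        m = subject_ids == s
        labs = set(labels[m])
        if len(labs) != 1:
            raise ValueError(f"subject {s} carries multiple labels")
        Xs.append(X[m].mean(axis=0))
        ys.append(labs.pop())
    return np.vstack(Xs), np.asarray(ys), subjects


def fit_lda(
    X: np.ndarray,
    labels,
    level: str = "cell",
    subject_ids=None,
    axis: SpectralAxis | None = None,
) -> tuple[LDAModel, pd.DataFrame]:
    """Fit shrinkage LDA; returns the model and projected coordinates.

    ``level="subject"`` averages each subject's rows first (labels must be
    constant within subject).  Axis signs follow the convention that the
    largest-|coefficient| feature is positive on every LD axis.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    ids = None
    if level == "subject":
        if subject_ids is None:
            raise ValueError("subject level requires subject_ids")
        X, labels, ids = _subject_average(X, labels, np.asarray(subject_ids))
    elif level != "cell":
        raise ValueError(f"unknown level {level!r}")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 members")

    n_axes = int(classes.size - 1)
    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")
    lda.fit(X, labels)
    directions = np.asarray(lda.scalings_[:, :n_axes], float)
    evr = np.asarray(lda.explained_variance_ratio_[:n_axes], float)
    evr = evr / evr.sum()

    # sign convention: dominant coefficient positive per axis
    for k in range(directions.shape[1]):
        j = int(np.argmax(np.abs(directions[:, k])))
        if directions[j, k] < 0:
            directions[:, k] = -directions[:, k]

    xbar = X.mean(axis=0)
    coords = (X - xbar) @ directions
    ld_cols = [f"LD{k + 1}" for k in range(n_axes)]
    coord_df = pd.DataFrame(coords, columns=ld_cols)
    coord_df["label"] = labels
    if ids is not None:
        coord_df["subject_id"] = ids
    class_means = coord_df.groupby("label", sort=True)[ld_cols].mean()
    model = LDAModel(
        classes=list(classes),
        directions=directions,
        explained_variance_ratio=evr,
        class_means_ld=class_means,
        level=level,
        wavenumbers=None if axis is None else axis.wavenumbers,
        _xbar=xbar,
    )
    return model, coord_df


def top_features(model: LDAModel, axis: int | str = "LD1", n: int = 10) -> pd.DataFrame:
    """Top-n features by |discriminant coefficient| on one LD axis.

    Ties are broken toward the lower wavenumber; both tied channels are
    reported when they fit in n.
    """
    k = int(axis[2:]) - 1 if isinstance(axis, str) else int(axis)
    if not 0 <= k < model.n_axes:
        raise ValueError(f"axis {axis!r} beyond model rank {model.n_axes}")
    coef = model.directions[:, k]
    wn = (
        model.wavenumbers
        if model.wavenumbers is not None
        else np.arange(coef.size, dtype=float)
    )
    order = np.lexsort((wn, -np.abs(coef)))
    sel = order[: max(int(n), 0)]
    return pd.DataFrame(
        {
            "wavenumber": wn[sel],
            "coefficient": coef[sel],
            "sign": np.sign(coef[sel]).astype(int),
        }
    )


@dataclass
class ConfounderReport:
    table: pd.DataFrame             # covariate, axis, r
    flag_threshold: float
    flagged: list


def _encode_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in cov.columns:
        s = cov[col]
        if s.dtype == bool:
            out[col] = s.astype(float)
        elif pd.api.types.is_numeric_dtype(s):
            out[col] = s.astype(float)
        else:
            dummies = pd.get_dummies(s, prefix=col)
            for d in dummies.columns:
                out[d] = dummies[d].astype(float)
    return pd.DataFrame(out, index=cov.index)


def confounder_scan(
    coords: pd.DataFrame, covariates: pd.DataFrame, flag_threshold: float = 0.75
) -> ConfounderReport:
    """Pearson r of every covariate against every LD axis.

    Binary covariates are 0/1-encoded, categoricals one-hot.  A
    zero-variance covariate yields r = NaN (reported, never flagged).
    """
    ld_cols = [c for c in coords.columns if c.startswith("LD")]
    if len(coords) < 3:
        raise ValueError("need n >= 3 for a correlation screen")
    enc = _encode_covariates(covariates)
    rows = []
    flagged = set()
    for cov_name in enc.columns:
        x = enc[cov_name].to_numpy(float)
        for ld in ld_cols:
            y = coords[ld].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"covariate": cov_name, "axis": ld, "r": r})
            if np.isfinite(r) and abs(r) > flag_threshold:
                flagged.add(cov_name)
    return ConfounderReport(
        table=pd.DataFrame(rows), flag_threshold=flag_threshold,
        flagged=sorted(flagged),
    )
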