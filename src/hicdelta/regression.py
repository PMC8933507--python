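"""Per-bin feature tables and regression of metric changes on genomic
properties: closed-form ridge and random-forest feature importances.

The design matrix holds numeric per-bin tracks plus a one-hot expansion of
one categorical annotation layer (all levels retained — 23 numeric tracks
and a 6-level categorical give 29 columns). Columns are standardized to
mean 0 and unit population standard deviation; ridge's L2 penalty absorbs
the collinearity the full one-hot encoding introduces.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .genome import AnnotationLabels, ProfileTrack, UNLABELED
from .insulation import BoundarySet

__all__ = ["FeatureTable", "build_feature_table", "ridge_fit", "forest_importance"]


@dataclasses.dataclass
class FeatureTable:
    X: pd.DataFrame  # standardized design, rows = retained bins
    y: np.ndarray
    bin_indices: np.ndarray  # global bin index per row
    centers: pd.Series
    spreads: pd.Series
    dropped_constant: list
    n_dropped_rows: int


def build_feature_table(
    tracks: dict,
    categorical: AnnotationLabels | None,
    response: ProfileTrack,
    restrict_to: BoundarySet | None = None,
) -> FeatureTable:
    """Assemble and standardize the per-bin design matrix.

    ``tracks`` maps feature name -> ProfileTrack on the response's bins.
    The categorical layer is one-hot encoded over its full vocabulary (no
    reference level dropped); unlabeled bins get all-zero indicators. Rows
    with a missing response (or missing in any numeric track) are dropped
    and counted; ``restrict_to`` limits rows to boundary bins. Constant
    columns are dropped with a warning. Standardization uses the population
    standard deviation.
    """
    bins = response.bins
    cols = {}
    for name, tr in tracks.items():
        if tr.bins != bins:
            raise ValueError(f"track {name!r} not on the response's bins")
        cols[name] = tr.values
    if categorical is not None:
        if len(categorical) != len(bins):
            raise ValueError("categorical layer not on the response's bins")
        for level in categorical.vocabulary:
            cols[f"{level}"] = (categorical.labels == level).astype(float)
    X = pd.DataFrame(cols)
    y = response.values
    keep = np.isfinite(y)
    for name in tracks:
        keep &= np.isfinite(X[name].to_numpy())
    if restrict_to is not None:
        if len(restrict_to) == 0:
            raise ValueError("empty design: restriction set has no boundaries")
        sel = np.zeros(len(bins), dtype=bool)
        sel[restrict_to.bin_indices] = True
        keep &= sel
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("empty design: no rows with a finite response")
    X = X.loc[keep].reset_index(drop=True)
    yv = y[keep]
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant columns: {const}", RuntimeWarning)
        X = X.drop(columns=const)
    centers = X.mean()
    spreads = X.std(ddof=0)
    Xs = (X - centers) / spreads
    return FeatureTable(
        X=Xs,
        y=yv,
        bin_indices=np.flatnonzero(keep),
        centers=centers,
        spreads=spreads,
        dropped_constant=const,
        n_dropped_rows=n_dropped,
    )


def ridge_fit(table: FeatureTable, penalty: float = 1.0) -> pd.DataFrame:
    """Closed-form ridge regression on the standardized design.

    Solves (X'X + penalty * I) w = X'y with an unpenalized intercept
    (equal to the response mean, since columns are centred). At
    ``penalty=0`` a singular normal system raises. Returns the coefficient
    table sorted by magnitude, with the intercept and R^2 attached as
    DataFrame attrs.
    """
    X = table.X.to_numpy()
    y = table.y
    intercept = float(y.mean())
    yc = y - intercept
    n, p = X.shape
    A = X.T @ X + penalty * np.eye(p)
    if penalty == 0:
        if np.linalg.matrix_rank(A) < p:
            raise np.linalg.LinAlgError(
                "singular normal equations at penalty=0 (collinear columns)"
            )
        w = np.linalg.solve(A, X.T @ yc)
    else:
        w = np.linalg.solve(A, X.T @ yc)
    resid = yc - X @ w
    ss_tot = float((yc**2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else np.nan
    out = pd.DataFrame(
        {"feature": table.X.columns, "coefficient": w}
    ).sort_values("coefficient", key=np.abs, ascending=False, kind="stable")
    out = out.reset_index(drop=True)
    out.attrs["intercept"] = intercept
    out.attrs["r2"] = r2
    out.attrs["penalty"] = penalty
    return out


def forest_importance(
    table: FeatureTable, n_trees: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Impurity-based random-forest feature importances, sorted descending.

    Importances are non-negative and sum to 1 (sklearn's normalization).
    Seeded for reproducibility.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rf = RandomForestRegressor(
        n_estimators=n_trees, random_state=int(seed) % 2**31, n_jobs=1
    )
    rf.fit(table.X.to_numpy(), table.y)
    out = pd.DataFrame(
        {"feature": table.X.columns, "importance": rf.feature_importances_}
    ).sort_values("importance", ascending=False, kind="stable")
    return out.reset_index(drop=True)
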