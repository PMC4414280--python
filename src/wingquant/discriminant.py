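"""Discriminant analysis of principal components (DAPC) and Mahalanobis tables.

DAPC reduces a specimens-x-coefficients feature matrix to its first
``n_pcs`` principal components (covariance PCA on column-centered data)
and then finds the linear discriminants of those PC scores with wingform
labels: g groups yield g-1 discriminant axes.  Contribution vectors map
the discrimination back to original coefficients as the column-normalized
elementwise absolute value of (PC loadings x LD loadings), and pairwise
Mahalanobis distances between group centroids - under the pooled
within-group covariance of the discriminant scores, hence in
standard-deviation units - summarize how well a feature set separates
the wingforms.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "FeatureMatrix",
    "DAPCResult",
    "dapc_fit",
    "contribution_vectors",
    "top_contributors",
    "mahalanobis_matrix",
    "md_summary",
    "loo_assignment_accuracy",
]

RIDGE_EPS = 1e-6  # shrinkage applied when the within-group scatter is singular


@dataclass
class FeatureMatrix:
    """Specimens x coefficients block with labels and a column catalogue."""

    X: np.ndarray
    labels: list[str]
    specimen_ids: list[str] = field(default_factory=list)
    name: str = ""
    catalogue: pd.DataFrame | None = None  # one row per column

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("one label per specimen row required")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")
        if not self.specimen_ids:
            self.specimen_ids = [f"sp{i}" for i in range(self.X.shape[0])]


@dataclass
class DAPCResult:
    groups: list[str]
    n_pcs: int
    pc_mean: np.ndarray  # (p,)
    pc_loadings: np.ndarray  # (p, n_pcs)
    pc_scores: np.ndarray  # (n, n_pcs)
    ld_loadings: np.ndarray  # (n_pcs, g-1)
    ld_scores: np.ndarray  # (n, g-1)
    centroids: np.ndarray  # (g, g-1)
    within_cov: np.ndarray  # (g-1, g-1) pooled within-group covariance
    labels: list[str] = field(default_factory=list)
    catalogue: pd.DataFrame | None = None
    feature_set: str = ""

    @property
    def n_axes(self) -> int:
        return self.ld_loadings.shape[1]

    def project(self, X_new: np.ndarray) -> np.ndarray:
        """Discriminant-space coordinates of new specimens."""
        return (np.asarray(X_new, dtype=float) - self.pc_mean) @ self.pc_loadings @ self.ld_loadings


def _pooled_within_cov(scores: np.ndarray, labels: np.ndarray, groups: list[str]) -> np.ndarray:
    n, d = scores.shape
    s = np.zeros((d, d))
    for g in groups:
        sel = scores[labels == g]
        if len(sel) > 1:
            c = sel - sel.mean(axis=0)
            s += c.T @ c
    dof = max(n - len(groups), 1)
    return s / dof


def dapc_fit(fm: FeatureMatrix, n_pcs: int = 50) -> DAPCResult:
    """Fit DAPC: covariance PCA (first ``n_pcs`` axes) then LDA on PC scores.

    When fewer than ``n_pcs`` components are available (small cohorts) the
    retained count drops to min(n-1, p, n_pcs) and is recorded on the
    result.  A singular within-group scatter triggers a warned ridge
    (shrinkage) refit.
    """
    X, labels = fm.X, np.asarray(fm.labels)
    groups = sorted(set(fm.labels))
    n, p = X.shape
    if len(groups) < 2:
        raise ValueError("discriminant fitting needs at least two groups")
    if n < len(groups) + 1:
        raise ValueError("need more specimens than groups")
    k = int(min(n_pcs, n - 1, p))

    pca = PCA(n_components=k, svd_solver="full")
    pc_scores = pca.fit_transform(X)
    # drop numerically null components (variance < 1e-9 of the leading one):
    # they carry no shape/color signal and would make the within-group
    # scatter singular
    ev = pca.explained_variance_
    keep = ev > ev[0] * 1e-9
    k = int(keep.sum())
    pc_scores = pc_scores[:, keep]
    pc_loadings = pca.components_.T[:, keep]  # (p, k)

    lda = LinearDiscriminantAnalysis(solver="eigen")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn warns about collinearity itself
            lda.fit(pc_scores, labels)
        if not np.all(np.isfinite(lda.scalings_)):
            raise linalg.LinAlgError("non-finite discriminant scalings")
    except (linalg.LinAlgError, np.linalg.LinAlgError):
        warnings.warn(
            f"within-group scatter is singular; refitting with shrinkage {RIDGE_EPS}",
            RuntimeWarning,
            stacklevel=2,
        )
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=RIDGE_EPS)
        lda.fit(pc_scores, labels)

    n_axes = len(groups) - 1
    ld_loadings = np.asarray(lda.scalings_)[:, :n_axes]
    # sign convention: largest-magnitude loading on each axis positive
    for j in range(n_axes):
        i = int(np.argmax(np.abs(ld_loadings[:, j])))
        if ld_loadings[i, j] < 0:
            ld_loadings[:, j] = -ld_loadings[:, j]
    ld_scores = pc_scores @ ld_loadings
    centroids = np.vstack([ld_scores[labels == g].mean(axis=0) for g in groups])
    within = _pooled_within_cov(ld_scores, labels, groups)
    return DAPCResult(
        groups=groups,
        n_pcs=k,
        pc_mean=pca.mean_,
        pc_loadings=pc_loadings,
        pc_scores=pc_scores,
        ld_loadings=ld_loadings,
        ld_scores=ld_scores,
        centroids=centroids,
        within_cov=within,
        labels=list(fm.labels),
        catalogue=fm.catalogue,
        feature_set=fm.name,
    )


def contribution_vectors(result: DAPCResult) -> np.ndarray:
    """Per-axis relative contribution of every original coefficient.

    |PC loadings x LD loadings| with each column rescaled to sum to 1, so
    entries are non-negative proportions.
    """
    contrib = np.abs(result.pc_loadings @ result.ld_loadings)
    sums = contrib.sum(axis=0)
    sums[sums == 0] = 1.0
    return contrib / sums


def top_contributors(result: DAPCResult, k: int = 5) -> pd.DataFrame:
    """The ``k`` highest-contributing coefficients per discriminant axis.

    Ties break by (contribution desc, column index asc).  Wing-location
    descriptors come from the feature matrix's column catalogue when present.
    """
    contrib = contribution_vectors(result)
    rows = []
    for axis in range(contrib.shape[1]):
        order = np.lexsort((np.arange(contrib.shape[0]), -contrib[:, axis]))
        for rank, idx in enumerate(order[:k], start=1):
            row = {
                "axis": axis + 1,
                "rank": rank,
                "column": int(idx),
                "contribution": float(contrib[idx, axis]),
                "feature_set": result.feature_set,
            }
            if result.catalogue is not None:
                row.update(result.catalogue.iloc[idx].to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def mahalanobis_matrix(result: DAPCResult) -> pd.DataFrame:
    """Pairwise Mahalanobis distances between group centroids.

    Distances use all discriminant axes under the pooled within-group
    covariance, i.e. they are expressed in standard deviations.  Groups with
    fewer than two specimens contribute nothing to the pooled covariance
    and are flagged via the DataFrame ``attrs``.
    """
    g = len(result.groups)
    if g < 2:
        raise ValueError("need at least two groups")
    prec = np.linalg.pinv(result.within_cov)
    out = np.zeros((g, g))
    for i, j in itertools.combinations(range(g), 2):
        d = result.centroids[i] - result.centroids[j]
        out[i, j] = out[j, i] = float(np.sqrt(d @ prec @ d))
    df = pd.DataFrame(out, index=result.groups, columns=result.groups)
    counts = pd.Series(result.labels).value_counts()
    df.attrs["small_groups"] = [g_ for g_ in result.groups if counts.get(g_, 0) < 2]
    return df


def md_summary(tables: dict[str, pd.DataFrame], threshold: float = 3.0) -> pd.DataFrame:
    """Long-form per-pair report across feature sets.

    One row per unordered group pair with one column per feature set, the
    per-pair mean, and the feature sets falling below ``threshold``; column
    means are appended as a final ``MEAN`` row.
    """
    if not tables:
        raise ValueError("at least one distance table required")
    sets = list(tables)
    groups = list(tables[sets[0]].index)
    for name, t in tables.items():
        if list(t.index) != groups or list(t.columns) != groups:
            raise ValueError(f"group set of table {name!r} does not match")
    rows = []
    for a, b in itertools.combinations(groups, 2):
        row: dict = {"pair": f"{a}—{b}"}
        for s in sets:
            row[s] = float(tables[s].loc[a, b])
        vals = [row[s] for s in sets]
        row["mean"] = float(np.mean(vals))
        row["below_threshold"] = ",".join(s for s in sets if row[s] < threshold)
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = {"pair": "MEAN", "below_threshold": ""}
    for s in sets + ["mean"]:
        mean_row[s] = float(df[s].mean())
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def loo_assignment_accuracy(fm: FeatureMatrix, n_pcs: int = 50) -> float:
    """Leave-one-out nearest-centroid assignment accuracy in DAPC space.

    For each specimen the DAPC is refit without it, the specimen is
    projected into the held-out discriminant space, and it is assigned to
    the nearest group centroid by Mahalanobis distance under the pooled
    within-group covariance.
    """
    n = fm.X.shape[0]
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n):
            keep = np.arange(n) != i
            sub = FeatureMatrix(
                X=fm.X[keep],
                labels=[l for j, l in enumerate(fm.labels) if j != i],
                name=fm.name,
            )
            res = dapc_fit(sub, n_pcs=n_pcs)
            z = res.project(fm.X[i : i + 1])[0]
            prec = np.linalg.pinv(res.within_cov)
            d2 = [
                float((z - c) @ prec @ (z - c)) for c in res.centroids
            ]
            if res.groups[int(np.argmin(d2))] == fm.labels[i]:
                hits += 1
    return hits / n
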