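"""Quality classification: clustering, radar coordinates, discriminant analysis.

Hierarchical clustering uses between-groups (average) linkage on squared
Euclidean distances of the raw mg/g values by default, with merge heights
mapped linearly onto the 0-25 "rescaled distance" dendrogram axis used by
common statistics packages, so a published cut height on that axis can be
applied directly.

Canonical discriminant analysis solves the eigenproblem of
W^{-1} B (within-group and between-group scatter); each eigenvalue's share
of the total measures that function's discriminating power. Fisher linear
classification functions are derived from the pooled within-group
covariance S and the group means m_g:

    coef_g = S^{-1} m_g,   const_g = -1/2 m_g' S^{-1} m_g + ln(prior_g),

and a sample is assigned to the group with the highest linear score.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .types import (
    ClassificationModel,
    ConcentrationMatrix,
    DendrogramResult,
    ValidationError,
)

__all__ = [
    "RescaledHierarchicalClustering",
    "FisherDiscriminantAnalysis",
    "hierarchical_cluster",
    "cut_clusters",
    "radar_coordinates",
    "polygon_area",
    "fit_discriminant",
    "classify_fisher",
    "cross_validate",
]

_METRICS = {"squared_euclidean": "sqeuclidean", "euclidean": "euclidean"}
_LINKAGES = ("average", "ward", "complete")

RESCALED_MAX = 25.0


def _as_array(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, ConcentrationMatrix):
        return matrix.values, list(matrix.sample_ids)
    arr = np.asarray(matrix, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


class RescaledHierarchicalClustering(ClusterMixin, BaseEstimator):
    """Agglomerative clustering with a 0-25 rescaled-distance axis.

    Parameters
    ----------
    linkage : {"average", "ward", "complete"}
        Merge criterion; "average" (between-groups) is the default.
    metric : {"squared_euclidean", "euclidean"}
        Pairwise distance on the unstandardized value matrix. Ward linkage
        requires plain Euclidean distances.
    cut_rescaled : float
        Threshold on the rescaled 0-25 axis used by :meth:`fit_predict`.
    """

    def __init__(
        self,
        linkage: str = "average",
        metric: str = "squared_euclidean",
        cut_rescaled: float = 9.0,
    ):
        self.linkage = linkage
        self.metric = metric
        self.cut_rescaled = cut_rescaled

    def fit(self, X, y=None) -> "RescaledHierarchicalClustering":
        values, sample_ids = _as_array(X)
        if values.shape[0] < 2:
            raise ValidationError("clustering needs >= 2 samples")
        if np.any(np.isnan(values)):
            raise ValidationError("clustering input contains missing values")
        if self.linkage not in _LINKAGES:
            raise ValidationError(f"linkage must be one of {_LINKAGES}, got {self.linkage!r}")
        if self.metric not in _METRICS:
            raise ValidationError(f"metric must be one of {tuple(_METRICS)}, got {self.metric!r}")
        metric = self.metric
        if self.linkage == "ward" and metric != "euclidean":
            metric = "euclidean"
        Z = scipy_linkage(pdist(values, _METRICS[metric]), method=self.linkage)
        heights = Z[:, 2]
        top = heights.max()
        rescaled = RESCALED_MAX * heights / top if top > 0 else np.zeros_like(heights)
        self.sample_ids_ = sample_ids
        self.linkage_matrix_ = Z
        self.dendrogram_ = DendrogramResult(
            sample_ids=sample_ids,
            merge_steps=[(int(a), int(b), float(h)) for a, b, h in Z[:, :3]],
            rescaled_heights=[float(h) for h in rescaled],
        )
        self.labels_ = np.array(
            [self.cut(self.cut_rescaled)[s] for s in sample_ids]
        )
        return self

    def cut(self, rescaled_threshold: float) -> dict[str, str]:
        check_is_fitted(self, "dendrogram_")
        return cut_clusters(self.dendrogram_, rescaled_threshold)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def hierarchical_cluster(
    matrix, linkage: str = "average", metric: str = "squared_euclidean"
) -> DendrogramResult:
    """Agglomerative merge tree with heights rescaled to the 0-25 axis."""
    est = RescaledHierarchicalClustering(linkage=linkage, metric=metric)
    est.fit(matrix)
    return est.dendrogram_


def cut_clusters(dendrogram: DendrogramResult, rescaled_threshold: float) -> dict[str, str]:
    """Partition samples by removing merges above a rescaled-distance cut.

    Groups are labelled G1, G2, ... by the order in which their first sample
    appears in the sample list.
    """
    if not 0 < rescaled_threshold <= RESCALED_MAX:
        raise ValidationError(
            f"threshold must be in (0, {RESCALED_MAX}], got {rescaled_threshold}"
        )
    n = dendrogram.n_samples
    parent = list(range(n + len(dendrogram.merge_steps)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, ((a, b, _), resc) in enumerate(
        zip(dendrogram.merge_steps, dendrogram.rescaled_heights)
    ):
        if resc <= rescaled_threshold:
            node = n + i
            parent[find(int(a))] = node
            parent[find(int(b))] = node
    roots: dict[int, str] = {}
    labels = {}
    for idx, sid in enumerate(dendrogram.sample_ids):
        root = find(idx)
        if root not in roots:
            roots[root] = f"G{len(roots) + 1}"
        labels[sid] = roots[root]
    return labels


def radar_coordinates(
    matrix, normalization: str = "none"
) -> dict[str, list[tuple[float, float]]]:
    """Closed radar-polygon coordinates (angle, radius) per sample.

    Compound j of p is placed at angle 2*pi*j/p; the radius is the content
    (optionally divided by the per-compound maximum over samples, putting
    all rays on a common 0-1 scale). The first vertex is repeated so the
    polygon closes.
    """
    values, sample_ids = _as_array(matrix)
    p = values.shape[1]
    if p < 3:
        raise ValidationError(f"radar plots need >= 3 variables, got {p}")
    if normalization not in ("none", "per_compound_max"):
        raise ValidationError(f"unknown normalization {normalization!r}")
    radii = values.astype(float)
    if normalization == "per_compound_max":
        col_max = radii.max(axis=0)
        if np.any(col_max <= 0):
            raise ValidationError("per-compound max normalization needs positive columns")
        radii = radii / col_max
    angles = 2.0 * np.pi * np.arange(p) / p
    out = {}
    for sid, row in zip(sample_ids, radii):
        verts = [(float(a), float(r)) for a, r in zip(angles, row)]
        verts.append(verts[0])
        out[sid] = verts
    return out


def polygon_area(vertices: Sequence[tuple[float, float]]) -> float:
    """Shoelace area of a closed polar polygon given as (angle, radius)."""
    xy = [(r * np.cos(a), r * np.sin(a)) for a, r in vertices]
    s = 0.0
    for (x1, y1), (x2, y2) in zip(xy, xy[1:]):
        s += x1 * y2 - x2 * y1
    return abs(s) / 2.0


class FisherDiscriminantAnalysis(ClassifierMixin, BaseEstimator):
    """Canonical discriminant analysis with Fisher classification functions.

    Parameters
    ----------
    priors : {"equal", "proportional"}
        Group priors entering the classification-function constants.
    ridge : float or None
        Relative ridge added to the pooled covariance diagonal when it is
        numerically singular; ``None`` applies 1e-8 * trace automatically
        (with a warning), 0 disables the fallback.

    Attributes
    ----------
    classes_ : ndarray of group labels.
    coefficients_ : (n_groups, n_features) Fisher function coefficients.
    constants_ : (n_groups,) Fisher function constants.
    eigenvalues_ : canonical eigenvalues of W^{-1} B, descending.
    variance_shares_pct_ : 100 * eigenvalue / sum(eigenvalues).
    """

    def __init__(self, priors: str = "equal", ridge: float | None = None):
        self.priors = priors
        self.ridge = ridge

    def fit(self, X, y) -> "FisherDiscriminantAnalysis":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValidationError("X must be 2-D with one label per row")
        classes, y_idx = np.unique(y, return_inverse=True)
        g, (n, p) = len(classes), X.shape
        if g < 2:
            raise ValidationError("discriminant analysis needs >= 2 groups")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            small = classes[counts.argmin()]
            raise ValidationError(f"every group needs >= 2 samples (group {small!r})")
        means = np.vstack([X[y_idx == k].mean(axis=0) for k in range(g)])
        grand = X.mean(axis=0)
        W = np.zeros((p, p))
        B = np.zeros((p, p))
        for k in range(g):
            d = X[y_idx == k] - means[k]
            W += d.T @ d
            B += counts[k] * np.outer(means[k] - grand, means[k] - grand)
        S = W / (n - g)  # pooled within-group covariance
        ridge = self.ridge
        cond = np.linalg.cond(S)
        if cond > 1e12:
            if ridge == 0:
                raise np.linalg.LinAlgError(
                    f"pooled within-group covariance is singular (cond={cond:.2e})"
                )
            if ridge is None:
                ridge = 1e-8 * float(np.trace(S))
                warnings.warn(
                    f"singular pooled covariance; applying ridge {ridge:.3e}", stacklevel=2
                )
            S = S + ridge * np.eye(p)
        S_inv = np.linalg.inv(S)
        self.coefficients_ = means @ S_inv
        log_prior = (
            np.zeros(g)
            if self.priors == "equal"
            else np.log(counts / counts.sum())
        )
        self.constants_ = -0.5 * np.einsum("ij,ij->i", self.coefficients_, means) + log_prior
        # W^{-1} B = S^{-1} B / (n - g); the ridge (if any) is already in S
        eigvals = np.linalg.eigvals(S_inv @ B / (n - g))
        eigvals = np.sort(np.clip(eigvals.real, 0.0, None))[::-1][: min(g - 1, p)]
        self.eigenvalues_ = eigvals
        total = eigvals.sum()
        self.variance_shares_pct_ = (
            100.0 * eigvals / total if total > 0 else np.zeros_like(eigvals)
        )
        self.classes_ = classes
        self.group_means_ = means
        self.n_features_in_ = p
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coefficients_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.coefficients_.shape[1]:
            raise ValidationError(
                f"expected {self.coefficients_.shape[1]} variables, got {X.shape[1]}"
            )
        return X @ self.coefficients_.T + self.constants_

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def to_model(self, variable_order: Sequence[str]) -> ClassificationModel:
        check_is_fitted(self, "coefficients_")
        return ClassificationModel(
            group_labels=[str(c) for c in self.classes_],
            fisher_coefficients=self.coefficients_.copy(),
            fisher_constants=self.constants_.copy(),
            variable_order=list(variable_order),
            canonical_eigenvalues=[float(e) for e in self.eigenvalues_],
            variance_shares_pct=[float(s) for s in self.variance_shares_pct_],
        )


def _matrix_and_labels(
    matrix, labels: Mapping[str, str] | Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    values, sample_ids = _as_array(matrix)
    if isinstance(labels, Mapping):
        missing = [s for s in sample_ids if s not in labels]
        if missing:
            raise ValidationError(f"no group label for sample(s): {', '.join(missing)}")
        y = np.array([labels[s] for s in sample_ids])
    else:
        y = np.asarray(list(labels))
    return values, y, sample_ids


def fit_discriminant(
    matrix, labels: Mapping[str, str] | Sequence[str], priors: str = "equal"
) -> ClassificationModel:
    """Fit canonical DA + Fisher functions on a concentration matrix."""
    values, y, _ = _matrix_and_labels(matrix, labels)
    est = FisherDiscriminantAnalysis(priors=priors).fit(values, y)
    order = (
        list(matrix.compound_ids)
        if isinstance(matrix, ConcentrationMatrix)
        else [f"x{j + 1}" for j in range(values.shape[1])]
    )
    return est.to_model(order)


def classify_fisher(
    model: ClassificationModel, x: Sequence[float]
) -> tuple[str, dict[str, float]]:
    """Evaluate the Fisher functions on one sample; return (argmax group, scores)."""
    scores = model.scores(x)
    best = int(np.argmax(scores))
    ties = np.flatnonzero(scores == scores[best])
    if ties.size > 1:
        warnings.warn(
            f"tied classification scores for groups {[model.group_labels[t] for t in ties]}; "
            "assigning the first in label order",
            stacklevel=2,
        )
    return model.group_labels[best], dict(zip(model.group_labels, map(float, scores)))


def cross_validate(
    matrix,
    labels: Mapping[str, str] | Sequence[str],
    scheme: str = "leave_one_out",
    priors: str = "equal",
) -> tuple[pd.DataFrame, float]:
    """Leave-one-out refit/classify; returns (confusion matrix, % correct).

    The confusion matrix has true groups as rows and predicted groups as
    columns. Folds that would leave a group with fewer than 2 training
    samples are skipped with a warning.
    """
    if scheme != "leave_one_out":
        raise ValidationError(f"unsupported scheme {scheme!r}")
    values, y, _ = _matrix_and_labels(matrix, labels)
    classes = sorted(set(map(str, y)))
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    n_correct = n_done = 0
    for i in range(values.shape[0]):
        mask = np.ones(values.shape[0], dtype=bool)
        mask[i] = False
        remaining = np.array([str(v) for v in y[mask]])
        if min(np.bincount(np.unique(remaining, return_inverse=True)[1])) < 2:
            warnings.warn(f"fold {i} skipped: a group would have < 2 training samples", stacklevel=2)
            continue
        est = FisherDiscriminantAnalysis(priors=priors).fit(values[mask], y[mask])
        pred = str(est.predict(values[i : i + 1])[0])
        conf.loc[str(y[i]), pred] += 1
        n_correct += pred == str(y[i])
        n_done += 1
    pct = 100.0 * n_correct / n_done if n_done else float("nan")
    return conf, pct
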