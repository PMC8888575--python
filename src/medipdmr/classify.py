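"""Biomarker evaluation on DMR-restricted features.

Samples are represented by log2(CPM + 1) values over the windows
covered by the DMR set (features). PCA and an average-linkage
dendrogram give unsupervised views; classification is linear
discriminant analysis fitted in a PCA-reduced space (rank
k = min(n - 2, 10)) with diagonal shrinkage of the pooled within-class
covariance, which keeps the model well-posed in the usual n << p
regime. Leave-one-out accuracy refits the discriminant with each
training sample held out.

Note on leakage: when evaluating a full pipeline, DMR selection should
use training samples only; these functions operate on a fixed feature
matrix, and :func:`lda_train_predict`'s LOO refits the classifier, not
the feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree

from .model import DMR, NormalizationFactors, WindowCounts


@dataclass
class FeatureMatrix:
    """Samples x DMR-covered-windows log2(CPM + 1) matrix."""

    samples: list[str]
    values: np.ndarray  # (n_samples, n_features)
    windows: pd.DataFrame  # chrom, start, end per feature column

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if self.values.shape != (len(self.samples), len(self.windows)):
            raise ValueError("feature matrix shape mismatch")


def dmr_feature_matrix(counts: WindowCounts, norm: NormalizationFactors,
                       dmrs: list[DMR]) -> FeatureMatrix:
    """Restrict samples to windows intersecting any DMR; log2(CPM + 1)."""
    if not dmrs:
        raise ValueError("empty DMR set: no features to build")
    mask = np.zeros(counts.n_windows, dtype=bool)
    for d in dmrs:
        mask |= ((counts.chroms == d.chrom)
                 & (counts.starts < d.end) & (counts.ends > d.start))
    if not mask.any():
        raise ValueError("no windows intersect the DMR set")
    eff = norm.effective_library_sizes
    cpm = 1e6 * counts.counts[mask].astype(np.float64) / eff
    values = np.log2(cpm + 1.0).T
    windows = pd.DataFrame({"chrom": counts.chroms[mask],
                            "start": counts.starts[mask],
                            "end": counts.ends[mask]})
    return FeatureMatrix(samples=list(counts.samples), values=values,
                         windows=windows.reset_index(drop=True))


def pca(features: FeatureMatrix | np.ndarray, n_components: int,
        ) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA by SVD: (scores, explained-variance fractions).

    Sign convention: in each component the largest-magnitude loading is
    positive, so scores are reproducible across runs and orderings.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    n = x.shape[0]
    if n < 2:
        raise ValueError("PCA needs >= 2 samples")
    if n_components > min(n - 1, x.shape[1]):
        raise ValueError(f"n_components={n_components} exceeds min(samples-1, features)")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total_var = float((xc ** 2).sum())
    scores = u[:, :n_components] * s[:n_components]
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    for j in range(n_components):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return scores, evr


def _newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.get_left(), labels)
    right = _newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def dendrogram(features: FeatureMatrix) -> str:
    """Average-linkage dendrogram on Euclidean distances, as Newick text.

    Features are column-centered first. scipy's linkage breaks distance
    ties deterministically by lowest observation index.
    """
    x = features.values
    if x.shape[0] < 2:
        raise ValueError("dendrogram needs >= 2 samples")
    xc = x - x.mean(axis=0)
    z = linkage(xc, method="average", metric="euclidean")
    root = to_tree(z)
    return _newick(root, features.samples) + ";"


@dataclass
class LdaModel:
    """LDA in PCA-reduced space with shrunken pooled covariance."""

    classes: list[str]
    center: np.ndarray       # training feature mean
    basis: np.ndarray        # (n_features, k) principal axes
    class_means: np.ndarray  # (2, k) in reduced space
    direction: np.ndarray    # discriminant direction in reduced space
    threshold: float         # midpoint score between class means

    def predict(self, values: np.ndarray) -> list[str]:
        z = (values - self.center) @ self.basis
        scores = z @ self.direction - self.threshold
        return [self.classes[1] if s > 0 else self.classes[0] for s in scores]


def _fit_lda(x: np.ndarray, labels: list[str], n_components: int | None,
             shrinkage: float) -> LdaModel:
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError("LDA training requires exactly two classes")
    n = x.shape[0]
    k = n_components if n_components is not None else min(n - 2, 10)
    k = max(1, min(k, n - 1, x.shape[1]))
    center = x.mean(axis=0)
    xc = x - center
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    basis = vt[:k].T
    z = xc @ basis
    y = np.array([classes.index(l) for l in labels])
    means = np.stack([z[y == c].mean(axis=0) for c in (0, 1)])
    sw = np.zeros((k, k))
    for c in (0, 1):
        d = z[y == c] - means[c]
        sw += d.T @ d
    sw /= max(n - 2, 1)
    sw = (1.0 - shrinkage) * sw + shrinkage * (np.trace(sw) / k) * np.eye(k)
    direction = np.linalg.solve(sw, means[1] - means[0])
    threshold = float(direction @ (means[0] + means[1]) / 2.0)
    return LdaModel(classes=classes, center=center, basis=basis,
                    class_means=means, direction=direction, threshold=threshold)


def lda_train_predict(train: FeatureMatrix, labels, test: FeatureMatrix | None = None,
                      n_components: int | None = None, shrinkage: float = 0.1,
                      ) -> tuple[list[str], float]:
    """Train shrinkage LDA, predict test labels, report LOO accuracy.

    Returns (predicted labels for the test set, leave-one-out training
    accuracy). LOO refits the model with each training sample held out.
    """
    labels = list(labels)
    if len(labels) != len(train.samples):
        raise ValueError("labels must align with training samples")
    if test is not None and not (
            test.windows.reset_index(drop=True)
            .equals(train.windows.reset_index(drop=True))):
        raise ValueError("test feature columns do not match training columns")
    model = _fit_lda(train.values, labels, n_components, shrinkage)
    predictions = model.predict(test.values) if test is not None else []
    correct = 0
    n = len(labels)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        sub_labels = [labels[j] for j in keep]
        if len(set(sub_labels)) < 2:
            continue
        m = _fit_lda(train.values[keep], sub_labels, n_components, shrinkage)
        if m.predict(train.values[i:i + 1])[0] == labels[i]:
            correct += 1
    return predictions, correct / n if n else 0.0
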