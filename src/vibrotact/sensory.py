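"""Semantic-differential panel analysis: subject clustering and PCA.

A sensory panel scores each material sample on a set of adjectives using
a seven-step unipolar scale.  Subjects differ systematically in how they
map sensation to words, so they are first grouped by Ward/Euclidean
hierarchical clustering on their full score vectors; a separate
correlation-matrix PCA per cluster (retaining components with eigenvalue
above one, the Kaiser criterion) then reduces the adjectives to a few
perceptual axes, and per-sample means of the component scores become the
regression targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

__all__ = [
    "SensoryPanel",
    "SubjectClusterer",
    "PanelPCA",
    "cluster_subjects",
    "run_pca",
    "sample_pc_scores",
]


@dataclass
class SensoryPanel:
    """Complete subject x sample x word score table, values in 1..7."""

    scores: pd.DataFrame  # long format: subject_id, sample_id, word, score
    subjects: tuple = field(init=False)
    samples: tuple = field(init=False)
    words: tuple = field(init=False)

    def __post_init__(self) -> None:
        required = {"subject_id", "sample_id", "word", "score"}
        missing = required - set(self.scores.columns)
        if missing:
            raise ValueError(f"panel table missing columns {sorted(missing)}")
        s = self.scores["score"]
        if s.isna().any():
            raise ValueError("panel has missing scores")
        if ((s < 1) | (s > 7)).any():
            raise ValueError("scores must lie in 1..7")
        self.subjects = tuple(pd.unique(self.scores["subject_id"]))
        self.samples = tuple(pd.unique(self.scores["sample_id"]))
        self.words = tuple(pd.unique(self.scores["word"]))
        expected = len(self.subjects) * len(self.samples) * len(self.words)
        cells = self.scores.set_index(["subject_id", "sample_id", "word"]).index
        if cells.has_duplicates or len(cells) != expected:
            raise ValueError("panel must have exactly one score per (subject, sample, word)")

    def subject_matrix(self) -> pd.DataFrame:
        """One row per subject: flattened (sample, word) scores."""
        wide = self.scores.pivot_table(
            index="subject_id", columns=["sample_id", "word"], values="score", sort=False
        )
        return wide.loc[list(self.subjects)]

    def observation_matrix(self, subjects=None) -> pd.DataFrame:
        """Rows = (subject, sample) observations, columns = words."""
        df = self.scores
        if subjects is not None:
            df = df[df["subject_id"].isin(set(subjects))]
        wide = df.pivot_table(
            index=["subject_id", "sample_id"], columns="word", values="score", sort=False
        )
        return wide[list(self.words)]

    @classmethod
    def from_csv(cls, path) -> "SensoryPanel":
        return cls(pd.read_csv(path))


class SubjectClusterer(ClusterMixin, BaseEstimator):
    """Ward/Euclidean agglomerative clustering of panel subjects.

    fit expects a :class:`SensoryPanel` (or a subjects x features array);
    labels are 0-based cluster ids at the cut giving ``n_clusters`` groups.
    """

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def fit(self, X, y=None) -> "SubjectClusterer":
        if isinstance(X, SensoryPanel):
            mat = X.subject_matrix()
            self.subject_ids_ = tuple(mat.index)
            data = mat.to_numpy(float)
        else:
            data = np.asarray(X, float)
            self.subject_ids_ = tuple(range(data.shape[0]))
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > data.shape[0]:
            raise ValueError(
                f"cannot cut {data.shape[0]} subjects into {self.n_clusters} clusters"
            )
        self.linkage_ = hierarchy.linkage(data, method="ward", metric="euclidean")
        raw = hierarchy.fcluster(self.linkage_, t=self.n_clusters, criterion="maxclust")
        # relabel clusters by first appearance for determinism
        order: dict[int, int] = {}
        labels = np.empty_like(raw)
        for i, r in enumerate(raw):
            order.setdefault(r, len(order))
            labels[i] = order[r]
        self.labels_ = labels
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def assignments(self) -> dict:
        return dict(zip(self.subject_ids_, self.labels_))


class PanelPCA(TransformerMixin, BaseEstimator):
    """Correlation-matrix PCA with Kaiser (eigenvalue > 1) retention.

    Observations are (subject, sample) rows, variables are words.  The
    correlation matrix is eigendecomposed; components with eigenvalue
    above 1 are kept, loadings are eigenvector * sqrt(eigenvalue), and
    each component's sign is fixed so its largest-|loading| word is
    positive.  ``transform`` returns standardized-variable component
    scores (variance of PC k equals its eigenvalue).
    """

    def __init__(self, eigenvalue_threshold: float = 1.0, min_components: int = 1):
        self.eigenvalue_threshold = eigenvalue_threshold
        self.min_components = min_components

    def fit(self, X, y=None) -> "PanelPCA":
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        data = X.to_numpy(float)
        sd = data.std(axis=0, ddof=1)
        zero = np.asarray(self.feature_names_in_)[sd == 0]
        if zero.size:
            raise ValueError(f"zero-variance word column(s): {list(zero)}")
        self.mean_ = data.mean(axis=0)
        self.scale_ = sd
        corr = np.corrcoef(data, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(corr)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        n_keep = max(int(np.sum(eigvals > self.eigenvalue_threshold)), self.min_components)
        vals, vecs = eigvals[:n_keep], eigvecs[:, :n_keep]
        loadings = vecs * np.sqrt(np.maximum(vals, 0.0))
        # sign convention: largest-|loading| word positive per component
        flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(n_keep)])
        flip[flip == 0] = 1.0
        self.eigenvalues_all_ = eigvals
        self.eigenvalues_ = vals
        self.components_ = (vecs * flip).T  # rows = components (unit eigenvectors)
        self.loadings_ = pd.DataFrame(
            loadings * flip,
            index=self.feature_names_in_,
            columns=[f"PC{i + 1}" for i in range(n_keep)],
        )
        self.contribution_ = 100.0 * vals / len(self.feature_names_in_)
        self.cumulative_contribution_ = np.cumsum(
            100.0 * eigvals / len(self.feature_names_in_)
        )[:n_keep]
        self.n_components_ = n_keep
        return self

    def transform(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        z = (X.to_numpy(float) - self.mean_) / self.scale_
        scores = z @ self.components_.T
        return pd.DataFrame(
            scores, index=X.index, columns=[f"PC{i + 1}" for i in range(self.n_components_)]
        )


def cluster_subjects(panel: SensoryPanel, k: int) -> SubjectClusterer:
    """Ward-cluster panel subjects into ``k`` groups; returns the fitted clusterer."""
    return SubjectClusterer(n_clusters=k).fit(panel)


def run_pca(panel: SensoryPanel, subject_subset=None, **kwargs) -> tuple[PanelPCA, pd.DataFrame]:
    """PCA over (subject, sample) observations of a subject subset.

    Returns the fitted :class:`PanelPCA` and the row scores indexed by
    (subject_id, sample_id).
    """
    if subject_subset is not None and len(subject_subset) == 0:
        raise ValueError("subject subset must be nonempty")
    obs = panel.observation_matrix(subject_subset)
    pca = PanelPCA(**kwargs).fit(obs)
    return pca, pca.transform(obs)


def sample_pc_scores(row_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean component scores (the regression targets)."""
    if "sample_id" not in row_scores.index.names:
        raise ValueError("row scores must be indexed by (subject_id, sample_id)")
    return row_scores.groupby(level="sample_id", sort=False).mean()
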