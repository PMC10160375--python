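"""PCA over the retained features, component selection by cumulative
contribution, composite weighting and CNN input assembly.

Features are z-scored before the eigendecomposition (correlation-matrix
PCA), matching the unit-norm loading constraint Σ_j e_ij² = 1.  Component
j's contribution is eigenvalue_j / Σ eigenvalues × 100 %; the retained
count k is the smallest cumulative contribution ≥ the threshold (default
87.7 %).  The composite weight of retained component i is its contribution
divided by the cumulative contribution of the retained set — the
normalization that reproduces the published composite-index coefficients
from the printed contribution column.

CNN inputs are built by stacking consecutive same-subject epochs' component
score vectors as columns of a fixed-size map (default 13 × 20), min-max
scaling each component row to [0, 1] and zero-padding the rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PCABasis:
    """Loadings, eigenvalues and variance contributions of a fitted PCA."""

    loadings: np.ndarray       # (z, z): row i = unit-norm loading vector e_i
    eigenvalues: np.ndarray    # (z,), descending
    contributions: np.ndarray  # (z,), percent of total variance
    cumulative: np.ndarray     # (z,), running sum of contributions
    feature_names: list[str]
    mean: np.ndarray           # per-feature mean used for standardization
    std: np.ndarray            # per-feature std (ddof=1)

    @property
    def z(self) -> int:
        return len(self.eigenvalues)

    def transform(self, X: pd.DataFrame | np.ndarray, k: int | None = None) -> np.ndarray:
        """Component scores of (possibly new) observations."""
        Xa = np.asarray(X, dtype=float)
        Xz = (Xa - self.mean) / self.std
        scores = Xz @ self.loadings.T
        return scores if k is None else scores[:, :k]

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Back-project scores to the standardized feature space."""
        scores = np.asarray(scores, dtype=float)
        return scores @ self.loadings[: scores.shape[1]]


def fit_pca(X: pd.DataFrame | np.ndarray) -> PCABasis:
    """Correlation-matrix PCA with a reproducible sign convention.

    Columns are z-scored (a constant column is an error, named); the
    correlation matrix is eigendecomposed, components sorted by decreasing
    eigenvalue, and each loading row oriented so its largest-magnitude
    entry is positive.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"X{j + 1}" for j in range(Xa.shape[1])]
    if Xa.ndim != 2 or Xa.shape[0] < 2 or Xa.shape[1] < 1:
        raise ValueError("PCA needs >= 2 rows and >= 1 column")
    mean = Xa.mean(axis=0)
    std = Xa.std(axis=0, ddof=1)
    dead = np.where(std == 0)[0]
    if dead.size:
        raise ValueError(f"constant column(s): {[names[j] for j in dead]}")
    Xz = (Xa - mean) / std
    corr = Xz.T @ Xz / (Xa.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    loadings = eigvecs[:, order].T  # rows = components
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1
    contributions = eigvals / eigvals.sum() * 100.0
    return PCABasis(
        loadings=loadings,
        eigenvalues=eigvals,
        contributions=contributions,
        cumulative=cumulative_contribution(contributions),
        feature_names=names,
        mean=mean,
        std=std,
    )


def cumulative_contribution(contributions: np.ndarray) -> np.ndarray:
    """Running sum of per-component contributions (%)."""
    c = np.asarray(contributions, dtype=float)
    if np.any(c < 0):
        raise ValueError("contributions must be non-negative")
    return np.cumsum(c)


def select_k(basis: PCABasis, threshold: float = 0.877) -> int:
    """Smallest k whose cumulative contribution reaches ``threshold``.

    ``threshold`` is a fraction in (0, 1]; 1.0 selects all components.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    target = threshold * 100.0
    reached = np.where(basis.cumulative >= target - 1e-9)[0]
    if reached.size == 0:
        raise ValueError(f"cumulative contribution never reaches {target:.3f}%")
    return int(reached[0]) + 1


def composite_weights(
    basis_or_contributions: PCABasis | np.ndarray, k: int
) -> np.ndarray:
    """Composite-index weights of the first k components.

    w_i = contribution_i / Σ_{j<=k} contribution_j, so the weights are
    positive, non-increasing and sum to 1.
    """
    if isinstance(basis_or_contributions, PCABasis):
        c = basis_or_contributions.contributions
    else:
        c = np.asarray(basis_or_contributions, dtype=float)
    if not 1 <= k <= len(c):
        raise ValueError(f"k must be in [1, {len(c)}]")
    head = c[:k]
    total = head.sum()
    if total <= 0:
        raise ValueError("retained contributions sum to zero")
    return head / total


def build_cnn_inputs(
    scores: np.ndarray,
    subject_ids: np.ndarray,
    groups: np.ndarray,
    shape: tuple[int, int] = (13, 20),
    stack: int = 20,
    stride: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble 2-D classifier input maps from per-epoch component scores.

    Consecutive same-subject epochs (``stack`` of them, advancing by
    ``stride``, default non-overlapping) become the columns of a
    ``shape``-sized map: rows 0..k-1 hold the k component scores.  Each
    component (channel) is min-max scaled to [0, 1] using its range over
    the whole score matrix, so between-sample level differences survive;
    all remaining cells are zero.  The sample label is the subject's group
    (1 = low SA).

    Returns ``(maps, labels, sample_subjects)`` with ``maps`` of shape
    (n_samples, *shape).
    """
    scores = np.asarray(scores, dtype=float)
    subject_ids = np.asarray(subject_ids)
    groups = np.asarray(groups)
    if scores.ndim != 2:
        raise ValueError("scores must be 2-D (epochs x components)")
    k = scores.shape[1]
    rows, cols = shape
    if k > rows or stack > cols:
        raise ValueError(f"shape {shape} smaller than (k={k}, stack={stack})")
    if stride is None:
        stride = stack
    if stride < 1:
        raise ValueError("stride must be >= 1")
    lo = scores.min(axis=0)
    span = scores.max(axis=0) - lo
    span[span == 0] = 1.0
    scaled = (scores - lo) / span
    maps: list[np.ndarray] = []
    labels: list[int] = []
    subjects: list[str] = []
    for sid in pd.unique(subject_ids):
        idx = np.where(subject_ids == sid)[0]
        grp = groups[idx[0]]
        label = 1 if grp == "low" else 0
        for start in range(0, len(idx) - stack + 1, stride):
            block = scaled[idx[start : start + stack]]  # (stack, k)
            m = np.zeros(shape)
            m[:k, :stack] = block.T
            maps.append(m)
            labels.append(label)
            subjects.append(str(sid))
    if not maps:
        raise ValueError("not enough epochs per subject to form one stack")
    return np.stack(maps), np.array(labels), np.array(subjects)
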