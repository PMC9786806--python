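"""Grouping of mother trees by reproductive profile.

The profile matrix (trees x seed-category percentages) is reduced two ways,
mirroring common community-ecology practice: detrended correspondence
analysis (DCA) of the raw percentage matrix, and Ward hierarchical
clustering of Bray-Curtis dissimilarities computed on the
percent-of-column-maximum transformed matrix.

DCA is implemented from Hill's algorithm rather than wrapped: axis 1 is the
plain reciprocal-averaging (correspondence analysis) axis; higher axes are
extracted by power iteration with segment-wise detrending against each
lower axis (default 26 segments).  Optional rescaling expresses axes in
beta-diversity sd units via the mean within-site dispersion of column
scores.  Axis scores are defined up to sign; each axis is oriented so the
first row scores non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import ContractError


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix, dtype=float)
    return pd.DataFrame(arr)


def filter_abundant_categories(matrix, min_count: float = 4) -> pd.DataFrame:
    """Keep columns whose total count is at least ``min_count`` (inclusive)."""
    df = _as_frame(matrix)
    keep = df.sum(axis=0) >= min_count
    return df.loc[:, keep]


def percent_max_transform(matrix) -> pd.DataFrame:
    """Divide every column by its maximum; output lies in [0, 1] with each
    column maximum exactly 1.  All-zero columns are a contract error (they
    should have been filtered)."""
    df = _as_frame(matrix).astype(float)
    if (df.values < 0).any():
        raise ContractError("matrix must be non-negative")
    col_max = df.max(axis=0)
    if (col_max <= 0).any():
        bad = list(df.columns[col_max <= 0])
        raise ContractError(f"all-zero columns cannot be percent-max transformed: {bad}")
    return df / col_max


def bray_curtis(matrix) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between rows:
    d(i,j) = sum|x_ik - x_jk| / sum(x_ik + x_jk).  Two all-zero rows get 0."""
    df = _as_frame(matrix).astype(float)
    if (df.values < 0).any():
        raise ContractError("Bray-Curtis requires non-negative input")
    x = df.values
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=df.index, columns=df.index)


@dataclass(frozen=True)
class ClusteringResult:
    """Ward merge tree with heights, k-cut labels and leaf order."""

    linkage_matrix: np.ndarray  # scipy format, heights in column 2
    labels: pd.Series  # group assignment, 1..k
    k: int

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def cophenetic_order(self) -> list:
        return [self.labels.index[i] for i in leaves_list(self.linkage_matrix)]


def ward_cluster(dissimilarity, k: int = 2) -> ClusteringResult:
    """Agglomerate under Ward's minimum-variance criterion and cut at k.

    Accepts a square symmetric dissimilarity (DataFrame or array).  The
    scipy implementation is deterministic; ties break on the smaller
    row index.  Ward's Lance-Williams update is reducible, so merge heights
    are monotone non-decreasing.
    """
    d = _as_frame(dissimilarity)
    if d.shape[0] != d.shape[1]:
        raise ContractError("dissimilarity must be square")
    if d.shape[0] < 2:
        raise ContractError("need at least two rows to cluster")
    condensed = squareform(d.values, checks=False)
    z = linkage(condensed, method="ward")
    labels = pd.Series(fcluster(z, t=k, criterion="maxclust"), index=d.index)
    return ClusteringResult(z, labels, k)


@dataclass(frozen=True)
class OrdinationResult:
    """Row and column scores on >= 2 DCA axes, plus axis diagnostics."""

    row_scores: pd.DataFrame  # trees x axes
    col_scores: pd.DataFrame  # categories x axes
    eigenvalues: np.ndarray
    axis_lengths: np.ndarray  # in sd units when rescaled


def _detrend_by_segments(x: np.ndarray, against: np.ndarray, r: np.ndarray, n_segments: int) -> np.ndarray:
    """Remove the segment-wise weighted mean of ``x`` along ``against``."""
    lo, hi = against.min(), against.max()
    if hi - lo <= 0:
        return x - np.average(x, weights=r)
    edges = np.linspace(lo, hi, n_segments + 1)
    seg = np.clip(np.digitize(against, edges[1:-1]), 0, n_segments - 1)
    out = x.copy()
    for s in range(n_segments):
        mask = seg == s
        if mask.any():
            out[mask] -= np.average(x[mask], weights=r[mask])
    return out


def dca(
    matrix,
    n_segments: int = 26,
    rescale: bool = True,
    n_axes: int = 2,
    max_iter: int = 300,
    tol: float = 1e-10,
) -> OrdinationResult:
    """Detrended correspondence analysis of a non-negative matrix.

    Reciprocal averaging by power iteration; the trivial constant axis is
    removed by weighted centring each step.  Axes after the first are
    detrended against every lower axis by ``n_segments`` segments each
    iteration.  With ``rescale`` the scores are divided by the root mean
    within-site dispersion of column scores so axis lengths read in sd
    units of compositional turnover.
    """
    df = _as_frame(matrix).astype(float)
    y = df.values
    if (y < 0).any():
        raise ContractError("DCA requires a non-negative matrix")
    if y.shape[0] < 3 or y.shape[1] < 3:
        raise ContractError(
            f"DCA needs >= 3 rows and columns, got {y.shape[0]}x{y.shape[1]}"
        )
    r = y.sum(axis=1)
    c = y.sum(axis=0)
    if (r <= 0).any() or (c <= 0).any():
        raise ContractError("DCA input has empty rows or columns")
    if np.linalg.matrix_rank(y - np.outer(r, c) / y.sum()) < 2:
        raise ContractError("matrix is degenerate (rank < 2) — no meaningful ordination")

    rng = np.random.default_rng(0)  # fixed: ordination must be deterministic
    axes, eigs = [], []
    for k in range(n_axes):
        x = rng.standard_normal(y.shape[0])
        x -= np.average(x, weights=r)
        prev = None
        eig = 0.0
        for _ in range(max_iter):
            u = (y.T @ x) / c
            x_new = (y @ u) / r
            x_new -= np.average(x_new, weights=r)
            for axis in axes[:k]:
                if k > 0:
                    x_new = _detrend_by_segments(x_new, axis, r, n_segments)
                    x_new -= np.average(x_new, weights=r)
            norm = np.sqrt(np.average(x_new**2, weights=r))
            if norm == 0:
                break
            eig = norm
            x = x_new / norm
            if prev is not None and np.max(np.abs(x - prev)) < tol:
                break
            prev = x
        axes.append(x)
        eigs.append(eig)

    row = np.column_stack(axes)
    # orient: first row non-negative on every axis
    sign = np.where(row[0] >= 0, 1.0, -1.0)
    row = row * sign
    col = ((y.T @ row) / c[:, None])

    if rescale:
        # mean within-site dispersion of column scores, per axis
        for a in range(row.shape[1]):
            disp = []
            for i in range(y.shape[0]):
                p = y[i] / r[i]
                mu = p @ col[:, a]
                disp.append(p @ (col[:, a] - mu) ** 2)
            scale = np.sqrt(np.average(disp, weights=r))
            if scale > 0:
                row[:, a] /= scale
                col[:, a] /= scale

    axis_cols = [f"DCA{i + 1}" for i in range(row.shape[1])]
    return OrdinationResult(
        row_scores=pd.DataFrame(row, index=df.index, columns=axis_cols),
        col_scores=pd.DataFrame(col, index=df.columns, columns=axis_cols),
        eigenvalues=np.asarray(eigs),
        axis_lengths=row.max(axis=0) - row.min(axis=0),
    )


def cluster_profiles(
    matrix, *, min_count: float = 4, k: int = 2, n_segments: int = 26
) -> tuple[pd.DataFrame, ClusteringResult, OrdinationResult | None]:
    """Full grouping pipeline: abundance filter, percent-max + Bray-Curtis +
    Ward for the clustering, DCA of the raw filtered matrix.  DCA is skipped
    (None) when the filtered matrix is too small or degenerate."""
    filtered = filter_abundant_categories(matrix, min_count=min_count)
    if filtered.shape[1] == 0:
        raise ContractError("no categories left after abundance filtering")
    transformed = percent_max_transform(filtered)
    clustering = ward_cluster(bray_curtis(transformed), k=k)
    try:
        ordination = dca(filtered, n_segments=n_segments)
    except ContractError:
        ordination = None
    return filtered, clustering, ordination
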