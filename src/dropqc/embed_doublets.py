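"""Doublet simulation/scoring and 2-D embeddings of retained cells.

Artificial doublets are built by summing the gene counts of random pairs of
observed cells. Observed and simulated cells are jointly normalized, log
transformed and projected by PCA; each cell's raw doublet score is the
fraction of simulated doublets among its k nearest neighbors, rescaled for
the simulated:observed ratio. The calling threshold is the minimum-density
point between the two modes of the simulated-score distribution (no cells
are flagged when that distribution is unimodal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

DEFAULT_KNN = 15
DEFAULT_PCA_DIMS = 30
DEFAULT_HVG = 2000


@dataclass
class DoubletResult:
    observed_scores: np.ndarray
    simulated_scores: np.ndarray
    threshold: float
    is_doublet: np.ndarray
    n_simulated: int
    seed: int
    parent_pairs: np.ndarray | None = None


@dataclass
class EmbeddingResult:
    coordinates_umap: np.ndarray | None
    coordinates_tsne: np.ndarray | None
    cell_indices: np.ndarray
    pipeline_params: dict[str, Any] = field(default_factory=dict)


def simulate_doublets(counts, n_simulated: int, seed: int = 0):
    """Sum random distinct pairs of rows; returns (matrix, parent pair array)."""
    n = counts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to simulate doublets")
    if n_simulated < 1:
        raise ValueError("n_simulated must be >= 1")
    rng = np.random.default_rng(seed)
    first = rng.integers(0, n, size=n_simulated)
    # offset in [1, n-1] guarantees a distinct partner
    second = (first + 1 + rng.integers(0, n - 1, size=n_simulated)) % n
    pairs = np.column_stack([first, second])
    simulated = counts[first] + counts[second]
    if sp.issparse(simulated):
        simulated = simulated.tocsr()
    return simulated, pairs


def _normalize_log(matrix, target: float) -> np.ndarray:
    dense = np.asarray(matrix.todense() if sp.issparse(matrix) else matrix, dtype=float)
    totals = dense.sum(axis=1)
    scale = np.where(totals > 0, target / np.maximum(totals, 1e-12), 0.0)
    return np.log1p(dense * scale[:, None])


def _joint_pca(observed, simulated, n_dims: int, seed: int) -> np.ndarray:
    from sklearn.decomposition import PCA

    obs_totals = np.asarray(observed.sum(axis=1)).ravel()
    target = float(np.median(obs_totals[obs_totals > 0])) if np.any(obs_totals > 0) else 1.0
    joint = np.vstack([_normalize_log(observed, target), _normalize_log(simulated, target)])
    n_dims = max(1, min(n_dims, joint.shape[0] - 1, joint.shape[1]))
    pca = PCA(n_components=n_dims, random_state=seed)
    return pca.fit_transform(joint)


def _bimodal_threshold(scores: np.ndarray) -> float | None:
    """Minimum-density point between the two dominant KDE modes, or None."""
    if scores.size < 4 or np.std(scores) < 1e-9:
        return None
    try:
        kde = gaussian_kde(scores)
    except np.linalg.LinAlgError:
        return None
    grid = np.linspace(0.0, 1.0, 512)
    density = kde(grid)
    # pad so modes sitting on the [0, 1] boundary register as peaks
    padded = np.concatenate(([density.min() - 1.0], density, [density.min() - 1.0]))
    peaks, _ = find_peaks(padded, prominence=0.05 * density.max())
    peaks -= 1
    if peaks.size < 2:
        return None
    top_two = np.sort(peaks[np.argsort(density[peaks])[-2:]])
    between = slice(top_two[0], top_two[1] + 1)
    return float(grid[between][np.argmin(density[between])])


def doublet_scores(
    observed,
    simulated,
    k: int = DEFAULT_KNN,
    embedding_dims: int = DEFAULT_PCA_DIMS,
    seed: int = 0,
) -> DoubletResult:
    """Score observed cells by the simulated fraction of their kNN neighborhood.

    The raw neighbor fraction q is rescaled to ``q / (q + r (1 - q))`` for the
    simulated:observed ratio r so that an unenriched neighborhood scores near
    the doublet prior regardless of how many doublets were simulated.
    """
    if observed.shape[1] != simulated.shape[1]:
        raise ValueError("observed and simulated matrices must share the gene axis")
    n_obs, n_sim = observed.shape[0], simulated.shape[0]
    n_joint = n_obs + n_sim
    if k < 1 or k >= n_joint:
        raise ValueError(f"k must be in [1, {n_joint - 1}]")

    from sklearn.neighbors import NearestNeighbors

    embedded = _joint_pca(observed, simulated, embedding_dims, seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedded)
    _, idx = nn.kneighbors(embedded)
    # drop self: remove own index when returned, else the farthest neighbor
    neighbor_rows = np.empty((n_joint, k), dtype=int)
    for i in range(n_joint):
        row = idx[i]
        row = row[row != i][:k] if np.any(row == i) else row[:k]
        neighbor_rows[i] = row

    is_sim = neighbor_rows >= n_obs
    q = is_sim.mean(axis=1)
    r = n_sim / n_obs
    scores = q / (q + r * (1.0 - q))

    observed_scores = scores[:n_obs]
    simulated_scores = scores[n_obs:]
    threshold = _bimodal_threshold(simulated_scores)
    if threshold is None:
        warnings.warn(
            "simulated doublet score distribution is not bimodal; "
            "no cells flagged as doublets",
            stacklevel=2,
        )
        threshold = np.inf
    is_doublet = observed_scores > threshold
    return DoubletResult(
        observed_scores=observed_scores,
        simulated_scores=simulated_scores,
        threshold=float(threshold),
        is_doublet=is_doublet,
        n_simulated=n_sim,
        seed=seed,
    )


def embed_cells(
    counts,
    n_hvg: int = DEFAULT_HVG,
    n_pcs: int = DEFAULT_PCA_DIMS,
    n_neighbors: int = DEFAULT_KNN,
    seed: int = 0,
    doublet_exclude: np.ndarray | None = None,
    min_cells: int = 30,
) -> EmbeddingResult | None:
    """UMAP and t-SNE coordinates via the standard scanpy pipeline.

    Normalization to the median total, log1p, dispersion-based HVG selection,
    PCA, neighbors, then both embeddings with fixed seeds. Degenerate inputs
    (too few cells, too little structure) skip with a warning instead of
    failing the report.
    """
    matrix = counts.tocsr() if sp.issparse(counts) else sp.csr_matrix(np.asarray(counts))
    cell_indices = np.arange(matrix.shape[0])
    if doublet_exclude is not None:
        keep = ~np.asarray(doublet_exclude, dtype=bool)
        matrix = matrix[keep]
        cell_indices = cell_indices[keep]
    if matrix.shape[0] < min_cells:
        warnings.warn(
            f"only {matrix.shape[0]} cells (< {min_cells}); skipping embeddings",
            stacklevel=2,
        )
        return None

    try:
        import anndata as ad
        import scanpy as sc

        adata = ad.AnnData(X=matrix.astype(np.float32))
        sc.pp.normalize_total(adata)
        sc.pp.log1p(adata)
        n_top = min(n_hvg, adata.n_vars - 1)
        if n_top >= 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
            if adata.var["highly_variable"].sum() >= 2:
                adata = adata[:, adata.var["highly_variable"]].copy()
        n_comps = max(1, min(n_pcs, adata.n_obs - 1, adata.n_vars - 1))
        sc.pp.pca(adata, n_comps=n_comps, random_state=seed)
        sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, adata.n_obs - 1), random_state=seed)
        sc.tl.umap(adata, random_state=seed)
        sc.tl.tsne(adata, random_state=seed, n_pcs=n_comps)
        return EmbeddingResult(
            coordinates_umap=np.asarray(adata.obsm["X_umap"]),
            coordinates_tsne=np.asarray(adata.obsm["X_tsne"]),
            cell_indices=cell_indices,
            pipeline_params={
                "normalization": "median_total",
                "n_hvg": n_top,
                "n_pcs": n_comps,
                "n_neighbors": min(n_neighbors, adata.n_obs - 1),
                "seed": seed,
            },
        )
    except Exception as exc:  # noqa: BLE001 - embeddings must never crash the report
        warnings.warn(f"embedding pipeline failed ({exc}); skipping embeddings", stacklevel=2)
        return None
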