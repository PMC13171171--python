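"""Two-stage cell calling.

Stage one (OrdMag) estimates the expected number of high-quality cells from
the shape of the ranked UMI-count distribution: for each candidate cell number
c_e, the 99th-percentile UMI count m of the top c_e barcodes defines a dynamic
cutoff m/10, the observed count c_o is the number of barcodes strictly above
that cutoff, and the selected c_e minimizes (c_o - c_e)^2 / c_e. The top c_e
barcodes are retained outright and bypass stage two.

Stage two is an ambient-multinomial Monte-Carlo test in the style of
EmptyDrops: barcodes that are not OrdMag-retained and have at least
``umi_floor`` UMIs (default 500) are scored against a smoothed ambient
profile estimated from low-count barcodes; Monte-Carlo p-values are
BH-adjusted and barcodes below the FDR threshold are added to the retained
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln

__all__ = [
    "BarcodeRanking",
    "CallParams",
    "CellCalls",
    "EmptyDropsResult",
    "OrdMagResult",
    "bh_adjust",
    "call_cells",
    "default_candidate_grid",
    "estimate_ambient_profile",
    "montecarlo_pvalues",
    "multinomial_loglik",
    "observed_cell_count",
    "ordmag_call",
    "ordmag_loss",
    "percentile99",
    "rank_barcodes",
]

#: chemistry tags for which the stricter FDR threshold applies (configurable;
#: shipped empty — the mapping is not published, see package docs)
STRICT_FDR_CHEMISTRIES: frozenset[str] = frozenset()

DEFAULT_UMI_FLOOR = 500
DEFAULT_FDR = 0.01
STRICT_FDR = 0.001
DEFAULT_N_SIMULATIONS = 10_000
DEFAULT_GRID_POINTS = 2000


@dataclass
class BarcodeRanking:
    """Per-barcode total UMI counts in descending order plus the permutation."""

    counts: np.ndarray  # non-increasing totals
    order: np.ndarray  # sorted position -> original barcode index

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.order = np.asarray(self.order, dtype=int)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.counts))


@dataclass
class OrdMagResult:
    candidates: np.ndarray
    m_k: np.ndarray
    observed: np.ndarray
    losses: np.ndarray
    expected_cells: int
    retained_indices: np.ndarray  # original barcode indices, ranking prefix


@dataclass
class EmptyDropsResult:
    candidate_indices: np.ndarray
    log_likelihoods: np.ndarray
    p_values: np.ndarray
    fdr: np.ndarray
    threshold_used: float
    n_simulations: int
    seed: int

    @classmethod
    def empty(cls, threshold: float, n_simulations: int, seed: int) -> "EmptyDropsResult":
        z = np.zeros(0)
        return cls(np.zeros(0, dtype=int), z, z, z, threshold, n_simulations, seed)


@dataclass
class CallParams:
    """Tunable parameters of :func:`call_cells`."""

    umi_floor: int = DEFAULT_UMI_FLOOR
    fdr_threshold: float | None = None  # None -> resolved from chemistry
    grid_points: int = DEFAULT_GRID_POINTS
    ambient_max: int | None = None  # None -> min(100, umi_floor // 5)
    pseudocount: float = 0.5
    n_simulations: int = DEFAULT_N_SIMULATIONS
    seed: int = 0
    chemistry: str | None = None

    def resolve_ambient_max(self) -> int:
        if self.ambient_max is not None:
            return self.ambient_max
        return min(100, self.umi_floor // 5)

    def resolve_fdr(self, chemistry: str | None = None) -> float:
        if self.fdr_threshold is not None:
            return self.fdr_threshold
        chem = self.chemistry if self.chemistry is not None else chemistry
        if chem is not None and chem in STRICT_FDR_CHEMISTRIES:
            return STRICT_FDR
        return DEFAULT_FDR

    def to_uns_dict(self) -> dict[str, Any]:
        return {
            "umi_floor": self.umi_floor,
            "fdr_threshold": -1.0 if self.fdr_threshold is None else self.fdr_threshold,
            "grid_points": self.grid_points,
            "ambient_max": self.resolve_ambient_max(),
            "pseudocount": self.pseudocount,
            "n_simulations": self.n_simulations,
            "seed": self.seed,
            "chemistry": self.chemistry or "",
        }


@dataclass
class CellCalls:
    ordmag: OrdMagResult
    emptydrops: EmptyDropsResult
    retained: set[int]
    parameters: CallParams = field(default_factory=CallParams)

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def rank_barcodes(bundle) -> BarcodeRanking:
    """Sort barcodes by total UMI count, descending, ties in original order."""
    totals = np.asarray(bundle.counts_total.sum(axis=1)).ravel().astype(np.int64)
    if totals.size == 0 or totals.max(initial=0) == 0:
        raise ValueError("no counted barcodes: all totals are zero")
    order = np.argsort(-totals, kind="stable")
    return BarcodeRanking(counts=totals[order], order=order)


def percentile99(top_counts) -> float:
    """99th percentile with linear interpolation between order statistics."""
    arr = np.asarray(top_counts, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile99 of empty list")
    return float(np.percentile(arr, 99, method="linear"))


def observed_cell_count(ranking: BarcodeRanking, m_k: float) -> int:
    """Number of barcodes with total UMIs strictly greater than m_k / 10."""
    if m_k < 0:
        raise ValueError("m_k must be non-negative")
    cutoff = m_k / 10.0
    # counts descending: searchsorted on the negated (ascending) array gives
    # the count of entries strictly above the cutoff
    return int(np.searchsorted(-ranking.counts, -cutoff, side="left"))


def ordmag_loss(c_obs: float, c_exp: float) -> float:
    """Squared relative deviation (c_obs - c_exp)^2 / c_exp."""
    if c_exp < 1:
        raise ValueError("candidate cell count must be >= 1")
    return (c_obs - c_exp) ** 2 / c_exp


def default_candidate_grid(n_nonzero: int, points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Deduplicated geometric grid round(10^x), x in [0, log10(n_nonzero)]."""
    if n_nonzero < 1:
        raise ValueError("need at least one nonzero barcode")
    x = np.linspace(0.0, np.log10(n_nonzero), points)
    grid = np.unique(np.round(10.0**x).astype(np.int64))
    return grid[(grid >= 1) & (grid <= n_nonzero)]


def ordmag_call(
    ranking: BarcodeRanking,
    grid: np.ndarray | None = None,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> OrdMagResult:
    """Evaluate the loss over the candidate grid and retain the top barcodes.

    Ties in the loss go to the smallest candidate. When no explicit grid is
    given, the geometric grid is refined with every integer between the two
    grid neighbors of the coarse argmin, so the selected candidate is the
    exact integer minimizer within that basin (the geometric grid alone has
    integer gaps above ~250 candidates).
    """
    n_nonzero = ranking.n_nonzero
    if n_nonzero == 0:
        raise ValueError("no counted barcodes")
    refine = grid is None
    if grid is None:
        grid = default_candidate_grid(n_nonzero, grid_points)
    grid = np.unique(np.asarray(grid, dtype=np.int64))
    grid = grid[(grid >= 1) & (grid <= n_nonzero)]
    if grid.size == 0:
        raise ValueError("candidate grid empty after clipping to nonzero barcodes")
    if refine and grid.size >= 2:
        coarse = _evaluate_grid(ranking, grid)
        best = int(np.argmin(coarse[2]))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, grid.size - 1)]
        grid = np.unique(np.concatenate([grid, np.arange(lo, hi + 1, dtype=np.int64)]))

    m_k, observed, losses = _evaluate_grid(ranking, grid)
    best = int(np.argmin(losses))  # grid ascending -> first minimum = smallest candidate
    expected_cells = int(grid[best])
    return OrdMagResult(
        candidates=grid,
        m_k=m_k,
        observed=observed,
        losses=losses,
        expected_cells=expected_cells,
        retained_indices=ranking.order[:expected_cells].copy(),
    )


def _evaluate_grid(ranking: BarcodeRanking, grid: np.ndarray):
    m_k = np.empty(grid.size)
    observed = np.empty(grid.size, dtype=np.int64)
    losses = np.empty(grid.size)
    for i, c_exp in enumerate(grid):
        m = percentile99(ranking.counts[:c_exp])
        m_k[i] = m
        observed[i] = observed_cell_count(ranking, m)
        losses[i] = ordmag_loss(observed[i], c_exp)
    return m_k, observed, losses


def estimate_ambient_profile(bundle, pool, pseudocount: float = 0.5) -> np.ndarray:
    """Normalized pooled gene counts over the pool, with a pseudocount per gene."""
    pool = np.asarray(sorted(pool), dtype=int)
    if pool.size == 0:
        raise ValueError("cannot estimate ambient profile from an empty pool")
    pooled = np.asarray(bundle.counts_total[pool].sum(axis=0)).ravel().astype(float)
    if pooled.sum() == 0 and pseudocount == 0:
        raise ValueError("cannot estimate ambient profile: pool has zero total counts")
    smoothed = pooled + pseudocount
    return smoothed / smoothed.sum()


def multinomial_loglik(barcode_counts, profile) -> np.ndarray | float:
    """Multinomial log-PMF of count vector(s) under ``profile`` (log-gamma form).

    Accepts a single count vector or a 2-D stack of them; the total of each
    vector is taken as its own multinomial size parameter.
    """
    x = np.asarray(barcode_counts, dtype=float)
    p = np.asarray(profile, dtype=float)
    if x.shape[-1] != p.shape[0]:
        raise ValueError(f"count vector length {x.shape[-1]} != profile length {p.shape[0]}")
    if np.any(p <= 0):
        raise ValueError("profile must be strictly positive")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("profile must sum to 1")
    n = x.sum(axis=-1)
    ll = gammaln(n + 1) - gammaln(x + 1).sum(axis=-1) + (x * np.log(p)).sum(axis=-1)
    return float(ll) if ll.ndim == 0 else ll


def montecarlo_pvalues(
    candidates,
    profile,
    n_simulations: int = DEFAULT_N_SIMULATIONS,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo p-values for candidate count vectors under the ambient profile.

    Candidates are binned by exact total T; for each T, ``n_simulations``
    multinomial draws of size T are scored and each candidate gets
    ``p = (1 + #{simulated loglik <= observed loglik}) / (1 + n_simulations)``.
    Deterministic given ``seed``; invariant to candidate ordering and to the
    presence of other candidates (each total gets its own seeded stream).
    """
    if n_simulations < 1:
        raise ValueError("n_simulations must be >= 1")
    if sp.issparse(candidates):
        candidates = np.asarray(candidates.todense())
    x = np.asarray(candidates, dtype=np.int64)
    if x.ndim == 1:
        x = x[None, :]
    p = np.asarray(profile, dtype=float)

    obs_ll = np.atleast_1d(multinomial_loglik(x, p))
    totals = x.sum(axis=1)
    pvals = np.empty(x.shape[0])
    for total in np.unique(totals):
        # independent stream per total: p-values do not depend on which other
        # totals happen to be in the candidate set
        rng = np.random.default_rng((seed, int(total)))
        sims = rng.multinomial(int(total), p, size=n_simulations)
        sim_ll = multinomial_loglik(sims, p)
        members = np.flatnonzero(totals == total)
        for i in members:
            pvals[i] = (1 + int(np.count_nonzero(sim_ll <= obs_ll[i]))) / (1 + n_simulations)
    return pvals


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, clipped to 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_cells(bundle, params: CallParams | None = None) -> CellCalls:
    """Run the full two-stage calling algorithm on a loaded bundle."""
    params = params or CallParams()
    ranking = rank_barcodes(bundle)
    ordmag = ordmag_call(ranking, grid_points=params.grid_points)
    retained = set(int(i) for i in ordmag.retained_indices)

    totals = np.zeros(bundle.n_barcodes, dtype=np.int64)
    totals[ranking.order] = ranking.counts
    is_ordmag = np.zeros(bundle.n_barcodes, dtype=bool)
    is_ordmag[ordmag.retained_indices] = True

    candidate_idx = np.flatnonzero(~is_ordmag & (totals >= params.umi_floor))
    fdr_threshold = params.resolve_fdr(bundle.log_meta.chemistry)
    seed = params.seed
    n_sims = params.n_simulations

    if candidate_idx.size == 0:
        emptydrops = EmptyDropsResult.empty(fdr_threshold, n_sims, seed)
        return CellCalls(ordmag, emptydrops, retained, params)

    ambient_max = params.resolve_ambient_max()
    pool_mask = ~is_ordmag & (totals >= 1) & (totals <= ambient_max)
    pool = np.flatnonzero(pool_mask)
    if pool.size == 0:
        # widen to anything sub-floor that is neither retained nor a candidate
        is_candidate = np.zeros(bundle.n_barcodes, dtype=bool)
        is_candidate[candidate_idx] = True
        pool = np.flatnonzero(~is_ordmag & ~is_candidate & (totals >= 1) & (totals < params.umi_floor))
    if pool.size == 0:
        warnings.warn(
            "no barcodes available for the ambient pool; skipping the ambient "
            "multinomial test and retaining only the OrdMag set",
            stacklevel=2,
        )
        emptydrops = EmptyDropsResult.empty(fdr_threshold, n_sims, seed)
        return CellCalls(ordmag, emptydrops, retained, params)

    profile = estimate_ambient_profile(bundle, pool, pseudocount=params.pseudocount)
    cand_counts = np.asarray(bundle.counts_total[candidate_idx].todense())
    loglik = np.atleast_1d(multinomial_loglik(cand_counts, profile))
    pvals = montecarlo_pvalues(cand_counts, profile, n_simulations=n_sims, seed=seed)
    fdr = bh_adjust(pvals)

    retained |= set(int(i) for i in candidate_idx[fdr <= fdr_threshold])
    emptydrops = EmptyDropsResult(
        candidate_indices=candidate_idx,
        log_likelihoods=loglik,
        p_values=pvals,
        fdr=fdr,
        threshold_used=fdr_threshold,
        n_simulations=n_sims,
        seed=seed,
    )
    return CellCalls(ordmag, emptydrops, retained, params)
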