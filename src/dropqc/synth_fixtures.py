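"""Synthetic quantification experiments with planted ground truth.

Generates sparse count matrices that reproduce the input regimes the QC
pipeline must handle — a deep true-cell population, a shallow ambient
background, optional doublets, splice-aware S/U/A layers and mitochondrial
genes — and writes them out as a loadable quantification directory
(MatrixMarket + barcode/feature lists + JSON step logs) whose planted
parameters are saved alongside for test harnesses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite

from dropqc.io_quant import AMBIGUOUS_SUFFIX, UNSPLICED_SUFFIX, QuantBundle, parse_logs


@dataclass
class SyntheticTruth:
    """Planted parameters of a simulated experiment."""

    n_true_cells: int = 100
    n_ambient: int = 1000
    n_genes: int = 50
    cell_depth_logmean: float = math.log(5000.0)
    cell_depth_logsigma: float = 0.25
    ambient_depth_range: tuple[int, int] = (1, 50)
    usa_fractions: tuple[float, float, float] | None = None  # (S, U, A)
    n_doublets: int = 0
    n_mito_genes: int = 0
    reads_per_umi: float = 2.0
    mapping_rate: float = 0.9
    chemistry: str = "synthetic_v1"
    seed: int = 0
    # filled by simulate_experiment
    cell_profile: np.ndarray | None = None
    ambient_profile: np.ndarray | None = None
    true_cell_indices: np.ndarray | None = None
    ambient_indices: np.ndarray | None = None
    doublet_indices: np.ndarray | None = None
    doublet_pairs: np.ndarray | None = field(default=None, repr=False)
    mito_gene_indices: np.ndarray | None = None

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.n_true_cells < 0 or self.n_ambient < 0:
            raise ValueError("population sizes must be non-negative")
        if self.n_true_cells + self.n_ambient < 1:
            raise ValueError("experiment must contain at least one barcode")
        if self.usa_fractions is not None:
            if abs(sum(self.usa_fractions) - 1.0) > 1e-9 or min(self.usa_fractions) < 0:
                raise ValueError("usa_fractions must be a point on the simplex")
        if self.n_doublets > 0 and self.n_true_cells < 2:
            raise ValueError("doublets need at least two true cells")
        if not 0 < self.mapping_rate <= 1:
            raise ValueError("mapping_rate must be in (0, 1]")
        if self.reads_per_umi < 1:
            raise ValueError("reads_per_umi must be >= 1")
        if self.n_mito_genes > self.n_genes:
            raise ValueError("more mitochondrial genes than genes")


def _barcode(i: int) -> str:
    return f"BC{i:06d}"


def simulate_experiment(truth: SyntheticTruth) -> tuple[QuantBundle, SyntheticTruth]:
    """Draw a planted experiment; deterministic given ``truth.seed``.

    True cells draw totals log-normally and gene vectors multinomially from a
    shared cell profile; ambient barcodes draw shallow totals uniformly on a
    log scale from a distinct ambient profile; doublets are sums of parent
    cell pairs; per-UMI S/U/A labels produce the three layers.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    g = truth.n_genes

    cell_profile = rng.dirichlet(np.full(g, 0.6))
    ambient_profile = rng.dirichlet(np.full(g, 2.0))
    truth.cell_profile = cell_profile
    truth.ambient_profile = ambient_profile

    rows = []
    # true cells
    depths = np.maximum(
        1, rng.lognormal(truth.cell_depth_logmean, truth.cell_depth_logsigma, truth.n_true_cells).astype(int)
    )
    for depth in depths:
        rows.append(rng.multinomial(depth, cell_profile))
    # doublets: sums of two distinct true cells
    doublet_pairs = np.zeros((0, 2), dtype=int)
    if truth.n_doublets > 0:
        first = rng.integers(0, truth.n_true_cells, truth.n_doublets)
        second = (first + 1 + rng.integers(0, truth.n_true_cells - 1, truth.n_doublets)) % truth.n_true_cells
        doublet_pairs = np.column_stack([first, second])
        for a, b in doublet_pairs:
            rows.append(rows[a] + rows[b])
    # ambient barcodes: uniform-log shallow depths
    lo, hi = truth.ambient_depth_range
    if truth.n_ambient > 0:
        amb_depths = np.round(
            np.exp(rng.uniform(math.log(max(lo, 1)), math.log(max(hi, 1)), truth.n_ambient))
        ).astype(int)
        amb_depths = np.maximum(amb_depths, 1)
        for depth in amb_depths:
            rows.append(rng.multinomial(depth, ambient_profile))

    matrix = sp.csr_matrix(np.asarray(rows, dtype=np.int64))
    n = matrix.shape[0]
    perm = rng.permutation(n)  # shuffle so loaders cannot rely on block order
    matrix = matrix[perm]
    position = np.empty(n, dtype=int)
    position[perm] = np.arange(n)

    n_cells = truth.n_true_cells
    n_doub = truth.n_doublets
    truth.true_cell_indices = np.sort(position[:n_cells])
    truth.doublet_indices = np.sort(position[n_cells : n_cells + n_doub])
    truth.ambient_indices = np.sort(position[n_cells + n_doub :])
    truth.doublet_pairs = doublet_pairs

    mito_idx = np.arange(truth.n_mito_genes)
    truth.mito_gene_indices = mito_idx
    genes = [f"G{j:05d}" for j in range(g)]
    symbols = [f"MT-{j}" if j < truth.n_mito_genes else f"SYM{j:05d}" for j in range(g)]
    barcodes = [_barcode(i) for i in range(n)]

    layer_s = layer_u = layer_a = None
    counts_total = matrix
    if truth.usa_fractions is not None:
        s_frac, u_frac, a_frac = truth.usa_fractions
        coo = matrix.tocoo()
        splits = rng.multinomial(coo.data.astype(np.int64), [s_frac, u_frac, a_frac])
        s_data, u_data, a_data = splits[:, 0], splits[:, 1], splits[:, 2]
        shape = matrix.shape
        layer_s = sp.csr_matrix((s_data, (coo.row, coo.col)), shape=shape)
        layer_u = sp.csr_matrix((u_data, (coo.row, coo.col)), shape=shape)
        layer_a = sp.csr_matrix((a_data, (coo.row, coo.col)), shape=shape)
        counts_total = (layer_s + layer_u + layer_a).tocsr()

    bundle = QuantBundle(
        counts_total=counts_total,
        barcodes=barcodes,
        genes=genes,
        layer_S=layer_s,
        layer_U=layer_u,
        layer_A=layer_a,
        gene_symbols=symbols,
    )
    bundle.validate()
    return bundle, truth


def write_fixture_dir(bundle: QuantBundle, truth: SyntheticTruth, path: str | Path) -> Path:
    """Write a loadable quantification directory plus the planted truth.

    Layers are stacked back into the USA feature convention when present.
    Synthetic step logs are derived so that the planted mapping rate and
    reads-per-UMI (hence saturation) round-trip through the log parser:
    mapped reads = ceil(total UMIs * reads_per_umi), processed = mapped / rate.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    if bundle.has_usa_layers:
        stacked = sp.hstack([bundle.layer_S, bundle.layer_U, bundle.layer_A]).tocsr()
        features = (
            list(bundle.genes)
            + [g + UNSPLICED_SUFFIX for g in bundle.genes]
            + [g + AMBIGUOUS_SUFFIX for g in bundle.genes]
        )
        symbols = (bundle.gene_symbols or bundle.genes) * 3
    else:
        stacked = bundle.counts_total
        features = list(bundle.genes)
        symbols = list(bundle.gene_symbols or bundle.genes)

    mmwrite(out / "matrix.mtx", stacked.tocoo(), field="integer")
    (out / "barcodes.txt").write_text("\n".join(bundle.barcodes) + "\n")
    (out / "features.txt").write_text(
        "\n".join(f"{f}\t{s}" for f, s in zip(features, symbols)) + "\n"
    )

    total_umis = int(bundle.counts_total.sum())
    mapped = math.ceil(total_umis * truth.reads_per_umi)
    processed = math.ceil(mapped / truth.mapping_rate)
    permit_log = {
        "num_reads": processed,
        "num_corrected_barcodes": bundle.n_barcodes,
        "chemistry": truth.chemistry,
        "version": "synthetic-0.1",
        "cmd": "dropqc simulate",
    }
    quant_log = {
        "num_mapped_reads": mapped,
        "num_processed_reads": processed,
        "num_quantified_reads": mapped,
        "version": "synthetic-0.1",
    }
    (out / "generate_permit_list.json").write_text(json.dumps(permit_log, indent=2))
    (out / "quant.json").write_text(json.dumps(quant_log, indent=2))

    truth_record = {
        "n_true_cells": truth.n_true_cells,
        "n_ambient": truth.n_ambient,
        "n_genes": truth.n_genes,
        "n_doublets": truth.n_doublets,
        "seed": truth.seed,
        "usa_fractions": list(truth.usa_fractions) if truth.usa_fractions else None,
        "reads_per_umi": truth.reads_per_umi,
        "mapping_rate": truth.mapping_rate,
        "true_cell_indices": _as_list(truth.true_cell_indices),
        "ambient_indices": _as_list(truth.ambient_indices),
        "doublet_indices": _as_list(truth.doublet_indices),
        "mito_gene_indices": _as_list(truth.mito_gene_indices),
    }
    (out / "synthetic_truth.json").write_text(json.dumps(truth_record, indent=2))
    # smoke-check: logs written here must parse back
    parse_logs(out)
    return out


def _as_list(arr):
    return None if arr is None else [int(v) for v in arr]


def simulate_two_populations(
    n_per_pop: int = 150,
    n_genes: int = 60,
    depth: int = 3000,
    hybrid_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Two well-separated cell populations plus planted cross-population hybrids.

    Population A expresses the first half of the gene axis, population B the
    second half; hybrids are sums of one freshly drawn cell from each.
    Returns (counts, is_hybrid flag per row); rows are shuffled.
    """
    if n_genes < 2 or n_per_pop < 2:
        raise ValueError("need at least 2 genes and 2 cells per population")
    rng = np.random.default_rng(seed)
    half = n_genes // 2
    eps = 1e-4
    profile_a = np.full(n_genes, eps)
    profile_a[:half] += rng.dirichlet(np.full(half, 1.0))
    profile_a /= profile_a.sum()
    profile_b = np.full(n_genes, eps)
    profile_b[half:] += rng.dirichlet(np.full(n_genes - half, 1.0))
    profile_b /= profile_b.sum()
    # low-rank within-population variation so cells spread biologically, not
    # just by sampling noise (doublet neighborhoods stay realistic)
    loadings = rng.normal(0.0, 1.0, size=(3, n_genes))

    def draw_cell(base: np.ndarray) -> np.ndarray:
        z = rng.normal(size=3)
        profile = base * np.exp(z @ loadings)
        return rng.multinomial(depth, profile / profile.sum())

    rows = [draw_cell(profile_a) for _ in range(n_per_pop)]
    rows += [draw_cell(profile_b) for _ in range(n_per_pop)]
    n_hybrid = max(1, int(round(hybrid_fraction * 2 * n_per_pop)))
    for _ in range(n_hybrid):
        rows.append(draw_cell(profile_a) + draw_cell(profile_b))

    counts = np.asarray(rows, dtype=np.int64)
    is_hybrid = np.zeros(counts.shape[0], dtype=bool)
    is_hybrid[2 * n_per_pop :] = True
    perm = rng.permutation(counts.shape[0])
    return sp.csr_matrix(counts[perm]), is_hybrid[perm]
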