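"""Scalar and per-barcode QC statistics for the report and the H5AD export."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from dropqc.cell_calling import BarcodeRanking

MITO_PREFIXES = ("MT-", "mt-")


@dataclass
class QCSummary:
    """Scalar report metrics; ``None`` marks metrics unavailable without logs."""

    n_retained_cells: int
    n_processed_barcodes: int
    mean_reads_per_cell: float | None
    median_umis_per_cell: float | None
    median_genes_per_cell: float | None
    total_genes_detected: int
    sequencing_saturation: float | None
    mapping_rate: float | None

    def to_uns_dict(self) -> dict[str, Any]:
        def enc(v):
            return -1.0 if v is None else float(v)

        return {
            "n_retained_cells": self.n_retained_cells,
            "n_processed_barcodes": self.n_processed_barcodes,
            "mean_reads_per_cell": enc(self.mean_reads_per_cell),
            "median_umis_per_cell": enc(self.median_umis_per_cell),
            "median_genes_per_cell": enc(self.median_genes_per_cell),
            "total_genes_detected": self.total_genes_detected,
            "sequencing_saturation": enc(self.sequencing_saturation),
            "mapping_rate": enc(self.mapping_rate),
        }


def sequencing_saturation(n_mapped_reads: int, n_dedup_umis: int) -> float:
    """1 - unique UMIs / mapped reads; 0 for an empty library."""
    if n_mapped_reads < 0 or n_dedup_umis < 0:
        raise ValueError("read and UMI counts must be non-negative")
    if n_dedup_umis > n_mapped_reads:
        raise ValueError(
            f"deduplicated UMIs ({n_dedup_umis}) exceed mapped reads ({n_mapped_reads})"
        )
    if n_mapped_reads == 0:
        return 0.0
    return 1.0 - n_dedup_umis / n_mapped_reads


def spliced_ratio(S: float, U: float, A: float) -> float:
    """(S + A) / (S + U + A); ambiguous counts group with spliced."""
    if S < 0 or U < 0 or A < 0:
        raise ValueError("S, U, A must be non-negative")
    total = S + U + A
    if total == 0:
        raise ValueError("spliced ratio undefined for an all-zero triple")
    return (S + A) / total


def mito_fraction(barcode_counts, mito_gene_mask) -> float:
    """Fraction of UMIs on mitochondrial genes; 0 for an empty barcode."""
    counts = np.asarray(barcode_counts, dtype=float).ravel()
    mask = np.asarray(mito_gene_mask, dtype=bool).ravel()
    if counts.shape != mask.shape:
        raise ValueError("mitochondrial mask must align with the gene axis")
    total = counts.sum()
    if total == 0:
        return 0.0
    return float(counts[mask].sum() / total)


def mito_gene_mask(bundle, mito_genes: list[str] | None = None) -> np.ndarray:
    """Mask from symbol prefix MT-/mt- when symbols exist, else a user list."""
    if mito_genes is not None:
        wanted = set(mito_genes)
        return np.array(
            [g in wanted or (s is not None and s in wanted) for g, s in _gene_sym_pairs(bundle)],
            dtype=bool,
        )
    names = bundle.gene_symbols if bundle.gene_symbols is not None else bundle.genes
    return np.array([str(name).startswith(MITO_PREFIXES) for name in names], dtype=bool)


def _gene_sym_pairs(bundle):
    symbols = bundle.gene_symbols or [None] * bundle.n_genes
    return zip(bundle.genes, symbols)


def knee_curve(ranking: BarcodeRanking, values=None) -> tuple[np.ndarray, np.ndarray]:
    """Descending (rank, value) series, run-length compressed, zeros dropped.

    Consecutive equal values are collapsed to their segment endpoints so the
    series stays faithful on a log-log plot while being cheap to draw. Ranks
    are 1-based.
    """
    vals = ranking.counts if values is None else np.asarray(values)
    if vals.size == 0:
        raise ValueError("empty ranking")
    vals = vals[vals > 0]
    if vals.size == 0:
        return np.zeros(0, dtype=int), np.zeros(0)
    ranks = np.arange(1, vals.size + 1)
    keep = np.zeros(vals.size, dtype=bool)
    keep[0] = keep[-1] = True
    keep[1:] |= vals[1:] != vals[:-1]  # run starts
    keep[:-1] |= vals[:-1] != vals[1:]  # run ends
    return ranks[keep], vals[keep]


def per_barcode_qc(bundle, mito_genes: list[str] | None = None) -> pd.DataFrame:
    """Per-barcode totals, genes detected, spliced ratio, mito fraction, rank."""
    counts = bundle.counts_total.tocsr()
    totals = np.asarray(counts.sum(axis=1)).ravel().astype(np.int64)
    genes_detected = np.asarray((counts > 0).sum(axis=1)).ravel().astype(np.int64)

    mask = mito_gene_mask(bundle, mito_genes)
    if mask.any():
        mito_totals = np.asarray(counts[:, np.flatnonzero(mask)].sum(axis=1)).ravel()
    else:
        mito_totals = np.zeros(bundle.n_barcodes)
    with np.errstate(invalid="ignore"):
        mito = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)

    # rank 1 = deepest barcode; stable, matches rank_barcodes
    order = np.argsort(-totals, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, totals.size + 1)

    frame = pd.DataFrame(
        {
            "total_umis": totals,
            "genes_detected": genes_detected,
            "mito_fraction": mito,
            "rank": rank,
        },
        index=pd.Index(bundle.barcodes, name="barcode"),
    )
    if bundle.has_usa_layers:
        s = np.asarray(bundle.layer_S.sum(axis=1)).ravel()
        u = np.asarray(bundle.layer_U.sum(axis=1)).ravel()
        a = np.asarray(bundle.layer_A.sum(axis=1)).ravel()
        denom = s + u + a
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(denom > 0, (s + a) / np.maximum(denom, 1), np.nan)
        frame["spliced_ratio"] = ratio
    return frame


def summarize(bundle, calls, logs=None) -> QCSummary:
    """Assemble the scalar summary; medians are over retained cells only."""
    logs = logs if logs is not None else bundle.log_meta
    retained = np.asarray(sorted(calls.retained), dtype=int)
    n_retained = retained.size
    n_processed = bundle.n_barcodes
    if (
        logs.num_processed_barcodes is not None
        and logs.num_processed_barcodes != n_processed
    ):
        warnings.warn(
            f"matrix has {n_processed} barcodes but logs report "
            f"{logs.num_processed_barcodes} processed barcodes",
            stacklevel=2,
        )

    counts = bundle.counts_total.tocsr()
    totals = np.asarray(counts.sum(axis=1)).ravel()
    total_umis_all = int(totals.sum())

    if n_retained == 0:
        warnings.warn("zero retained cells: per-cell medians are unavailable", stacklevel=2)
        median_umis = median_genes = mean_reads = None
        total_genes = 0
    else:
        retained_counts = counts[retained]
        umis = np.asarray(retained_counts.sum(axis=1)).ravel()
        genes = np.asarray((retained_counts > 0).sum(axis=1)).ravel()
        median_umis = float(np.median(umis))
        median_genes = float(np.median(genes))
        total_genes = int(np.count_nonzero(np.asarray(retained_counts.sum(axis=0)).ravel()))
        mean_reads = (
            logs.num_processed_reads / n_retained
            if logs.num_processed_reads is not None
            else None
        )

    saturation = None
    if logs.num_mapped_reads is not None:
        if total_umis_all <= logs.num_mapped_reads:
            saturation = sequencing_saturation(logs.num_mapped_reads, total_umis_all)
        else:
            warnings.warn(
                "total UMIs exceed mapped reads in logs; saturation not computed",
                stacklevel=2,
            )
    mapping_rate = None
    if (
        logs.num_mapped_reads is not None
        and logs.num_processed_reads is not None
        and logs.num_processed_reads > 0
    ):
        mapping_rate = logs.num_mapped_reads / logs.num_processed_reads

    return QCSummary(
        n_retained_cells=n_retained,
        n_processed_barcodes=n_processed,
        mean_reads_per_cell=mean_reads,
        median_umis_per_cell=median_umis,
        median_genes_per_cell=median_genes,
        total_genes_detected=total_genes,
        sequencing_saturation=saturation,
        mapping_rate=mapping_rate,
    )
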