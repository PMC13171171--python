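"""Input/output for quantification directories and annotated H5AD files.

Loads a sparse UMI count matrix (MatrixMarket + barcode/feature text lists),
detects and collapses splice-aware USA-mode feature blocks into per-gene
S/U/A layers, parses the JSON logs of the quantification and permit-list
steps, and writes the final annotated H5AD output.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread

logger = logging.getLogger(__name__)

#: suffixes marking unspliced / ambiguous feature copies in USA-mode output
UNSPLICED_SUFFIX = "-U"
AMBIGUOUS_SUFFIX = "-A"

_PROCESSED_READ_KEYS = ("num_processed_reads", "num_processed", "num_reads", "total_reads")
_MAPPED_READ_KEYS = ("num_mapped_reads", "num_mapped", "mapped_reads")
_BARCODE_KEYS = (
    "num_processed_barcodes",
    "num_corrected_barcodes",
    "num_barcodes",
    "total_barcodes",
)
_CHEMISTRY_KEYS = ("chemistry", "chem")


class QuantLoadError(RuntimeError):
    """Fatal problem while loading quantification output."""


@dataclass
class LogSummary:
    """Recognized fields plus raw tables parsed from the step log files.

    Missing fields are ``None`` (explicitly absent), never zero.
    """

    num_processed_reads: int | None = None
    num_mapped_reads: int | None = None
    num_processed_barcodes: int | None = None
    tool_versions: dict[str, str] = field(default_factory=dict)
    command_arguments: dict[str, str] = field(default_factory=dict)
    chemistry: str | None = None
    raw_log_tables: dict[str, dict[str, Any]] = field(default_factory=dict)

    def validate(self) -> list[str]:
        """Return human-readable warnings for violated expectations."""
        problems = []
        if (
            self.num_processed_reads is not None
            and self.num_mapped_reads is not None
            and self.num_mapped_reads > self.num_processed_reads
        ):
            problems.append(
                f"num_mapped_reads ({self.num_mapped_reads}) exceeds "
                f"num_processed_reads ({self.num_processed_reads})"
            )
        return problems


@dataclass
class QuantBundle:
    """Sparse barcodes x genes count matrix with optional S/U/A layers.

    ``counts_total`` is the X layer (total UMIs). When splice-aware layers are
    present, ``counts_total == layer_S + layer_U + layer_A`` elementwise.
    """

    counts_total: sp.csr_matrix
    barcodes: list[str]
    genes: list[str]
    layer_S: sp.csr_matrix | None = None
    layer_U: sp.csr_matrix | None = None
    layer_A: sp.csr_matrix | None = None
    gene_symbols: list[str] | None = None
    log_meta: LogSummary = field(default_factory=LogSummary)

    @property
    def n_barcodes(self) -> int:
        return self.counts_total.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts_total.shape[1]

    @property
    def has_usa_layers(self) -> bool:
        return self.layer_S is not None and self.layer_U is not None and self.layer_A is not None

    def validate(self) -> None:
        n, g = self.counts_total.shape
        if len(self.barcodes) != n:
            raise QuantLoadError(
                f"barcode list length {len(self.barcodes)} != matrix rows {n}"
            )
        if len(self.genes) != g:
            raise QuantLoadError(f"gene list length {len(self.genes)} != matrix columns {g}")
        if self.counts_total.nnz and self.counts_total.data.min() < 0:
            raise QuantLoadError("negative counts in matrix")
        if self.has_usa_layers:
            for name, layer in (("S", self.layer_S), ("U", self.layer_U), ("A", self.layer_A)):
                if layer.shape != (n, g):
                    raise QuantLoadError(f"layer {name} shape {layer.shape} != {(n, g)}")
            total = self.layer_S + self.layer_U + self.layer_A
            if (self.counts_total - total).nnz != 0:
                raise QuantLoadError("counts_total != S + U + A")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_lines(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _find_one(directory: Path, patterns: list[str]) -> Path | None:
    """First match of the patterns, searching the directory then one level down."""
    roots = [directory] + sorted(p for p in directory.iterdir() if p.is_dir())
    for root in roots:
        for pattern in patterns:
            hits = sorted(root.glob(pattern))
            if hits:
                return hits[0]
    return None


def _detect_usa(features: list[str]) -> bool:
    """USA convention: every gene appears as base, base-U and base-A."""
    if not any(f.endswith(UNSPLICED_SUFFIX) for f in features):
        return False
    bases = {
        f[: -len(UNSPLICED_SUFFIX)] if f.endswith((UNSPLICED_SUFFIX, AMBIGUOUS_SUFFIX)) else f
        for f in features
    }
    if len(features) != 3 * len(bases):
        return False
    feature_set = set(features)
    return all(
        b in feature_set and b + UNSPLICED_SUFFIX in feature_set and b + AMBIGUOUS_SUFFIX in feature_set
        for b in bases
    )


def _collapse_usa(
    matrix: sp.csc_matrix, features: list[str], symbols: list[str] | None
) -> tuple[sp.csr_matrix, sp.csr_matrix, sp.csr_matrix, sp.csr_matrix, list[str], list[str] | None]:
    # gene order = order of first appearance of unsuffixed features
    genes = [f for f in features if not f.endswith((UNSPLICED_SUFFIX, AMBIGUOUS_SUFFIX))]
    col_of = {f: i for i, f in enumerate(features)}
    s_cols = [col_of[g] for g in genes]
    u_cols = [col_of[g + UNSPLICED_SUFFIX] for g in genes]
    a_cols = [col_of[g + AMBIGUOUS_SUFFIX] for g in genes]
    layer_s = matrix[:, s_cols].tocsr()
    layer_u = matrix[:, u_cols].tocsr()
    layer_a = matrix[:, a_cols].tocsr()
    total = (layer_s + layer_u + layer_a).tocsr()
    gene_symbols = [symbols[col_of[g]] for g in genes] if symbols is not None else None
    return total, layer_s, layer_u, layer_a, genes, gene_symbols


def load_quant_dir(path: str | Path, usa_mode: bool | str = "auto") -> QuantBundle:
    """Load a quantification output directory into a :class:`QuantBundle`.

    The matrix, barcode and feature files are located automatically (searching
    the directory and its immediate subdirectories). With ``usa_mode="auto"``
    the feature list is inspected for the USA suffix convention; when detected
    the three feature blocks are collapsed onto one gene axis and stored as
    S/U/A layers with ``counts_total = S + U + A``.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise QuantLoadError(f"not a directory: {directory}")

    mtx_path = _find_one(directory, ["*.mtx", "*.mtx.gz"])
    if mtx_path is None:
        raise QuantLoadError(f"no MatrixMarket matrix file found under {directory}")
    barcodes_path = _find_one(
        directory, ["barcodes.txt", "barcodes.tsv", "barcodes.txt.gz", "barcodes.tsv.gz", "*rows*"]
    )
    features_path = _find_one(
        directory, ["features.txt", "features.tsv", "features.txt.gz", "features.tsv.gz", "*cols*"]
    )
    if barcodes_path is None:
        raise QuantLoadError(f"no barcode list file found under {directory}")
    if features_path is None:
        raise QuantLoadError(f"no feature list file found under {directory}")

    with _open_text(mtx_path) as fh:
        matrix = sp.csr_matrix(mmread(fh))
    barcodes = [line.split("\t")[0] for line in _read_lines(barcodes_path)]
    feature_rows = [line.split("\t") for line in _read_lines(features_path)]
    features = [row[0] for row in feature_rows]
    symbols = [row[1] for row in feature_rows] if all(len(r) > 1 for r in feature_rows) else None

    if matrix.shape[0] != len(barcodes):
        raise QuantLoadError(
            f"{barcodes_path.name}: {len(barcodes)} barcodes but matrix has "
            f"{matrix.shape[0]} rows"
        )
    if matrix.shape[1] != len(features):
        raise QuantLoadError(
            f"{features_path.name}: {len(features)} features but matrix has "
            f"{matrix.shape[1]} columns"
        )

    if usa_mode == "auto":
        usa = _detect_usa(features)
    else:
        usa = bool(usa_mode)
        if usa and not _detect_usa(features):
            raise QuantLoadError("usa_mode requested but feature list lacks USA structure")

    log_meta = parse_logs(directory)

    if usa:
        total, layer_s, layer_u, layer_a, genes, gene_symbols = _collapse_usa(
            matrix.tocsc(), features, symbols
        )
        bundle = QuantBundle(
            counts_total=total,
            barcodes=barcodes,
            genes=genes,
            layer_S=layer_s,
            layer_U=layer_u,
            layer_A=layer_a,
            gene_symbols=gene_symbols,
            log_meta=log_meta,
        )
    else:
        bundle = QuantBundle(
            counts_total=matrix,
            barcodes=barcodes,
            genes=features,
            gene_symbols=symbols,
            log_meta=log_meta,
        )
    bundle.validate()
    return bundle


def _first_int(table: dict[str, Any], keys: tuple[str, ...]) -> int | None:
    for key in keys:
        if key in table:
            try:
                return int(table[key])
            except (TypeError, ValueError):
                continue
    return None


def parse_logs(path: str | Path) -> LogSummary:
    """Parse the JSON logs of the quantification and permit-list steps.

    Tolerant by design: absent or malformed files produce absent fields plus a
    warning, never an error; unrecognized keys are preserved verbatim in
    ``raw_log_tables`` for the report.
    """
    directory = Path(path)
    summary = LogSummary()
    if not directory.is_dir():
        return summary

    roots = [directory] + sorted(p for p in directory.iterdir() if p.is_dir())
    json_paths: list[Path] = []
    for root in roots:
        json_paths.extend(sorted(root.glob("*.json")))

    for json_path in json_paths:
        try:
            with open(json_path) as fh:
                table = json.load(fh)
        except (json.JSONDecodeError, OSError) as exc:
            warnings.warn(f"could not parse log file {json_path.name}: {exc}", stacklevel=2)
            continue
        if not isinstance(table, dict):
            continue
        summary.raw_log_tables[json_path.name] = table

        name = json_path.name.lower()
        is_permit = "permit" in name
        is_quant = "quant" in name or "map" in name
        if not (is_permit or is_quant):
            continue

        processed = _first_int(table, _PROCESSED_READ_KEYS)
        if processed is not None and summary.num_processed_reads is None:
            summary.num_processed_reads = processed
        mapped = _first_int(table, _MAPPED_READ_KEYS)
        if mapped is not None and summary.num_mapped_reads is None:
            summary.num_mapped_reads = mapped
        barcodes = _first_int(table, _BARCODE_KEYS)
        if barcodes is not None and summary.num_processed_barcodes is None:
            summary.num_processed_barcodes = barcodes
        for key in _CHEMISTRY_KEYS:
            if key in table and summary.chemistry is None:
                summary.chemistry = str(table[key])
        for key in ("version", "tool_version"):
            if key in table:
                summary.tool_versions[json_path.name] = str(table[key])
        for key in ("cmd", "cmdline", "command"):
            if key in table:
                summary.command_arguments[json_path.name] = str(table[key])
        if isinstance(table.get("args"), dict):
            for arg_key, arg_val in table["args"].items():
                summary.command_arguments[f"{json_path.name}:{arg_key}"] = str(arg_val)

    for problem in summary.validate():
        warnings.warn(f"log consistency: {problem}", stacklevel=2)
    return summary


def _bundle_to_anndata(bundle: QuantBundle):
    import anndata as ad
    import pandas as pd

    obs = pd.DataFrame(index=pd.Index(bundle.barcodes, name="barcode"))
    var = pd.DataFrame(index=pd.Index(bundle.genes, name="gene_id"))
    if bundle.gene_symbols is not None:
        var["gene_symbol"] = bundle.gene_symbols
    adata = ad.AnnData(X=bundle.counts_total.tocsr(), obs=obs, var=var)
    if bundle.has_usa_layers:
        adata.layers["S"] = bundle.layer_S.tocsr()
        adata.layers["U"] = bundle.layer_U.tocsr()
        adata.layers["A"] = bundle.layer_A.tocsr()
    return adata


def load_h5_input(path: str | Path) -> QuantBundle:
    """Load an annotated H5AD file into a :class:`QuantBundle`.

    If S/U/A layers are present but X is missing or inconsistent with their
    sum, X is rebuilt as ``S + U + A``.
    """
    import anndata as ad

    file_path = Path(path)
    if not file_path.is_file():
        raise QuantLoadError(f"cannot read H5AD file: {file_path}")
    try:
        adata = ad.read_h5ad(file_path)
    except Exception as exc:  # noqa: BLE001 - h5py raises many types here
        raise QuantLoadError(f"cannot read H5AD file {file_path}: {exc}") from exc

    layers = {}
    for name in ("S", "U", "A"):
        if name in adata.layers:
            layers[name] = sp.csr_matrix(adata.layers[name]).astype(np.int64)
    has_usa = len(layers) == 3

    x = None
    if adata.X is not None:
        x = sp.csr_matrix(adata.X).astype(np.int64)
    if has_usa:
        total = (layers["S"] + layers["U"] + layers["A"]).tocsr()
        if x is None or (x - total).nnz != 0:
            x = total
    if x is None:
        raise QuantLoadError(f"{file_path}: no X matrix and no complete S/U/A layers")

    gene_symbols = (
        [str(s) for s in adata.var["gene_symbol"]] if "gene_symbol" in adata.var else None
    )
    log_meta = LogSummary()
    if "log_meta" in adata.uns:
        stored = adata.uns["log_meta"]
        log_meta = LogSummary(
            num_processed_reads=_none_if_missing(stored, "num_processed_reads"),
            num_mapped_reads=_none_if_missing(stored, "num_mapped_reads"),
            num_processed_barcodes=_none_if_missing(stored, "num_processed_barcodes"),
            chemistry=stored.get("chemistry") or None,
            tool_versions=dict(stored.get("tool_versions", {})),
            command_arguments=dict(stored.get("command_arguments", {})),
            raw_log_tables={k: dict(v) for k, v in stored.get("raw_log_tables", {}).items()},
        )

    bundle = QuantBundle(
        counts_total=x,
        barcodes=[str(b) for b in adata.obs_names],
        genes=[str(g) for g in adata.var_names],
        layer_S=layers.get("S") if has_usa else None,
        layer_U=layers.get("U") if has_usa else None,
        layer_A=layers.get("A") if has_usa else None,
        gene_symbols=gene_symbols,
        log_meta=log_meta,
    )
    bundle.validate()
    return bundle


def _none_if_missing(table, key):
    value = table.get(key, -1)
    try:
        value = int(value)
    except (TypeError, ValueError):
        return None
    return None if value < 0 else value


def _log_meta_to_uns(log_meta: LogSummary) -> dict[str, Any]:
    # h5ad cannot store None; use -1 sentinel for absent counts
    return {
        "num_processed_reads": -1 if log_meta.num_processed_reads is None else log_meta.num_processed_reads,
        "num_mapped_reads": -1 if log_meta.num_mapped_reads is None else log_meta.num_mapped_reads,
        "num_processed_barcodes": -1
        if log_meta.num_processed_barcodes is None
        else log_meta.num_processed_barcodes,
        "chemistry": log_meta.chemistry or "",
        "tool_versions": {k: str(v) for k, v in log_meta.tool_versions.items()},
        "command_arguments": {k: str(v) for k, v in log_meta.command_arguments.items()},
        "raw_log_tables": {
            name: {str(k): str(v) for k, v in table.items()}
            for name, table in log_meta.raw_log_tables.items()
        },
    }


def export_h5(bundle: QuantBundle, calls, qc, doublets=None, path: str | Path = "dropqc.h5ad"):
    """Write the annotated H5AD output file.

    Stores counts (+ layers), per-barcode QC/calling columns and unstructured
    metadata (QC summary scalars, log tables, tool version, parameters). The
    mitochondrial fraction is stored but never used for filtering.
    """
    from dropqc import __version__
    from dropqc.qc_metrics import per_barcode_qc

    adata = _bundle_to_anndata(bundle)
    pb = per_barcode_qc(bundle)
    adata.obs["total_umis"] = pb["total_umis"].to_numpy()
    adata.obs["genes_detected"] = pb["genes_detected"].to_numpy()
    adata.obs["mito_fraction"] = pb["mito_fraction"].to_numpy()
    if "spliced_ratio" in pb:
        adata.obs["spliced_ratio"] = pb["spliced_ratio"].to_numpy()

    n = bundle.n_barcodes
    ordmag_flag = np.zeros(n, dtype=bool)
    ordmag_flag[calls.ordmag.retained_indices] = True
    retained_flag = np.zeros(n, dtype=bool)
    retained_flag[sorted(calls.retained)] = True
    pvals = np.full(n, np.nan)
    fdrs = np.full(n, np.nan)
    ed = calls.emptydrops
    if len(ed.candidate_indices):
        pvals[ed.candidate_indices] = ed.p_values
        fdrs[ed.candidate_indices] = ed.fdr
    adata.obs["ordmag_retained"] = ordmag_flag
    adata.obs["emptydrops_pvalue"] = pvals
    adata.obs["emptydrops_fdr"] = fdrs
    adata.obs["retained"] = retained_flag

    if doublets is not None:
        score = np.full(n, np.nan)
        flag = np.zeros(n, dtype=bool)
        cell_idx = np.asarray(sorted(calls.retained), dtype=int)
        score[cell_idx] = doublets.observed_scores
        flag[cell_idx] = doublets.is_doublet
        adata.obs["doublet_score"] = score
        adata.obs["is_doublet"] = flag

    adata.uns["qc_summary"] = qc.to_uns_dict()
    adata.uns["log_meta"] = _log_meta_to_uns(bundle.log_meta)
    adata.uns["dropqc"] = {
        "version": __version__,
        "parameters": calls.parameters.to_uns_dict(),
        "mito_filter_applied": False,
    }

    out_path = Path(path)
    try:
        out_path.parent.mkdir(parents=True, exist_ok=True)
        adata.write_h5ad(out_path)
    except OSError as exc:
        raise QuantLoadError(f"cannot write H5AD to {out_path}: {exc}") from exc
    return out_path
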