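"""Assemble and render the self-contained HTML QC report.

The report has three parts — Summary, Plots and Log info. Every optional
section degrades gracefully: when its inputs are unavailable it is rendered
as an explicitly skipped block with a reason, never as an empty plot
container, and no stage error is allowed to fail report generation.
Figures are rendered with matplotlib and inlined as SVG so the file opens
offline; rendering is deterministic for a fixed ReportBundle (stable section
ordering, fixed SVG hash salt, no embedded dates) apart from the timestamp
field itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from jinja2 import Template

from dropqc.qc_metrics import QCSummary, knee_curve

_TEMPLATE = Template(
    """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{{ title }}</title>
<style>
body { font-family: sans-serif; margin: 2em auto; max-width: 1000px; color: #222; }
h1 { border-bottom: 2px solid #444; }
h2 { margin-top: 2em; border-bottom: 1px solid #bbb; }
table.kv { border-collapse: collapse; margin: 1em 0; }
table.kv td, table.kv th { border: 1px solid #ccc; padding: 4px 10px; text-align: left; }
.skipped { color: #777; font-style: italic; background: #f6f6f6; padding: 0.6em 1em; }
.warning { color: #8a2d00; background: #fff3e6; padding: 0.6em 1em; }
.guideline { color: #444; background: #eef4fb; padding: 0.6em 1em; font-size: 0.92em; }
.provenance { color: #888; font-size: 0.85em; margin-top: 3em; }
</style>
</head>
<body>
<h1>{{ title }}</h1>
{% for warning in warnings_ %}
<div class="warning">{{ warning }}</div>
{% endfor %}

<h2 id="summary">Summary</h2>
<table class="kv">
{% for key, value in summary_rows %}
<tr><th>{{ key }}</th><td>{{ value }}</td></tr>
{% endfor %}
</table>

{% for section in sections %}
<h2 id="{{ section.id }}">{{ section.title }}</h2>
{% if section.status == 'ok' %}
{% if section.guideline %}<div class="guideline">{{ section.guideline }}</div>{% endif %}
{% if section.table %}
<table class="kv">
{% for key, value in section.table %}
<tr><th>{{ key }}</th><td>{{ value }}</td></tr>
{% endfor %}
</table>
{% endif %}
{% if section.svg %}{{ section.svg }}{% endif %}
{% else %}
<div class="skipped">Section skipped: {{ section.reason }}</div>
{% endif %}
{% endfor %}

<h2 id="loginfo">Log info</h2>
{% if log_tables %}
{% for name, table in log_tables.items() %}
<h3>{{ name }}</h3>
<table class="kv">
{% for key, value in table.items() %}
<tr><th>{{ key }}</th><td>{{ value }}</td></tr>
{% endfor %}
</table>
{% endfor %}
{% else %}
<div class="skipped">Log information not available.</div>
{% endif %}

<div class="provenance">
Generated by {{ provenance.tool }} {{ provenance.version }}{% if provenance.timestamp %} at {{ provenance.timestamp }}{% endif %}.
Parameters: {{ provenance.parameters }}
</div>
</body>
</html>
"""
)

MITO_GUIDELINE = (
    "A 10% mitochondrial-content threshold is a common quality-control guideline for "
    "human samples; high-mito cells are often damaged or dying. This threshold is shown "
    "for reference only and is never applied automatically — the per-cell fraction is "
    "stored in the exported file so the decision stays with the analyst."
)


@dataclass
class ReportSection:
    id: str
    title: str
    status: str = "ok"  # 'ok' | 'skipped'
    reason: str = ""
    payload: dict[str, Any] = field(default_factory=dict)
    table: list[tuple[str, str]] | None = None
    guideline: str = ""
    svg: str = ""


@dataclass
class ReportBundle:
    summary: QCSummary
    sections: list[ReportSection]
    log_tables: dict[str, dict[str, Any]]
    provenance: dict[str, Any]
    warnings: list[str] = field(default_factory=list)

    def section(self, section_id: str) -> ReportSection:
        for s in self.sections:
            if s.id == section_id:
                return s
        raise KeyError(section_id)


def _fmt_count(value) -> str:
    return "n/a" if value is None else f"{int(value):,}"


def _fmt_real(value) -> str:
    return "n/a" if value is None else f"{value:,.1f}"


def _fmt_pct(value) -> str:
    return "n/a" if value is None else f"{100.0 * value:.1f}%"


def summary_rows(summary: QCSummary) -> list[tuple[str, str]]:
    """Display rows for the Summary table (percentages to 1 decimal)."""
    return [
        ("Retained cells", _fmt_count(summary.n_retained_cells)),
        ("Processed barcodes", _fmt_count(summary.n_processed_barcodes)),
        ("Mean reads per cell", _fmt_real(summary.mean_reads_per_cell)),
        ("Median UMIs per cell", _fmt_real(summary.median_umis_per_cell)),
        ("Median genes per cell", _fmt_real(summary.median_genes_per_cell)),
        ("Total genes detected", _fmt_count(summary.total_genes_detected)),
        ("Sequencing saturation", _fmt_pct(summary.sequencing_saturation)),
        ("Mapping rate", _fmt_pct(summary.mapping_rate)),
    ]


def build_report(
    bundle,
    calls,
    qc: QCSummary,
    doublets=None,
    embeddings=None,
    per_barcode=None,
    title: str = "dropqc QC report",
) -> ReportBundle:
    """Populate plot payloads for everything computable from the given inputs."""
    from dropqc import __version__
    from dropqc.cell_calling import rank_barcodes
    from dropqc.qc_metrics import per_barcode_qc

    warns: list[str] = []
    sections: list[ReportSection] = []
    if per_barcode is None:
        per_barcode = per_barcode_qc(bundle)

    cutoff_rank = calls.n_retained if calls is not None else None

    try:
        ranking = rank_barcodes(bundle)
    except ValueError as exc:
        ranking = None
        warns.append(f"barcode ranking unavailable: {exc}")

    # knee plots
    if ranking is not None:
        ranks, values = knee_curve(ranking)
        sections.append(
            ReportSection(
                id="knee_umi",
                title="Knee plot: UMI counts",
                payload={"ranks": ranks, "values": values, "cutoff_rank": cutoff_rank},
            )
        )
        genes_sorted = np.sort(per_barcode["genes_detected"].to_numpy())[::-1]
        g_ranks, g_values = knee_curve(ranking, values=genes_sorted)
        sections.append(
            ReportSection(
                id="knee_genes",
                title="Knee plot: genes detected",
                payload={"ranks": g_ranks, "values": g_values, "cutoff_rank": cutoff_rank},
            )
        )
        sections.append(
            ReportSection(
                id="umi_vs_genes",
                title="UMIs vs genes detected",
                payload={
                    "total_umis": per_barcode["total_umis"].to_numpy(),
                    "genes_detected": per_barcode["genes_detected"].to_numpy(),
                },
            )
        )
    else:
        for sid, stitle in (
            ("knee_umi", "Knee plot: UMI counts"),
            ("knee_genes", "Knee plot: genes detected"),
            ("umi_vs_genes", "UMIs vs genes detected"),
        ):
            sections.append(
                ReportSection(id=sid, title=stitle, status="skipped", reason="no counted barcodes")
            )

    # barcode collapsing: mapped reads vs deduplicated UMIs
    logs = bundle.log_meta
    if logs.num_mapped_reads is not None:
        sections.append(
            ReportSection(
                id="barcode_collapsing",
                title="Barcode collapsing",
                payload={
                    "mapped_reads": logs.num_mapped_reads,
                    "dedup_umis": int(bundle.counts_total.sum()),
                },
                table=[
                    ("Mapped reads", _fmt_count(logs.num_mapped_reads)),
                    ("Deduplicated UMIs", _fmt_count(int(bundle.counts_total.sum()))),
                    ("Sequencing saturation", _fmt_pct(qc.sequencing_saturation)),
                ],
            )
        )
    else:
        sections.append(
            ReportSection(
                id="barcode_collapsing",
                title="Barcode collapsing",
                status="skipped",
                reason="mapped-read totals not found in logs",
            )
        )

    # USA sections, present iff splice-aware layers exist
    if bundle.has_usa_layers:
        s_tot = int(bundle.layer_S.sum())
        u_tot = int(bundle.layer_U.sum())
        a_tot = int(bundle.layer_A.sum())
        sections.append(
            ReportSection(
                id="usa_bar",
                title="UMIs per splicing category",
                payload={"S": s_tot, "U": u_tot, "A": a_tot},
                table=[
                    ("Spliced (S)", _fmt_count(s_tot)),
                    ("Unspliced (U)", _fmt_count(u_tot)),
                    ("Ambiguous (A)", _fmt_count(a_tot)),
                ],
            )
        )
        ratios = per_barcode["spliced_ratio"].to_numpy()
        sections.append(
            ReportSection(
                id="spliced_ratio_hist",
                title="Spliced ratio distribution",
                payload={"ratios": ratios[~np.isnan(ratios)]},
                guideline=(
                    "The spliced ratio is (S + A)/(S + U + A); ambiguous UMIs are grouped "
                    "with spliced. Nuclei samples are dominated by unspliced transcripts "
                    "and show a low ratio; whole cells show a high ratio."
                ),
            )
        )
    else:
        for sid, stitle in (
            ("usa_bar", "UMIs per splicing category"),
            ("spliced_ratio_hist", "Spliced ratio distribution"),
        ):
            sections.append(
                ReportSection(
                    id=sid,
                    title=stitle,
                    status="skipped",
                    reason="no splice-aware (S/U/A) layers in the input",
                )
            )

    # mitochondrial content
    sections.append(
        ReportSection(
            id="mito_hist",
            title="Mitochondrial content",
            payload={"fractions": per_barcode["mito_fraction"].to_numpy()},
            guideline=MITO_GUIDELINE,
        )
    )

    # doublets
    if doublets is not None:
        sections.append(
            ReportSection(
                id="doublets",
                title="Doublet scores",
                payload={
                    "observed": doublets.observed_scores,
                    "simulated": doublets.simulated_scores,
                    "threshold": doublets.threshold,
                },
                table=[
                    ("Simulated doublets", _fmt_count(doublets.n_simulated)),
                    (
                        "Threshold",
                        "n/a (unimodal)" if not np.isfinite(doublets.threshold) else f"{doublets.threshold:.3f}",
                    ),
                    ("Flagged doublets", _fmt_count(int(doublets.is_doublet.sum()))),
                ],
            )
        )
    else:
        sections.append(
            ReportSection(
                id="doublets", title="Doublet scores", status="skipped", reason="doublet scoring not run"
            )
        )

    # embeddings
    if embeddings is not None and embeddings.coordinates_umap is not None:
        sections.append(
            ReportSection(
                id="embeddings",
                title="UMAP / t-SNE embeddings",
                payload={
                    "umap": embeddings.coordinates_umap,
                    "tsne": embeddings.coordinates_tsne,
                },
            )
        )
    else:
        sections.append(
            ReportSection(
                id="embeddings",
                title="UMAP / t-SNE embeddings",
                status="skipped",
                reason="embedding stage skipped or not viable for this input",
            )
        )

    provenance = {
        "tool": "dropqc",
        "version": __version__,
        "timestamp": "",
        "parameters": dict(calls.parameters.to_uns_dict()) if calls is not None else {},
    }
    return ReportBundle(
        summary=qc,
        sections=sections,
        log_tables=bundle.log_meta.raw_log_tables,
        provenance=provenance,
        warnings=warns,
    )


def _fig_svg(draw) -> str:
    """Render a matplotlib figure to a deterministic inline SVG string."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    with matplotlib.rc_context({"svg.hashsalt": "dropqc", "svg.fonttype": "none"}):
        fig, ax = plt.subplots(figsize=(6.0, 4.0))
        try:
            draw(ax)
            from io import StringIO

            buf = StringIO()
            fig.savefig(buf, format="svg", metadata={"Date": None})
            return buf.getvalue()
        finally:
            plt.close(fig)


def _section_svg(section: ReportSection) -> str:
    p = section.payload
    if section.id in ("knee_umi", "knee_genes"):
        ylabel = "UMI count" if section.id == "knee_umi" else "genes detected"

        def draw(ax):
            ax.plot(p["ranks"], np.maximum(p["values"], 1e-9), drawstyle="steps-post")
            if p.get("cutoff_rank"):
                ax.axvline(p["cutoff_rank"], color="crimson", linestyle="--", label="cell-calling cutoff")
                ax.legend()
            ax.set_xscale("log")
            ax.set_yscale("log")
            ax.set_xlabel("barcode rank")
            ax.set_ylabel(ylabel)

        return _fig_svg(draw)
    if section.id == "umi_vs_genes":

        def draw(ax):
            ax.scatter(p["total_umis"], p["genes_detected"], s=4, alpha=0.5)
            ax.set_xlabel("total UMIs")
            ax.set_ylabel("genes detected")

        return _fig_svg(draw)
    if section.id == "barcode_collapsing":

        def draw(ax):
            ax.bar(["mapped reads", "deduplicated UMIs"], [p["mapped_reads"], p["dedup_umis"]])
            ax.set_ylabel("count")

        return _fig_svg(draw)
    if section.id == "usa_bar":

        def draw(ax):
            ax.bar(["S", "U", "A"], [p["S"], p["U"], p["A"]])
            ax.set_ylabel("total UMIs")

        return _fig_svg(draw)
    if section.id == "spliced_ratio_hist":

        def draw(ax):
            ax.hist(p["ratios"], bins=40, range=(0, 1))
            ax.set_xlabel("spliced ratio (S+A)/(S+U+A)")
            ax.set_ylabel("cells")

        return _fig_svg(draw)
    if section.id == "mito_hist":

        def draw(ax):
            ax.hist(p["fractions"], bins=40, range=(0, 1))
            ax.axvline(0.10, color="crimson", linestyle="--", label="10% guideline")
            ax.legend()
            ax.set_xlabel("mitochondrial fraction")
            ax.set_ylabel("barcodes")

        return _fig_svg(draw)
    if section.id == "doublets":

        def draw(ax):
            ax.hist(p["simulated"], bins=30, range=(0, 1), alpha=0.6, label="simulated")
            ax.hist(p["observed"], bins=30, range=(0, 1), alpha=0.6, label="observed")
            if np.isfinite(p["threshold"]):
                ax.axvline(p["threshold"], color="crimson", linestyle="--", label="threshold")
            ax.legend()
            ax.set_xlabel("doublet score")
            ax.set_ylabel("count")

        return _fig_svg(draw)
    if section.id == "embeddings":

        def draw(ax):
            umap_xy = p["umap"]
            ax.scatter(umap_xy[:, 0], umap_xy[:, 1], s=5, alpha=0.6, label="UMAP")
            if p.get("tsne") is not None:
                tsne = p["tsne"]
                span = np.ptp(umap_xy, axis=0).max() or 1.0
                t_span = np.ptp(tsne, axis=0).max() or 1.0
                shifted = (tsne - tsne.mean(axis=0)) / t_span * span
                shifted[:, 0] += umap_xy[:, 0].max() + 1.5 * span
                ax.scatter(shifted[:, 0], shifted[:, 1], s=5, alpha=0.6, label="t-SNE")
            ax.legend()
            ax.set_xticks([])
            ax.set_yticks([])

        return _fig_svg(draw)
    return ""


def render_html(report: ReportBundle, path: str | Path, timestamp: str | None = None) -> Path:
    """Write the report to a single self-contained HTML file."""
    provenance = dict(report.provenance)
    if timestamp is not None:
        provenance["timestamp"] = timestamp

    rendered_sections = []
    for section in report.sections:
        svg = ""
        if section.status == "ok":
            try:
                svg = _section_svg(section)
            except Exception as exc:  # noqa: BLE001 - report must render regardless
                warnings.warn(f"could not draw section {section.id}: {exc}", stacklevel=2)
                section = ReportSection(
                    id=section.id,
                    title=section.title,
                    status="skipped",
                    reason=f"plot rendering failed: {exc}",
                )
        rendered_sections.append(
            {
                "id": section.id,
                "title": section.title,
                "status": section.status,
                "reason": section.reason,
                "table": section.table,
                "guideline": section.guideline,
                "svg": svg,
            }
        )

    html = _TEMPLATE.render(
        title="dropqc QC report",
        summary_rows=summary_rows(report.summary),
        sections=rendered_sections,
        log_tables=report.log_tables,
        provenance=provenance,
        warnings_=report.warnings,
    )
    out = Path(path)
    try:
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(html)
    except OSError as exc:
        raise RuntimeError(f"cannot write report to {out}: {exc}") from exc
    return out
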