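"""Gene description reports and plot-data exports.

Gene summaries come from an offline annotation table (TSV: gene id,
symbol, description) rather than a live database query; requested genes
missing from the table are flagged, never dropped.  Plot exports emit the
data behind the standard displays — volcano coordinates, per-group
box-plot five-number summaries, bar-plot and heat-map matrices — as plain
tables so any plotting front end can render them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import DEResult
from .io import ExpressionDataset, GroupAssignment, normalize_gene, write_result_table

__all__ = ["GeneReport", "gene_report", "export_plot_data"]


@dataclass
class GeneReport:
    gene_id: str
    symbol: str
    description: str
    source_version: str
    found: bool

    def as_record(self) -> dict:
        return {
            "gene_id": self.gene_id, "symbol": self.symbol,
            "description": self.description,
            "source_version": self.source_version, "found": self.found,
        }


def gene_report(genes, annotation_table, version: str = "") -> list[GeneReport]:
    """Look up each requested gene in the offline annotation table,
    preserving request order; misses are flagged not-found."""
    table: dict[str, tuple[str, str]] = {}
    with open(str(annotation_table), newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not row[0].strip():
                continue
            if len(row) < 3:
                raise ValueError(
                    f"{annotation_table}: line {lineno}: need gene id, "
                    f"symbol and description"
                )
            table[normalize_gene(row[0])] = (row[1].strip(), row[2].strip())
    reports = []
    for g in genes:
        hit = table.get(normalize_gene(g))
        if hit is None:
            reports.append(GeneReport(g, "", "not found", version, False))
        else:
            reports.append(GeneReport(g, hit[0], hit[1], version, True))
    return reports


def _five_number(values: np.ndarray) -> dict:
    """min, Q1, median, Q3, max with the linear-interpolation quantile rule."""
    q = np.percentile(values, [0, 25, 50, 75, 100], method="linear")
    return {"min": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
            "q3": float(q[3]), "max": float(q[4])}


def export_plot_data(kind: str, inputs, path) -> None:
    """Write the data table behind a plot.

    ``volcano``: inputs = list of DEResult -> (probe, log2FC, -log10 p,
    significant).  ``boxplot``: inputs = (ExpressionDataset,
    GroupAssignment) -> per-group five-number summary.  ``barplot`` /
    ``heatmap``: inputs = a labelled DataFrame, written as-is.
    """
    if kind == "volcano":
        if not (isinstance(inputs, list)
                and all(isinstance(r, DEResult) for r in inputs)):
            raise ValueError("volcano export expects a list of DE results")
        rows = [{
            "probe_id": r.probe_id,
            "log2_fold_change": r.log2_fold_change,
            "neg_log10_p": float(-np.log10(max(r.p_value, 5e-324))),
            "significant": r.significant,
        } for r in inputs]
        write_result_table(rows, path)
    elif kind == "boxplot":
        try:
            data, groups = inputs
        except (TypeError, ValueError):
            raise ValueError(
                "boxplot export expects (ExpressionDataset, GroupAssignment)"
            ) from None
        if not isinstance(data, ExpressionDataset) or not isinstance(
                groups, GroupAssignment):
            raise ValueError(
                "boxplot export expects (ExpressionDataset, GroupAssignment)"
            )
        rows = []
        for level in groups.levels:
            samples = [s for s in data.sample_ids
                       if groups.mapping.get(s) == level]
            vals = data.intensities[samples].to_numpy(dtype=float).ravel()
            rows.append({"group": level, "n_values": vals.size,
                         **_five_number(vals)})
        write_result_table(rows, path)
    elif kind in ("barplot", "heatmap"):
        if not isinstance(inputs, pd.DataFrame):
            raise ValueError(f"{kind} export expects a labelled DataFrame")
        inputs.to_csv(str(path), sep="\t", index_label="id")
    else:
        raise ValueError(f"unknown plot kind {kind!r}")
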