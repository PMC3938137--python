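"""End-to-end pipeline recipes with provenance.

``run_pipeline`` composes the canonical stage order — quantile
normalization, background filtering, differential expression or trend
ranking (plus clustering for time courses), then gene-set/GO enrichment —
from a flat key=value configuration, writing every output into one
directory together with a JSON-lines manifest of (path, sha256) so a rerun
with the same config and seed is byte-verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import cluster as _cluster
from . import diffexp as _diffexp
from . import enrichment as _enrichment
from . import preprocess as _preprocess
from .io import (ExpressionDataset, read_expression_table, read_gene_sets_gmt,
                 read_group_map, read_ontology, write_expression_table,
                 write_result_table)
from .reports import export_plot_data

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_RECIPES = ("two_group", "timecourse")


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run.

    ``recipe`` selects the stage chain: ``two_group`` (volcano DE then
    enrichment) or ``timecourse`` (trend correlation, ranking, k-means,
    then enrichment).  Threshold fields mirror the stage signatures.
    """

    recipe: str
    expression_path: str
    groups_path: str
    out_dir: str
    gmt_path: str | None = None
    obo_path: str | None = None
    go_annotation_path: str | None = None
    has_detection: bool = False
    normalize: bool = True
    detection_alpha: float | None = None
    intensity_floor: float | None = None
    variance_fraction: float | None = None
    test_level: str | None = None
    control_level: str | None = None
    fc_cutoff: float = 2.0
    p_cutoff: float = 0.05
    r_threshold: float = 0.6
    kmeans_k: int = 2
    enrich_p_cutoff: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.recipe not in _RECIPES:
            raise ValueError(f"recipe must be one of {_RECIPES}")
        if self.fc_cutoff < 1:
            raise ValueError("fc_cutoff must be >= 1")
        if not 0 < self.p_cutoff <= 1:
            raise ValueError("p_cutoff must lie in (0, 1]")
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must lie in (0, 1)")
        if self.detection_alpha is not None and not 0 < self.detection_alpha < 1:
            raise ValueError("detection_alpha must lie in (0, 1)")
        if self.variance_fraction is not None and not (
                0 <= self.variance_fraction < 1):
            raise ValueError("variance_fraction must lie in [0, 1)")
        if self.recipe == "two_group" and not (
                self.test_level and self.control_level):
            raise ValueError("two_group recipe needs test_level and control_level")
        for label, p in (("expression_path", self.expression_path),
                         ("groups_path", self.groups_path),
                         ("gmt_path", self.gmt_path),
                         ("obo_path", self.obo_path),
                         ("go_annotation_path", self.go_annotation_path)):
            if p is not None and not Path(p).exists():
                raise ValueError(f"{label} does not exist: {p}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` config file (one pair per line,
        '#' comments allowed)."""
        values: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            values[key] = val
        kwargs: dict = {}
        for f in cls.__dataclass_fields__.values():
            if f.name not in values:
                continue
            raw = values.pop(f.name)
            if f.type in ("float | None", "float"):
                kwargs[f.name] = float(raw)
            elif f.type == "int":
                kwargs[f.name] = int(raw)
            elif f.type == "bool":
                kwargs[f.name] = raw.lower() in ("1", "true", "yes")
            else:
                kwargs[f.name] = raw
        if values:
            raise ValueError(f"{path}: unknown config keys {sorted(values)}")
        return cls(**kwargs)

    def as_flat_text(self) -> str:
        lines = []
        for f in self.__dataclass_fields__:
            v = getattr(self, f)
            if v is not None:
                lines.append(f"{f} = {v}")
        return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    out_dir: Path
    manifest_path: Path
    outputs: list[Path] = field(default_factory=list)


def _collapse_to_genes(probe_ids, annotation) -> frozenset[str]:
    """Probe -> gene collapse; probes without annotation map to themselves."""
    annotation = annotation or {}
    return frozenset(str(annotation.get(p, p)) for p in probe_ids)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the configured recipe end to end, writing outputs + manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def emit(name: str) -> Path:
        p = out / name
        outputs.append(p)
        return p

    (out / "config.txt").write_text(config.as_flat_text())
    outputs.append(out / "config.txt")

    data = read_expression_table(config.expression_path,
                                 has_detection=config.has_detection)
    groups = read_group_map(config.groups_path)
    groups.check_covers(data.sample_ids)

    if config.normalize:
        logger.info("quantile normalization over %d samples", data.n_samples)
        data = _preprocess.quantile_normalize(data)
        write_expression_table(data, emit("normalized.tsv"))

    reports = []
    if config.detection_alpha is not None:
        data, rep = _preprocess.filter_by_detection(data, config.detection_alpha)
        reports.append(rep)
    if config.intensity_floor is not None:
        data, rep = _preprocess.filter_by_intensity(data, config.intensity_floor)
        reports.append(rep)
    if config.variance_fraction is not None:
        data, rep = _preprocess.filter_low_variance(data, config.variance_fraction)
        reports.append(rep)
    if reports:
        for rep in reports:
            logger.info("filter %s (threshold %s): %d -> %d probes",
                        rep.rule, rep.threshold, rep.probes_before,
                        rep.probes_after)
        write_result_table([r.as_record() for r in reports],
                           emit("filter_report.tsv"))

    if config.recipe == "two_group":
        results = _diffexp.two_group_stats(data, groups, config.test_level,
                                           config.control_level)
        write_result_table([vars(r) for r in results], emit("diffexp.tsv"))
        selected = _diffexp.select_volcano(results, config.fc_cutoff,
                                           config.p_cutoff)
        write_result_table([vars(r) for r in selected],
                           emit("diffexp_selected.tsv"))
        export_plot_data("volcano", results, emit("volcano.tsv"))
        query_probes = [r.probe_id for r in selected]
    else:
        trends = _diffexp.timeseries_r(data, groups)
        ranked = _diffexp.select_and_rank_trends(trends, data, groups,
                                                 config.r_threshold)
        write_result_table([vars(r) for r in ranked], emit("trends.tsv"))
        query_probes = [r.probe_id for r in ranked]
        if len(query_probes) >= config.kmeans_k:
            subset = data.subset_probes(query_probes)
            clusters = _cluster.kmeans_cluster(subset, config.kmeans_k,
                                               seed=config.seed,
                                               center_rows=True,
                                               log2_transform=True)
            write_result_table(
                [{"probe_id": p, "cluster": int(c)} for p, c in clusters.items()],
                emit("kmeans.tsv"))
            tree = _cluster.hierarchical_cluster(subset, axis="genes")
            heat = _cluster.heatmap_matrix(subset, tree)
            export_plot_data("heatmap", heat, emit("heatmap.tsv"))

    if query_probes:
        background = _collapse_to_genes(data.probe_ids, data.annotation)
        query = _collapse_to_genes(query_probes, data.annotation)
        if config.gmt_path:
            collection = read_gene_sets_gmt(config.gmt_path)
            records = _enrichment.enrich_gene_sets(
                query, background, collection, config.enrich_p_cutoff)
            write_result_table([r.as_record() for r in records],
                               emit("enrichment.tsv"))
        if config.obo_path and config.go_annotation_path:
            ontology = read_ontology(config.obo_path, config.go_annotation_path)
            records = _enrichment.enrich_go(
                query, background, ontology, config.enrich_p_cutoff)
            write_result_table([r.as_record() for r in records],
                               emit("go_enrichment.tsv"))
            _enrichment.export_go_graph(records, ontology, emit("go_graph.dot"))

    manifest = out / "manifest.jsonl"
    with open(manifest, "w") as fh:
        for p in outputs:
            fh.write(json.dumps({"path": p.name, "sha256": _sha256(p)},
                                sort_keys=True) + "\n")
    return PipelineResult(out, manifest, outputs)
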