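"""Reading and writing of the external formats the pipeline touches.

Canonical formats are plain delimited text: expression matrices as TSV with
a probe-ID column and one column per sample (optionally paired
``<sample>.detection`` columns of detection p-values), sample-to-group maps
as two/three-column TSV, gene sets as GMT, ontologies as an OBO 1.2 subset
plus a two-column annotation TSV, and cDNA templates as FASTA.  Every
reader validates on ingest and raises informative errors rather than
propagating malformed tables downstream.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "GroupAssignment",
    "GeneSetCollection",
    "OntologyGraph",
    "normalize_gene",
    "read_expression_table",
    "read_group_map",
    "read_gene_sets_gmt",
    "read_ontology",
    "write_result_table",
]


def normalize_gene(gene: str) -> str:
    """Canonical gene identifier: whitespace-trimmed, upper-cased.

    All set/annotation lookups match identifiers case-insensitively because
    gene symbols are cased inconsistently across annotation sources.
    """
    return gene.strip().upper()


@dataclass
class ExpressionDataset:
    """A probe x sample intensity table with optional detection p-values.

    ``intensities`` is a pandas DataFrame indexed by probe ID with one
    column per sample (arbitrary fluorescence units, non-negative).
    ``detection_pvalues``, if present, is shape-identical with values in
    [0, 1]; a small value means the probe signal is reliably above the
    negative-control background in that sample.  Missing intensity cells
    are permitted (NaN) and are only tolerated by the PPCA path.
    """

    intensities: pd.DataFrame
    detection_pvalues: pd.DataFrame | None = None
    annotation: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            dups = self.intensities.index[self.intensities.index.duplicated()]
            raise ValueError(f"duplicate probe IDs: {sorted(set(dups))}")
        if self.intensities.columns.has_duplicates:
            dups = self.intensities.columns[self.intensities.columns.duplicated()]
            raise ValueError(f"duplicate sample IDs: {sorted(set(dups))}")
        if self.detection_pvalues is not None:
            det = self.detection_pvalues
            if det.shape != self.intensities.shape:
                raise ValueError(
                    f"detection table shape {det.shape} does not match "
                    f"intensity table shape {self.intensities.shape}"
                )
            if not (det.index.equals(self.intensities.index)
                    and det.columns.equals(self.intensities.columns)):
                raise ValueError("detection table must share probe/sample labels")
            vals = det.to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError("missing detection p-values are not permitted")
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_probes(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def has_missing(self) -> bool:
        return bool(self.intensities.isna().any().any())

    def subset_probes(self, probe_ids) -> "ExpressionDataset":
        det = None
        if self.detection_pvalues is not None:
            det = self.detection_pvalues.loc[probe_ids]
        return ExpressionDataset(self.intensities.loc[probe_ids], det, self.annotation)


@dataclass
class GroupAssignment:
    """Sample -> condition/timepoint mapping with an explicit level order.

    For time-series data the level order *is* the time order; it drives the
    sample-order ramp used by the trend correlation.
    """

    mapping: dict[str, str]
    levels: list[str]

    def __post_init__(self) -> None:
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("group levels must be unique")
        unknown = set(self.mapping.values()) - set(self.levels)
        if unknown:
            raise ValueError(f"samples mapped to unlisted levels: {sorted(unknown)}")

    def samples_of(self, level: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == level]

    def check_covers(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise ValueError(f"samples without a group: {missing}")


@dataclass
class GeneSetCollection:
    """Named, described sets of gene identifiers (pathway-style)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class OntologyGraph:
    """A DAG of ontology terms (edges child -> parent along is_a) plus a
    gene -> terms annotation map.

    Root terms are the ones with no outgoing (is_a) edge.  Annotations are
    stored as directly asserted; ancestor propagation (the true-path rule)
    happens at enrichment time.
    """

    graph: nx.DiGraph
    annotations: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology is_a graph contains a cycle")
        known = set(self.graph.nodes)
        for gene, terms in self.annotations.items():
            bad = terms - known
            if bad:
                raise ValueError(f"gene {gene} annotated to unknown terms {sorted(bad)}")

    @property
    def roots(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` along is_a edges (excludes term)."""
        return nx.descendants(self.graph, term)

    def term_name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)


def _parse_float(cell: str, row: int, col: int, path: str) -> float:
    cell = cell.strip()
    if cell == "" or cell.upper() in {"NA", "NAN"}:
        return math.nan
    try:
        return float(cell)
    except ValueError:
        raise ValueError(
            f"{path}: non-numeric value {cell!r} at row {row}, column {col}"
        ) from None


def read_expression_table(path, delimiter: str = "\t",
                          has_detection: bool = False) -> ExpressionDataset:
    """Read a probe x sample intensity table from delimited text.

    The first column holds probe IDs; the header row holds sample labels.
    With ``has_detection`` each sample contributes a paired
    ``<sample>.detection`` column of detection p-values.  Missing intensity
    cells (empty or NA) are recorded as NaN; missing detection cells are an
    error.  Decimal points only — parsing is locale-independent.
    """
    path = str(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        ncol = len(header)
        if ncol < 2:
            raise ValueError(f"{path}: need a probe-ID column and >=1 sample column")
        rows = []
        probe_ids = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != ncol:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(row)} fields, expected {ncol})"
                )
            probe_ids.append(row[0].strip())
            rows.append([_parse_float(c, lineno, j + 2, path)
                         for j, c in enumerate(row[1:])])
    counts: dict[str, int] = {}
    for p in probe_ids:
        counts[p] = counts.get(p, 0) + 1
    dups = sorted(p for p, c in counts.items() if c > 1)
    if dups:
        raise ValueError(f"{path}: duplicate probe IDs: {dups}")

    values = np.asarray(rows, dtype=float) if rows else np.empty((0, ncol - 1))
    colnames = [c.strip() for c in header[1:]]
    if has_detection:
        sample_cols = [j for j, c in enumerate(colnames)
                       if not c.endswith(".detection")]
        samples = [colnames[j] for j in sample_cols]
        det_cols = []
        for s in samples:
            want = f"{s}.detection"
            if want not in colnames:
                raise ValueError(f"{path}: missing detection column {want!r}")
            det_cols.append(colnames.index(want))
        inten = pd.DataFrame(values[:, sample_cols], index=probe_ids, columns=samples)
        det = pd.DataFrame(values[:, det_cols], index=probe_ids, columns=samples)
        return ExpressionDataset(inten, det)
    inten = pd.DataFrame(values, index=probe_ids, columns=colnames)
    return ExpressionDataset(inten)


def read_group_map(path, delimiter: str = "\t") -> GroupAssignment:
    """Read a sample -> group map (TSV: sample_id, group[, order]).

    Levels are ordered by the integer order column when present, else by
    first appearance.  A sample listed twice with conflicting groups is an
    error.
    """
    path = str(path)
    mapping: dict[str, str] = {}
    order_of: dict[str, int] = {}
    first_seen: list[str] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: line {lineno}: need sample and group")
            sample, group = row[0].strip(), row[1].strip()
            if lineno == 1 and sample.lower() in {"sample", "sample_id"}:
                continue  # optional header
            if sample in mapping:
                if mapping[sample] != group:
                    raise ValueError(
                        f"{path}: sample {sample!r} mapped to both "
                        f"{mapping[sample]!r} and {group!r}"
                    )
                continue
            mapping[sample] = group
            if group not in first_seen:
                first_seen.append(group)
            if len(row) >= 3 and row[2].strip():
                try:
                    order = int(row[2])
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: order column must be an integer"
                    ) from None
                prev = order_of.get(group)
                if prev is not None and prev != order:
                    raise ValueError(
                        f"{path}: group {group!r} has conflicting orders "
                        f"{prev} and {order}"
                    )
                order_of[group] = order
    if not mapping:
        raise ValueError(f"{path}: no samples listed")
    if order_of:
        missing = [g for g in first_seen if g not in order_of]
        if missing:
            raise ValueError(f"{path}: groups without an order value: {missing}")
        levels = sorted(first_seen, key=order_of.__getitem__)
    else:
        levels = first_seen
    return GroupAssignment(mapping, levels)


def read_gene_sets_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description,
    then members.  Duplicate members within a line collapse to one."""
    path = str(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need name, description "
                    f"and >=1 member (got {len(fields)} fields)"
                )
            name, desc = fields[0].strip(), fields[1].strip()
            members = frozenset(normalize_gene(g) for g in fields[2:] if g.strip())
            if not members:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def read_ontology(obo_path, annotation_path) -> OntologyGraph:
    """Read an OBO 1.2 subset plus a two-column gene->term annotation TSV.

    Obsolete terms are dropped together with their annotations (with a
    logged warning); an is_a edge to an unknown term or a cycle is a hard
    error.  Annotation gene identifiers are normalized case-insensitively.
    """
    obo_path, annotation_path = str(obo_path), str(annotation_path)
    full = obonet.read_obo(obo_path, ignore_obsolete=False)
    obsolete = {n for n, d in full.nodes(data=True)
                if d.get("is_obsolete") in ("true", True)}
    named = {n for n, d in full.nodes(data=True) if "name" in d}
    graph = nx.DiGraph()
    for node, data in full.nodes(data=True):
        if node in obsolete:
            continue
        graph.add_node(node, name=data.get("name", node),
                       namespace=data.get("namespace", ""))
    for child, parent, key in full.edges(keys=True):
        if key != "is_a" or child in obsolete or parent in obsolete:
            continue
        if parent not in named:
            raise ValueError(f"{obo_path}: is_a references unknown term {parent!r}")
        graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"{obo_path}: is_a cycle detected: {cycle}")

    annotations: dict[str, set[str]] = {}
    n_dropped = 0
    with open(annotation_path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not row[0].strip():
                continue
            if len(row) < 2:
                raise ValueError(
                    f"{annotation_path}: line {lineno}: need gene and term"
                )
            gene, term = normalize_gene(row[0]), row[1].strip()
            if term in obsolete:
                n_dropped += 1
                continue
            if term not in graph:
                raise ValueError(
                    f"{annotation_path}: line {lineno}: unknown term {term!r}"
                )
            annotations.setdefault(gene, set()).add(term)
    if n_dropped:
        logger.warning("dropped %d annotation(s) to obsolete terms", n_dropped)
    return OntologyGraph(graph, {g: frozenset(t) for g, t in annotations.items()})


def _format_number(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        x = float(x)
        if math.isnan(x):
            return "NA"
        if x != 0 and abs(x) < 1e-4:
            return np.format_float_scientific(x, unique=True)
        return repr(x)
    return str(x)


def write_result_table(rows, path, delimiter: str = "\t") -> None:
    """Write an ordered list of records (dicts sharing a schema) as
    delimited text: header plus one line per record.

    Numbers are serialized at full (round-trip) precision, switching to
    scientific notation below 1e-4 so small p-values stay readable.
    """
    rows = list(rows)
    path = str(path)
    if rows:
        schema = list(rows[0].keys())
        for i, r in enumerate(rows):
            if list(r.keys()) != schema:
                raise ValueError(f"record {i} does not share the field schema")
    else:
        schema = []
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(schema)
        for r in rows:
            writer.writerow([_format_number(v) for v in r.values()])


def write_expression_table(data: ExpressionDataset, path,
                           delimiter: str = "\t") -> None:
    """Write an ExpressionDataset back to the canonical TSV layout
    (detection columns interleaved as ``<sample>.detection`` when present)."""
    path = str(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        if data.detection_pvalues is None:
            writer.writerow(["probe_id"] + data.sample_ids)
            for pid, row in zip(data.probe_ids, data.intensities.to_numpy()):
                writer.writerow([pid] + [_format_number(v) for v in row])
        else:
            header = ["probe_id"]
            for s in data.sample_ids:
                header += [s, f"{s}.detection"]
            writer.writerow(header)
            inten = data.intensities.to_numpy()
            det = data.detection_pvalues.to_numpy()
            for i, pid in enumerate(data.probe_ids):
                row = [pid]
                for j in range(data.n_samples):
                    row += [_format_number(inten[i, j]), _format_number(det[i, j])]
                writer.writerow(row)
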