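"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its parameters and an explicit
integer seed, and returns the generated objects together with a
:class:`SimulationTruth` record of the planted ground truth, so recovery
rates and false-discovery proportions can be measured downstream.

The expression generators work on the log2 scale — baseline log2 means
drawn uniformly in [6, 12] (a typical fluorescence dynamic range), planted
effects added as log2 shifts, Gaussian noise with a stated log2 standard
deviation — and exponentiate to linear intensities, so planted linear fold
changes are exact in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionDataset, GroupAssignment, GeneSetCollection, OntologyGraph
from . import primers as _primers

__all__ = [
    "SimulationTruth",
    "gen_two_group",
    "gen_timecourse",
    "gen_genesets_and_ontology",
    "gen_template",
]

_BASELINE_LOG2_RANGE = (6.0, 12.0)


@dataclass
class SimulationTruth:
    """Ground truth planted by a generator, serializable as JSON."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    probe_labels: dict[str, str] = field(default_factory=dict)
    planted_set: str | None = None
    planted_term: str | None = None
    planted_forward: tuple[int, int] | None = None   # (start, length)
    planted_reverse: tuple[int, int] | None = None

    def to_json(self, path) -> None:
        with open(str(path), "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(str(path)) as fh:
            d = json.load(fh)
        for key in ("planted_forward", "planted_reverse"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _probe_names(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(1, n + 1)]


def gen_two_group(n_probes: int = 2000, n_per_group: int = 5, n_de: int = 100,
                  fold: float = 2.5, sigma_log2: float = 0.25,
                  seed: int = 0) -> tuple[ExpressionDataset, GroupAssignment,
                                          SimulationTruth]:
    """Two-condition dataset with ``n_de`` probes shifted by ±log2(fold)
    in the test group and Gaussian log2 noise everywhere."""
    if n_de > n_probes:
        raise ValueError("n_de cannot exceed n_probes")
    rng = np.random.default_rng(seed)
    probes = _probe_names(n_probes)
    samples = ([f"ctrl{i+1}" for i in range(n_per_group)]
               + [f"trt{i+1}" for i in range(n_per_group)])
    base = rng.uniform(*_BASELINE_LOG2_RANGE, size=n_probes)
    log2 = np.tile(base[:, None], (1, 2 * n_per_group))
    de_idx = rng.choice(n_probes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    shift = signs * np.log2(fold)
    log2[de_idx, n_per_group:] += shift[:, None]
    log2 += rng.normal(scale=sigma_log2, size=log2.shape)
    inten = pd.DataFrame(2.0 ** log2, index=probes, columns=samples)
    groups = GroupAssignment(
        {s: ("ctrl" if s.startswith("ctrl") else "trt") for s in samples},
        ["ctrl", "trt"],
    )
    labels = {p: "null" for p in probes}
    for i, s in zip(de_idx, signs):
        labels[probes[i]] = "de_up" if s > 0 else "de_down"
    truth = SimulationTruth(
        "two_group", seed,
        {"n_probes": n_probes, "n_per_group": n_per_group, "n_de": n_de,
         "fold": fold, "sigma_log2": sigma_log2},
        labels,
    )
    return ExpressionDataset(inten), groups, truth


def gen_timecourse(n_probes: int = 2000, timepoints=("d0", "d1", "d2", "d5",
                                                     "d8", "d14"),
                   reps_per_timepoint: int = 4, n_up: int = 50,
                   n_down: int = 50, sigma_log2: float = 0.25,
                   amplitude_log2: float = 2.0,
                   seed: int = 0) -> tuple[ExpressionDataset, GroupAssignment,
                                           SimulationTruth]:
    """Multi-timepoint dataset with planted monotone log2 trends.

    Trending probes follow a linear log2 ramp across the ordered
    timepoints with total amplitude ``amplitude_log2`` (rising for the
    up-probes, falling for the down-probes, emulating expression waves
    that rise or decay over the sampled days); all other probes are flat.
    """
    timepoints = list(timepoints)
    if n_up + n_down > n_probes:
        raise ValueError("n_up + n_down cannot exceed n_probes")
    if len(timepoints) < 2:
        raise ValueError("need >=2 timepoints")
    rng = np.random.default_rng(seed)
    probes = _probe_names(n_probes)
    samples, mapping = [], {}
    for t in timepoints:
        for r in range(reps_per_timepoint):
            s = f"{t}_r{r+1}"
            samples.append(s)
            mapping[s] = t
    n_t = len(timepoints)
    ramp = np.linspace(0.0, 1.0, n_t)
    per_sample_ramp = np.repeat(ramp, reps_per_timepoint)

    base = rng.uniform(*_BASELINE_LOG2_RANGE, size=n_probes)
    slopes = np.zeros(n_probes)
    up_down = rng.permutation(n_probes)[: n_up + n_down]
    up_idx, down_idx = up_down[:n_up], up_down[n_up:]
    slopes[up_idx] = amplitude_log2
    slopes[down_idx] = -amplitude_log2
    log2 = base[:, None] + slopes[:, None] * per_sample_ramp[None, :]
    log2 += rng.normal(scale=sigma_log2, size=log2.shape)
    inten = pd.DataFrame(2.0 ** log2, index=probes, columns=samples)
    groups = GroupAssignment(mapping, timepoints)
    labels = {p: "flat" for p in probes}
    for i in up_idx:
        labels[probes[i]] = "trend_up"
    for i in down_idx:
        labels[probes[i]] = "trend_down"
    truth = SimulationTruth(
        "timecourse", seed,
        {"n_probes": n_probes, "timepoints": timepoints,
         "reps_per_timepoint": reps_per_timepoint, "n_up": n_up,
         "n_down": n_down, "sigma_log2": sigma_log2,
         "amplitude_log2": amplitude_log2},
        labels,
    )
    return ExpressionDataset(inten), groups, truth


def gen_genesets_and_ontology(n_genes: int = 400, n_sets: int = 20,
                              planted_set_size: int = 25,
                              query_size: int = 40, query_overlap: int = 20,
                              seed: int = 0):
    """Gene-set collection and toy ontology with one planted enrichment.

    The background holds ``n_genes`` genes; one planted set shares
    ``query_overlap`` genes with the query while the other sets are random
    draws.  The ontology is a three-layer DAG (root -> branches -> leaves)
    whose leaves partition the background; the planted leaf is annotated
    with exactly the planted set's genes, so after ancestor propagation the
    leaf and its lineage dominate the enrichment ranking.
    """
    if not (0 < query_overlap <= min(planted_set_size, query_size)
            and planted_set_size <= n_genes and query_size <= n_genes):
        raise ValueError("inconsistent generator counts")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    background = frozenset(genes)

    planted = list(rng.choice(genes, size=planted_set_size, replace=False))
    non_planted = [g for g in genes if g not in set(planted)]
    query = set(rng.choice(planted, size=query_overlap, replace=False))
    query |= set(rng.choice(non_planted, size=query_size - query_overlap,
                            replace=False))

    sets: dict[str, tuple[str, frozenset[str]]] = {
        "SET_PLANTED": ("planted enrichment", frozenset(planted)),
    }
    for k in range(1, n_sets):
        members = rng.choice(genes, size=planted_set_size, replace=False)
        sets[f"SET_{k:03d}"] = (f"random set {k}", frozenset(members))
    collection = GeneSetCollection(sets)

    # layered DAG: root -> 4 branches -> 8 leaves; leaves partition genes
    graph = nx.DiGraph()
    graph.add_node("T:ROOT", name="root", namespace="toy")
    branches = [f"T:B{i}" for i in range(4)]
    leaves = [f"T:L{i}" for i in range(8)]
    for b in branches:
        graph.add_node(b, name=b, namespace="toy")
        graph.add_edge(b, "T:ROOT")
    for i, leaf in enumerate(leaves):
        graph.add_node(leaf, name=leaf, namespace="toy")
        graph.add_edge(leaf, branches[i // 2])
    annotations: dict[str, set[str]] = {}
    planted_leaf = "T:L0"
    for g in planted:
        annotations.setdefault(g, set()).add(planted_leaf)
    remaining = [g for g in non_planted]
    chunks = np.array_split(np.array(remaining, dtype=object), 7)
    for leaf, chunk in zip(leaves[1:], chunks):
        for g in chunk:
            annotations.setdefault(str(g), set()).add(leaf)
    ontology = OntologyGraph(graph, {g: frozenset(t)
                                     for g, t in annotations.items()})
    truth = SimulationTruth(
        "genesets", seed,
        {"n_genes": n_genes, "n_sets": n_sets,
         "planted_set_size": planted_set_size, "query_size": query_size,
         "query_overlap": query_overlap},
        planted_set="SET_PLANTED", planted_term=planted_leaf,
    )
    return collection, ontology, frozenset(query), background, truth


_SITE_FLANK = "G" * 8


def _locale_is_exclusive(locale: str, site_start: int, site_len: int,
                         strand: str,
                         constraints: _primers.PrimerConstraints) -> bool:
    """True iff, within ``locale``, the planted window is the ONLY window
    (on its strand) passing every single-primer filter."""
    for length in range(constraints.length_min, constraints.length_max + 1):
        for start in range(0, len(locale) - length + 1):
            window = locale[start:start + length]
            seq = (window if strand == "forward"
                   else _primers.reverse_complement(window))
            verdict, _ = _primers.screen_oligo(seq, constraints)
            if verdict == "pass" and (start, length) != (site_start, site_len):
                return False
    return True


def _random_primer_site(rng: np.random.Generator,
                        constraints: _primers.PrimerConstraints,
                        length: int = 20, strand: str = "forward",
                        tm_target: float | None = None,
                        max_tries: int = 20000) -> str:
    """Rejection-sample one oligo that passes every single-primer filter
    AND, once framed by homopolymer flanks, is the only passing window in
    its neighborhood (so shifted/extended variants are screened out)."""
    bases = np.array(list("ACGT"))
    for _ in range(max_tries):
        seq = "".join(rng.choice(bases, size=length))
        verdict, props = _primers.screen_oligo(seq, constraints)
        if verdict != "pass":
            continue
        if tm_target is not None and abs(props["tm"] - tm_target) > 0.3:
            continue
        insert = seq if strand == "forward" else _primers.reverse_complement(seq)
        locale = _SITE_FLANK + insert + _SITE_FLANK
        if _locale_is_exclusive(locale, len(_SITE_FLANK), length, strand,
                                constraints):
            return seq
    raise RuntimeError("could not sample a constraint-compliant primer site")


def gen_template(length: int = 400, gc_background: float = 0.9,
                 planted_sites: bool = True, seed: int = 0,
                 constraints: _primers.PrimerConstraints | None = None
                 ) -> tuple[str, str, SimulationTruth]:
    """cDNA template (FASTA-ready) with optional planted primer sites.

    The background sequence is drawn at ``gc_background`` GC with
    homopolymer-heavy decoy stretches, so background windows fail the
    default GC/repeat filters.  With ``planted_sites`` one forward and one
    reverse 20-mer satisfying every default constraint are inserted with
    an amplicon span at the midpoint of the allowed range and closely
    matched melting temperatures.  Returns (name, sequence, truth).
    """
    constraints = constraints or _primers.PrimerConstraints()
    if planted_sites and length < 300:
        raise ValueError("planting sites needs template length >= 300")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    p_gc = gc_background / 2
    p_at = (1 - gc_background) / 2

    def draw_background() -> str:
        seq = rng.choice(bases, size=length, p=[p_at, p_gc, p_gc, p_at])
        # homopolymer decoys: a few 8-base runs sprinkled into the background
        for _ in range(max(length // 100, 1)):
            pos = int(rng.integers(0, length - 8))
            seq[pos:pos + 8] = rng.choice(bases)
        return "".join(seq)

    truth = SimulationTruth(
        "template", seed,
        {"length": length, "gc_background": gc_background,
         "planted_sites": planted_sites},
    )
    if not planted_sites:
        return f"template_seed{seed}", draw_background(), truth

    site_len = 20
    flank = len(_SITE_FLANK)
    amplicon = int((constraints.amplicon_min + constraints.amplicon_max) // 2)
    fwd_start = max((length - amplicon) // 2, flank)
    rev_start = fwd_start + amplicon - site_len
    if rev_start + site_len + flank > length:
        raise ValueError("template too short for the planted amplicon span")
    max_cross = constraints.max_dimer_score
    # Each planted site is framed by homopolymer flanks and sampled so it
    # is the only passing window in its neighborhood; a final global
    # screen confirms the planted pair is the unique surviving
    # combination, so recovery is guaranteed by construction.
    for _attempt in range(50):
        fwd = _random_primer_site(rng, constraints, site_len, "forward")
        fwd_tm = _primers.melting_temperature(fwd, method=constraints.tm_method)
        for _ in range(100):
            rev = _random_primer_site(rng, constraints, site_len, "reverse",
                                      tm_target=fwd_tm)
            if (max_cross is None
                    or _primers.dimer_score(fwd, rev) <= max_cross):
                break
        else:
            continue
        chars = list(draw_background())
        chars[fwd_start - flank:fwd_start] = list(_SITE_FLANK)
        chars[fwd_start:fwd_start + site_len] = list(fwd)
        chars[fwd_start + site_len:fwd_start + site_len + flank] = \
            list(_SITE_FLANK)
        chars[rev_start - flank:rev_start] = list(_SITE_FLANK)
        chars[rev_start:rev_start + site_len] = list(
            _primers.reverse_complement(rev))
        chars[rev_start + site_len:rev_start + site_len + flank] = \
            list(_SITE_FLANK)
        template = "".join(chars)
        result = _primers.design_primers(template, constraints, top_k=2)
        passing = (int((result.feasibility == 0).sum())
                   if result.feasibility is not None else 0)
        if passing == 1 and result.pairs:
            top = result.pairs[0]
            if ((top.forward.start, top.forward.length) == (fwd_start, site_len)
                    and (top.reverse.start, top.reverse.length)
                    == (rev_start, site_len)):
                truth.planted_forward = (fwd_start, site_len)
                truth.planted_reverse = (rev_start, site_len)
                return f"template_seed{seed}", template, truth
    raise RuntimeError("could not construct a template with a unique "
                       "planted primer pair")


def write_fasta(name: str, sequence: str, path, width: int = 70) -> None:
    """Write one record in FASTA format."""
    with open(str(path), "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")
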