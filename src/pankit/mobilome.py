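"""Mobile-ome discovery via sequence nestedness.

Recently active mobile elements leave similar insertion/deletion sequences
at different genomic locations. Clustering the presence alleles of simple
indels by *nestedness* — sequence A points at sequence B when A is
(approximately) contained in B — yields a directed graph whose weakly
connected components approximate TE families, with no annotation required.
TE-content categories, a six-frame ORF scan and a keyword classifier for
protein-hit descriptions complete the characterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from Bio.Seq import Seq

from . import localalign as la
from .seqs import TEAnnotationSet, revcomp

DEFAULT_NESTEDNESS_THRESHOLD = 0.85
DEFAULT_MIN_GRAPH_LEN = 100

TE_CATEGORIES = ("is_complete", "contains_complete", "is_fragment", "contains_fragment", "none")

_TE_KEYWORDS = (
    "transcriptase", "reverse", "transpos", "gag-", "pol-", "integrase",
    "gag/pol", "gagpol", "retrovirus", "rna-directed dna polymerase",
    "rna-dependent dna polymerase",
)
_UNDEFINED_KEYWORDS = (
    "hypothetical protein", "unnamed protein product", "uncharacterized protein",
    "predicted protein", "predicted:", "putative protein", "unknown",
)


@dataclass
class NestednessEdge:
    nested_id: str
    container_id: str
    coverage: float
    identity: float


# ---------------------------------------------------------------------------
# Containment search
# ---------------------------------------------------------------------------

def _containment(a: str, b: str, threshold: float, k: int = 13) -> tuple[float, float]:
    """Coverage of ``a`` by merged local hits in ``b`` (at >= threshold
    identity) and the length-weighted identity of those hits."""
    # fast path: best single semi-global placement of a inside b. Edit
    # distance conflates mismatches with uncovered sequence (an unrelated
    # tail of length j costs only ~j/2 edits), so accept outright only when
    # coverage is safe even if every edit hides uncovered bases
    ident = la.infix_identity(a, b)
    if 1.0 - 2.0 * (1.0 - ident) >= threshold:
        return 1.0, ident
    hits = la.local_hits(a, b, k=k, min_len=max(30, k + 1), min_identity=threshold)
    if not hits:
        return 0.0, 0.0
    covered = la.merged_coverage([(h.qs, h.qe) for h in hits])
    total_len = sum(h.length for h in hits)
    ident = sum(h.identity * h.length for h in hits) / total_len
    return covered / len(a), ident


def pairwise_nestedness(
    sequences: dict[str, str],
    threshold: float = DEFAULT_NESTEDNESS_THRESHOLD,
    min_len: int = DEFAULT_MIN_GRAPH_LEN,
) -> list[NestednessEdge]:
    """All nestedness edges among ``sequences`` (ids -> nucleotide strings).

    Edge A -> B when merged local hits of A against B cover at least
    ``threshold`` of A at ``threshold`` identity and A is not longer than B
    beyond the tolerance the threshold itself allows. Sequences shorter than
    ``min_len`` are excluded.
    """
    ids = [i for i, s in sequences.items() if len(s) >= min_len]
    edges: list[NestednessEdge] = []
    for i, a_id in enumerate(ids):
        for b_id in ids:
            if a_id == b_id:
                continue
            a, b = sequences[a_id], sequences[b_id]
            if len(a) * threshold > len(b):
                continue  # a cannot be covered inside a much shorter b
            cov, ident = _containment(a, b, threshold)
            if cov >= threshold:
                edges.append(NestednessEdge(a_id, b_id, round(cov, 6), round(ident, 6)))
    return edges


def build_graph(edges: list[NestednessEdge], sequences: dict[str, str],
                min_len: int = DEFAULT_MIN_GRAPH_LEN) -> nx.DiGraph:
    """Directed nestedness graph over all qualifying sequences; sequences
    without edges remain isolated nodes. Weak components are stored on the
    nodes as the ``component`` attribute."""
    g = nx.DiGraph()
    for sid, seq in sequences.items():
        if len(seq) >= min_len:
            g.add_node(sid, length=len(seq), members=[sid], size=1)
    for e in edges:
        if e.nested_id == e.container_id:
            continue
        g.add_edge(e.nested_id, e.container_id, coverage=e.coverage, identity=e.identity)
    _label_components(g)
    return g


def _label_components(g: nx.DiGraph) -> None:
    for ci, comp in enumerate(sorted(nx.weakly_connected_components(g), key=lambda c: sorted(c)[0])):
        for node in comp:
            g.nodes[node]["component"] = ci


def merge_nodes(g: nx.DiGraph, merge_threshold: float = DEFAULT_NESTEDNESS_THRESHOLD) -> nx.DiGraph:
    """Collapse sets of mutually nested sequences into single nodes.

    Two nodes merge when edges exist in both directions, each with coverage
    at least ``merge_threshold``; merging is transitive. Node size counts the
    merged members; edges are re-attached and deduplicated (keeping the
    maximal coverage).
    """
    parent = {n: n for n in g.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v, data in g.edges(data=True):
        if g.has_edge(v, u):
            c1 = data["coverage"]
            c2 = g.edges[v, u]["coverage"]
            if c1 >= merge_threshold and c2 >= merge_threshold:
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[max(ru, rv)] = min(ru, rv)

    groups: dict[str, list[str]] = {}
    for n in g.nodes:
        groups.setdefault(find(n), []).append(n)

    merged = nx.DiGraph()
    rep_of = {}
    for root, members in groups.items():
        rep = max(members, key=lambda m: (g.nodes[m]["length"], m))
        for m in members:
            rep_of[m] = rep
        all_members = [x for m in members for x in g.nodes[m].get("members", [m])]
        merged.add_node(
            rep,
            length=g.nodes[rep]["length"],
            members=sorted(all_members),
            size=len(all_members),
        )
    for u, v, data in g.edges(data=True):
        ru, rv = rep_of[u], rep_of[v]
        if ru == rv:
            continue
        if merged.has_edge(ru, rv):
            if data["coverage"] > merged.edges[ru, rv]["coverage"]:
                merged.edges[ru, rv].update(coverage=data["coverage"], identity=data["identity"])
        else:
            merged.add_edge(ru, rv, coverage=data["coverage"], identity=data["identity"])
    _label_components(merged)
    return merged


# ---------------------------------------------------------------------------
# TE content
# ---------------------------------------------------------------------------

def te_content_category(
    sequence: str,
    te_annotations: TEAnnotationSet,
    cov_threshold: float = DEFAULT_NESTEDNESS_THRESHOLD,
    k: int = 13,
) -> str:
    """Categorize a sequence by its overlap with an annotated TE library.

    ``a`` = fraction of the sequence covered by merged TE hits; ``b`` = the
    largest fraction of any single matched element covered by its hits.
    ``is_complete``: a and b both high (the sequence *is* a TE);
    ``contains_complete``: a full element plus extra sequence;
    ``is_fragment``: the sequence is (part of) an element but covers little
    of it; ``contains_fragment``: partial TE similarity plus extra sequence;
    ``none``: no hits at all.
    """
    if len(te_annotations) == 0:
        raise ValueError("TE annotation set is empty")
    seq_intervals: list[tuple[int, int]] = []
    best_b = 0.0
    any_hit = False
    for elem in te_annotations:
        elem_intervals: list[tuple[int, int]] = []
        for target in (elem.sequence, revcomp(elem.sequence)):
            hits = la.local_hits(
                sequence, target, k=k, min_len=max(30, k + 1), min_identity=cov_threshold
            )
            for h in hits:
                seq_intervals.append((h.qs, h.qe))
                elem_intervals.append((h.ts, h.te))
        if not elem_intervals:
            # fall back on whole-sequence containment for diverged copies
            ident = la.infix_identity(sequence, elem.sequence)
            if len(sequence) <= len(elem.sequence) / cov_threshold and ident >= cov_threshold:
                seq_intervals.append((0, len(sequence)))
                ln = min(len(sequence), len(elem.sequence))
                elem_intervals.append((0, ln))
        if elem_intervals:
            any_hit = True
            b = la.merged_coverage(elem_intervals) / len(elem.sequence)
            best_b = max(best_b, b)
    if not any_hit:
        return "none"
    a = la.merged_coverage(seq_intervals) / len(sequence)
    if a >= cov_threshold and best_b >= cov_threshold:
        return "is_complete"
    if a < cov_threshold and best_b >= cov_threshold:
        return "contains_complete"
    if a >= cov_threshold and best_b < cov_threshold:
        return "is_fragment"
    if 0 < a < cov_threshold:
        return "contains_fragment"
    return "none"


# ---------------------------------------------------------------------------
# ORFs and protein-hit descriptions
# ---------------------------------------------------------------------------

def orf_scan(sequence: str, long_codons: int = 100, fallback_codons: int = 30) -> list[str]:
    """Six-frame ORF scan.

    Translates all six frames with the standard genetic code, splits every
    frame on stop codons, and returns all stop-free stretches longer than
    ``long_codons``; if none exists, the single longest stretch is returned
    provided it exceeds ``fallback_codons``; otherwise the result is empty.
    """
    stretches: list[str] = []
    for strand_seq in (sequence, revcomp(sequence)):
        for frame in range(3):
            sub = strand_seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate())
            stretches.extend(part for part in aa.split("*") if part)
    long_orfs = [s for s in stretches if len(s) > long_codons]
    if long_orfs:
        return long_orfs
    if stretches:
        longest = max(stretches, key=len)
        if len(longest) > fallback_codons:
            return [longest]
    return []


def classify_protein_hits(hit_descriptions: list[str]) -> str:
    """Keyword classification of protein BLAST hit descriptions into
    ``te_like`` / ``undefined_protein`` / ``defined_protein`` / ``no_protein``."""
    if not hit_descriptions:
        return "no_protein"
    lowered = [d.lower() for d in hit_descriptions]
    if any(kw in d for d in lowered for kw in _TE_KEYWORDS):
        return "te_like"
    if all(any(kw in d for kw in _UNDEFINED_KEYWORDS) for d in lowered):
        return "undefined_protein"
    return "defined_protein"


# ---------------------------------------------------------------------------
# Convenience driver
# ---------------------------------------------------------------------------

@dataclass
class MobilomeResult:
    graph: nx.DiGraph
    merged: nx.DiGraph
    edges: list[NestednessEdge]
    categories: dict[str, str] = field(default_factory=dict)


def discover_mobilome(
    sequences: dict[str, str],
    te_annotations: TEAnnotationSet | None = None,
    threshold: float = DEFAULT_NESTEDNESS_THRESHOLD,
    min_len: int = DEFAULT_MIN_GRAPH_LEN,
) -> MobilomeResult:
    """Nestedness graph + node merging (+ optional TE categorization) for a
    set of presence-allele sequences."""
    edges = pairwise_nestedness(sequences, threshold=threshold, min_len=min_len)
    graph = build_graph(edges, sequences, min_len=min_len)
    categories = {}
    if te_annotations is not None and len(te_annotations):
        for sid in graph.nodes:
            categories[sid] = te_content_category(sequences[sid], te_annotations, cov_threshold=threshold)
        for sid, cat in categories.items():
            graph.nodes[sid]["te_category"] = cat
    merged = merge_nodes(graph, merge_threshold=threshold)
    return MobilomeResult(graph=graph, merged=merged, edges=edges, categories=categories)
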