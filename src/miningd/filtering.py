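"""Filtering extensions and collapsing them into candidate D genes.

Extensions produced by the core engine come from three sources: true D
genes, suffixes of V genes and prefixes of J genes (which flank every CDR3).
Because V, D and J parts appear in order along a CDR3, the *mean relative
position* of an extension across the CDR3s containing it separates the three
classes into left, central and right clusters; only the central (D) cluster
is kept. Redundant reconstructions of the same gene are then collapsed via a
similarity graph: extensions e1, e2 are adjacent when

    Dist(e1, e2) = min(|e1|, |e2|) - |LCS(e1, e2)| <= maxDist,

with LCS the longest common substring; every maximal clique is replaced by
the longest common substring of its members, re-extended with the core
stopping rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .core import DEFAULT_ALPHA, DEFAULT_MAX_LEN, Extension, ExtensionEngine
from .io import CDR3Set

logger = logging.getLogger(__name__)

DEFAULT_MAX_DIST = 2
MIN_MERGE_CORE = 6  # cliques whose common substring is shorter pass through


def relative_position(sub: str, c: str) -> float:
    """Start index of the first occurrence of sub in c, normalized to [0, 1).

    RP_c(sub) = I_c(sub) / (|c| - |sub| + 1): the index among all windows of
    length |sub| in c, so positions are comparable across CDR3 lengths.
    """
    idx = c.find(sub)
    if idx < 0:
        raise ValueError("sub does not occur in c")
    return idx / (len(c) - len(sub) + 1)


def mean_relative_position(sub: str, cdr3s) -> tuple[float, int]:
    """Mean RP of ``sub`` over the CDR3s containing it, and their number."""
    total, n = 0.0, 0
    for c in cdr3s:
        if sub in c:
            total += relative_position(sub, c)
            n += 1
    return (total / n if n else float("nan")), n


@dataclass
class PositionedExtension:
    extension: Extension
    mean_rp: float
    n_cdr3s: int
    segment_class: str = "unassigned"  # one of V, D, J, unassigned


def _kmeans_1d(values, centroids, iterations: int = 100):
    """Plain 1-D k-means with fixed initial centroids (deterministic).

    Empty clusters keep their previous centroid.
    """
    cents = list(centroids)
    assign = [0] * len(values)
    for _ in range(iterations):
        new_assign = [
            min(range(len(cents)), key=lambda j: abs(v - cents[j])) for v in values
        ]
        if new_assign == assign and _ > 0:
            break
        assign = new_assign
        for j in range(len(cents)):
            members = [v for v, a in zip(values, assign) if a == j]
            if members:
                cents[j] = sum(members) / len(members)
    return assign, cents


def classify_by_position(
    exts: list[PositionedExtension],
    centroids: tuple[float, float, float] = (0.1, 0.5, 0.9),
) -> list[PositionedExtension]:
    """Cluster mean relative positions into three groups: V (left), D
    (central), J (right).

    1-D k-means with fixed initial centroids; the cluster with the middle
    final centroid is labelled D. Fewer than 3 extensions, or fully
    degenerate positions, are all labelled D with a warning.
    """
    if len(exts) < 3:
        logger.warning("fewer than 3 extensions: all classed D")
        for e in exts:
            e.segment_class = "D"
        return exts
    values = [e.mean_rp for e in exts]
    if max(values) - min(values) < 1e-12:
        logger.warning("degenerate relative positions: all classed D")
        for e in exts:
            e.segment_class = "D"
        return exts
    assign, cents = _kmeans_1d(values, centroids)
    order = sorted(range(3), key=lambda j: cents[j])
    labels = {order[0]: "V", order[1]: "D", order[2]: "J"}
    for e, a in zip(exts, assign):
        e.segment_class = labels[a]
    return exts


def filter_unidirectional(
    exts: list[Extension], keep_unidirectional: bool = False
) -> list[Extension]:
    """Drop extensions that grew on one side only (zero steps on a side).

    Such extensions typically start from a seed straddling a gene boundary
    and junk, and duplicate a bidirectional reconstruction of the same gene.
    """
    if keep_unidirectional:
        return list(exts)
    return [e for e in exts if e.left_steps > 0 and e.right_steps > 0]


def longest_common_substring(a: str, b: str) -> str:
    """Longest common substring via DP; ties resolved lexicographically."""
    if not a or not b:
        return ""
    best_len, best = 0, ""
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best_len:
                    best_len, best = cur[j], a[i - cur[j] : i]
                elif cur[j] == best_len:
                    cand = a[i - cur[j] : i]
                    if cand < best:
                        best = cand
        prev = cur
    return best


def _common_substring_all(seqs: list[str]) -> str:
    """Longest substring common to all sequences (ties lexicographic)."""
    ref = min(seqs, key=len)
    for L in range(len(ref), 0, -1):
        hits = sorted(
            {
                ref[i : i + L]
                for i in range(len(ref) - L + 1)
                if all(ref[i : i + L] in s for s in seqs)
            }
        )
        if hits:
            return hits[0]
    return ""


def similarity_distance(e1: str, e2: str) -> int:
    """Dist(e1, e2) = min(|e1|, |e2|) - |longest common substring|.

    The number of edge nucleotides of the shorter extension that must be
    changed or deleted to turn it into (a substring of) the other. Zero iff
    one string is a substring of the other.
    """
    if not e1 or not e2:
        raise ValueError("extensions must be non-empty")
    return min(len(e1), len(e2)) - len(longest_common_substring(e1, e2))


@dataclass
class SimilarityGraph:
    """Undirected graph on extension sequences; edges where Dist <= maxDist."""

    graph: nx.Graph
    max_dist: int = DEFAULT_MAX_DIST

    @property
    def nodes(self):
        return list(self.graph.nodes)


def build_similarity_graph(sequences, max_dist: int = DEFAULT_MAX_DIST) -> SimilarityGraph:
    """Exact duplicates are collapsed before construction; no self-loops."""
    uniq = sorted(set(sequences))
    g = nx.Graph()
    g.add_nodes_from(uniq)
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            if similarity_distance(a, b) <= max_dist:
                g.add_edge(a, b)
    return SimilarityGraph(graph=g, max_dist=max_dist)


def merge_cliques(
    graph: SimilarityGraph,
    engine: ExtensionEngine | CDR3Set | None = None,
    alpha: float = DEFAULT_ALPHA,
    max_len: int = DEFAULT_MAX_LEN,
    min_core: int = MIN_MERGE_CORE,
) -> list[str]:
    """Collapse each maximal clique into one candidate sequence.

    Maximal cliques (Bron-Kerbosch with pivoting) are processed in
    decreasing size, ties by lexicographically smallest member; each node is
    consumed by at most one clique. The clique's members are replaced by the
    longest common substring of them all, re-extended on the dataset with
    the branch-free stopping rule when an engine (or CDR3Set) is given.
    Cliques whose common substring is shorter than ``min_core`` pass their
    members through unmerged, with a warning. Singletons pass through.
    """
    if isinstance(engine, CDR3Set):
        engine = ExtensionEngine(engine)
    cliques = sorted(
        (sorted(cl) for cl in nx.find_cliques(graph.graph)),
        key=lambda cl: (-len(cl), cl[0]),
    )
    consumed: set[str] = set()
    out: list[str] = []
    for clique in cliques:
        members = [n for n in clique if n not in consumed]
        if not members:
            continue
        consumed.update(members)
        if len(members) == 1:
            out.append(members[0])
            continue
        core = _common_substring_all(members)
        if len(core) < min_core:
            logger.warning(
                "clique common substring %r shorter than %d: members kept unmerged",
                core,
                min_core,
            )
            out.extend(members)
            continue
        out.append(engine.reextend(core, alpha=alpha, max_len=max_len) if engine else core)
    # preserve determinism and drop duplicates arising from re-extension
    seen: dict[str, None] = {}
    for s in out:
        seen.setdefault(s)
    return list(seen)


def merge_across_datasets(
    candidate_lists: list[list[str]], max_dist: int = DEFAULT_MAX_DIST
) -> list[str]:
    """Consolidate candidates inferred from several datasets of one cohort.

    Union of candidates; candidates that are substrings of another are
    dropped; remaining near-duplicates (Dist <= max_dist) are merged by the
    clique procedure without re-extension.
    """
    if not candidate_lists:
        raise ValueError("at least one candidate list is required")
    pool = sorted({c for lst in candidate_lists for c in lst})
    kept = [
        c
        for c in pool
        if not any(c != other and c in other for other in pool)
    ]
    graph = build_similarity_graph(kept, max_dist=max_dist)
    return merge_cliques(graph, engine=None, min_core=1)
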