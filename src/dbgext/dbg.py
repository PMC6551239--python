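"""Condensed de Bruijn graph with twin-node (reverse-complement) semantics.

Vertices of the raw graph are the k-mers occurring in the reads; two k-mers
are joined by a directed edge when the (k-1)-suffix of the first equals the
(k-1)-prefix of the second.  Every maximal non-branching chain is collapsed
into a single *condensed node*.  Each stored node represents a twin pair: the
``+`` orientation spells the stored sequence, the ``-`` orientation its
reverse complement, and every edge (a -> b) coexists with its twin edge
(twin(b) -> twin(a)).  Twin symmetry is structural — only one member of each
pair is stored, the other is realized at query time.

Graph simplification follows short-read assembler practice: short dead-end
tips (spelled length < ``tip_len``, with a sibling alternative at the branch
point) are pruned, then a k-mer coverage cutoff ``c`` removes condensed nodes
whose average k-mer multiplicity falls below ``c``, and the graph is
re-condensed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional

from .seqio import Read, reverse_complement

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass(frozen=True)
class GraphParams:
    k: int = 25
    c: float = 0.0
    tip_len: Optional[int] = None  # None -> 2k

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError("k must be an odd integer >= 3")
        if self.c < 0:
            raise ValueError("coverage cutoff c must be >= 0")
        if self.tip_len is not None and self.tip_len < self.k:
            raise ValueError("tip_len must be >= k")

    @property
    def effective_tip_len(self) -> int:
        return 2 * self.k if self.tip_len is None else self.tip_len


class OrientedNode(NamedTuple):
    """A node reference with strand: +1 spells the stored seq, -1 its twin."""

    id: int
    orient: int

    @property
    def twin(self) -> "OrientedNode":
        return OrientedNode(self.id, -self.orient)

    def __str__(self) -> str:
        return f"{self.id}{'+' if self.orient > 0 else '-'}"


@dataclass
class CondensedNode:
    id: int
    seq: str
    kmer_count: int
    total_cov: int

    def avg_cov(self) -> float:
        return self.total_cov / self.kmer_count


@dataclass
class GraphPath:
    """An ordered walk of oriented nodes; consecutive steps share an edge."""

    steps: tuple[OrientedNode, ...]

    def __post_init__(self) -> None:
        self.steps = tuple(self.steps)
        if not self.steps:
            raise ValueError("a path must contain at least one step")

    def __len__(self) -> int:
        return len(self.steps)

    def extend(self, step: OrientedNode) -> "GraphPath":
        return GraphPath(self.steps + (step,))

    def id_signature(self) -> tuple[tuple[int, int], ...]:
        return tuple((s.id, s.orient) for s in self.steps)

    def __str__(self) -> str:
        return ",".join(str(s) for s in self.steps)


class DeBruijnGraph:
    """Bidirected condensed de Bruijn graph storing one record per twin pair."""

    def __init__(self, params: GraphParams):
        self.params = params
        self.nodes: dict[int, CondensedNode] = {}
        self._adj: dict[OrientedNode, set[OrientedNode]] = {}

    # -- construction ---------------------------------------------------

    def add_node(self, seq: str, total_cov: int, node_id: Optional[int] = None) -> int:
        k = self.params.k
        if len(seq) < k:
            raise ValueError("node sequence shorter than k")
        if node_id is None:
            node_id = max(self.nodes, default=0) + 1
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id}")
        self.nodes[node_id] = CondensedNode(
            node_id, seq, len(seq) - k + 1, total_cov
        )
        return node_id

    def add_edge(self, a: OrientedNode, b: OrientedNode) -> None:
        """Insert edge a->b together with its twin edge twin(b)->twin(a)."""
        for x, y in ((a, b), (b.twin, a.twin)):
            if x.id not in self.nodes or y.id not in self.nodes:
                raise KeyError(f"edge {x}->{y} references unknown node")
            self._adj.setdefault(x, set()).add(y)

    def remove_node(self, node_id: int) -> None:
        for orient in (1, -1):
            x = OrientedNode(node_id, orient)
            for y in self._adj.pop(x, set()):
                self._adj.get(y.twin, set()).discard(x.twin)
        del self.nodes[node_id]

    # -- queries --------------------------------------------------------

    def spell(self, step: OrientedNode) -> str:
        seq = self.nodes[step.id].seq
        return seq if step.orient > 0 else reverse_complement(seq)

    def out_steps(self, tail: OrientedNode) -> list[OrientedNode]:
        """Successors of an oriented node, ascending id, + before -."""
        if tail.id not in self.nodes:
            raise KeyError(f"unknown node id {tail.id}")
        return sorted(self._adj.get(tail, ()), key=lambda s: (s.id, -s.orient))

    def in_degree(self, x: OrientedNode) -> int:
        return len(self._adj.get(x.twin, ()))

    def out_degree(self, x: OrientedNode) -> int:
        return len(self._adj.get(x, ()))

    def edges(self) -> Iterator[tuple[OrientedNode, OrientedNode]]:
        for a, succs in self._adj.items():
            for b in succs:
                yield a, b

    def n_edges(self) -> int:
        return sum(len(s) for s in self._adj.values())

    def has_edge(self, a: OrientedNode, b: OrientedNode) -> bool:
        return b in self._adj.get(a, ())


# -- path operations ----------------------------------------------------


def spell_path(graph: DeBruijnGraph, path: GraphPath) -> str:
    """Concatenate oriented node sequences with (k-1)-overlap at junctions."""
    k = graph.params.k
    parts = [graph.spell(path.steps[0])]
    prev = path.steps[0]
    for step in path.steps[1:]:
        if not graph.has_edge(prev, step):
            raise ValueError(f"steps {prev} -> {step} are not joined by an edge")
        parts.append(graph.spell(step)[k - 1 :])
        prev = step
    return "".join(parts)


def twin_path(path: GraphPath) -> GraphPath:
    """Reverse the walk on the opposite strand; an involution."""
    return GraphPath(tuple(s.twin for s in reversed(path.steps)))


def path_node_offsets(graph: DeBruijnGraph, path: GraphPath) -> list[tuple[int, int]]:
    """Spelled half-open interval [start, end) occupied by each step."""
    k = graph.params.k
    out = []
    pos = 0
    for step in path.steps:
        length = len(graph.nodes[step.id].seq)
        out.append((pos, pos + length))
        pos += length - (k - 1)
    return out


# -- k-mer counting and construction ------------------------------------


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def count_kmers(reads: Iterable[Read], k: int) -> dict[str, int]:
    """Count every k-mer occurrence under its canonical form.

    k must be odd so that no k-mer equals its own reverse complement.
    k-mers containing N are excluded.
    """
    if k < 3 or k % 2 == 0:
        raise ValueError("k must be an odd integer >= 3")
    counts: dict[str, int] = {}
    for read in reads:
        seq = read.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            c = canonical(kmer)
            counts[c] = counts.get(c, 0) + 1
    return counts


def _count_and_link(
    reads: Iterable[Read], k: int
) -> tuple[dict[str, int], set[tuple[str, str]]]:
    """One pass over the reads: canonical k-mer counts plus the set of
    adjacent k-mer pairs ((k+1)-mer links) observed on either strand."""
    counts: dict[str, int] = {}
    links: set[tuple[str, str]] = set()
    for read in reads:
        seq = read.seq
        prev = None
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                prev = None
                continue
            c = canonical(kmer)
            counts[c] = counts.get(c, 0) + 1
            if prev is not None:
                links.add((prev, kmer))
            prev = kmer
    return counts, links


def _kmer_graph(
    counts: dict[str, int],
    links: set[tuple[str, str]],
    params: GraphParams,
) -> DeBruijnGraph:
    """Raw graph: one node per canonical k-mer; edges from read adjacency.

    Every link and its reverse complement are inserted, so the edge set is
    twin-symmetric by construction.
    """
    g = DeBruijnGraph(params)
    ids: dict[str, int] = {}
    for i, kmer in enumerate(sorted(counts), start=1):
        ids[kmer] = i
        g.add_node(kmer, counts[kmer], node_id=i)

    def oriented(kmer: str) -> OrientedNode:
        canon = canonical(kmer)
        return OrientedNode(ids[canon], 1 if kmer == canon else -1)

    for u, v in links:
        g.add_edge(oriented(u), oriented(v))
    return g


def _mergeable(g: DeBruijnGraph, x: OrientedNode, y: OrientedNode) -> bool:
    """True when x's unique successor y can be absorbed into x's chain."""
    if g.out_degree(x) != 1 or g.in_degree(y) != 1:
        return False
    if y.id == x.id:  # self-loop or hairpin: never condense across
        return False
    return True


def condense(graph: DeBruijnGraph) -> DeBruijnGraph:
    """Collapse every maximal non-branching chain into a single node."""
    g = DeBruijnGraph(graph.params)
    k = graph.params.k
    chain_of: dict[int, tuple[int, int]] = {}  # old id -> (new id, orient in chain)
    chains: list[list[OrientedNode]] = []
    seen: set[int] = set()

    for nid in sorted(graph.nodes):
        if nid in seen:
            continue
        start = OrientedNode(nid, 1)
        # walk backwards to the start of the chain
        walked = {nid}
        while True:
            preds = [p.twin for p in graph.out_steps(start.twin)]
            if len(preds) != 1 or not _mergeable(graph, preds[0], start):
                break
            prev = preds[0]
            if prev.id in seen or prev.id in walked:  # cycle guard
                break
            start = prev
            walked.add(prev.id)
        chain = [start]
        seen.add(start.id)
        cur = start
        while True:
            succs = graph.out_steps(cur)
            if len(succs) != 1 or not _mergeable(graph, cur, succs[0]):
                break
            nxt = succs[0]
            if nxt.id in seen:
                break
            chain.append(nxt)
            seen.add(nxt.id)
            cur = nxt
        chains.append(chain)

    for new_id, chain in enumerate(chains, start=1):
        parts = [graph.spell(chain[0])]
        for step in chain[1:]:
            parts.append(graph.spell(step)[k - 1 :])
        seq = "".join(parts)
        cov = sum(graph.nodes[s.id].total_cov for s in chain)
        g.add_node(seq, cov, node_id=new_id)
        for s in chain:
            chain_of[s.id] = (new_id, s.orient)

    def translate_end(x: OrientedNode) -> OrientedNode:
        new_id, orient_in_chain = chain_of[x.id]
        return OrientedNode(new_id, x.orient * orient_in_chain)

    for new_id, chain in enumerate(chains, start=1):
        tail = chain[-1]
        for succ in graph.out_steps(tail):
            g.add_edge(OrientedNode(new_id, 1), translate_end(succ))
        head = chain[0]
        for succ in graph.out_steps(head.twin):
            g.add_edge(OrientedNode(new_id, -1), translate_end(succ))
    return g


def remove_tips(graph: DeBruijnGraph, tip_len: Optional[int] = None) -> DeBruijnGraph:
    """Iteratively prune short dead-end branches (tips) in place.

    A tip is a node that is a dead end in one orientation, spells fewer than
    ``tip_len`` bases, and whose branch point offers an alternative
    continuation (some predecessor has out-degree >= 2).
    """
    if tip_len is None:
        tip_len = graph.params.effective_tip_len
    changed = True
    while changed:
        changed = False
        for nid in sorted(graph.nodes):
            node = graph.nodes[nid]
            if len(node.seq) >= tip_len:
                continue
            for orient in (1, -1):
                x = OrientedNode(nid, orient)
                if graph.out_degree(x) != 0:
                    continue
                preds = [p.twin for p in graph.out_steps(x.twin)]
                if not preds:
                    continue  # isolated node: not a tip
                if any(graph.out_degree(p) >= 2 for p in preds):
                    graph.remove_node(nid)
                    changed = True
                    break
    return graph


def apply_coverage_cutoff(graph: DeBruijnGraph, c: float) -> DeBruijnGraph:
    """Remove condensed nodes whose average k-mer coverage is below c."""
    for nid in sorted(graph.nodes):
        if graph.nodes[nid].avg_cov() < c:
            graph.remove_node(nid)
    return graph


def build_graph(reads: Iterable[Read], params: GraphParams) -> DeBruijnGraph:
    """Count k-mers, build the raw graph, condense, prune tips, apply the
    coverage cutoff, and re-condense."""
    counts, links = _count_and_link(reads, params.k)
    if not counts:
        logger.warning("no k-mer survives; returning an empty graph")
        return DeBruijnGraph(params)
    g = _kmer_graph(counts, links, params)
    g = condense(g)
    remove_tips(g)
    if params.c > 0:
        apply_coverage_cutoff(g, params.c)
    g = condense(g)
    return g


# -- GFA 1.0 serialization ----------------------------------------------


def write_gfa(graph: DeBruijnGraph, path: str | Path) -> None:
    """Serialize to GFA 1.0: S lines carry KC (total k-mer count) tags, L
    lines a (k-1)M overlap; one L line per twin-edge pair."""
    k = graph.params.k
    with open(path, "w") as fh:
        fh.write(f"H\tVN:Z:1.0\tkk:i:{k}\n")
        for nid in sorted(graph.nodes):
            n = graph.nodes[nid]
            fh.write(f"S\t{nid}\t{n.seq}\tKC:i:{n.total_cov}\n")
        written: set[tuple] = set()
        for a, b in sorted(graph.edges()):
            key = (a, b)
            tkey = (b.twin, a.twin)
            if tkey in written:
                continue
            written.add(key)
            sa = "+" if a.orient > 0 else "-"
            sb = "+" if b.orient > 0 else "-"
            fh.write(f"L\t{a.id}\t{sa}\t{b.id}\t{sb}\t{k-1}M\n")


def read_gfa(path: str | Path, c: float = 0.0) -> DeBruijnGraph:
    """Load a graph written by :func:`write_gfa` (k from the header tag)."""
    k = None
    s_lines: list[tuple[int, str, int]] = []
    l_lines: list[tuple[int, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "H":
                for tag in fields[1:]:
                    if tag.startswith("kk:i:"):
                        k = int(tag[5:])
            elif fields[0] == "S":
                cov = 0
                for tag in fields[3:]:
                    if tag.startswith("KC:i:"):
                        cov = int(tag[5:])
                s_lines.append((int(fields[1]), fields[2], cov))
            elif fields[0] == "L":
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: malformed L line")
                l_lines.append(
                    (
                        int(fields[1]),
                        1 if fields[2] == "+" else -1,
                        int(fields[3]),
                        1 if fields[4] == "+" else -1,
                    )
                )
    if k is None:
        raise ValueError(f"{path}: missing kk:i header tag")
    g = DeBruijnGraph(GraphParams(k=k, c=c))
    for nid, seq, cov in s_lines:
        g.add_node(seq, cov, node_id=nid)
    for aid, ao, bid, bo in l_lines:
        g.add_edge(OrientedNode(aid, ao), OrientedNode(bid, bo))
    return g
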