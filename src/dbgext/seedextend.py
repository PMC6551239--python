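"""Seed-and-extend search over the condensed de Bruijn graph.

For each transcript in the related-organism database, the nodes giving the
best hits (e-value below the permissive initial cutoff ``e_i``) are chosen as
seeds.  Each seed is extended greedily one node at a time in a single
direction: every one-node extension is spelled and searched against the whole
database, and the step whose e-value to the seeding transcript improves the
most is accepted — extension stops when no outgoing edge remains or the
e-value no longer improves.  The same procedure runs from the twin node in
the opposite direction, and the two extended paths are merged through the
seed into one longer path, which is searched once more.

Because the e-value of a path cannot improve indefinitely (the raw score is
bounded by the subject, while the search-space term grows with the query),
the greedy loop terminates even on cyclic graphs; ``max_steps`` is a safety
bound only.

Every alignment invocation performed anywhere in the search updates a
:class:`CandidatePool` holding, per transcript, the best (path, hit) seen so
far — the final report is drawn from this pool, so a path explored while
serving one transcript can still be the winner for another.

Very short nodes (e.g. the ~2(k-1) bp junction node created by an exon
skip) may not improve the e-value on their own; a bounded lookahead explores
up to ``lookahead`` nodes past such a short candidate and commits the
multi-node step when the terminal e-value improves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

from .dbg import DeBruijnGraph, GraphPath, OrientedNode, spell_path, twin_path
from .homology import AlignmentHit, ScoringScheme, TranscriptDB

logger = logging.getLogger(__name__)

#: relative tolerance below which two e-values count as equal
REL_TOL = 1e-12


@dataclass(frozen=True)
class SearchParams:
    e_i: float = 1e-6
    e_f: float = 1e-20
    n_seeds: int = 8
    short_len: Optional[int] = None  # None -> k at run time
    lookahead: int = 2
    max_steps: int = 10_000

    def __post_init__(self) -> None:
        if not (0 < self.e_f < self.e_i):
            raise ValueError("cutoffs must satisfy 0 < e_f < e_i")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


@dataclass
class SeedAssignment:
    transcript_id: str
    seeds: list[tuple[OrientedNode, AlignmentHit]]  # best first


def _improves(new_e: float, cur_e: float) -> bool:
    """Strictly smaller e-value, with relative tolerance REL_TOL."""
    return new_e < cur_e * (1.0 - REL_TOL)


def _path_order_key(graph: DeBruijnGraph, path: GraphPath, hit: AlignmentHit):
    """Deterministic tie-break: e-value, bit desc, shorter spelled length,
    lexicographically smallest oriented-id list."""
    spelled_len = sum(len(graph.nodes[s.id].seq) for s in path.steps) - (
        len(path.steps) - 1
    ) * (graph.params.k - 1)
    return (hit.evalue, -hit.bit_score, spelled_len, path.id_signature())


class CandidatePool:
    """Per-transcript running best (path, hit) over all alignment calls."""

    def __init__(self, graph: DeBruijnGraph):
        self._graph = graph
        self.best: dict[str, tuple[GraphPath, AlignmentHit]] = {}

    def offer(self, path: GraphPath, hits: list[AlignmentHit]) -> None:
        for hit in hits:
            cur = self.best.get(hit.subject_id)
            if cur is None or (
                _path_order_key(self._graph, path, hit)
                < _path_order_key(self._graph, *cur)
            ):
                self.best[hit.subject_id] = (path, hit)

    def evalue_of(self, transcript_id: str) -> float:
        entry = self.best.get(transcript_id)
        return entry[1].evalue if entry else math.inf

    def __len__(self) -> int:
        return len(self.best)


class _Searcher:
    """Shared state of one run: engine access, pool updates, counters."""

    def __init__(self, graph: DeBruijnGraph, db: TranscriptDB,
                 scheme: ScoringScheme, params: SearchParams,
                 pool: CandidatePool):
        self.graph = graph
        self.db = db
        self.engine = db.engine(scheme)
        self.params = params
        self.pool = pool
        self.n_searches = 0

    def search_path(self, path: GraphPath) -> dict[str, AlignmentHit]:
        """Search a path's spelled sequence against the whole database,
        update the pool, and return hits keyed by subject."""
        seq = spell_path(self.graph, path)
        hits = self.engine.search(seq, e_cut=self.params.e_i, with_coords=False)
        self.n_searches += 1
        self.pool.offer(path, hits)
        return {h.subject_id: h for h in hits}

    def evalue_to(self, path: GraphPath, transcript_id: str) -> float:
        h = self.search_path(path).get(transcript_id)
        return h.evalue if h else math.inf


def select_seeds(graph: DeBruijnGraph, db: TranscriptDB,
                 scheme: ScoringScheme, params: SearchParams,
                 pool: Optional[CandidatePool] = None
                 ) -> list[SeedAssignment]:
    """Search every node against the database and keep, per transcript, the
    ``n_seeds`` nodes with the best e-value (<= e_i)."""
    if pool is None:
        pool = CandidatePool(graph)
    searcher = _Searcher(graph, db, scheme, params, pool)
    per_transcript: dict[str, list[tuple[OrientedNode, AlignmentHit]]] = {}
    for nid in sorted(graph.nodes):
        step = OrientedNode(nid, 1)
        hits = searcher.search_path(GraphPath((step,)))
        for tid, hit in hits.items():
            per_transcript.setdefault(tid, []).append((step, hit))
    out = []
    for tid in sorted(per_transcript):
        ranked = sorted(
            per_transcript[tid],
            key=lambda nh: (nh[1].evalue, -nh[1].bit_score, nh[0].id),
        )
        out.append(SeedAssignment(tid, ranked[: params.n_seeds]))
    return out


def _candidate_order(searcher: _Searcher, path: GraphPath,
                     transcript_id: str,
                     succs: list[OrientedNode]
                     ) -> list[tuple[float, GraphPath]]:
    cands = []
    for s in succs:
        p2 = path.extend(s)
        hits = searcher.search_path(p2)
        h = hits.get(transcript_id)
        e = h.evalue if h else math.inf
        key = (
            _path_order_key(searcher.graph, p2, h)
            if h
            else (math.inf, 0.0, 0, p2.id_signature())
        )
        cands.append((e, key, p2))
    cands.sort(key=lambda t: t[1])
    return [(e, p) for e, _, p in cands]


def short_node_lookahead(searcher: _Searcher, path: GraphPath,
                         transcript_id: str, cur_e: float
                         ) -> Optional[tuple[GraphPath, float]]:
    """Explore up to ``lookahead`` nodes past a short next node; commit the
    best multi-node step only if its terminal e-value improves on ``cur_e``."""
    params = searcher.params
    graph = searcher.graph
    k = graph.params.k
    short_len = params.short_len if params.short_len is not None else k
    depth = params.lookahead
    if depth <= 0:
        return None

    best: Optional[tuple[tuple, GraphPath, float]] = None
    frontier = []
    for s in graph.out_steps(path.steps[-1]):
        contrib = len(graph.nodes[s.id].seq) - (k - 1)
        if contrib < short_len:
            frontier.append((path.extend(s), 1))
    while frontier:
        p, d = frontier.pop(0)
        hits = searcher.search_path(p)
        h = hits.get(transcript_id)
        if h is not None and _improves(h.evalue, cur_e):
            key = _path_order_key(graph, p, h)
            if best is None or key < best[0]:
                best = (key, p, h.evalue)
        if d < depth:
            for s in graph.out_steps(p.steps[-1]):
                frontier.append((p.extend(s), d + 1))
    if best is None:
        return None
    return best[1], best[2]


def extend_forward(graph: DeBruijnGraph, path: GraphPath, transcript_id: str,
                   db: TranscriptDB, scheme: ScoringScheme,
                   params: SearchParams, pool: CandidatePool) -> GraphPath:
    """Greedy single-direction extension driven by e-value improvement."""
    searcher = _Searcher(graph, db, scheme, params, pool)
    return _extend_forward(searcher, path, transcript_id)


def _extend_forward(searcher: _Searcher, path: GraphPath,
                    transcript_id: str) -> GraphPath:
    graph = searcher.graph
    params = searcher.params
    cur_e = searcher.evalue_to(path, transcript_id)
    steps = 0
    while steps < params.max_steps:
        succs = graph.out_steps(path.steps[-1])
        if not succs:
            break
        cands = _candidate_order(searcher, path, transcript_id, succs)
        best_e, best_path = cands[0]
        if _improves(best_e, cur_e):
            path, cur_e = best_path, best_e
            steps += 1
            continue
        ahead = short_node_lookahead(searcher, path, transcript_id, cur_e)
        if ahead is not None:
            committed, cur_e = ahead
            steps += len(committed.steps) - len(path.steps)
            path = committed
            continue
        break
    else:
        logger.warning(
            "extension for %s truncated at max_steps=%d",
            transcript_id, params.max_steps,
        )
    return path


def extend_seed(graph: DeBruijnGraph, seed: OrientedNode, transcript_id: str,
                db: TranscriptDB, scheme: ScoringScheme, params: SearchParams,
                pool: CandidatePool) -> GraphPath:
    """Extend forward from the seed and from its twin, merge the two through
    the seed, search the merged path, and return it."""
    searcher = _Searcher(graph, db, scheme, params, pool)
    return _extend_seed(searcher, seed, transcript_id)


def _extend_seed(searcher: _Searcher, seed: OrientedNode,
                 transcript_id: str) -> GraphPath:
    p_fwd = _extend_forward(searcher, GraphPath((seed,)), transcript_id)
    p_twin = _extend_forward(searcher, GraphPath((seed.twin,)), transcript_id)
    upstream = twin_path(p_twin)
    assert upstream.steps[-1] == seed, "twin extension must end at the seed"
    merged = GraphPath(upstream.steps[:-1] + p_fwd.steps)
    searcher.search_path(merged)
    return merged


def run_search(graph: DeBruijnGraph, db: TranscriptDB, scheme: ScoringScheme,
               params: Optional[SearchParams] = None) -> CandidatePool:
    """Full pipeline: seed selection, then extension of every (transcript,
    seed) pair in deterministic order, with (seed, transcript) memoization."""
    if params is None:
        params = SearchParams()
    pool = CandidatePool(graph)
    if not graph.nodes or not db.records:
        return pool
    assignments = select_seeds(graph, db, scheme, params, pool)
    searcher = _Searcher(graph, db, scheme, params, pool)
    done: set[tuple[OrientedNode, str]] = set()
    for assignment in assignments:  # already sorted by transcript id
        for seed, _hit in assignment.seeds:  # already best-first
            key = (seed, assignment.transcript_id)
            if key in done:
                continue
            done.add(key)
            _extend_seed(searcher, seed, assignment.transcript_id)
    logger.info(
        "run_search: %d transcripts pooled, %d path searches",
        len(pool), searcher.n_searches,
    )
    return pool
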