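"""Final per-transcript extraction and evaluation metrics.

Applies the final e-value cutoff ``e_f`` to the candidate pool, trims each
winning path to the nodes that take part in the best alignment, and emits
FASTA/TSV output.  Also computes the evaluation quantities used throughout:
the number of transcripts recovered, the count of near-full-length records
(subject coverage above a threshold, 0.8 by default), and a nodes-only
baseline that mimics reporting raw assembler contigs without any extension.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from .dbg import DeBruijnGraph, GraphPath, OrientedNode, path_node_offsets, spell_path
from .homology import AlignmentHit, ScoringScheme, TranscriptDB
from .seedextend import CandidatePool
from .seqio import TranscriptRecord


@dataclass
class RecoveredTranscript:
    transcript_id: str
    path: GraphPath
    spelled_seq: str
    hit: AlignmentHit
    subject_coverage: float

    @property
    def fasta_id(self) -> str:
        return f"{self.transcript_id}|{self.path}|e={self.hit.evalue:.3g}"


def _trim(path: GraphPath, hit: AlignmentHit, graph: DeBruijnGraph
          ) -> tuple[GraphPath, int]:
    """Trimmed path plus the spelled offset of its first kept node."""
    intervals = path_node_offsets(graph, path)
    keep = [
        i for i, (a, b) in enumerate(intervals)
        if a < hit.q_end and b > hit.q_start
    ]
    if not keep:
        raise ValueError("alignment does not intersect any node of the path")
    lo, hi = keep[0], keep[-1]
    return GraphPath(path.steps[lo : hi + 1]), intervals[lo][0]


def trim_to_alignment(path: GraphPath, hit: AlignmentHit,
                      graph: DeBruijnGraph) -> GraphPath:
    """Drop leading/trailing nodes whose spelled interval lies entirely
    outside the aligned query region; interior nodes are always kept."""
    return _trim(path, hit, graph)[0]


def finalize(pool: CandidatePool, graph: DeBruijnGraph, db: TranscriptDB,
             scheme: ScoringScheme, e_f: float) -> list[RecoveredTranscript]:
    """Report, per transcript with pool e-value <= e_f, the best path trimmed
    to its alignment.  Pure function of the pool (deterministic)."""
    engine = db.engine(scheme)
    by_id = {r.id: r for r in db.records}
    out = []
    for tid in sorted(pool.best):
        path, hit = pool.best[tid]
        if hit.evalue > e_f:
            continue
        if hit.q_start is None:  # score-only pool entry: recover coordinates
            full = engine.hit_with_coords(spell_path(graph, path), by_id[tid])
            if full is None:  # pragma: no cover - pool hits always realign
                continue
            hit = full
        trimmed, offset = _trim(path, hit, graph)
        spelled = spell_path(graph, trimmed)
        shifted = replace(
            hit, q_start=hit.q_start - offset, q_end=hit.q_end - offset
        )
        coverage = (hit.s_end - hit.s_start) / len(by_id[tid].seq)
        out.append(RecoveredTranscript(tid, trimmed, spelled, shifted, coverage))
    return out


def full_length_count(records: Iterable[RecoveredTranscript],
                      threshold: float = 0.8) -> int:
    """Number of records whose best alignment covers at least ``threshold``
    of the subject (the near-full-length rule; threshold inclusive)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    return sum(1 for r in records if r.subject_coverage >= threshold)


def nodes_only_baseline(graph: DeBruijnGraph, db: TranscriptDB,
                        scheme: ScoringScheme, e_f: float
                        ) -> list[RecoveredTranscript]:
    """Per transcript, the best single-node hit passing e_f — what one gets
    by searching raw contigs without any graph extension."""
    engine = db.engine(scheme)
    best: dict[str, tuple[GraphPath, AlignmentHit]] = {}
    for nid in sorted(graph.nodes):
        path = GraphPath((OrientedNode(nid, 1),))
        for hit in engine.search(graph.nodes[nid].seq, e_cut=e_f,
                                 with_coords=False):
            cur = best.get(hit.subject_id)
            if cur is None or (hit.evalue, -hit.bit_score, nid) < (
                cur[1].evalue, -cur[1].bit_score, cur[0].steps[0].id
            ):
                best[hit.subject_id] = (path, hit)
    by_id = {r.id: r for r in db.records}
    out = []
    for tid in sorted(best):
        path, _ = best[tid]
        hit = engine.hit_with_coords(spell_path(graph, path), by_id[tid])
        if hit is None or hit.evalue > e_f:
            continue
        coverage = (hit.s_end - hit.s_start) / len(by_id[tid].seq)
        out.append(RecoveredTranscript(
            tid, path, spell_path(graph, path), hit, coverage
        ))
    return out


# -- output writers ------------------------------------------------------

TSV_COLUMNS = [
    "transcript_id", "node_path", "path_len_nt", "bit_score", "evalue",
    "q_start", "q_end", "s_start", "s_end", "frame", "subject_coverage",
]


def write_results_tsv(records: Iterable[RecoveredTranscript],
                      path: str | Path) -> None:
    """TSV report; alignment coordinates are 1-based inclusive (BLAST
    convention), converted from the internal 0-based half-open form."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in records:
            h = r.hit
            fh.write("\t".join(map(str, [
                r.transcript_id, str(r.path), len(r.spelled_seq),
                f"{h.bit_score:.1f}", f"{h.evalue:.3g}",
                h.q_start + 1, h.q_end, h.s_start + 1, h.s_end,
                h.frame, f"{r.subject_coverage:.3f}",
            ])) + "\n")


def write_recovered_fasta(records: Iterable[RecoveredTranscript],
                          path: str | Path) -> None:
    recs = [
        TranscriptRecord(r.fasta_id, r.spelled_seq, "nucleotide")
        for r in records
    ]
    from .seqio import write_fasta

    write_fasta(recs, path)
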