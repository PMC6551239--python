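"""Independent reference implementations used only by the tests.

These are deliberately naive (quadratic dynamic programming, exhaustive path
enumeration) and share no code with the package internals they check.
"""

from __future__ import annotations

import itertools

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def gotoh_local(a: str, b: str, score, gap_open: int, gap_extend: int) -> int:
    """Textbook affine-gap local alignment score.

    A gap of length L costs ``gap_open + gap_extend * L`` (the first gap
    position costs open+extend, each further one extend).  ``score(x, y)``
    gives the substitution score.
    """
    NEG = float("-inf")
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + score(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(round(best))


def sw_nt_best(query: str, subject: str, match: int, mismatch: int,
               gap_open: int, gap_extend: int) -> int:
    """Best local score over both query strands under match/mismatch scoring."""

    def s(x: str, y: str) -> int:
        return match if (x == y and x != "N") else mismatch

    return max(
        gotoh_local(query, subject, s, gap_open, gap_extend),
        gotoh_local(rc(query), subject, s, gap_open, gap_extend),
    )


_CODON_TABLE = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def translate(seq: str) -> str:
    table = _codon_table()
    return "".join(
        table.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def six_frame_best(query: str, subject: str, matrix, gap_open: int,
                   gap_extend: int) -> int:
    """Best local score over all six reading frames against a peptide."""

    def s(x: str, y: str) -> float:
        return matrix[x, y]

    best = 0
    for strand_seq in (query, rc(query)):
        for off in (0, 1, 2):
            pep = translate(strand_seq[off:])
            if pep:
                best = max(
                    best, gotoh_local(pep, subject, s, gap_open, gap_extend)
                )
    return best


def enumerate_simple_paths(graph, max_paths: int = 200_000):
    """Every simple oriented path (no oriented node visited twice; a node may
    appear once per orientation) of a condensed graph."""
    from dbgext.dbg import GraphPath, OrientedNode

    paths = []

    def extend(steps, used):
        paths.append(GraphPath(tuple(steps)))
        if len(paths) > max_paths:
            raise RuntimeError("path explosion")
        for nxt in graph.out_steps(steps[-1]):
            if nxt not in used:
                extend(steps + [nxt], used | {nxt})

    for nid in sorted(graph.nodes):
        for orient in (1, -1):
            start = OrientedNode(nid, orient)
            extend([start], {start})
    return paths
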