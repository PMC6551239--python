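"""Local-alignment scoring engine with Karlin-Altschul e-value statistics.

Two search modes mirror the two database flavors:

* ``nt`` — nucleotide query against nucleotide transcripts, both query
  strands (blastn-like scoring: match +2 / mismatch -3, gap 5+2L).
* ``tx`` — nucleotide query translated in all six reading frames against
  protein sequences (blastx-like: BLOSUM62, gap 11+1L).

The Smith-Waterman dynamic programming itself runs through
:class:`Bio.Align.PairwiseAligner`; this module owns scheme configuration,
strand/frame handling, coordinate conversion back to the forward nucleotide
strand, and the statistics: ``bit = (lambda * raw - ln K) / ln 2`` and
``E = m * n * 2^-bit`` with raw (uncorrected) search-space lengths.  In tx
mode the query length m is the translated length ``floor(len/3)``.

A gap of length L costs ``gap_open + gap_extend * L`` (BLAST convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy.optimize import brentq

from .seqio import TranscriptRecord, reverse_complement

#: frames in deterministic preference order for ties
FRAMES = (1, 2, 3, -1, -2, -3)

_UNIFORM_NT = {b: 0.25 for b in "ACGT"}


def solve_lambda(
    scores: dict[tuple[str, str], float] | Sequence[Sequence[float]],
    background: dict[str, float] | Sequence[float],
    tol: float = 1e-12,
) -> float:
    """Solve the ungapped Karlin-Altschul identity sum p_i p_j e^(lambda s_ij) = 1.

    Requires a negative expected pair score and at least one positive score;
    the positive root is found by bracketing + Brent's method.
    """
    if isinstance(background, dict):
        letters = sorted(background)
        p = np.array([background[a] for a in letters])
        s = np.array([[scores[(a, b)] for b in letters] for a in letters])
    else:
        p = np.asarray(background, dtype=float)
        s = np.asarray(scores, dtype=float)
    pp = np.outer(p, p)
    expected = float((pp * s).sum())
    if expected >= 0:
        raise ValueError("expected pair score must be negative")
    if s.max() <= 0:
        raise ValueError("at least one pair score must be positive")

    def f(lam: float) -> float:
        return float((pp * np.exp(lam * s)).sum()) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - defensive
            raise ValueError("failed to bracket lambda")
    return float(brentq(f, 1e-9, hi, xtol=tol, rtol=8.9e-16))


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring parameters plus the Karlin-Altschul constants they imply."""

    mode: str  # "nt" | "tx"
    match: int = 2
    mismatch: int = -3
    matrix_name: str = "BLOSUM62"
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 0.0
    kparam: float = 0.0

    @staticmethod
    def nucleotide(match: int = 2, mismatch: int = -3,
                   gap_open: int = 5, gap_extend: int = 2,
                   kparam: float = 0.41) -> "ScoringScheme":
        """blastn-like scheme; lambda solved for the ungapped scores under a
        uniform nucleotide background and reused for gapped scores."""
        lam = solve_lambda(
            {(a, b): (match if a == b else mismatch) for a in "ACGT" for b in "ACGT"},
            _UNIFORM_NT,
        )
        return ScoringScheme("nt", match=match, mismatch=mismatch,
                             gap_open=gap_open, gap_extend=gap_extend,
                             lam=lam, kparam=kparam)

    @staticmethod
    def translated(matrix_name: str = "BLOSUM62", gap_open: int = 11,
                   gap_extend: int = 1, lam: float = 0.267,
                   kparam: float = 0.041) -> "ScoringScheme":
        """blastx-like scheme with the published gapped BLOSUM62 constants."""
        return ScoringScheme("tx", matrix_name=matrix_name, gap_open=gap_open,
                             gap_extend=gap_extend, lam=lam, kparam=kparam)

    def bit_score(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.kparam)) / math.log(2)

    def query_units(self, nt_len: int) -> int:
        """Search-space query length: residues (tx) or bases (nt)."""
        return nt_len // 3 if self.mode == "tx" else nt_len


def evalue(bit_score: float, query_len: int, db_len: int) -> float:
    """E = m * n * 2^(-bit)."""
    return query_len * db_len * math.pow(2.0, -bit_score)


@dataclass
class AlignmentHit:
    """Best local alignment of one query against one subject.

    Query coordinates are 0-based half-open on the forward nucleotide strand
    of the query; ``frame`` is 0 in nt mode and +-1..3 in tx mode.
    Coordinates may be ``None`` for score-only hits produced inside the
    extension loop; they are filled in before reporting.
    """

    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    q_start: Optional[int] = None
    q_end: Optional[int] = None
    s_start: Optional[int] = None
    s_end: Optional[int] = None
    frame: int = 0


@dataclass
class TranscriptDB:
    """A related-organism transcript database (nucleotide or protein)."""

    records: list[TranscriptRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in database")
        alphabets = {r.alphabet for r in self.records}
        if len(alphabets) > 1:
            raise ValueError("mixed alphabets in database")
        self._engines: dict[ScoringScheme, SearchEngine] = {}

    @property
    def total_len(self) -> int:
        return sum(len(r.seq) for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def engine(self, scheme: ScoringScheme) -> "SearchEngine":
        eng = self._engines.get(scheme)
        if eng is None:
            eng = SearchEngine(self, scheme)
            self._engines[scheme] = eng
        return eng


def _nt_matrix(match: int, mismatch: int) -> substitution_matrices.Array:
    m = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            m[a, b] = float(match) if (a == b and a != "N") else float(mismatch)
    return m


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    if scheme.mode == "nt":
        aligner.substitution_matrix = _nt_matrix(scheme.match, scheme.mismatch)
    else:
        aligner.substitution_matrix = substitution_matrices.load(scheme.matrix_name)
    # first gap position costs open+extend, later positions extend each
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def translate_frame(seq: str, frame: int) -> str:
    """Translate one reading frame; stops rendered as '*'."""
    s = seq if frame > 0 else reverse_complement(seq)
    off = abs(frame) - 1
    sub = s[off : off + 3 * ((len(s) - off) // 3)]
    return str(Seq(sub).translate())


def _blocks(alignment) -> tuple[int, int, int, int]:
    """(q_start, q_end, s_start, s_end) of a Bio.Align alignment where the
    query was passed as target and the subject as query."""
    qb, sb = alignment.aligned
    return int(qb[0][0]), int(qb[-1][1]), int(sb[0][0]), int(sb[-1][1])


class SearchEngine:
    """Searches queries against one database under one scoring scheme.

    Results for a given spelled sequence are cached, which matters in the
    extension loop where many seeds revisit the same paths.
    """

    def __init__(self, db: TranscriptDB, scheme: ScoringScheme,
                 word_size: int = 14):
        expected = "protein" if scheme.mode == "tx" else "nucleotide"
        if db.records and db.records[0].alphabet != expected:
            raise ValueError(
                f"{scheme.mode} mode requires a {expected} database"
            )
        self.db = db
        self.scheme = scheme
        self.aligner = _make_aligner(scheme)
        self.word_size = word_size
        self._cache: dict[str, list[AlignmentHit]] = {}
        self._subject_words = None
        if scheme.mode == "nt":
            self._subject_words = [
                _word_set(r.seq, word_size) for r in db.records
            ]

    # -- pairwise -------------------------------------------------------

    def _score_nt(self, query: str, subject: str) -> tuple[int, int]:
        """(raw score, strand +1/-1) over both query strands."""
        best = 0.0
        strand = 1
        for st, q in ((1, query), (-1, reverse_complement(query))):
            if not q or not subject:
                continue
            sc = self.aligner.score(q, subject)
            if sc > best:
                best, strand = sc, st
        return int(round(best)), strand

    def _score_tx(self, query: str, subject: str) -> tuple[int, int]:
        """(raw score, frame) over all six reading frames."""
        best = 0.0
        best_frame = 0
        for frame in FRAMES:
            pep = translate_frame(query, frame)
            if not pep or not subject:
                continue
            sc = self.aligner.score(pep, subject)
            if sc > best:
                best, best_frame = sc, frame
        return int(round(best)), best_frame

    def score_pair(self, query: str, subject: str) -> tuple[int, int]:
        """(raw score, strand-or-frame) without traceback."""
        if self.scheme.mode == "nt":
            return self._score_nt(query, subject)
        return self._score_tx(query, subject)

    def hit_with_coords(self, query: str, subject_rec: TranscriptRecord
                        ) -> Optional[AlignmentHit]:
        """Full best hit (with coordinates) of query against one subject."""
        scheme = self.scheme
        subject = subject_rec.seq
        raw, sf = self.score_pair(query, subject)
        if raw <= 0:
            return None
        L = len(query)
        if scheme.mode == "nt":
            q = query if sf > 0 else reverse_complement(query)
            aln = self.aligner.align(q, subject)[0]
            qs, qe, ss, se = _blocks(aln)
            if sf < 0:
                qs, qe = L - qe, L - qs
            frame = 0
        else:
            frame = sf
            pep = translate_frame(query, frame)
            aln = self.aligner.align(pep, subject)[0]
            aqs, aqe, ss, se = _blocks(aln)
            off = abs(frame) - 1
            if frame > 0:
                qs, qe = off + 3 * aqs, off + 3 * aqe
            else:
                qs, qe = L - (off + 3 * aqe), L - (off + 3 * aqs)
        bit = scheme.bit_score(raw)
        ev = evalue(bit, scheme.query_units(L), self.db.total_len)
        return AlignmentHit(subject_rec.id, raw, bit, ev, qs, qe, ss, se, frame)

    # -- database search ------------------------------------------------

    def _candidates(self, query: str) -> list[int]:
        """Indices of subjects passing the shared-word prefilter (nt only)."""
        if self._subject_words is None or len(query) < 2 * self.word_size:
            return list(range(len(self.db.records)))
        words = _word_set(query, self.word_size)
        words |= _word_set(reverse_complement(query), self.word_size)
        return [
            i for i, sw in enumerate(self._subject_words)
            if not words.isdisjoint(sw)
        ]

    def search(self, query: str, e_cut: float,
               with_coords: bool = True) -> list[AlignmentHit]:
        """Best hit per subject with e-value <= e_cut, sorted by (e-value,
        bit score desc, subject id).  Score-only searches are cached
        unfiltered, so the cutoff may differ between calls."""
        key = query
        hits = self._cache.get(key)
        if hits is None:
            hits = []
            scheme = self.scheme
            m = scheme.query_units(len(query))
            n = self.db.total_len
            if m >= 1 and n >= 1:
                for i in self._candidates(query):
                    rec = self.db.records[i]
                    raw, sf = self.score_pair(query, rec.seq)
                    if raw <= 0:
                        continue
                    bit = scheme.bit_score(raw)
                    ev = evalue(bit, m, n)
                    frame = sf if scheme.mode == "tx" else 0
                    hits.append(AlignmentHit(rec.id, raw, bit, ev, frame=frame))
                hits.sort(key=lambda h: (h.evalue, -h.bit_score, h.subject_id))
            self._cache[key] = hits
        out = [h for h in hits if h.evalue <= e_cut]
        if with_coords:
            by_id = {r.id: r for r in self.db.records}
            out = [self.hit_with_coords(query, by_id[h.subject_id]) for h in out]
            out = [h for h in out if h is not None and h.evalue <= e_cut]
        return out


def _word_set(seq: str, w: int) -> set[str]:
    return {seq[i : i + w] for i in range(len(seq) - w + 1)}


# -- module-level conveniences (pairwise ops per the module contract) ----


def align_local_nt(query: str, subject: str,
                   scheme: Optional[ScoringScheme] = None
                   ) -> Optional[AlignmentHit]:
    """Optimal local alignment over both query strands; exact, no prefilter.

    Coordinates are on the forward query strand; returns None when no
    positive-scoring alignment exists (including empty inputs).
    """
    if scheme is None:
        scheme = ScoringScheme.nucleotide()
    if scheme.mode != "nt":
        raise ValueError("align_local_nt requires an nt-mode scheme")
    db = TranscriptDB([TranscriptRecord("subject", subject, "nucleotide")]) \
        if subject else None
    if db is None or not query:
        return None
    return db.engine(scheme).hit_with_coords(query, db.records[0])


def align_translated(query: str, subject: str,
                     scheme: Optional[ScoringScheme] = None
                     ) -> Optional[AlignmentHit]:
    """Best hit over all six reading frames against a protein subject."""
    if scheme is None:
        scheme = ScoringScheme.translated()
    if scheme.mode != "tx":
        raise ValueError("align_translated requires a tx-mode scheme")
    if len(query) < 3 or not subject:
        return None
    db = TranscriptDB([TranscriptRecord("subject", subject, "protein")])
    return db.engine(scheme).hit_with_coords(query, db.records[0])


def search_db(query: str, db: TranscriptDB, scheme: ScoringScheme,
              e_cut: float, with_coords: bool = True) -> list[AlignmentHit]:
    """Per-subject best local alignment with e-value <= e_cut."""
    if not db.records:
        return []
    return db.engine(scheme).search(query, e_cut, with_coords=with_coords)
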