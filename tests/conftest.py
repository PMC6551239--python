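import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from dbgext.dbg import DeBruijnGraph, GraphParams, build_graph
from dbgext.homology import ScoringScheme, TranscriptDB
from dbgext.seqio import Read, TranscriptRecord


@pytest.fixture(scope="session")
def nt_scheme() -> ScoringScheme:
    return ScoringScheme.nucleotide()


@pytest.fixture(scope="session")
def tx_scheme() -> ScoringScheme:
    return ScoringScheme.translated()


@pytest.fixture()
def bubble_graph() -> DeBruijnGraph:
    """Two 6 nt sequences sharing a 3 nt prefix: a branch node spelling AAT
    with two 5 nt continuations (ATCTG / ATGTG).  Palindrome-free at k=3."""
    reads = [Read("a", "AATCTG"), Read("b", "AATGTG")]
    return build_graph(reads, GraphParams(k=3, c=0, tip_len=3))


@pytest.fixture()
def bubble_db() -> TranscriptDB:
    return TranscriptDB([TranscriptRecord("t1", "AATCTG")])
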