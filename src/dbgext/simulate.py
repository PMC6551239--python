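"""Synthetic data: planted transcriptomes, diverged orthologs, short reads.

The generator emulates the input regime the pipeline targets: multi-exon
gene models with exon-skipping isoforms, a related-organism database at a
controlled divergence, and single-end short reads (71 bp by default) with
per-base qualities and optional substitution errors.

Transcripts are built from stop-free codons and exon lengths are rounded to
multiples of 3, so every transcript carries a clean open reading frame in
frame +1 — protein-mode orthologs are then simply the translated, mutated
peptide.  Exon skipping removes one random internal exon per extra isoform,
which plants the bubble structures (including the short ~2(k-1) bp junction
node) that the graph search must navigate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .seqio import Read, TranscriptRecord

_AA = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (90, 300)  # rounded down to multiples of 3
    isoform_count: tuple[int, int] = (1, 1)
    read_len: int = 71
    coverage: float = 30.0            # mean per-transcript coverage
    coverage_sigma: float = 0.0       # log-normal sigma; 0 = constant
    base_error_rate: float = 0.0
    low_qual_tail_frac: float = 0.0   # fraction of reads given a low-qual tail
    low_qual_tail_len: int = 10
    ortholog_identity: float = 0.85
    ortholog_mode: str = "protein"    # "nt" | "protein"

    def __post_init__(self) -> None:
        for lo, hi in (self.exons_per_gene, self.exon_len, self.isoform_count):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be nonempty")
        if not 0 < self.ortholog_identity <= 1:
            raise ValueError("ortholog_identity must be in (0, 1]")
        if not 0 <= self.base_error_rate < 1:
            raise ValueError("base_error_rate must be in [0, 1)")


@dataclass
class ExonModel:
    gene: str
    isoform: str
    exon_index: int
    start: int  # 0-based half-open, on the isoform transcript
    end: int


@dataclass
class Transcriptome:
    transcripts: list[TranscriptRecord]
    exon_models: list[ExonModel]
    gene_of: dict[str, str]  # transcript id -> gene id


def simulate_transcriptome(config: SimConfig) -> Transcriptome:
    """Generate gene models and their isoform transcripts.

    Isoform 1 of each gene contains every exon; each further isoform skips
    one distinct random internal exon.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    transcripts: list[TranscriptRecord] = []
    models: list[ExonModel] = []
    gene_of: dict[str, str] = {}
    for g in range(1, config.n_genes + 1):
        gene = f"gene{g:03d}"
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        exon_seqs = []
        for _ in range(n_exons):
            ln = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            n_codons = max(ln // 3, 1)
            idx = rng.integers(0, len(_CODONS), size=n_codons)
            exon_seqs.append("".join(_CODONS[i] for i in idx))

        n_iso = int(rng.integers(config.isoform_count[0],
                                 config.isoform_count[1] + 1))
        internal = list(range(1, n_exons - 1))
        max_extra = min(n_iso - 1, len(internal))
        skipped = list(rng.choice(internal, size=max_extra, replace=False)) \
            if max_extra > 0 else []

        isoform_exons = [list(range(n_exons))]
        for skip in skipped:
            isoform_exons.append([i for i in range(n_exons) if i != skip])

        for iso_num, exon_ids in enumerate(isoform_exons, start=1):
            tid = f"{gene}.i{iso_num}"
            pos = 0
            seq_parts = []
            for ei in exon_ids:
                s = exon_seqs[ei]
                models.append(ExonModel(gene, tid, ei, pos, pos + len(s)))
                seq_parts.append(s)
                pos += len(s)
            transcripts.append(TranscriptRecord(tid, "".join(seq_parts)))
            gene_of[tid] = gene
    return Transcriptome(transcripts, models, gene_of)


def mutate_ortholog(transcript: TranscriptRecord, identity: float,
                    mode: str, seed: int) -> TranscriptRecord:
    """A diverged related-organism counterpart of one transcript.

    nt mode substitutes bases at rate 1-identity; protein mode translates
    the transcript's reading frame and substitutes amino acids at rate
    1-identity.  Deterministic under a fixed seed.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if mode == "nt":
        alphabet, seq = "ACGT", transcript.seq
    elif mode == "protein":
        alphabet = _AA
        seq = str(Seq(transcript.seq[: 3 * (len(transcript.seq) // 3)]).translate())
        seq = seq.rstrip("*")
    else:
        raise ValueError(f"unknown ortholog mode {mode!r}")
    out = list(seq)
    hit = rng.random(len(out)) < (1.0 - identity)
    for i in np.flatnonzero(hit):
        choices = [a for a in alphabet if a != out[i]]
        out[i] = choices[int(rng.integers(0, len(choices)))]
    return TranscriptRecord(
        f"{transcript.id}_ortholog", "".join(out),
        "nucleotide" if mode == "nt" else "protein",
    )


def make_ortholog_db(transcriptome: Transcriptome, config: SimConfig
                     ) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Ortholog record per transcript plus the truth mapping
    transcript id -> ortholog id."""
    rng = np.random.default_rng(config.seed + 1)
    records, truth = [], {}
    for t in transcriptome.transcripts:
        rec = mutate_ortholog(t, config.ortholog_identity,
                              config.ortholog_mode,
                              int(rng.integers(0, 2**31 - 1)))
        records.append(rec)
        truth[t.id] = rec.id
    return records, truth


def simulate_reads(transcripts: list[TranscriptRecord],
                   config: SimConfig) -> list[Read]:
    """Uniform single-end reads from both strands of each transcript.

    Per-transcript coverage is log-normal with mean ``coverage`` (constant
    when ``coverage_sigma`` is 0).  Substitution errors occur at
    ``base_error_rate``; correct bases get quality 38, and a configurable
    fraction of reads receives a low-quality (q=2) tail to exercise the
    quality-trimming rule (the tail bases themselves stay correct).
    """
    from .seqio import reverse_complement

    rng = np.random.default_rng(config.seed + 2)
    L = config.read_len
    reads: list[Read] = []
    for t in transcripts:
        if len(t.seq) < L:
            raise ValueError(f"{t.id}: transcript shorter than read length")
        if config.coverage_sigma > 0:
            sigma = config.coverage_sigma
            mu = np.log(config.coverage) - sigma**2 / 2
            cov = float(rng.lognormal(mu, sigma))
        else:
            cov = config.coverage
        n_reads = int(round(cov * len(t.seq) / L))
        starts = rng.integers(0, len(t.seq) - L + 1, size=n_reads)
        # anchor one read at each transcript end so terminal k-mers are
        # always covered (uniform starts alone leave ends uncovered)
        if n_reads >= 2:
            starts[0] = 0
            starts[1] = len(t.seq) - L
        strands = rng.random(n_reads) < 0.5
        for j, (st, minus) in enumerate(zip(starts, strands)):
            frag = t.seq[st : st + L]
            if minus:
                frag = reverse_complement(frag)
            bases = list(frag)
            if config.base_error_rate > 0:
                errs = np.flatnonzero(rng.random(L) < config.base_error_rate)
                for i in errs:
                    bases[i] = "ACGT"[(("ACGT".index(bases[i])) +
                                       int(rng.integers(1, 4))) % 4]
            quals = [38] * L
            if (config.low_qual_tail_frac > 0
                    and rng.random() < config.low_qual_tail_frac):
                for i in range(max(0, L - config.low_qual_tail_len), L):
                    quals[i] = 2
            reads.append(Read(f"{t.id}_r{j}", "".join(bases), quals))
    return reads


def write_gene_models_tsv(models: list[ExonModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tisoform\texon_index\tstart\tend\n")
        for m in models:
            fh.write(f"{m.gene}\t{m.isoform}\t{m.exon_index}\t{m.start}\t{m.end}\n")


def write_truth_tsv(truth: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript\tortholog\n")
        for tid in sorted(truth):
            fh.write(f"{tid}\t{truth[tid]}\n")
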