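# dbgext

Recover transcripts similar to a related organism's **directly from the
condensed de Bruijn graph** of RNA-Seq reads, instead of predicting
transcripts first and searching them afterwards.

## The problem

Transcriptome studies of non-model organisms usually (1) assemble reads into
predicted transcripts with a de novo assembler and (2) BLAST the predictions
against a well-annotated relative to assign function. Because prediction is
driven by coverage, low-coverage transcripts are dropped before the homology
evidence is ever consulted. The intermediate de Bruijn graph, however, still
contains every branching possibility. `dbgext` searches that graph directly:
a path supported by strong similarity to a known transcript is reported even
when no assembler would have predicted it, which recovers more transcripts,
longer transcripts, and a finer resolution of splice isoforms.

## The algorithm

Reads are quality-trimmed (cut before the first base with Phred quality
< 15) and assembled into a **condensed de Bruijn graph**: k-mers are
vertices, read-adjacent k-mers share an edge, maximal non-branching chains
collapse into single nodes. Each stored node represents a twin pair — the
`-` orientation spells the reverse complement — and every edge `a -> b`
coexists with `twin(b) -> twin(a)`. Short dead-end tips are pruned and a
k-mer coverage cutoff *c* removes noise nodes.

For a transcript database *D* (nucleotide, or protein for cross-organism
searches) the search proceeds per transcript *t*:

1. **Seeding.** Every node is aligned against *D* (Smith–Waterman, both
   strands in `nt` mode, all six reading frames in `tx` mode). Significance
   uses Karlin–Altschul statistics: bit score
   `S' = (λ·S − ln K)/ln 2` and e-value `E = m·n·2^(−S')`. The
   `n` best-scoring nodes per transcript with `E ≤ e_i` become seeds
   (`n = 8` by default, with a permissive initial cutoff `e_i`).
2. **Greedy extension.** A seed path is extended one node at a time along
   all outgoing edges; each candidate's spelled sequence is searched against
   the whole database, and the step with the best e-value to *t* is accepted
   iff it strictly improves. A bounded lookahead lets the extension step
   across very short nodes (e.g. the ~2(k−1) bp junction node of an exon
   skip) when the improvement only materializes one node later. The same
   procedure runs from the twin node in the opposite direction, and the two
   extended paths are merged through the seed.
3. **Reporting.** Every alignment performed anywhere in the search feeds a
   candidate pool; per transcript the best (path, hit) with `E ≤ e_f`
   (`e_f < e_i`) is reported, trimmed to the nodes that take part in the
   best alignment.

Because the raw score is bounded by the subject while the e-value's
search-space term grows with the query, the e-value cannot improve
indefinitely — extension terminates even on cyclic (repeat-induced) graphs.

## Worked example

Simulate three two-isoform genes with an 85%-identity protein ortholog
database, build the graph from error-free 71 bp reads at 30×, and search:

```sh
dbgext simulate --seed 4 --n-genes 3 --isoforms 2 --out sim
dbgext build --reads sim/reads.fastq -k 25 -c 3 -o graph.gfa
dbgext search --graph graph.gfa --db sim/ortholog_db.fasta --mode tx --out out
```

The log reports per-stage counters:

```
INFO dbgext: simulated 6 transcripts, 3637 reads -> sim
INFO dbgext: graph: 12 nodes, 24 oriented edges -> graph.gfa
INFO dbgext.seedextend: run_search: 6 transcripts pooled, 87 path searches
INFO dbgext: recovered 6 transcripts (6 near-full-length) -> out
```

and `out/results.tsv` contains one row per recovered transcript:

```
transcript_id        node_path  bit_score  evalue     subject_coverage
gene001.i1_ortholog  3-,5-,7+   811.2      8.82e-239  1.000
gene001.i2_ortholog  3-,12-,7+  724.2      1.26e-212  0.993
gene002.i1_ortholog  6+,4+,9-   953.7      1.23e-281  1.000
gene002.i2_ortholog  6+,10-,9-  817.0      1.55e-240  0.998
gene003.i1_ortholog  1+,8+,2-   827.0      1.53e-243  1.000
gene003.i2_ortholog  1+,11-,2-  760.4      1.65e-223  1.000
```

Each gene's two isoforms are recovered on **distinct node paths** — they
share the flanking nodes (e.g. `3-` and `7+`) but differ in the middle,
where the skipped exon forms a bubble in the graph. `subject_coverage` is
the fraction of the database protein covered by the best alignment; every
recovery here is essentially full length. `out/recovered.fasta` holds the
spelled nucleotide sequences, with FASTA ids tracing each sequence back to
its graph path and e-value.

## Library use

```python
from dbgext import (build_graph, GraphParams, TranscriptDB, ScoringScheme,
                    SearchParams, run_search, finalize)

graph = build_graph(reads, GraphParams(k=25, c=3))
db = TranscriptDB(records)                      # nucleotide or protein
scheme = ScoringScheme.translated()             # or .nucleotide()
pool = run_search(graph, db, scheme, SearchParams(e_i=1e-6, e_f=1e-20))
recovered = finalize(pool, graph, db, scheme, e_f=1e-20)
```

See `docs/methods.md` for the model, parameter semantics, numerical choices
and known limitations.
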