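# Methods

## Graph model

The graph is the standard bidirected condensed de Bruijn graph over
canonical k-mers. A k-mer and its reverse complement are one vertex, stored
once under the lexicographically smaller form; orientation (`+`/`-`) is
realized at query time, which makes twin symmetry structural rather than a
property to maintain. k must be odd so that no k-mer is its own reverse
complement.

Edges come from **read adjacency**: two k-mers are linked when they occur
consecutively in some read (equivalently, when a (k+1)-mer occurs), on
either strand. At working k (25, 31) this coincides in practice with the
textbook definition by (k−1)-overlap, but at small k it avoids linking
k-mers that merely happen to overlap without ever being read-adjacent.
Every maximal non-branching chain is collapsed into one condensed node;
chains never extend across a hairpin (a node adjacent to its own twin,
which arises from palindromic (k+1)-mers), so spelled sequences stay
well-defined. A node records its spelled sequence, its k-mer count and the
total multiplicity of its k-mers in the reads.

Simplification mirrors short-read assembler practice:

* **Tips** — a node that is a dead end in one orientation, spells fewer
  than `tip_len` bases (default 2k, the usual tip criterion) and has an
  alternative sibling at its branch point is removed; iterated to fixpoint.
* **Coverage cutoff** — after tip removal, condensed nodes whose *average*
  k-mer multiplicity (`total_cov / kmer_count`) is below `c` are removed,
  and the graph is re-condensed. Applying the cutoff to condensed-node
  averages rather than raw k-mers matches the `cov_cutoff` semantics of the
  assemblers this tool builds on.

k-mers containing N are excluded at counting time; quality trimming
(remove everything from the first base with Phred < 15, default threshold
15) happens upstream in `seqio` and reads shorter than k then simply
contribute nothing. Graphs serialize to GFA 1.0 (one S line per twin pair
with a `KC` count tag, one L line per twin-edge pair with a `(k−1)M`
overlap, k in a `kk` header tag); the round trip is exact.

## Alignment and statistics

Local alignment is Smith–Waterman with affine gaps (a gap of length L costs
`gap_open + gap_extend·L`), executed by Biopython's `PairwiseAligner`
(C implementation); this module's tests pin it against an independent
brute-force Gotoh DP, exactly. Two schemes are provided:

* `nt` (blastn-like): match +2, mismatch −3, gap 5+2L. λ is solved from
  the ungapped Karlin–Altschul identity Σ pᵢpⱼ·exp(λ·sᵢⱼ) = 1 under a
  uniform background (λ ≈ 0.634 for +2/−3) and reused for gapped scores —
  a documented approximation, as is standard when gapped parameters are not
  estimated by simulation. K is preset to 0.41, the standard table value.
* `tx` (blastx-like): BLOSUM62, gap 11+1L, with the published gapped
  constants λ = 0.267, K = 0.041. Queries are translated in all six frames
  (stops rendered `*`, scored by the matrix's stop column); hit coordinates
  are mapped back to the forward nucleotide strand.

Bit score `S' = (λ·S − ln K)/ln 2`; e-value `E = m·n·2^(−S')` with raw
lengths (m = ⌊query/3⌋ in `tx` mode, n = total database residues). No
edge-effect length correction is applied: it would not change any
monotonicity the search relies on, and omitting it keeps E a strictly
increasing function of query length at fixed score — the property that
makes the greedy stopping rule sound.

Database search returns the best hit per subject. In `nt` mode a shared-word
prefilter (word size 14, skipped for queries shorter than twice that) skips
subjects sharing no exact word with the query; at ≥75% identity over
realistic lengths the probability of losing a true hit is negligible, and
the pairwise entry points bypass the filter entirely. During the search
loop hits are computed score-only; traceback coordinates are recovered just
before reporting, for the winning (path, subject) pairs only. Per-sequence
search results are cached, since many seeds revisit the same paths.

## Seed-and-extend search

Per database transcript, the `n_seeds` (default 8) nodes with the best
e-value ≤ `e_i` seed the extension. The permissive initial cutoff admits
lower-quality seeds that extension can later improve; the final cutoff
`e_f < e_i` is applied only at reporting. Defaults follow the two regimes
the tool is built for: same-organism nucleotide searches use
`e_i = 1e−15, e_f = 1e−100`; cross-organism translated searches use
`e_i = 1e−6, e_f = 1e−20`.

Extension is greedy and single-direction: all one-node extensions are
spelled and searched against the whole database, and the best candidate is
accepted only if its e-value to the seeding transcript strictly improves
(relative tolerance 1e−12; ties broken by bit score, then shorter spelled
length, then lexicographically smallest oriented-id list — all tie-breaks
are total, so runs are deterministic). The loop stops at a dead end, on
non-improvement, or at `max_steps` (a safety bound; the e-value argument
above guarantees termination before it in practice). The twin node is
extended the same way in the opposite direction and the two paths are
merged through the seed; the merged path is searched once more. Merged
paths are not re-extended.

**Short-node rule.** A very short node (contributing fewer than `short_len`
new bases, default k) may not improve the e-value by itself even when the
path through it does — the exon-skip junction node of length ~2(k−1) is the
canonical case. When the best one-node step fails and some candidate is
short, a bounded lookahead (depth `lookahead`, default 2) explores past the
short candidates and commits the multi-node step iff its terminal e-value
improves on the pre-step best. Setting `lookahead = 0` disables the rule.
All paths explored — accepted or not — still update the candidate pool.

Every alignment invocation anywhere in the run updates a per-transcript
pool of the best (path, hit) seen; the pool is monotone by construction.
Reporting applies `e_f`, trims each winning path to the nodes whose spelled
interval intersects the aligned query region (interior nodes are always
kept), and emits FASTA plus a TSV with 1-based inclusive alignment
coordinates. `subject_coverage` is the aligned subject span over the
subject length (amino-acid length in `tx` mode). A nodes-only baseline —
best single-node hit per transcript, no extension — provides the comparison
point for what raw contigs alone would recover; because seeding searches
every node under the looser cutoff and the pool is monotone, every
baseline recovery is also an extension recovery with an e-value at least
as good.

## Synthetic data

The generator plants what the search must recover: multi-exon genes
(default 4–8 exons of 90–300 nt), optional exon-skipping isoforms (isoform
1 keeps all exons; each further isoform skips one distinct internal exon,
planting exactly the bubble-plus-short-junction-node structure described
above), a diverged ortholog database, and single-end short reads (71 bp
default) with per-base qualities.

Transcripts are built from stop-free codons with exon lengths rounded to
multiples of 3, so frame +1 is a clean ORF; the protein-mode ortholog is
the translated peptide with amino acids substituted at rate 1 − identity
(nucleotide mode substitutes bases directly). Reads are drawn uniformly
along each transcript on both strands at a per-transcript coverage that is
log-normal around the configured mean (constant by default), with
substitution errors at `base_error_rate` and quality 38 everywhere except
an optional low-quality (q=2) tail on a configurable fraction of reads to
exercise the trimming rule. The first two reads of each transcript are
anchored at its ends: under pure uniform sampling the terminal k-mers are
covered only by reads starting exactly at an end, so anchoring is what
guarantees the planted path exists in the graph at moderate coverage.
Everything is deterministic under a fixed seed.

What the generator does *not* emulate — indels, paired ends, coverage
gradients along transcripts, sequence-composition bias, alternative
donor/acceptor sites, real codon usage — bounds what passing tests show:
they validate the algorithm's behavior on clean instances of the structures
it targets, not performance on real libraries.

## Problem sizes and verification

The test suite and the acceptance script run two headline experiments,
sized for a single CPU: (1) 50 planted single-isoform transcripts
(500–2000 nt, codon-rounded), error-free 71 bp reads at 30×, k=25, c=3,
searched in `nt` mode against the transcripts themselves; (2) 20
two-isoform genes under the same read model, searched in `tx` mode against
an 85%-identity protein ortholog database with `e_i = 1e−6, e_f = 1e−20`.
Alignment-engine exactness is established against a brute-force DP on
random pairs, and greedy-search soundness against exhaustive enumeration of
all simple oriented paths on small random acyclic graphs.

## Known limitations

* **Greedy myopia on repeats.** On cyclic (tandem-repeat) subgraphs the
  single-direction, one-step-best extension can exit the cycle before
  spelling all repeat copies when the exit's one-step gain exceeds the next
  lap's: the search terminates with a strong but sub-full-length hit.
  Multi-direction search is deliberately out of scope (exponential).
* **No bubble popping or error correction** in the graph; sequencing noise
  is handled only by the coverage cutoff and tip removal.
* E-values are those of *this* engine; they track, but do not reproduce,
  any particular BLAST release's numbers (different K handling, no length
  correction, no sum statistics or composition adjustment).
* The `nt` word prefilter can in principle drop marginal hits for highly
  diverged (<~70% identity) nucleotide searches; translated mode, the
  recommended regime at such distances, applies no filter.
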