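# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.  It is the package's own account; the README
covers usage.

## Model and search

**Profile HMM.**  Standard match/insert/delete ladder over `L` match
columns; transitions are stored per column as the seven probabilities out
of that column's states, with the begin state treated as `M_0` and the end
as `M_{L+1}`.  Training counts every sequence with weight one (no sequence
weighting — the tool targets close homologs, not remote paralogs).  Match
columns are those with gap fraction below `symfrac` (default 0.5).
Emissions take a uniform Laplace pseudocount (default 1/20 per residue), so
a column observing residues {A, A} gives `P(A) = (2 + 0.05)/(2 + 1)`.
Transition rows mix observed counts with one pseudo-observation distributed
by the prior means: uniform thirds for match rows, and 0.95/0.05 for
delete and insert rows in favour of returning to the match track — with no
observed delete events, `t(D→M)` is exactly 0.95.  This is a deliberately
simple counting rule: it reproduces the intended close-homolog behaviour
and is fully declared, but it is not claimed to match any particular
hmmbuild prior library (Dirichlet mixtures and effective-sequence-number
weighting are out of scope; a `PriorConfig` hook accepts alternatives).
The rare alignments that imply plan7-illegal `D↔I` adjacencies simply do
not contribute those transition counts.

**Background.**  A fixed Swiss-Prot-style amino-acid frequency table,
normalised at import; a uniform 1/20 table is available by flag.  Insert
emissions are pinned to the background, so normalised insert log-odds are
exactly zero and non-match edges carry transition-only weight.

**Weights.**  Raw edge weight = log transition (+ null-normalised match
emission log-odds when entering a match state).  Modified weight
additionally subtracts the column's maximum emission log-odds `c_j` from
every edge entering column `j`'s match **or delete** state; edges into
inserts are untouched.  Since some residue always sits at or above
background, `c_j ≥ 0` and every modified weight is ≤ 0.  A complete path
through a fixed set of columns differs between raw and modified scoring by
the path-independent constant Σ `c_j` (asserted to 1e-9 in the tests), so
the two scorings rank complete paths with identical endpoints identically.

**Heuristic.**  `h(v)` = best modified single step from `v` into the next
match column (the emission maximum cancels `c`, leaving `log t`) plus the
suffix sum of best `M→M` transitions to the model end; zero at the terminal
column.  Delete-heavy completions could in principle beat the all-match
estimate for pathological transition tables, so admissibility is *audited*,
not assumed: the toy-instance tests compare `h` against every completion
observed by exhaustive enumeration and fail on any violation (none occur
under the priors above).  A* keeps a best-known-score map and re-expands a
vertex when a strictly better prefix arrives, so optimality holds even if
`h` were admissible but inconsistent.

**Search mechanics.**  Open-set ordering is `(f, raw score, insertion
sequence)` — deterministic without randomness.  The prune rule discards a
popped node whose raw score has not improved within `prune` expansions
(default 20; −1 disables).  Note that an all-delete completion to the goal
always exists grammatically; on models longer than the prune horizon it is
pruned away, which is precisely how searches in zero-coverage regions
terminate and return the best intermediate (partial) path.  The best-path
cache stores, per vertex of a completed best path, its successor step;
cached vertices open only that successor.  Caches are per gene, per
direction, per run.

**Bidirectional assembly.**  The right search runs the forward model from
the seed's last column; the left search runs the reversed-alignment model
from the mirrored column `L − j + 1`, prepending codons.  Seed emissions
are credited only at the final rescoring pass (directional scores are used
only for ranking within a search).  The fused path is rescored under the
forward model with raw weights; the first state contributes its emission
only, making the bit score a function of the assembled sequence and its
implied alignment, independent of the seed that produced it.  Contigs keep
their per-column residue map, which later drives clustering.

**K shortest paths.**  Yen's algorithm with Lawler's restriction, modified
two ways: a candidate adds a rank only if it contains ≥ 1 edge and ≥ 1
nucleotide kmer absent from all previously accepted paths.  Both filters
are applied when a completed candidate is popped; rejected candidates still
spawn spur searches.  That placement makes the ranked output equal, on
small graphs, to brute-force enumeration sorted by score and greedily
filtered — the property the tests assert.  Spur searches reuse the prune
rule, never the cache, and a `max_spur_attempts` guard (default 100 K)
bounds worst-case work.  The pipeline applies K-paths to the right search
and pairs each ranked path with the single best left path; crossing every
left variant with every right variant would manufacture combinations no
single search supports.

## Kmer layer

Canonical storage (lexicographic minimum of kmer and reverse complement),
both orientations queryable; reads sample both strands and six-frame
seeding requires it.  A codon step demands all three intermediate
single-shift kmers, not one three-base jump.  The counting Bloom filter
uses 4-bit saturating counters, keyed blake2b hashing with
Kirsch–Mitzenmacher double hashing, and a fixed published seed, so filters
are identical across processes; construction fails if the configured size
implies an expected false-positive rate above the ceiling (default 5 %).
The exact hash backend is the default for testability.

## Post-processing

Identity between contigs is computed over the overlap of their model-column
projections (residues agree / columns compared; disjoint spans score 0).
Contigs are emitted along HMM paths, so no pairwise aligner is needed and
the measure is deterministic; this column-space denominator is our
convention where the upstream clustering tools leave gap handling
unspecified.  Clustering is scipy complete linkage on `1 − identity`, cut
at `1 − threshold` (+1e-9 for float safety); inputs are canonically sorted
(length, bits, id) first, so results are independent of input order.
Representatives are the longest members, ties broken by bits then id.

Coverage is mapping-free: each read-kmer occurrence adds `1/m` to each of
the `m` contigs containing the (canonical) kmer, so split counts sum
exactly to the matched occurrences; a contig's coverage is the mean over
its kmer positions.  Abundance is the ratio of reads covering ≥ 1 kmer of a
gene's contigs to the same count for *rplB*; zero marker hits yield a
warned missing value.  Chimera screening is delegated: the package writes
the representative and reference FASTA a UCHIME-style screen consumes and
drops contigs its tab report flags.

## Synthetic data: what it does and does not show

The generator evolves a protein family by i.i.d. substitution (uniform
replacement, so expected identity is `1 − rate·19/20`), back-translates
with uniform synonymous codons, plants genes in uniform random background
DNA, and samples uniform-start, strand-balanced, substitution-error reads
at constant quality.  Defaults: 130-aa proteins, 100-bp reads, 30×
coverage, error rate 0 for the clean community, 1.5-kb backgrounds.

Four fixtures (deterministic from seeds 1–4) cover the regimes of
interest:

* **clean** — two gene families (*nirK*- and *rplB*-like), three planted
  variants each at ~88 % identity: full-length exact recovery through the
  filters, coverage conservation, marker-normalised abundance.
* **two_haplotype** — one gene in two haplotypes differing by three
  substitutions in the 3′ half: the K-paths mixture case.
* **shared_kmer** — two genes ~70 % identical sharing an identical
  codon-aligned 12-aa window (36 nt, flanked by forced differences so the
  shared run stays < 45 nt), with gene A's coverage ending at the window:
  a 30-mer graph must cross into gene B (the chimeric join is assembled),
  while a 45-mer graph cannot bridge the run and returns a partial pure-A
  contig.  This reproduces the mechanism by which kmer length controls
  chimera formation, qualitatively not numerically.
* **low_coverage** — 0.6× coverage with zero-coverage gaps: partial-path
  flagging and search exhaustion.

Toy instances for the search audits use 4–12 column models and a handful
of ~40-nt genes (k = 6), small enough for exhaustive depth-first
enumeration of all simple start-to-goal paths.  Enumeration caps
insert/delete events per path (default 2; raised to whatever the searched
path actually used), because indel detours explode the simple-path count
while each one carries a strongly negative weight; the tests assert the A*
result itself respects the cap, which keeps the capped comparison sound.

None of this emulates quality-dependent error profiles, indel sequencing
errors, repeats, amplification bias, or real community structure.  Passing
tests show the algorithms are implemented to specification and behave
correctly in controlled regimes; they do not certify recovery rates on
real soil or gut metagenomes.

## Problem sizes and defaults

Defaults follow the tool's intended operating point: k = 45 (peptide
seeds of 15 aa), minimum kmer count 1, prune 20, contig filters 300 nt and
50 bits, clustering at 0.99 (OTUs at 0.95).  The test suite and acceptance
script run the full pipeline on the fixture communities (≈ 1000–3400 reads,
models of 130 columns) and 200 toy instances; these sizes exercise every
code path while keeping exhaustive oracles feasible.  On the near-linear
fixture graphs the prune rule removes little work (opened-vertex fraction
≈ 99 % of unpruned); its large savings arise on branchy real-data graphs,
which the invariance tests do not attempt to reproduce — they assert
equality of outputs and the direction of the reduction only.

## Known limitations

* Local/glocal alignment modes are not modelled; paths run from a seed
  column to a model end, and a poor seed yields a low-scoring contig
  rather than a trimmed local hit.
* Insert states cannot start or end a contig, and stop codons are
  hard excluded (emission −∞) rather than penalised.
* The HMMER3 reader/writer covers the probability fields this tool uses;
  stats lines, MAP/CONS annotations and DNA-alphabet models are not
  round-tripped.
* Multi-threading parallelises per-gene searches only; graph building is
  single-threaded.
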