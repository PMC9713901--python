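# Methods

## Data model

A *classification* is a rooted hierarchy of functional terms whose
leaves carry sets of reference protein sequence identifiers. One
sequence may sit under several leaves (KEGG-style multi-membership),
and one term label may occur on several nodes: hierarchies derived from
a DAG (GO-style) are flattened at load time by duplicating the node
under each parent with a suffixed id (`label#2`, …) while preserving
the label. A label that terminates two root-to-leaf paths under
different parents is rejected instead, because the leaf-to-sequence map
addresses leaves by id and would become ambiguous.

Depth counts nodes, not edges: the root alone has depth 1, and a leaf's
depth is the number of nodes on the root→leaf path inclusive. The
median depth of an even number of leaves is the mean of the two central
values rounded half up, so reported depths are integers. Sequence
counts are over distinct identifiers — a sequence under several leaves
counts once. (The alternative, counting one occurrence per leaf, would
inflate counts in multi-membership systems.)

Comparison-level nodes are chosen either by a fixed depth (all nodes
exactly *k* levels below the root — the natural choice for
eggNOG/KEGG-like tiers) or by an explicit list (needed for SEED-like
systems whose comparable terms sit at mixed levels). A selection may
not contain an ancestor/descendant pair; this is checked and violations
are errors.

## Alignment

Pairwise protein alignment is Smith–Waterman local alignment with
affine gaps, delegated to `Bio.Align.PairwiseAligner` with BLOSUM62 and
BLAST-style penalties (gap of length L costs 11 + L). Raw scores are
used for ranking, not E-values: at desk scale E-value calibration is
meaningless, and the pipeline only ever consumes the best match. The
acceptance threshold is a raw score of 50 by default; on the generated
families (length ≥ 50, identity ≥ 0.7) true homologs score in the
hundreds, while unrelated sequence pairs rarely reach 40.

Conventions, stated per consumer because the field's tools disagree:

* the *aligner* reports identity as identical positions / alignment
  columns (gap columns included) and query coverage as the query span
  of the local alignment / query length (BLAST qcov-style);
* the *clustering* module computes identity as identical positions /
  length of the shorter sequence (the CD-HIT convention) and coverage
  on the member sequence.

Candidate subjects are pre-filtered by shared 5-mers (single-hit
seeding, no two-hit rule). At the identity ranges the pipeline probes
(≥ 0.7 within and across databases) a shared 5-mer is essentially
certain, and the test suite verifies seeded best hits equal an
exhaustive all-vs-all scan; at much lower identities seeding would
become lossy, which is out of the pipeline's operating range. Ties on
raw score are broken by smallest subject id so the whole pipeline is
deterministic.

Reads are translated in all six frames under the standard genetic code
(stops emitted as `*`, codons containing `N` as `X`); the best hit over
all frame peptides, with coverage measured on the peptide, assigns the
read.

## Greedy clustering

Sequences are sorted by length descending (ties: id ascending) and
scanned once; each sequence joins the *first* representative — in
founding order — passing the length-ratio (≥ 0.9), member-coverage
(≥ 0.9) and identity (≥ t) gates, else it founds a new cluster. This is
the fast greedy rule (`-g 0` semantics); a best-match variant exists in
CD-HIT but the default here mirrors its default. The raw-score
threshold of the scoring scheme is deliberately not applied inside
clustering — the three gates are the only acceptance rules. Input order
cannot affect results because ordering is canonicalised internally.
(A survey note, not code: USEARCH-style heuristics find ~0.4 % more
clusters on comparable inputs; no second algorithm is implemented.)

## Cross-mapping

For coverage and concordance every distinct query sequence is aligned
once against the target database and cached. A best hit landing in the
target but outside every selected column node is reported as a separate
`hit_outside_selection` column rather than folded into `unassigned`:
unassigned means "no qualifying hit at all", and with partial node
selections the residual keeps the accounting honest. Because one best
hit can credit several overlapping column nodes, row sums may exceed 1
and are not normalised. Matrices keep full precision; percentages are
rounded (half up, to integers in best-match tables, one decimal in
coverage tables) only at the reporting layer. Empty rows are emitted
with size 0 and NaN fractions, never silent zeros.

Self-overlap is pure identifier set intersection — no alignment — and
`overlap(i, j) = |S_i ∩ S_j| / |S_i|` is deliberately asymmetric so
containment (a node wholly inside another) reads as 1.0.

## Read pipeline

Quality filtering keeps reads with mean Phred quality ≥ 20 (reads
without qualities pass with a warning); sliding-window trimming is out
of scope. Assignment is direct best-hit-to-leaf: no lowest-common-
ancestor logic, no min-score/top-percent binning heuristics of
MEGAN-style post-processors. This is a deliberate substitution — the
pipeline reproduces the comparative design (which database assigns
which reads), not any particular binner's counts; rates here isolate
database content from binning policy. A read whose subject sits under
several leaves credits all of them but counts once in rate denominators.

In the pooled comparison all databases' records compete and a read
counts for a database only when the overall best hit belongs to it;
since competition can only divert reads, the specific rate is a
structural upper bound on the pooled rate, which the tests assert on
every run.

## Synthetic data

The generator plants families: an unmutated founder (copy 0) plus
copies substituted at exactly `⌈(1 − t)·L⌉` positions, no indels, so
the planted identity is exact rather than approximate. Copies are
mutated from the founder, not from each other: two independently
mutated copies would sit near t² pairwise identity and straddle the
clustering threshold, whereas member-to-founder identity is exactly t
and the founder (lexicographically first at equal length) becomes the
greedy representative, making planted cluster counts deterministic.
Cross-database sharing copies a founder into the destination at the
designed cross-copy identity and attaches the same record under every
destination node listed, realising multi-membership. Families of
different lineages are independent uniform sequences; their pairwise
identity stays below 0.4 (asserted on samples), so thresholds 0.7/0.9
separate cleanly.

Defaults are desk-scale: families of 80–140 residues, 2–5 copies,
30–60 families per classification, within-family and cross-copy
identity 0.95, a 70/15/5/5/5 Bacteria/Eukarya/Archaea/Virus/
Unclassified mix, and 150 bp reads at 1 % substitution error with
constant Q35 — small enough that the full pipeline runs in seconds on
one CPU, large enough that fractions of interest are resolved to a few
percent. The standard four-classification design uses depth profiles
4/5/3/5 with comparison tiers at depth 2/2/1/1, mirroring the tier
structure of the four large real systems.

Reads are produced by reverse-translating source proteins with
uniformly chosen synonymous codons, fragmenting at a uniform offset,
flipping strand with probability ½ and applying per-base substitution
error. All randomness flows from a single seed; identical seeds give
byte-identical bundles and FASTQ.

What the generator does **not** emulate: realistic amino-acid
substitution processes, indels (an option exists for mutation but
planted-truth tests use substitutions only), domain architectures,
phylogenetically structured families, or real quality-score
distributions. Passing tests therefore demonstrate that the *methods*
recover planted structure exactly under controlled conditions — they do
not certify accuracy on real databases, where family structure is far
messier and identity distributions are continuous.

## Numerical and design choices

* Even-median rounding half up is computed in integer arithmetic to
  avoid float ties.
* The greedy clustering representative must be at least as long as its
  members; this follows from the length-descending scan and is asserted.
* `SyntheticDesign` is per-classification (shape, family count,
  selection tier, optional per-node taxonomy mix) with explicit share
  specs, rather than one flat parameter set: planted concordance
  designs need per-node fractions and per-pair sharing that a single
  global fraction cannot express.
* Report files carry a header with the tool version and a digest of the
  configuration (output directory excluded, so identical analyses into
  different directories produce byte-identical reports).
* Zero-sequence nodes, empty taxonomy strata, and reads shorter than a
  codon are all flagged or passed through explicitly rather than
  erroring or silently zeroing.

## Known limitations

* The aligner is a desk-scale stand-in: no double indexing, seed
  masking, compositional adjustment or SIMD; it is validated against an
  independent DP oracle, not against production search engines.
* Coverage/concordance semantics measure sequence sharing, not semantic
  term similarity; two terms with equivalent meaning but disjoint
  reference sets will not match by construction.
* Cluster counts at thresholds far below the planted identity are
  bounded, not pinned, by the design (merging across families cannot
  occur, but the count cannot drop below the family count either).
* The read pipeline's rates are not comparable to MEGAN-style outputs
  in absolute terms, only in comparative design.
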