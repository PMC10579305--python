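# Methods

This note documents the models, parameter choices and numerical conventions
behind `synmod`, and what the validation experiments do and do not show.

## Alignment model

All protein comparison uses exact affine-gap Smith–Waterman with BLOSUM62
and BLAST-default gap penalties: a gap of length *k* costs
`gap_open + k·gap_extend` = 11 + *k*. No heuristic word seeding is used —
phage genomes are small enough for full dynamic programming at gene scale.
The fill is a numba-compiled three-state recurrence (match state M, gap
states X/Y); a score-only rolling-row kernel screens candidate pairs so the
full traceback fill runs only for pairs that can still pass the score
filter (this cannot change results, only skip work).

Conventions:

- **Percent identity / similarity** use the alignment length *including gap
  columns* as denominator. "Similarity" is the positives fraction — aligned
  columns with positive substitution score, identities included. This is the
  BLAST convention, and the measure all thresholds refer to. Whether the
  similarity filter uses positives or identity is switchable
  (`metric="positives" | "identity"`); positives is the default.
- **Determinism.** Traceback ties prefer diagonal over up over left; gap
  opening is preferred over extension at equal score; among equal-scoring
  maximal cells the lexicographically smallest (q_end, s_end) wins. Identical
  inputs therefore produce byte-identical outputs on any platform.
- **Stops.** In translated mode stop codons are rendered as `*` and score
  −10⁶ against everything else, so alignments never cross a stop; frames are
  additionally split at stops into segments before alignment, which bounds
  memory.
- The accepted residue alphabet is the 20 canonical amino acids plus B, Z,
  X and `*`; anything else is rejected with the offending position named.

### The raw-score floor

Legend-style filters ("20 % minimal similarity on 10 bp minimum
alignments") presuppose a search tool that only reports *significant* hits.
An exact aligner has no such notion: the single best local alignment of two
unrelated ~300-aa proteins typically scores 25–40 over 10–30 columns with a
positives fraction far above any legend threshold, so similarity/length
filters alone would pass essentially every random gene pair (measured:
396/396 on a simulated null pair). We therefore expose `min_score`
(default 60, raw BLOSUM62 score) as a stand-in for significance filtering.
By Karlin–Altschul statistics with gapped BLOSUM62 constants
(λ ≈ 0.267, K ≈ 0.041), score 60 corresponds to E ≈ 1e-3 for two ~340-aa
sequences — the same cutoff magnitude commonly used for phage gene
annotation. Measured on simulated null pairs, fewer than 1 % of unrelated
gene pairs pass the default filter set, while planted homologs at 45–95 %
similarity score in the hundreds. The floor applies to both gene mode and
translated-genome mode; setting `min_score=0` restores the raw legend
semantics (useful for figure modes that tolerate faint random ribbons).

`min_aln_len` thresholds given in bp apply to translated hits as
aa columns × 3, so "10 bp minimum" means ≥ 4 aa.

No E-values are reported; raw score and lengths are, so users can
post-filter differently.

## Genome representation

Internal coordinates are 0-based half-open on the forward strand; GenBank's
1-based inclusive coordinates are converted on input and back on output
(round-trip identity is property-tested). Translation uses table 11
(bacterial/phage); alternative start codons are rendered as M at annotated
CDS starts; `/translation` qualifiers, when present, are taken verbatim —
the loader never tries to reconcile annotated protein lengths with span
arithmetic. CDS features with compound `join()` locations are rejected
rather than silently flattened. Sequence handling is case-insensitive and
maps U→T.

## Orthology and the synteny rule

Gene pairs are reciprocal best hits by raw score (ties: higher similarity,
then lower partner rank), subject to a "similar size" floor of protein
length ratio ≥ 0.5 — permissive enough to keep homolog pairs that differ by
the ~25 % length difference an extended-vs-truncated fiber pair shows.

A synteny block is a set of gene pairs, ordered along genome A, with

- at least `min_genes` = 5 members,
- at most `max_gap` = 4 genes between consecutive members, counted on
  genome A as `rank_a(next) − rank_a(prev) − 1` (unpaired *and* weakly
  paired genes both count as non-syntenic), and
- strictly monotone genome-B ranks (collinear or uniformly inverted; an
  inversion terminates a block).

The detector enumerates **maximal** chains — chains into which no further
pair can be inserted, prepended or appended without breaking the rule — by
depth-first extension with an insertability check, then resolves overlaps
greedily left-to-right along genome A (longer chain wins at equal start;
blocks never share pairs). On small inputs this provably matches an
exhaustive search over all pair subsets (tested against one). Gap counting
on genome A follows the visual convention of pairwise comparison figures;
a strict mode bounding gaps on both genomes is a straightforward extension
but not currently exposed.

A module call lifts a block to nucleotide spans (first to last member gene
on each genome), an unweighted mean of member similarities, and a per-pair
table with aligned residue ranges.

## Fiber-architecture detection

**Insertion.** The extended and truncated proteins are aligned globally
with free end gaps (biopython `PairwiseAligner`, same matrix and gap costs),
so terminal length differences are never miscalled as internal insertions.
After trimming terminal overhangs, the longest run of columns gapped in the
truncated sequence becomes the insertion if ≥ `min_insertion` = 30 aa —
well below the ~90-residue difference of a fiber knob-domain duplication,
well above alignment jitter. The nearest `flank_window` = 10 aligned
columns on each side are reported as flanks S1 (upstream) and S2
(downstream) with percent identity; both must reach
`flank_identity_min` = 50 %, which rejects length differences between
unrelated proteins. The call is driven by the conserved flanks, not the
insert: shuffling the insert moves boundaries by ≤ 2 residues
(property-tested). Only residue spans are reported — geometric quantities
(hairpin lengths in Å) are structural and not derivable from sequence.

**Tandem duplication.** The protein is locally aligned against itself with
all cells within `min_unit` = 50 of the main diagonal excluded. The best
off-diagonal alignment defines two unit spans (trimmed to disjoint
intervals at the overlap midpoint when they touch), accepted at
≥ `min_unit` aligned columns and ≥ 20 % similarity. For a true tandem
duplication the alignment pairs copy 1 with copy 2 at offset ≈ unit length,
so the two spans recover the copies; coordinates mirror under sequence
reversal up to ±2 residues.

## The simulator

`simulate_module_pair` emulates the discovery scenario: two genomes with
mutually unrelated random gene backbones (default 18 and 22 genes, lengths
uniform 80–600 aa, Robinson–Robinson residue frequencies) sharing one
contiguous module (default 10 genes) placed at an independent random
position in each genome, flanked by random intergenic spacers (2–150 nt);
module genes are back-translated with uniform synonymous codons (table 11)
and kept on the forward strand, background genes get random strands.

Module divergence is **calibrated in closed loop**: substitutions (applied
alternately to the two copies; replacement residues drawn ∝
`p(y)·2^(S(x,y)/2)`, i.e. BLOSUM62-conditioned) are added or reverted until
the measured Smith–Waterman percent similarity of the pair lies within ±5
points of the target (default 60 %), bounded at 500 control iterations with
a hard error reporting the achieved value. Calibrating against the
pipeline's own measure guarantees the simulator's "percent similarity"
means exactly what the detector later measures. Realized values cluster in
the upper half of the band because the proportional controller stops at
first entry; they are recorded per pair in the truth file.

Optional variant edits on the genome-A copies: a tandem duplication of a
central 80-aa unit of the fiber-like gene (middle of the module; second
copy 30 % randomized) and/or a 90-aa random insertion at the center of the
chaperone-like gene (next gene). Both are recorded with their residue spans
in `truth.planted_insertions`.

All sampling comes from a single `numpy.random.default_rng(seed)` stream in
a fixed documented order, so a seed reproduces genomes and truth
byte-for-byte.

**What the simulator does not model:** nucleotide-level evolution (indels,
recombination breakpoints), codon usage bias, gene-content realism, shared
folds between non-orthologous genes, or annotation noise. Passing the
planted-truth experiments therefore shows the *detection logic* is correct
under controlled divergence; it does not certify performance on real
genomes with partial homology, split genes or mis-annotation.

## Validation experiments and problem sizes

Run by the test suite and by `scripts/acceptance.py`:

- **Aligner oracle** — 200 seeded random peptide pairs (length ≤ 12)
  compared exactly (score, identities, positives) against an independent
  plain-Python full-table DP oracle; a second check compares scores against
  biopython's local aligner on longer peptides.
- **Synteny boundary suite** — the four hand-enumerable boundary cases of
  the block rule (5 vs 4 members; gap 4 vs 5).
- **Module recovery** — 50 simulated pairs at default conditions: exactly
  one module whose gene set equals the planted orthology (observed
  96–100 % across seeds; the occasional miss is a background RBH pair that
  lands within four genes of the module edge with a compatible rank and
  legitimately extends the block under the rule). 50 null pairs must yield
  zero module calls (observed 0).
- **Insertion / duplication recovery** — 50 planted 60-aa insertions at
  random internal positions of 300-mers, boundaries within ±5 residues
  (observed 100 %); 50 planted 80-aa tandem duplications at 30 %
  divergence, second unit covering ≥ 80 % of the planted copy (observed
  92–100 %).

Problem sizes were chosen so the full suite and the acceptance script each
run in about one to two minutes on a single CPU.

## Known limitations

- The RBH + size-ratio orthology proxy has no paralog handling; a genome
  with two similar copies of a module gene can displace the true pair.
- Gap counting is asymmetric (genome A); modules embedded in very
  gene-dense regions of genome B are judged only through monotonicity.
- The maximal-chain enumeration is exponential in adversarial inputs
  (many mutually compatible crossing pairs); real and simulated RBH sets
  are far from this regime.
- Aggregate module similarity is reported as the unweighted mean of
  per-pair values; no length weighting is attempted.
- Translated-genome mode reports one best alignment per stop-free segment
  pair, not multiple HSPs per pair.
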