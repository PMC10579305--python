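# synmod

Detection of shared **host-recognition modules** between phage genomes.

Tailed phages attach to their bacterial hosts through receptor-binding
proteins (tail fibers, tailspikes) encoded, together with distal tail
components and dedicated folding chaperones, in a contiguous *host
recognition module*. Because these modules are exchanged between otherwise
unrelated phages by horizontal gene transfer, two genomes can share a single
block of homologous, collinear genes while the rest of their gene content is
unrelated — a pattern that whole-genome identity metrics miss. `synmod`
finds such modules from annotated genomes, and detects the internal
insertion / domain-duplication events that distinguish "extended" from
"truncated" variants of the fiber and its chaperone.

## What it computes

1. **Translated comparison** — exact affine-gap Smith–Waterman over protein
   space: all-vs-all gene products, and tBLASTx-style comparison of all 6×6
   reading-frame pairs of both genomes (stop-free segments, hits mapped back
   to forward-strand nucleotide coordinates). Percentages follow BLAST
   conventions; *percent similarity* is the fraction of aligned columns with
   positive substitution score ("positives", identities included):

   `pct_similarity = 100 · positives / aln_len`, with the alignment length
   including gap columns.

2. **Orthology** — reciprocal best hits (RBH) by raw score, with a "similar
   size" requirement: protein length ratio min(ℓa, ℓb)/max(ℓa, ℓb) ≥ 0.5.

3. **Synteny blocks / module calls** — maximal runs of ≥ 5 syntenic gene
   pairs in consistent (strictly monotone) order with at most 4 non-syntenic
   genes between consecutive members. A block is lifted to a module call
   with nucleotide spans on both genomes, a per-pair similarity table, and
   the unweighted mean similarity.

4. **Fiber architecture** — from sequence alone: (a) the single internal
   insertion separating an extended fiber/chaperone from its truncated
   homolog, found as the longest run of columns gapped in the truncated
   protein under free-end-gap global alignment, with conserved flanks S1/S2
   reported; (b) internal tandem duplications (the knob-domain duplication
   signature), found as the best off-diagonal local self-alignment.

5. **Simulation** — mosaic genome pairs with unrelated gene backbones and
   one planted module whose gene pairs are calibrated to a target percent
   similarity (closed loop against the pipeline's own aligner), optionally
   with planted duplication/insertion variants, plus machine-readable ground
   truth. This is what the validation experiments score against.

Because the exact aligner reports the best local alignment of *every*
protein pair, legend-style similarity/length filters alone would pass the
short high-scoring alignments that database search tools suppress as
insignificant. A configurable raw-score floor (default 60, roughly an
E-value of 1e-3 at typical phage gene lengths) stands in for that
significance filter; see `docs/methods.md`.

## Worked example

Simulate a genome pair sharing a ten-gene module at ~60 % similarity, then
recover it:

```bash
synmod simulate --seed 11 --out demo/sim
synmod compare --a demo/sim/A.fna --a-proteins demo/sim/A.faa \
               --b demo/sim/B.fna --b-proteins demo/sim/B.faa --out demo/cmp
# 10 orthologous pairs, 1 blocks, 1 module call(s)
cat demo/cmp/modules.tsv
```

```text
# thresholds: max_gap=4 min_aln_len_bp=10 min_genes=5 min_score=60 min_similarity=20.0 size_ratio_min=0.5
module	locus_a	locus_b	pct_similarity	q_range	s_range
1	gp12	gp15	64	(1-149)	(1-149)
1	gp13	gp16	65	(1-97)	(1-97)
1	gp14	gp17	65	(1-317)	(1-317)
...
1	gp21	gp24	64	(1-526)	(1-526)
```

One module of ten syntenic gene pairs was called; each row gives the gene
pair, its integer-rounded percent similarity (all near the 60 % simulation
target) and the aligned residue ranges. `blocks.tsv` summarizes the block
(10 members, collinear, all gap runs 0), `hits_genome.tsv` holds the
translated-genome hits, and `comparison.svg` is the two-track figure with
ribbons shaded by similarity. GenBank flat files are accepted directly
(`--a genome.gb`); the FASTA-pair dialect uses protein headers
`locus|start|end|strand` with 0-based half-open coordinates.

The same analysis is available as a library:

```python
from synmod import read_genbank, compare_genomes
result = compare_genomes(read_genbank("A.gb"), read_genbank("B.gb"))
for call in result.modules:
    print(call.span_a, call.span_b, round(call.mean_similarity, 1))
```

## Report column schemas

- `hits_genes.tsv` / `hits_genome.tsv`: BLAST outfmt-6-like, with extra
  columns `positives`, `pct_similarity`, reading frames and gene ranks
  (header line documents the order).
- `modules.tsv`: `module, locus_a, locus_b, pct_similarity` (rounded to
  integer), `q_range, s_range` as `(start-end)` in 1-based residues.
- `blocks.tsv`: block size, member rank spans, direction (+1 collinear,
  −1 inverted), per-step gap runs, mean similarity.
- `truth.json` (simulator): planted orthology, module spans, planted
  insertion spans, realized per-pair similarities.
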