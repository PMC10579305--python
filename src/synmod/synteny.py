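"""Gene-level orthology pairing and gap-tolerant synteny block detection.

Orthologous gene pairs are called as reciprocal best hits (RBH) by raw
alignment score, with a "similar size" requirement expressed as a protein
length ratio.  Syntenic blocks then follow the rule: at least ``min_genes``
(default 5) syntenic gene pairs in consistent order, with at most ``max_gap``
(default 4) non-syntenic genes separating consecutive members, counted on
genome A.  Gene order must be collinear within a block: subject ranks are
strictly monotone (increasing or decreasing); an inversion terminates a
block.

The detector enumerates *maximal* chains -- ordered pair subsets satisfying
the rule into which no further pair can be inserted, prepended or appended --
and resolves overlaps greedily left-to-right along genome A (longer chain
wins at equal start).  Unchosen or below-threshold pairs count as
non-syntenic gap genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignmentHit
from .genome_io import GenomeRecord

__all__ = [
    "SyntenyPair",
    "SyntenyBlock",
    "ModuleCall",
    "pair_genes",
    "detect_blocks",
    "call_modules",
    "validate_block",
]


@dataclass
class SyntenyPair:
    """One orthologous gene pair (reciprocal best hit of similar size)."""

    rank_a: int
    rank_b: int
    locus_a: str
    locus_b: str
    pct_similarity: float
    size_ratio: float
    score: int = 0
    q_range: tuple[int, int] = (0, 0)  # 1-based inclusive aligned residues on A
    s_range: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not (0 < self.size_ratio <= 1):
            raise ValueError(f"size_ratio {self.size_ratio} outside (0, 1]")
        if not (0 < self.pct_similarity <= 100):
            raise ValueError(f"pct_similarity {self.pct_similarity} outside (0, 100]")


@dataclass
class SyntenyBlock:
    """A maximal run of syntenic gene pairs satisfying the block rule."""

    pairs: list[SyntenyPair]
    gap_runs: list[int] = field(default_factory=list)

    @property
    def n_syntenic(self) -> int:
        return len(self.pairs)

    @property
    def direction(self) -> int:
        """+1 collinear, -1 inverted order on genome B (0 for single pair)."""
        if len(self.pairs) < 2:
            return 0
        return 1 if self.pairs[1].rank_b > self.pairs[0].rank_b else -1


@dataclass
class ModuleCall:
    """A syntenic block lifted to genomic module coordinates."""

    block: SyntenyBlock
    span_a: tuple[int, int]  # 0-based half-open nt interval on genome A
    span_b: tuple[int, int]
    mean_similarity: float
    gene_table: list[dict] = field(default_factory=list)


def pair_genes(
    hits: list[AlignmentHit], size_ratio_min: float = 0.5
) -> list[SyntenyPair]:
    """Reciprocal-best-hit orthology over filtered gene-product hits.

    Best hits are by raw score, ties broken by higher pct_similarity then by
    lower partner rank.  Pairs whose protein length ratio
    min(len)/max(len) falls below ``size_ratio_min`` are dropped ("similar
    size"); every gene ends up in at most one pair.
    """
    best_for_a: dict[int, AlignmentHit] = {}
    best_for_b: dict[int, AlignmentHit] = {}
    for h in hits:
        if h.q_rank < 0 or h.s_rank < 0:
            raise ValueError("pair_genes requires gene-product hits with ranks")
        cur = best_for_a.get(h.q_rank)
        if cur is None or (h.score, h.pct_similarity, -h.s_rank) > (
            cur.score,
            cur.pct_similarity,
            -cur.s_rank,
        ):
            best_for_a[h.q_rank] = h
        cur = best_for_b.get(h.s_rank)
        if cur is None or (h.score, h.pct_similarity, -h.q_rank) > (
            cur.score,
            cur.pct_similarity,
            -cur.q_rank,
        ):
            best_for_b[h.s_rank] = h
    pairs = []
    for rank_a in sorted(best_for_a):
        h = best_for_a[rank_a]
        if best_for_b.get(h.s_rank) is not h:
            continue
        if not h.q_len or not h.s_len:
            raise ValueError("pair_genes requires hits carrying protein lengths")
        ratio = min(h.q_len, h.s_len) / max(h.q_len, h.s_len)
        if ratio < size_ratio_min:
            continue
        pairs.append(
            SyntenyPair(
                rank_a=h.q_rank,
                rank_b=h.s_rank,
                locus_a=h.query_id,
                locus_b=h.subject_id,
                pct_similarity=h.pct_similarity,
                size_ratio=ratio,
                score=h.score,
                q_range=(h.q_start, h.q_end),
                s_range=(h.s_start, h.s_end),
            )
        )
    return pairs


def _edge(p: SyntenyPair, q: SyntenyPair, max_gap: int) -> int:
    """Direction (+1/-1) if q can directly follow p in a block, else 0."""
    if q.rank_a <= p.rank_a or q.rank_a - p.rank_a - 1 > max_gap:
        return 0
    if q.rank_b == p.rank_b:
        return 0
    return 1 if q.rank_b > p.rank_b else -1


def _insertable(
    p: SyntenyPair, q: SyntenyPair, direction: int, pairs: list[SyntenyPair], max_gap: int
) -> bool:
    """True if some pair fits between p and q with consistent direction."""
    for x in pairs:
        if p.rank_a < x.rank_a < q.rank_a:
            if _edge(p, x, max_gap) == direction and _edge(x, q, max_gap) == direction:
                return True
    return False


def _maximal_chains(
    pairs: list[SyntenyPair], max_gap: int
) -> list[list[SyntenyPair]]:
    """All maximal valid chains (no pair can be inserted at any position)."""
    chains: list[list[SyntenyPair]] = []

    def extend(chain: list[SyntenyPair], direction: int) -> None:
        last = chain[-1]
        extended = False
        for q in pairs:
            d = _edge(last, q, max_gap)
            if d != direction:
                continue
            # skipping over an insertable pair would make the chain non-maximal
            if _insertable(last, q, direction, pairs, max_gap):
                continue
            extend(chain + [q], direction)
            extended = True
        if not extended:
            chains.append(chain)

    for start in pairs:
        for direction in (1, -1):
            # a maximal chain's first member has no valid predecessor
            if any(_edge(x, start, max_gap) == direction for x in pairs):
                continue
            has_succ = any(_edge(start, q, max_gap) == direction for q in pairs)
            if not has_succ:
                if direction == 1 and not any(
                    _edge(x, start, max_gap) or _edge(start, x, max_gap)
                    for x in pairs
                ):
                    chains.append([start])  # isolated pair
                continue
            extend([start], direction)
    return chains


def detect_blocks(
    pairs: list[SyntenyPair], min_genes: int = 5, max_gap: int = 4
) -> list[SyntenyBlock]:
    """Syntenic blocks: maximal chains with >= min_genes members, consecutive
    separations of <= max_gap genes on genome A, and strictly monotone
    genome-B ranks.  Overlapping candidates are resolved greedily
    left-to-right by genome-A rank; blocks never share pairs."""
    pairs = sorted(pairs, key=lambda p: p.rank_a)
    candidates = [c for c in _maximal_chains(pairs, max_gap) if len(c) >= min_genes]
    candidates.sort(
        key=lambda c: (
            c[0].rank_a,
            -len(c),
            tuple(p.rank_a for p in c),
            tuple(p.rank_b for p in c),
        )
    )
    blocks: list[SyntenyBlock] = []
    used: set[tuple[int, int]] = set()
    for chain in candidates:
        keys = {(p.rank_a, p.rank_b) for p in chain}
        if keys & used:
            continue
        used |= keys
        gap_runs = [
            chain[i + 1].rank_a - chain[i].rank_a - 1 for i in range(len(chain) - 1)
        ]
        blocks.append(SyntenyBlock(pairs=list(chain), gap_runs=gap_runs))
    blocks.sort(key=lambda blk: blk.pairs[0].rank_a)
    return blocks


def validate_block(
    block: SyntenyBlock, min_genes: int = 5, max_gap: int = 4
) -> None:
    """Independent post-hoc check of the block-rule invariants; raises
    ValueError on violation."""
    if block.n_syntenic < min_genes:
        raise ValueError(f"block has {block.n_syntenic} pairs < min_genes {min_genes}")
    ranks_a = [p.rank_a for p in block.pairs]
    ranks_b = [p.rank_b for p in block.pairs]
    if ranks_a != sorted(ranks_a) or len(set(ranks_a)) != len(ranks_a):
        raise ValueError("genome-A ranks not strictly increasing")
    inc = all(b2 > b1 for b1, b2 in zip(ranks_b, ranks_b[1:]))
    dec = all(b2 < b1 for b1, b2 in zip(ranks_b, ranks_b[1:]))
    if not (inc or dec):
        raise ValueError("genome-B ranks not strictly monotone")
    gaps = [a2 - a1 - 1 for a1, a2 in zip(ranks_a, ranks_a[1:])]
    if gaps != block.gap_runs:
        raise ValueError("recorded gap_runs inconsistent with member ranks")
    if any(g > max_gap for g in gaps):
        raise ValueError(f"gap run exceeds max_gap {max_gap}")


def call_modules(
    A: GenomeRecord, B: GenomeRecord, blocks: list[SyntenyBlock]
) -> list[ModuleCall]:
    """Lift blocks to module calls with genomic spans and per-pair table."""
    calls = []
    for block in blocks:
        ranks_a = [p.rank_a for p in block.pairs]
        ranks_b = [p.rank_b for p in block.pairs]
        first_a, last_a = A.features[min(ranks_a)], A.features[max(ranks_a)]
        first_b, last_b = B.features[min(ranks_b)], B.features[max(ranks_b)]
        mean_similarity = sum(p.pct_similarity for p in block.pairs) / len(block.pairs)
        gene_table = [
            {
                "locus_a": p.locus_a,
                "locus_b": p.locus_b,
                "pct_similarity": p.pct_similarity,
                "q_range": p.q_range,
                "s_range": p.s_range,
            }
            for p in block.pairs
        ]
        calls.append(
            ModuleCall(
                block=block,
                span_a=(first_a.start, last_a.end),
                span_b=(first_b.start, last_b.end),
                mean_similarity=mean_similarity,
                gene_table=gene_table,
            )
        )
    return calls
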