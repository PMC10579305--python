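"""Local protein alignment and six-frame translated genome comparison.

The aligner is an exact affine-gap Smith-Waterman (no heuristic word seeding:
phage genomes are small enough for full dynamic programming at gene scale).
Percentages follow BLAST conventions: ``pct_identity`` and ``pct_similarity``
use the alignment length including gap columns as denominator, and
"similarity" means the *positives* fraction -- aligned columns whose
substitution score is positive, identities included.

Hit filters are expressed as percent similarity and minimum alignment length,
the way genome-comparison figure legends state them.  Because the exact
aligner has no significance statistic, a configurable raw-score floor
(``min_score``) stands in for the significance filtering that database search
tools apply implicitly before such legend thresholds; without it, the single
best local alignment of two unrelated proteins (typically a short, dense
segment scoring ~25-40 with BLOSUM62) would pass any permissive
similarity/length filter.  See ``docs/methods.md`` for the calibration of the
default.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from ._kernels import sw_fill, sw_score_only, sw_traceback
from .genome_io import GenomeRecord, six_frame_translate

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "smith_waterman",
    "all_vs_all_proteins",
    "translated_genome_compare",
    "write_hits_tsv",
    "read_hits_tsv",
]

#: residues accepted by the aligner: the 20 canonical amino acids plus the
#: ambiguity codes B/Z/X and the stop symbol ``*``.
ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}

#: stop symbols never align against residues: alignments cannot cross a stop.
_STOP_SCORE = -(10**6)


@functools.lru_cache(maxsize=4)
def _load_matrix(name: str) -> np.ndarray:
    mat = substitution_matrices.load(name)
    S = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int32)
    for i, x in enumerate(ALPHABET):
        for j, y in enumerate(ALPHABET):
            if ("*" in (x, y)) and x != y:
                S[i, j] = _STOP_SCORE
            else:
                S[i, j] = int(mat[x, y])
    return S


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (BLAST defaults).

    A gap of length k costs ``gap_open + k * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")

    def substitution_matrix(self) -> np.ndarray:
        return _load_matrix(self.matrix_name)


DEFAULT_SCHEME = ScoringScheme()


def encode_protein(seq: str, label: str = "sequence") -> np.ndarray:
    """Encode a protein string for the DP kernels; error names the offending
    position for any character outside the accepted alphabet."""
    arr = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq.upper()):
        idx = _INDEX.get(c)
        if idx is None:
            raise ValueError(f"invalid residue {c!r} at position {i} of {label}")
        arr[i] = idx
    return arr


@dataclass
class AlignmentHit:
    """One local alignment, BLAST-style.

    Coordinates are 1-based inclusive, in amino acids for protein-mode hits
    and in forward-strand nucleotides for translated-genome hits (where
    ``frame_q``/``frame_s`` carry the reading frames, negative = reverse
    strand).  ``positives`` counts aligned columns with positive substitution
    score, identities included.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: int
    aln_len: int
    identities: int
    positives: int
    gaps: int
    pct_identity: float
    pct_similarity: float
    frame_q: int = 0
    frame_s: int = 0
    q_rank: int = -1
    s_rank: int = -1
    q_len: int = 0
    s_len: int = 0
    columns: list[tuple[int, int]] = field(default_factory=list, repr=False)


def _hit_from_columns(
    cols: list[tuple[int, int]],
    a_enc: np.ndarray,
    b_enc: np.ndarray,
    S: np.ndarray,
) -> tuple[int, int, int, int, int, int, int]:
    """(q_start0, q_end0, s_start0, s_end0, identities, positives, gaps)."""
    identities = positives = gaps = 0
    for qi, sj in cols:
        if qi < 0 or sj < 0:
            gaps += 1
            continue
        if a_enc[qi] == b_enc[sj]:
            identities += 1
        if S[a_enc[qi], b_enc[sj]] > 0:
            positives += 1
    q_idx = [qi for qi, _ in cols if qi >= 0]
    s_idx = [sj for _, sj in cols if sj >= 0]
    return q_idx[0], q_idx[-1] + 1, s_idx[0], s_idx[-1] + 1, identities, positives, gaps


def smith_waterman(
    a: str,
    b: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "query",
    subject_id: str = "subject",
    band: int = 0,
    keep_columns: bool = False,
) -> AlignmentHit | None:
    """Optimal local alignment of two proteins under affine gaps.

    Returns ``None`` when the optimal score is not positive.  Traceback is
    deterministic: ties prefer diagonal over up over left, and among
    equal-scoring maximal cells the lexicographically smallest
    (q_end, s_end) wins.  ``band`` > 0 excludes cells within ``band`` of the
    main diagonal (off-diagonal self-alignment).
    """
    if not a or not b:
        raise ValueError("smith_waterman requires non-empty sequences")
    a_enc = encode_protein(a, "query")
    b_enc = encode_protein(b, "subject")
    S = scheme.substitution_matrix()
    best, bi, bj, ptr_m, ptr_x, ptr_y = sw_fill(
        a_enc, b_enc, S, scheme.gap_open, scheme.gap_extend, band
    )
    if best <= 0:
        return None
    cols = sw_traceback(bi, bj, ptr_m, ptr_x, ptr_y)
    q0, q1, s0, s1, ident, pos, gaps = _hit_from_columns(cols, a_enc, b_enc, S)
    aln_len = len(cols)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        q_start=q0 + 1,
        q_end=q1,
        s_start=s0 + 1,
        s_end=s1,
        score=int(best),
        aln_len=aln_len,
        identities=ident,
        positives=pos,
        gaps=gaps,
        pct_identity=100.0 * ident / aln_len,
        pct_similarity=100.0 * pos / aln_len,
        q_len=len(a),
        s_len=len(b),
        columns=cols if keep_columns else [],
    )


def _passes(
    hit: AlignmentHit,
    min_similarity: float,
    min_aln_len: int,
    min_score: int,
    metric: str,
) -> bool:
    pct = hit.pct_identity if metric == "identity" else hit.pct_similarity
    return (
        pct >= min_similarity
        and hit.aln_len >= min_aln_len
        and hit.score >= min_score
    )


def all_vs_all_proteins(
    A: GenomeRecord,
    B: GenomeRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_similarity: float = 20.0,
    min_aln_len: int = 4,
    min_score: int = 60,
    metric: str = "positives",
) -> list[AlignmentHit]:
    """Best local alignment for every ordered gene-product pair, filtered.

    ``min_aln_len`` is in aligned amino-acid columns (a "10 bp minimum
    alignment" legend threshold corresponds to 4 aa).  ``metric`` selects
    whether ``min_similarity`` filters on positives ("positives", default) or
    on identity ("identity").  Output is sorted by (query rank, subject rank).
    """
    if not A.features or not B.features:
        raise ValueError("all_vs_all_proteins requires genomes with gene features")
    if metric not in ("positives", "identity"):
        raise ValueError(f"unknown similarity metric {metric!r}")
    S = scheme.substitution_matrix()
    enc_a = [(fa, encode_protein(fa.protein, fa.locus_id)) for fa in A.features if fa.protein]
    enc_b = [(fb, encode_protein(fb.protein, fb.locus_id)) for fb in B.features if fb.protein]
    hits: list[AlignmentHit] = []
    for fa, ea in enc_a:
        for fb, eb in enc_b:
            # cheap score-only screen: the full traceback fill runs only for
            # pairs that can still pass the score filter
            best = sw_score_only(ea, eb, S, scheme.gap_open, scheme.gap_extend, 0)
            if best <= 0 or best < min_score:
                continue
            hit = smith_waterman(
                fa.protein, fb.protein, scheme, query_id=fa.locus_id, subject_id=fb.locus_id
            )
            if hit is None:
                continue
            if not _passes(hit, min_similarity, min_aln_len, min_score, metric):
                continue
            hit.q_rank = fa.rank
            hit.s_rank = fb.rank
            hits.append(hit)
    hits.sort(key=lambda h: (h.q_rank, h.s_rank))
    return hits


def _stop_free_segments(frame_aa: str, min_len: int) -> list[tuple[int, str]]:
    """(aa_offset, segment) pieces of a frame translation between stops."""
    segments = []
    pos = 0
    for piece in frame_aa.split("*"):
        if len(piece) >= min_len:
            segments.append((pos, piece))
        pos += len(piece) + 1
    return segments


def _aa_to_nt(frame: int, aa_start: int, aa_end: int, length: int) -> tuple[int, int]:
    """Map an aa interval in a reading frame to forward-strand 0-based
    half-open nucleotide coordinates."""
    k = abs(frame)
    start = (k - 1) + 3 * aa_start
    end = (k - 1) + 3 * aa_end
    if frame < 0:
        start, end = length - end, length - start
    return start, end


def translated_genome_compare(
    A: GenomeRecord,
    B: GenomeRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_similarity: float = 30.0,
    min_aln_len_bp: int = 100,
    min_score: int = 0,
    metric: str = "positives",
) -> list[AlignmentHit]:
    """tBLASTx-style comparison: all 6x6 frame pairs of stop-free translated
    segments, reported in forward-strand nucleotide coordinates.

    The minimum alignment length is given in bp (aa columns x 3).  Frames are
    numbered +1..+3 on the forward strand and -1..-3 on the reverse
    complement.
    """
    min_aa = max(1, -(-min_aln_len_bp // 3))  # ceil
    S = scheme.substitution_matrix()
    frames_a = six_frame_translate(A.sequence)
    frames_b = six_frame_translate(B.sequence)
    frame_ids = (1, 2, 3, -1, -2, -3)
    seg_enc_a = [
        [(off, seg, encode_protein(seg, A.id)) for off, seg in _stop_free_segments(fa, min_aa)]
        for fa in frames_a
    ]
    seg_enc_b = [
        [(off, seg, encode_protein(seg, B.id)) for off, seg in _stop_free_segments(fb, min_aa)]
        for fb in frames_b
    ]
    hits: list[AlignmentHit] = []
    for fi, segs_a in zip(frame_ids, seg_enc_a):
        for fj, segs_b in zip(frame_ids, seg_enc_b):
            for off_a, seg_a, ea in segs_a:
                for off_b, seg_b, eb in segs_b:
                    best = sw_score_only(ea, eb, S, scheme.gap_open, scheme.gap_extend, 0)
                    if best <= 0 or best < min_score:
                        continue
                    hit = smith_waterman(seg_a, seg_b, scheme, A.id, B.id)
                    if hit is None or hit.aln_len < min_aa:
                        continue
                    if not _passes(
                        hit, min_similarity, min_aa, min_score, metric
                    ):
                        continue
                    q0, q1 = _aa_to_nt(
                        fi, off_a + hit.q_start - 1, off_a + hit.q_end, A.length
                    )
                    s0, s1 = _aa_to_nt(
                        fj, off_b + hit.s_start - 1, off_b + hit.s_end, B.length
                    )
                    hit.q_start, hit.q_end = q0 + 1, q1
                    hit.s_start, hit.s_end = s0 + 1, s1
                    hit.frame_q, hit.frame_s = fi, fj
                    hit.q_len, hit.s_len = A.length, B.length
                    hits.append(hit)
    hits.sort(key=lambda h: (h.frame_q, h.frame_s, h.q_start, h.s_start, -h.score))
    return hits


_TSV_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_len",
    "identities",
    "gaps",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "score",
    "positives",
    "pct_similarity",
    "frame_q",
    "frame_s",
    "q_rank",
    "s_rank",
    "q_len",
    "s_len",
]


def write_hits_tsv(hits: list[AlignmentHit], path) -> None:
    """BLAST outfmt-6-like hit table with extra positives / pct_similarity
    columns; a single documented header line starting with '#'."""
    with open(path, "w") as out:
        out.write("#" + "\t".join(_TSV_COLUMNS) + "\n")
        for h in hits:
            row = [
                h.query_id,
                h.subject_id,
                f"{h.pct_identity:.2f}",
                h.aln_len,
                h.identities,
                h.gaps,
                h.q_start,
                h.q_end,
                h.s_start,
                h.s_end,
                h.score,
                h.positives,
                f"{h.pct_similarity:.2f}",
                h.frame_q,
                h.frame_s,
                h.q_rank,
                h.s_rank,
                h.q_len,
                h.s_len,
            ]
            out.write("\t".join(str(x) for x in row) + "\n")


def read_hits_tsv(path) -> list[AlignmentHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline().lstrip("#").split()
        if header != _TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected hit-table header")
        for line in fh:
            t = line.rstrip("\n").split("\t")
            rec = dict(zip(_TSV_COLUMNS, t))
            hits.append(
                AlignmentHit(
                    query_id=rec["query_id"],
                    subject_id=rec["subject_id"],
                    q_start=int(rec["q_start"]),
                    q_end=int(rec["q_end"]),
                    s_start=int(rec["s_start"]),
                    s_end=int(rec["s_end"]),
                    score=int(rec["score"]),
                    aln_len=int(rec["aln_len"]),
                    identities=int(rec["identities"]),
                    positives=int(rec["positives"]),
                    gaps=int(rec["gaps"]),
                    pct_identity=float(rec["pct_identity"]),
                    pct_similarity=float(rec["pct_similarity"]),
                    frame_q=int(rec["frame_q"]),
                    frame_s=int(rec["frame_s"]),
                    q_rank=int(rec["q_rank"]),
                    s_rank=int(rec["s_rank"]),
                    q_len=int(rec["q_len"]),
                    s_len=int(rec["s_len"]),
                )
            )
    return hits
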