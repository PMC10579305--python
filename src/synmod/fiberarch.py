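"""Tail-fiber architecture calls from sequence alone.

Two sequence signatures distinguish the "extended" from the "truncated"
variant of a fiber or chaperone:

* an internal insertion: a long run of alignment columns present only in the
  extended protein, flanked on both sides by conserved segments (labelled S1
  upstream and S2 downstream), detected from a global alignment with free end
  gaps so that terminal length differences are never miscalled as internal
  insertions; and
* an internal tandem duplication (the knob-domain duplication signature):
  a high-scoring off-diagonal local self-alignment whose two spans define the
  repeat units.

Only residue-level quantities are reported; structural measurements (domain
geometry, hairpin lengths) are not derivable from sequence and are out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .align import DEFAULT_SCHEME, ScoringScheme, encode_protein, smith_waterman

__all__ = ["InsertionCall", "RepeatCall", "detect_insertion", "detect_internal_repeat"]


@dataclass
class InsertionCall:
    """An insertion in the extended protein with conserved flanks S1/S2.

    ``ins_start``/``ins_end`` are a 0-based half-open residue interval on the
    extended protein; flanks are the adjacent aligned segments with their
    percent identity to the truncated protein.
    """

    extended_id: str
    truncated_id: str
    ins_start: int
    ins_end: int
    flank_s1: tuple[int, int]
    flank_s2: tuple[int, int]
    flank_identity_s1: float
    flank_identity_s2: float

    @property
    def length(self) -> int:
        return self.ins_end - self.ins_start


@dataclass
class RepeatCall:
    """Internal tandem repeat: ordered, non-overlapping unit spans (0-based
    half-open residue intervals) and their mean pairwise percent similarity."""

    unit_spans: list[tuple[int, int]]
    unit_similarity: float


def _free_end_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scheme.matrix_name)
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    aligner.end_gap_score = 0.0
    return aligner


def _segments(coordinates) -> list[tuple[int, int, int, int]]:
    """Alignment path as (t0, t1, q0, q1) segments (target = extended)."""
    segs = []
    t_pts, q_pts = coordinates
    for k in range(len(t_pts) - 1):
        segs.append((int(t_pts[k]), int(t_pts[k + 1]), int(q_pts[k]), int(q_pts[k + 1])))
    return segs


def detect_insertion(
    extended: str,
    truncated: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_insertion: int = 30,
    flank_window: int = 10,
    flank_identity_min: float = 50.0,
    extended_id: str = "extended",
    truncated_id: str = "truncated",
) -> InsertionCall | None:
    """Locate the single largest internal insertion of the extended protein
    relative to the truncated one.

    The proteins are aligned globally with free end gaps; the longest
    contiguous run of columns gapped in the truncated sequence becomes the
    insertion if it spans at least ``min_insertion`` residues and both
    flanking ``flank_window`` aligned columns reach
    ``flank_identity_min`` percent identity.  Returns ``None`` otherwise
    (in particular for identical or equal-length inputs).
    """
    if not extended or not truncated:
        raise ValueError("detect_insertion requires non-empty protein sequences")
    encode_protein(extended, "extended")
    encode_protein(truncated, "truncated")
    if len(extended) <= len(truncated):
        return None
    aligner = _free_end_aligner(scheme)
    aln = aligner.align(extended.upper(), truncated.upper())[0]
    segs = _segments(aln.coordinates)
    # trim free end-gap segments: they are terminal overhangs, not insertions
    while segs and (segs[0][0] == segs[0][1] or segs[0][2] == segs[0][3]):
        segs.pop(0)
    while segs and (segs[-1][0] == segs[-1][1] or segs[-1][2] == segs[-1][3]):
        segs.pop()
    # longest run of target-only columns (gap in the truncated sequence)
    best = None
    for idx, (t0, t1, q0, q1) in enumerate(segs):
        if q0 == q1 and t1 - t0 >= min_insertion:
            if best is None or (t1 - t0) > (best[1] - best[0]):
                best = (t0, t1, idx)
    if best is None:
        return None
    ins_start, ins_end, seg_idx = best

    def flank(side: str) -> tuple[tuple[int, int], float] | None:
        """Nearest flank_window aligned columns up-/downstream of the run."""
        cols: list[tuple[int, int]] = []
        rng = range(seg_idx - 1, -1, -1) if side == "up" else range(seg_idx + 1, len(segs))
        for k in rng:
            t0, t1, q0, q1 = segs[k]
            if t1 - t0 == 0 or q1 - q0 == 0:
                continue  # gap segment: skip, keep collecting aligned columns
            pairs = list(zip(range(t0, t1), range(q0, q1)))
            if side == "up":
                pairs.reverse()
            for pair in pairs:
                cols.append(pair)
                if len(cols) == flank_window:
                    break
            if len(cols) == flank_window:
                break
        if len(cols) < flank_window:
            return None
        matches = sum(1 for ti, qi in cols if extended[ti] == truncated[qi])
        t_positions = [ti for ti, _ in cols]
        return (min(t_positions), max(t_positions) + 1), 100.0 * matches / flank_window

    up = flank("up")
    down = flank("down")
    if up is None or down is None:
        return None
    (s1_span, s1_ident), (s2_span, s2_ident) = up, down
    if s1_ident < flank_identity_min or s2_ident < flank_identity_min:
        return None
    return InsertionCall(
        extended_id=extended_id,
        truncated_id=truncated_id,
        ins_start=ins_start,
        ins_end=ins_end,
        flank_s1=s1_span,
        flank_s2=s2_span,
        flank_identity_s1=s1_ident,
        flank_identity_s2=s2_ident,
    )


def detect_internal_repeat(
    protein: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_unit: int = 50,
    min_unit_similarity: float = 20.0,
) -> RepeatCall | None:
    """Internal tandem repeat from off-diagonal self-alignment.

    The protein is locally aligned against itself excluding a band of width
    ``min_unit`` around the main diagonal; the best off-diagonal alignment
    defines two candidate unit spans, accepted when the aligned length
    reaches ``min_unit`` and similarity reaches ``min_unit_similarity``.
    Overlapping spans are trimmed to disjoint intervals at the overlap
    midpoint.
    """
    if len(protein) < 2 * min_unit:
        raise ValueError(
            f"protein of length {len(protein)} is shorter than 2 x min_unit ({min_unit})"
        )
    hit = smith_waterman(protein, protein, scheme, band=min_unit)
    if hit is None:
        return None
    if hit.aln_len < min_unit or hit.pct_similarity < min_unit_similarity:
        return None
    span_q = (hit.q_start - 1, hit.q_end)
    span_s = (hit.s_start - 1, hit.s_end)
    first, second = sorted([span_q, span_s])
    if first[1] > second[0]:  # overlapping: trim at the midpoint
        mid = (second[0] + first[1]) // 2
        first = (first[0], mid)
        second = (mid, second[1])
    if first[1] - first[0] < min_unit or second[1] - second[0] < min_unit:
        return None
    return RepeatCall(unit_spans=[first, second], unit_similarity=hit.pct_similarity)
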