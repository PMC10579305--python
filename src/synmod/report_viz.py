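"""Human-readable outputs: pairwise genome-comparison SVG and TSV reports.

The comparison figure follows the familiar linear genome-alignment layout:
one horizontal track per genome with gene arrows, and shaded ribbons between
adjacent tracks for each translated-genome alignment hit, ribbon shade
monotone in percent similarity.  Output is deterministic SVG (vector only),
so figures are assertable artifacts: ribbons carry ``data-`` attributes with
their hit coordinates and similarity.
"""

from __future__ import annotations

import math
from pathlib import Path

from .align import AlignmentHit
from .genome_io import GenomeRecord
from .synteny import ModuleCall, SyntenyBlock

__all__ = [
    "render_comparison",
    "write_module_report",
    "read_module_report",
    "write_block_summary",
]

_TRACK_GAP = 130
_MARGIN = 50
_WIDTH = 1000
_GENE_H = 12


def _shade(pct: float, lo: float, hi: float) -> str:
    """Single-hue (grey) linear ramp: light at ``lo``, dark at ``hi``."""
    t = 0.0 if hi <= lo else min(1.0, max(0.0, (pct - lo) / (hi - lo)))
    v = int(round(225 - 170 * t))
    return f"rgb({v},{v},{v})"


def render_comparison(
    records: list[GenomeRecord],
    hits: list[list[AlignmentHit]],
    out_path: str | Path,
    similarity_bounds: tuple[float, float] = (20.0, 100.0),
    thresholds_note: str = "",
) -> None:
    """Render genome tracks with inter-track ribbons for the given hits.

    ``hits[i]`` connects ``records[i]`` (query) to ``records[i + 1]``
    (subject).  Ribbon x-extents scale linearly with nucleotide position per
    track; a legend prints the similarity ramp bounds and the filter
    thresholds used.
    """
    if len(records) < 2:
        raise ValueError("render_comparison requires at least two genomes")
    if len(hits) != len(records) - 1:
        raise ValueError("need one hit list per adjacent genome pair")
    lo, hi = similarity_bounds
    max_len = max(r.length for r in records)
    scale = (_WIDTH - 2 * _MARGIN) / max_len

    def x(track: int, pos: int) -> float:
        return _MARGIN + pos * scale

    def y(track: int) -> float:
        return 70.0 + track * _TRACK_GAP

    height = 70 + (len(records) - 1) * _TRACK_GAP + 110
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_WIDTH}" '
        f'height="{height}" viewBox="0 0 {_WIDTH} {height}">',
        "<!-- pairwise genome comparison; ribbons shaded by percent similarity -->",
    ]
    # ribbons first so gene arrows draw on top
    for k, pair_hits in enumerate(hits):
        qa, qb = records[k], records[k + 1]
        for h in pair_hits:
            if h.q_end > qa.length or h.s_end > qb.length or h.q_start < 1 or h.s_start < 1:
                raise ValueError(
                    f"hit {h.query_id}->{h.subject_id} outside track coordinates"
                )
            x0, x1 = x(k, h.q_start - 1), x(k, h.q_end)
            x2, x3 = x(k + 1, h.s_end), x(k + 1, h.s_start - 1)
            y0, y1 = y(k) + _GENE_H, y(k + 1) - _GENE_H
            parts.append(
                f'<polygon class="ribbon" data-pct="{h.pct_similarity:.2f}" '
                f'data-q0="{h.q_start}" data-q1="{h.q_end}" '
                f'data-s0="{h.s_start}" data-s1="{h.s_end}" '
                f'points="{x0:.2f},{y0:.2f} {x1:.2f},{y0:.2f} '
                f'{x2:.2f},{y1:.2f} {x3:.2f},{y1:.2f}" '
                f'fill="{_shade(h.pct_similarity, lo, hi)}" fill-opacity="0.85" '
                f'stroke="none"/>'
            )
    for k, rec in enumerate(records):
        ty = y(k)
        parts.append(
            f'<line x1="{x(k, 0):.2f}" y1="{ty:.2f}" x2="{x(k, rec.length):.2f}" '
            f'y2="{ty:.2f}" stroke="black" stroke-width="1"/>'
        )
        parts.append(
            f'<text x="{_MARGIN}" y="{ty - _GENE_H - 6:.2f}" font-size="12" '
            f'font-family="sans-serif">{rec.id} ({rec.length:,} bp)</text>'
        )
        for f in rec.features:
            x0, x1 = x(k, f.start), x(k, f.end)
            head = min(6.0, x1 - x0)
            if f.strand == "+":
                pts = (
                    f"{x0:.2f},{ty - _GENE_H / 2:.2f} {x1 - head:.2f},{ty - _GENE_H / 2:.2f} "
                    f"{x1:.2f},{ty:.2f} {x1 - head:.2f},{ty + _GENE_H / 2:.2f} "
                    f"{x0:.2f},{ty + _GENE_H / 2:.2f}"
                )
            else:
                pts = (
                    f"{x1:.2f},{ty - _GENE_H / 2:.2f} {x0 + head:.2f},{ty - _GENE_H / 2:.2f} "
                    f"{x0:.2f},{ty:.2f} {x0 + head:.2f},{ty + _GENE_H / 2:.2f} "
                    f"{x1:.2f},{ty + _GENE_H / 2:.2f}"
                )
            parts.append(
                f'<polygon class="gene" points="{pts}" fill="#7fb2d9" '
                f'stroke="black" stroke-width="0.5"><title>{f.locus_id}</title></polygon>'
            )
    # legend: similarity ramp with printed bounds
    ly = height - 60
    for i in range(10):
        pct = lo + (hi - lo) * (i + 0.5) / 10
        parts.append(
            f'<rect class="legend" x="{_MARGIN + i * 20}" y="{ly}" width="20" '
            f'height="12" fill="{_shade(pct, lo, hi)}"/>'
        )
    parts.append(
        f'<text x="{_MARGIN}" y="{ly + 26}" font-size="11" font-family="sans-serif">'
        f"percent similarity: {lo:g}&#8211;{hi:g}"
        + (f" | {thresholds_note}" if thresholds_note else "")
        + "</text>"
    )
    parts.append("</svg>")
    Path(out_path).write_text("\n".join(parts) + "\n")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _fmt_range(rng: tuple[int, int]) -> str:
    return f"({rng[0]}-{rng[1]})"


def _parse_range(text: str) -> tuple[int, int]:
    a, b = text.strip("()").split("-")
    return int(a), int(b)


def write_module_report(
    calls: list[ModuleCall], out_path: str | Path, thresholds: dict | None = None
) -> None:
    """Per-gene-pair module report TSV.

    One row per gene pair: module index, loci, integer-rounded percent
    similarity and the aligned residue ranges in ``(start-end)`` notation.
    Threshold settings are recorded in a leading comment line.
    """
    lines = []
    if thresholds:
        settings = " ".join(f"{k}={v}" for k, v in sorted(thresholds.items()))
        lines.append(f"# thresholds: {settings}")
    lines.append("module\tlocus_a\tlocus_b\tpct_similarity\tq_range\ts_range")
    for m, call in enumerate(calls, start=1):
        for row in call.gene_table:
            lines.append(
                "\t".join(
                    [
                        str(m),
                        row["locus_a"],
                        row["locus_b"],
                        str(_round_half_up(row["pct_similarity"])),
                        _fmt_range(row["q_range"]),
                        _fmt_range(row["s_range"]),
                    ]
                )
            )
    Path(out_path).write_text("\n".join(lines) + "\n")


def read_module_report(path: str | Path) -> list[dict]:
    """Parse a module report back into row dictionaries."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("module\t"):
            continue
        m, la, lb, pct, qr, sr = line.split("\t")
        rows.append(
            {
                "module": int(m),
                "locus_a": la,
                "locus_b": lb,
                "pct_similarity": int(pct),
                "q_range": _parse_range(qr),
                "s_range": _parse_range(sr),
            }
        )
    return rows


def write_block_summary(
    blocks: list[SyntenyBlock], out_path: str | Path, thresholds: dict | None = None
) -> None:
    """One row per syntenic block: size, rank spans, direction, gaps."""
    lines = []
    if thresholds:
        settings = " ".join(f"{k}={v}" for k, v in sorted(thresholds.items()))
        lines.append(f"# thresholds: {settings}")
    lines.append(
        "block\tn_syntenic\trank_a_first\trank_a_last\trank_b_first\trank_b_last"
        "\tdirection\tgap_runs\tmean_similarity"
    )
    for i, blk in enumerate(blocks, start=1):
        mean_sim = sum(p.pct_similarity for p in blk.pairs) / blk.n_syntenic
        lines.append(
            "\t".join(
                [
                    str(i),
                    str(blk.n_syntenic),
                    str(blk.pairs[0].rank_a),
                    str(blk.pairs[-1].rank_a),
                    str(blk.pairs[0].rank_b),
                    str(blk.pairs[-1].rank_b),
                    str(blk.direction),
                    ",".join(str(g) for g in blk.gap_runs) or "-",
                    f"{mean_sim:.1f}",
                ]
            )
        )
    Path(out_path).write_text("\n".join(lines) + "\n")
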