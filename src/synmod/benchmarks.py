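"""Recovery experiments on planted ground truth.

These are the package's own validation experiments: each one generates
synthetic inputs under the documented study conditions, runs the pipeline (or
a single detector), and scores the result against the simulator's ground
truth.  They are used by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .fiberarch import detect_insertion, detect_internal_repeat
from .pipeline import PipelineConfig, compare_genomes
from .synteny import SyntenyPair, detect_blocks
from .synthetic_data import (
    SimConfig,
    plant_insertion,
    plant_tandem_duplication,
    random_protein,
    simulate_module_pair,
)

__all__ = [
    "random_peptide_pairs",
    "synteny_boundary_results",
    "module_recovery",
    "null_module_calls",
    "insertion_recovery",
    "repeat_recovery",
]


def random_peptide_pairs(
    n_pairs: int, max_len: int = 12, seed: int = 0
) -> list[tuple[str, str]]:
    """Seeded random peptide pairs over the 20 canonical residues."""
    from .synthetic_data import AMINO_ACIDS

    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        la = int(rng.integers(1, max_len + 1))
        lb = int(rng.integers(1, max_len + 1))
        pa = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=la))
        pb = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=lb))
        pairs.append((pa, pb))
    return pairs


def _pairs_at(ranks: list[tuple[int, int]]) -> list[SyntenyPair]:
    return [
        SyntenyPair(
            rank_a=a,
            rank_b=b,
            locus_a=f"a{a}",
            locus_b=f"b{b}",
            pct_similarity=60.0,
            size_ratio=1.0,
        )
        for a, b in ranks
    ]


def synteny_boundary_results() -> dict[str, int]:
    """Block counts for the hand-enumerable boundary cases of the block rule
    (five-or-more members; separations of at most four non-syntenic genes)."""
    five = _pairs_at([(i, i) for i in range(5)])
    four = _pairs_at([(i, i) for i in range(4)])
    gap4 = _pairs_at([(i, i) for i in (0, 1, 2, 7, 8, 9)])
    gap5 = _pairs_at([(i, i) for i in (0, 1, 2, 8, 9, 10)])
    return {
        "five_consecutive": len(detect_blocks(five)),
        "four_consecutive": len(detect_blocks(four)),
        "gap_of_four": len(detect_blocks(gap4)),
        "gap_of_five": len(detect_blocks(gap5)),
    }


def module_recovery(
    n_runs: int = 50, seed0: int = 0, config: PipelineConfig | None = None
) -> dict:
    """Run the full pipeline on simulated module pairs at default study
    conditions (ten module genes, 60 percent target similarity); a run counts
    as correct when exactly one module is called and its gene set equals the
    planted orthology."""
    config = config or PipelineConfig()
    correct = 0
    mean_similarities = []
    for i in range(n_runs):
        A, B, truth = simulate_module_pair(SimConfig(seed=seed0 + i))
        result = compare_genomes(A, B, config, with_genome_hits=False)
        if len(result.modules) == 1:
            called = [(r["locus_a"], r["locus_b"]) for r in result.modules[0].gene_table]
            if called == truth.orthology:
                correct += 1
            mean_similarities.append(result.modules[0].mean_similarity)
    return {
        "n_runs": n_runs,
        "n_correct": correct,
        "pct_correct": 100.0 * correct / n_runs,
        "mean_module_similarity": float(np.mean(mean_similarities)) if mean_similarities else float("nan"),
    }


def null_module_calls(
    n_runs: int = 50, seed0: int = 10_000, config: PipelineConfig | None = None
) -> dict:
    """Total module calls over genome pairs sharing no module (expect zero)."""
    config = config or PipelineConfig()
    total = 0
    for i in range(n_runs):
        A, B, _ = simulate_module_pair(SimConfig(seed=seed0 + i, module_genes=0))
        result = compare_genomes(A, B, config, with_genome_hits=False)
        total += len(result.modules)
    return {"n_runs": n_runs, "total_module_calls": total}


def insertion_recovery(
    n_runs: int = 50,
    seed0: int = 0,
    truncated_len: int = 300,
    insert_len: int = 60,
    tolerance: int = 5,
) -> dict:
    """Plant an unrelated insertion at a random internal position and score
    boundary localization to within ``tolerance`` residues."""
    ok = 0
    for i in range(n_runs):
        rng = np.random.default_rng(seed0 + i)
        truncated = random_protein(rng, truncated_len)
        insert = random_protein(rng, insert_len + 1)[1:]
        position = int(rng.integers(50, truncated_len - 50))
        extended = plant_insertion(truncated, position, insert)
        call = detect_insertion(extended, truncated)
        if (
            call is not None
            and abs(call.ins_start - position) <= tolerance
            and abs(call.ins_end - (position + insert_len)) <= tolerance
        ):
            ok += 1
    return {"n_runs": n_runs, "n_recovered": ok, "pct_recovered": 100.0 * ok / n_runs}


def repeat_recovery(
    n_runs: int = 50,
    seed0: int = 0,
    protein_len: int = 300,
    unit_len: int = 80,
    divergence: float = 0.3,
) -> dict:
    """Plant a tandem domain duplication and score recovery: two units called
    with the second covering at least 80 percent of the planted copy."""
    ok = 0
    for i in range(n_runs):
        rng = np.random.default_rng(seed0 + i)
        base = random_protein(rng, protein_len)
        start = int(rng.integers(40, protein_len - 2 * unit_len - 20))
        mutated, span = plant_tandem_duplication(base, start, unit_len, divergence, rng)
        call = detect_internal_repeat(mutated, min_unit=50)
        if call is None or len(call.unit_spans) != 2:
            continue
        second = call.unit_spans[1]
        overlap = max(0, min(second[1], span[1]) - max(second[0], span[0]))
        if overlap >= 0.8 * unit_len:
            ok += 1
    return {"n_runs": n_runs, "n_recovered": ok, "pct_recovered": 100.0 * ok / n_runs}
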