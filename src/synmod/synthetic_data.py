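"""Synthetic mosaic phage genome pairs with planted shared modules.

The generator emulates the discovery scenario the pipeline targets: two
phage genomes with mutually unrelated gene backbones that nevertheless share
one syntenic module of homologous genes (the host-recognition module
scenario), optionally with an "extended" variant of a fiber-like gene
carrying an internal tandem domain duplication and of a chaperone-like gene
carrying an elongated insertion.

Module gene pairs are generated from a common ancestor protein and diverged
by i.i.d. residue substitution (replacement residues drawn from a
BLOSUM62-conditioned distribution) under *closed-loop calibration*: residues
are substituted or reverted until the measured Smith-Waterman percent
similarity of the pair falls within a tolerance band of the target, so the
simulator's "percent similarity" means exactly what the detector measures.

All sampling is drawn from a single numpy Generator seeded once, in the
documented order (module ancestors, divergence, variant edits, backgrounds,
placement, strands, intergenic spacers, back-translation), making runs
byte-reproducible for a fixed config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .align import DEFAULT_SCHEME, ScoringScheme, smith_waterman
from .genome_io import GeneFeature, GenomeRecord, write_fasta_pair

__all__ = [
    "SimConfig",
    "SimTruth",
    "CalibrationError",
    "simulate_module_pair",
    "plant_insertion",
    "plant_tandem_duplication",
    "random_protein",
    "diverge_to_target",
    "write_simulation",
    "read_truth",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Robinson & Robinson background amino-acid frequencies, indexed as
#: AMINO_ACIDS above.
ROBINSON_FREQS = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

_TABLE_11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS_FOR = {}
for codon, aa in _TABLE_11.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for codons in _CODONS_FOR.values():
    codons.sort()
_STOP_CODONS = sorted(_TABLE_11.stop_codons)

TRUTH_SCHEMA_VERSION = 1


class CalibrationError(RuntimeError):
    """Raised when divergence calibration cannot reach the target band."""


@dataclass
class SimConfig:
    """Generator settings.  Defaults encode the study conditions the
    pipeline is meant to recover: a ten-gene shared module at ~60 percent
    similarity embedded in unrelated gene backbones."""

    seed: int = 0
    n_background_a: int = 18
    n_background_b: int = 22
    gene_len_aa: tuple[int, int] = (80, 600)
    module_genes: int = 10
    target_similarity: float = 60.0
    similarity_tolerance: float = 5.0
    insert_duplication: bool = False
    duplication_unit_aa: int = 80
    duplication_divergence: float = 0.3
    extend_chaperone: bool = False
    chaperone_hairpin_aa: int = 90
    intergenic_nt: tuple[int, int] = (2, 150)
    residue_freqs: str = "robinson"
    max_calibration_iter: int = 500

    def __post_init__(self) -> None:
        if self.n_background_a <= 0 or self.n_background_b <= 0:
            raise ValueError("background gene counts must be positive")
        if self.module_genes < 0:
            raise ValueError("module_genes must be non-negative")
        if self.module_genes and not (20 < self.target_similarity <= 100):
            raise ValueError("target_similarity must lie in (20, 100]")
        if self.residue_freqs not in ("robinson", "uniform"):
            raise ValueError("residue_freqs must be 'robinson' or 'uniform'")


@dataclass
class SimTruth:
    """Machine-readable ground truth for one simulated genome pair."""

    orthology: list[tuple[str, str]]
    module_span_a: tuple[int, int] | None
    module_span_b: tuple[int, int] | None
    planted_insertions: list[tuple[str, tuple[int, int]]]
    realized_similarity: list[float]
    schema_version: int = TRUTH_SCHEMA_VERSION
    rng: str = "numpy.random.default_rng(PCG64)"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            orthology=[tuple(x) for x in d["orthology"]],
            module_span_a=tuple(d["module_span_a"]) if d["module_span_a"] else None,
            module_span_b=tuple(d["module_span_b"]) if d["module_span_b"] else None,
            planted_insertions=[(loc, tuple(span)) for loc, span in d["planted_insertions"]],
            realized_similarity=list(d["realized_similarity"]),
            schema_version=d["schema_version"],
            rng=d.get("rng", ""),
        )


def _freq_vector(kind: str) -> np.ndarray:
    if kind == "uniform":
        return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    v = np.array([ROBINSON_FREQS[a] for a in AMINO_ACIDS])
    return v / v.sum()


def _conditional_substitution_matrix(scheme: ScoringScheme) -> np.ndarray:
    """q(y | x) proportional to p_y * 2^(S_xy / 2) over y != x.

    Replacement residues are thus biased the way substitution-matrix target
    frequencies are: conservative replacements are more likely, so the
    similarity of a diverged pair decays smoothly with mutation load.
    """
    S = scheme.substitution_matrix()
    p = _freq_vector("robinson")
    from .align import ALPHABET

    idx = [ALPHABET.index(a) for a in AMINO_ACIDS]
    Q = np.zeros((len(AMINO_ACIDS), len(AMINO_ACIDS)))
    for i in range(len(AMINO_ACIDS)):
        for j in range(len(AMINO_ACIDS)):
            if i == j:
                continue
            Q[i, j] = p[j] * 2.0 ** (S[idx[i], idx[j]] / 2.0)
        Q[i] /= Q[i].sum()
    return Q


def random_protein(rng: np.random.Generator, length: int, freqs: str = "robinson") -> str:
    """Random protein with the given residue frequency model; always starts
    with M (annotated gene products do)."""
    p = _freq_vector(freqs)
    body = rng.choice(list(AMINO_ACIDS), size=length - 1, p=p)
    return "M" + "".join(body)


def plant_insertion(protein: str, position: int, insert: str) -> str:
    """Splice ``insert`` into ``protein`` at ``position`` (0..len)."""
    if not (0 <= position <= len(protein)):
        raise ValueError(
            f"insertion position {position} outside [0, {len(protein)}]"
        )
    return protein[:position] + insert + protein[position:]


def plant_tandem_duplication(
    protein: str,
    start: int,
    unit_len: int,
    divergence: float,
    rng: np.random.Generator,
) -> tuple[str, tuple[int, int]]:
    """Duplicate ``protein[start:start+unit_len]`` in tandem, randomizing
    ``divergence`` of the second copy's residues.  Returns the new protein
    and the 0-based half-open span of the inserted copy."""
    if start < 0 or start + unit_len > len(protein):
        raise ValueError("duplication unit outside protein")
    unit = list(protein[start : start + unit_len])
    n_mut = int(round(divergence * unit_len))
    positions = rng.choice(unit_len, size=n_mut, replace=False)
    for pos in positions:
        unit[pos] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    new = plant_insertion(protein, start + unit_len, "".join(unit))
    return new, (start + unit_len, start + 2 * unit_len)


def _measure_similarity(a: str, b: str, scheme: ScoringScheme) -> float:
    hit = smith_waterman(a, b, scheme)
    return hit.pct_similarity if hit is not None else 0.0


def diverge_to_target(
    protein: str,
    target: float,
    rng: np.random.Generator,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    tolerance: float = 5.0,
    max_iter: int = 500,
) -> tuple[str, str, float]:
    """Diverge an ancestor protein into two copies whose measured percent
    similarity lies within ``target +/- tolerance``.

    Substitutions are applied alternately to either copy and reverted when
    the band is overshot (closed-loop calibration against the pipeline's own
    similarity measure).  Raises :class:`CalibrationError`, reporting the
    achieved similarity, if the band is not reached within ``max_iter``
    control iterations.
    """
    Q = _conditional_substitution_matrix(scheme)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    copies = [list(protein), list(protein)]
    stack: list[tuple[int, int, str]] = []
    toggle = 0
    n = len(protein)
    sim = _measure_similarity(protein, protein, scheme)
    for _ in range(max_iter):
        if target - tolerance <= sim <= target + tolerance:
            return "".join(copies[0]), "".join(copies[1]), sim
        if sim > target + tolerance:
            k = max(1, min(n // 4, int(n * (sim - target) / 200)))
            for _ in range(k):
                which = toggle
                toggle ^= 1
                pos = int(rng.integers(n))
                old = copies[which][pos]
                row = Q[aa_index[old]] if old in aa_index else None
                if row is None:
                    new = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
                else:
                    new = AMINO_ACIDS[int(rng.choice(len(AMINO_ACIDS), p=row))]
                stack.append((which, pos, old))
                copies[which][pos] = new
        else:
            k = max(1, min(len(stack), int(n * (target - sim) / 200)))
            for _ in range(k):
                if not stack:
                    break
                which, pos, old = stack.pop()
                copies[which][pos] = old
        sim = _measure_similarity("".join(copies[0]), "".join(copies[1]), scheme)
    raise CalibrationError(
        f"could not reach similarity {target}+/-{tolerance} within {max_iter} "
        f"iterations (achieved {sim:.1f})"
    )


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = _CODONS_FOR[aa]
        codons.append(options[int(rng.integers(len(options)))])
    codons.append(_STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[int(i)] for i in rng.integers(4, size=length))


def _assemble_genome(
    genome_id: str,
    proteins: list[str],
    strands: list[str],
    rng: np.random.Generator,
    intergenic_nt: tuple[int, int],
) -> GenomeRecord:
    lo, hi = intergenic_nt
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for i, (protein, strand) in enumerate(zip(proteins, strands)):
        spacer = _random_dna(rng, int(rng.integers(lo, hi + 1)))
        parts.append(spacer)
        pos += len(spacer)
        nt = _back_translate(protein, rng)
        if strand == "-":
            from .genome_io import reverse_complement

            nt = reverse_complement(nt)
        parts.append(nt)
        features.append(
            GeneFeature(
                rank=i,
                locus_id=f"gp{i + 1}",
                start=pos,
                end=pos + len(nt),
                strand=strand,
                protein=protein,
            )
        )
        pos += len(nt)
    parts.append(_random_dna(rng, int(rng.integers(lo, hi + 1))))
    return GenomeRecord(id=genome_id, sequence="".join(parts), features=features)


def simulate_module_pair(
    config: SimConfig, scheme: ScoringScheme = DEFAULT_SCHEME
) -> tuple[GenomeRecord, GenomeRecord, SimTruth]:
    """Generate a pair of mosaic genomes sharing one planted syntenic module,
    together with the ground truth needed to score pipeline output.

    With ``module_genes = 0`` the genomes are entirely unrelated (a null
    pair).  The fiber-like gene (middle of the module) optionally carries a
    tandem domain duplication in genome A (``insert_duplication``); the next
    gene optionally carries an elongated chaperone insertion
    (``extend_chaperone``).  Both edits are recorded in
    ``truth.planted_insertions`` with their residue spans on the A copy.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_len_aa

    # 1. module ancestors and diverged copies
    module_a: list[str] = []
    module_b: list[str] = []
    realized: list[float] = []
    for _ in range(config.module_genes):
        length = int(rng.integers(lo, hi + 1))
        ancestor = random_protein(rng, length, config.residue_freqs)
        pa, pb, sim = diverge_to_target(
            ancestor,
            config.target_similarity,
            rng,
            scheme,
            config.similarity_tolerance,
            config.max_calibration_iter,
        )
        module_a.append(pa)
        module_b.append(pb)
        realized.append(sim)

    # 2. extended-variant edits on genome A copies
    fiber_idx = config.module_genes // 2 if config.module_genes else None
    chap_idx = fiber_idx + 1 if fiber_idx is not None and fiber_idx + 1 < config.module_genes else None
    planted: list[tuple[int, tuple[int, int]]] = []  # (module index, span)
    if config.insert_duplication and fiber_idx is not None:
        fiber = module_a[fiber_idx]
        unit = config.duplication_unit_aa
        if len(fiber) < unit * 2:
            fiber = fiber + random_protein(rng, unit * 2, config.residue_freqs)[1:]
        start = (len(fiber) - unit) // 2
        fiber, span = plant_tandem_duplication(
            fiber, start, unit, config.duplication_divergence, rng
        )
        module_a[fiber_idx] = fiber
        planted.append((fiber_idx, span))
    if config.extend_chaperone and chap_idx is not None:
        chap = module_a[chap_idx]
        position = len(chap) // 2
        insert = random_protein(rng, config.chaperone_hairpin_aa, config.residue_freqs)[1:]
        insert = "G" + insert  # keep insert length as configured
        module_a[chap_idx] = plant_insertion(chap, position, insert)
        planted.append((chap_idx, (position, position + len(insert))))

    # 3. background genes
    bg_a = [
        random_protein(rng, int(rng.integers(lo, hi + 1)), config.residue_freqs)
        for _ in range(config.n_background_a)
    ]
    bg_b = [
        random_protein(rng, int(rng.integers(lo, hi + 1)), config.residue_freqs)
        for _ in range(config.n_background_b)
    ]

    # 4. module placement and strands
    ins_a = int(rng.integers(config.n_background_a + 1))
    ins_b = int(rng.integers(config.n_background_b + 1))
    order_a = bg_a[:ins_a] + module_a + bg_a[ins_a:]
    order_b = bg_b[:ins_b] + module_b + bg_b[ins_b:]
    strands_a = ["+" if rng.integers(2) else "-" for _ in order_a]
    strands_b = ["+" if rng.integers(2) else "-" for _ in order_b]
    for k in range(config.module_genes):
        strands_a[ins_a + k] = "+"
        strands_b[ins_b + k] = "+"

    # 5. assembly (intergenic spacers + back-translation)
    A = _assemble_genome(
        f"sim{config.seed}_A", order_a, strands_a, rng, config.intergenic_nt
    )
    B = _assemble_genome(
        f"sim{config.seed}_B", order_b, strands_b, rng, config.intergenic_nt
    )

    if config.module_genes:
        orthology = [
            (A.features[ins_a + k].locus_id, B.features[ins_b + k].locus_id)
            for k in range(config.module_genes)
        ]
        span_a = (A.features[ins_a].start, A.features[ins_a + config.module_genes - 1].end)
        span_b = (B.features[ins_b].start, B.features[ins_b + config.module_genes - 1].end)
    else:
        orthology, span_a, span_b = [], None, None
    truth = SimTruth(
        orthology=orthology,
        module_span_a=span_a,
        module_span_b=span_b,
        planted_insertions=[
            (A.features[ins_a + idx].locus_id, span) for idx, span in planted
        ],
        realized_similarity=realized,
    )
    return A, B, truth


def write_simulation(
    A: GenomeRecord, B: GenomeRecord, truth: SimTruth, out_dir: str | Path
) -> None:
    """Write the FASTA-pair dialect for both genomes plus the JSON truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta_pair(A, out / "A.fna", out / "A.faa")
    write_fasta_pair(B, out / "B.fna", out / "B.faa")
    (out / "truth.json").write_text(truth.to_json() + "\n")


def read_truth(path: str | Path) -> SimTruth:
    return SimTruth.from_json(Path(path).read_text())
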