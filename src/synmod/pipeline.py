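"""End-to-end comparison pipeline: configuration and orchestration.

:class:`PipelineConfig` gathers every threshold of the analysis (gene-mode
and genome-figure-mode hit filters, the synteny block rule, the size-ratio
floor, and the fiber-architecture thresholds) with the defaults used
throughout: gene-product hits at 20 percent minimal similarity on 10 bp
minimum alignments, genome-figure hits at 30 percent on 100 bp, blocks of at
least five syntenic genes separated by at most four non-syntenic genes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from . import __version__
from .align import (
    AlignmentHit,
    ScoringScheme,
    all_vs_all_proteins,
    translated_genome_compare,
)
from .genome_io import GenomeRecord
from .synteny import ModuleCall, SyntenyBlock, SyntenyPair, call_modules, detect_blocks, pair_genes

__all__ = ["PipelineConfig", "CompareResult", "compare_genomes"]


@dataclass
class PipelineConfig:
    """All thresholds of the comparison pipeline, in documented units."""

    # gene-product (protein) hit filters
    min_similarity: float = 20.0
    min_aln_len_bp: int = 10
    min_score: int = 60
    metric: str = "positives"
    # translated-genome (figure) hit filters
    genome_min_similarity: float = 30.0
    genome_min_aln_len_bp: int = 100
    genome_min_score: int = 60
    # orthology and synteny rule
    size_ratio_min: float = 0.5
    min_genes: int = 5
    max_gap: int = 4
    # fiber architecture
    min_insertion: int = 30
    flank_window: int = 10
    flank_identity_min: float = 50.0
    min_unit: int = 50
    min_unit_similarity: float = 20.0
    # scoring
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    # run provenance
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.size_ratio_min <= 1):
            raise ValueError("size_ratio_min must lie in (0, 1]")
        if self.min_genes < 1 or self.max_gap < 0:
            raise ValueError("min_genes must be >= 1 and max_gap >= 0")
        if self.metric not in ("positives", "identity"):
            raise ValueError("metric must be 'positives' or 'identity'")

    @property
    def scheme(self) -> ScoringScheme:
        return ScoringScheme(self.matrix_name, self.gap_open, self.gap_extend)

    @property
    def min_aln_len_aa(self) -> int:
        return max(1, -(-self.min_aln_len_bp // 3))

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


@dataclass
class CompareResult:
    """All intermediate and final products of one genome comparison."""

    gene_hits: list[AlignmentHit]
    genome_hits: list[AlignmentHit]
    pairs: list[SyntenyPair]
    blocks: list[SyntenyBlock]
    modules: list[ModuleCall]
    config: PipelineConfig = field(default_factory=PipelineConfig)


def compare_genomes(
    A: GenomeRecord,
    B: GenomeRecord,
    config: PipelineConfig | None = None,
    with_genome_hits: bool = True,
) -> CompareResult:
    """Run the full comparison: gene-product hits, orthologous pairing,
    synteny blocks, module calls, and (optionally) translated-genome hits
    for the comparison figure."""
    config = config or PipelineConfig()
    scheme = config.scheme
    gene_hits = all_vs_all_proteins(
        A,
        B,
        scheme,
        min_similarity=config.min_similarity,
        min_aln_len=config.min_aln_len_aa,
        min_score=config.min_score,
        metric=config.metric,
    )
    pairs = pair_genes(gene_hits, size_ratio_min=config.size_ratio_min)
    blocks = detect_blocks(pairs, min_genes=config.min_genes, max_gap=config.max_gap)
    modules = call_modules(A, B, blocks)
    genome_hits: list[AlignmentHit] = []
    if with_genome_hits:
        genome_hits = translated_genome_compare(
            A,
            B,
            scheme,
            min_similarity=config.genome_min_similarity,
            min_aln_len_bp=config.genome_min_aln_len_bp,
            min_score=config.genome_min_score,
            metric=config.metric,
        )
    return CompareResult(
        gene_hits=gene_hits,
        genome_hits=genome_hits,
        pairs=pairs,
        blocks=blocks,
        modules=modules,
        config=config,
    )


def run_manifest(config: PipelineConfig, inputs: dict, seed: int | None = None) -> dict:
    """Provenance manifest accompanying every output directory."""
    return {
        "tool": "synmod",
        "version": __version__,
        "inputs": inputs,
        "seed": config.seed if seed is None else seed,
        "thresholds": config.to_dict(),
    }
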