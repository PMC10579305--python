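"""Reading, writing and basic statistics of annotated phage genomes.

A genome is represented as a :class:`GenomeRecord`: the nucleotide sequence
plus an ordered list of :class:`GeneFeature` gene annotations with their
protein products.  Internal coordinates are 0-based half-open on the forward
strand; GenBank's 1-based inclusive coordinates are converted on input (see
:func:`genbank_to_internal` / :func:`internal_to_genbank`).

Two input dialects are supported:

* single-record GenBank flat files with CDS features (translations taken
  verbatim from ``/translation`` qualifiers when present, otherwise computed
  with translation table 11), and
* a FASTA pair: one nucleotide FASTA plus a protein multi-FASTA whose headers
  carry ``locus|start|end|strand`` tokens (the dialect written by
  :func:`write_fasta_pair`).

ORF prediction and functional annotation are out of scope: the pipeline
consumes genomes that are already annotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "GeneFeature",
    "GenomeRecord",
    "read_genbank",
    "read_fasta_pair",
    "write_fasta_pair",
    "gc_content",
    "six_frame_translate",
    "reverse_complement",
    "genbank_to_internal",
    "internal_to_genbank",
]

_TABLE_11 = CodonTable.unambiguous_dna_by_id[11]
_START_CODONS_11 = set(_TABLE_11.start_codons)

# IUPAC nucleotide codes, including ambiguity codes, are accepted on input.
_DNA_ALPHABET = set("ACGTRYSWKMBDHVN")
_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


def _normalize_dna(seq: str) -> str:
    """Uppercase and map U->T; reject characters outside IUPAC DNA codes."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide character(s): {sorted(bad)}")
    return s


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """One annotated gene (CDS) on the forward-strand coordinate system.

    ``start``/``end`` are 0-based half-open nucleotide coordinates; ``rank``
    is the 0-based position of the gene in genome order.  ``protein`` is the
    gene product with any terminal stop stripped.
    """

    rank: int
    locus_id: str
    start: int
    end: int
    strand: str
    product_label: str = ""
    protein: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.locus_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.locus_id!r}: strand must be '+' or '-'")
        self.protein = self.protein.upper().rstrip("*")

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    def nucleotide_sequence(self, genome_sequence: str) -> str:
        """Coding-strand nucleotide sequence of this gene."""
        sub = genome_sequence[self.start : self.end]
        return reverse_complement(sub) if self.strand == "-" else sub


@dataclass
class GenomeRecord:
    """An annotated genome: sequence plus gene features sorted by start."""

    id: str
    sequence: str
    topology: str = "linear"
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = _normalize_dna(self.sequence)
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be 'linear' or 'circular', got {self.topology!r}")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for rank, f in enumerate(self.features):
            f.rank = rank
            if f.end > self.length:
                raise ValueError(
                    f"feature {f.locus_id!r} span [{f.start}, {f.end}) exceeds "
                    f"genome length {self.length}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_genes(self) -> int:
        return len(self.features)

    def proteins(self) -> list[str]:
        return [f.protein for f in self.features]


def genbank_to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """GenBank 1-based inclusive span -> internal 0-based half-open span."""
    return start_1based - 1, end_inclusive


def internal_to_genbank(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open span -> GenBank 1-based inclusive span."""
    return start + 1, end


def translate_cds(nt: str) -> str:
    """Translate a coding sequence with translation table 11.

    The trailing partial codon (if any) is dropped, a terminal stop is
    stripped, and an annotated alternative start codon (GTG, TTG, ...) is
    rendered as M, matching standard phage/bacterial annotation practice.
    """
    nt = _normalize_dna(nt)
    trimmed = nt[: len(nt) - len(nt) % 3]
    if not trimmed:
        return ""
    aa = str(Seq(trimmed).translate(table=11))
    aa = aa.rstrip("*") if aa.endswith("*") else aa
    if trimmed[:3] in _START_CODONS_11 and aa:
        aa = "M" + aa[1:]
    return aa


def read_genbank(path: str | Path) -> GenomeRecord:
    """Read a single-record GenBank flat file with CDS features.

    ``/translation`` qualifiers are used verbatim when present; otherwise the
    product is computed with translation table 11 (honouring ``codon_start``).
    CDS features with compound ``join()`` locations are rejected.
    """
    path = Path(path)
    with open(path) as handle:  # raises FileNotFoundError for missing input
        record = SeqIO.read(handle, "genbank")
    topology = record.annotations.get("topology", "linear")
    if topology not in ("linear", "circular"):
        topology = "linear"
    sequence = str(record.seq)
    features: list[GeneFeature] = []
    for i, feat in enumerate(record.features):
        if feat.type != "CDS":
            continue
        if len(feat.location.parts) > 1:
            raise ValueError(
                f"{path}: CDS feature #{i} has a compound join() location; "
                "compound locations are not supported"
            )
        start = int(feat.location.start)
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        quals = feat.qualifiers
        locus = (
            quals.get("locus_tag", [None])[0]
            or quals.get("gene", [None])[0]
            or quals.get("protein_id", [None])[0]
            or f"cds{len(features) + 1}"
        )
        product = quals.get("product", [""])[0]
        if "translation" in quals:
            protein = quals["translation"][0]
        else:
            nt = sequence[start:end]
            if strand == "-":
                nt = reverse_complement(nt)
            offset = int(quals.get("codon_start", ["1"])[0]) - 1
            protein = translate_cds(nt[offset:])
        features.append(
            GeneFeature(
                rank=0,
                locus_id=locus,
                start=start,
                end=end,
                strand=strand,
                product_label=product,
                protein=protein,
            )
        )
    if not features:
        raise ValueError(f"no genes: {path} contains no CDS features")
    return GenomeRecord(
        id=record.id or record.name or path.stem,
        sequence=sequence,
        topology=topology,
        features=features,
    )


def _parse_pair_header(header: str) -> tuple[str, int, int, str]:
    tokens = header.split("|")
    if len(tokens) != 4:
        raise ValueError(
            f"protein header {header!r} is not of the form 'locus|start|end|strand'"
        )
    locus, start_s, end_s, strand = tokens
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(
            f"protein header {header!r} has non-integer coordinates"
        ) from exc
    if strand not in ("+", "-"):
        raise ValueError(f"protein header {header!r} has invalid strand {strand!r}")
    return locus, start, end, strand


def read_fasta_pair(genome_path: str | Path, proteins_path: str | Path) -> GenomeRecord:
    """Assemble a :class:`GenomeRecord` from a nucleotide FASTA plus a protein
    multi-FASTA with ``locus|start|end|strand`` headers."""
    genome_path, proteins_path = Path(genome_path), Path(proteins_path)
    with open(genome_path) as handle:
        genome = SeqIO.read(handle, "fasta")
    sequence = str(genome.seq)
    features = []
    with open(proteins_path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            locus, start, end, strand = _parse_pair_header(rec.id)
            if start < 0 or end > len(sequence):
                raise ValueError(
                    f"protein header {rec.id!r}: span [{start}, {end}) outside "
                    f"genome of length {len(sequence)}"
                )
            product = rec.description[len(rec.id) :].strip()
            features.append(
                GeneFeature(
                    rank=0,
                    locus_id=locus,
                    start=start,
                    end=end,
                    strand=strand,
                    product_label=product,
                    protein=str(rec.seq),
                )
            )
    if not features:
        raise ValueError(f"no genes: {proteins_path} contains no protein records")
    return GenomeRecord(id=genome.id, sequence=sequence, features=features)


def write_fasta_pair(
    record: GenomeRecord, genome_path: str | Path, proteins_path: str | Path
) -> None:
    """Write the FASTA-pair dialect read by :func:`read_fasta_pair`."""
    with open(genome_path, "w") as out:
        out.write(f">{record.id}\n")
        for i in range(0, record.length, 70):
            out.write(record.sequence[i : i + 70] + "\n")
    with open(proteins_path, "w") as out:
        for f in record.features:
            header = f"{f.locus_id}|{f.start}|{f.end}|{f.strand}"
            if f.product_label:
                header += f" {f.product_label}"
            out.write(f">{header}\n{f.protein}\n")


def gc_content(record: GenomeRecord | str) -> float:
    """Percent G+C of the whole genome (0-100).

    Ambiguous bases are excluded from the numerator but counted in the
    denominator, so heavily ambiguous sequences report a lower G+C.
    """
    seq = record.sequence if isinstance(record, GenomeRecord) else _normalize_dna(record)
    if not seq:
        raise ValueError("gc_content of an empty sequence is undefined")
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / len(seq)


def six_frame_translate(dna: str) -> tuple[str, str, str, str, str, str]:
    """Translate all six reading frames (+1, +2, +3, -1, -2, -3).

    Frame +k starts at offset k-1 on the forward strand; frame -k starts at
    offset k-1 on the reverse complement.  Each frame drops its trailing
    partial codon; stop codons are rendered as ``*`` and retained (translated
    alignments never cross them).
    """
    dna = _normalize_dna(dna)
    if len(dna) < 3:
        raise ValueError(f"sequence of length {len(dna)} is too short to translate")
    rc = reverse_complement(dna)
    frames = []
    for template in (dna, rc):
        for offset in range(3):
            sub = template[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(Seq(sub).translate(table=11)) if sub else "")
    return tuple(frames)  # type: ignore[return-value]
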