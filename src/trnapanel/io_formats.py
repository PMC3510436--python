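"""Readers, writers and parsers for the external formats the tool consumes.

Covers FASTA sequence sets, aligned FASTA / Clustal alignments, tab-separated
gene annotation tables, ``m.<pos><ref>><alt>`` variant strings, and the
bundled consensus-panel configuration. All genomic coordinates are 1-based
inclusive, matching rCRS "m." numbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .msa import Alignment

__all__ = [
    "SequenceRecord",
    "VariantSpec",
    "GeneAnnotation",
    "PanelEntry",
    "PanelConfig",
    "ParseError",
    "parse_variant",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "load_panel_config",
    "extract_gene",
    "read_gene_table",
]

_VALID_ALPHABET = frozenset("ACGTN")
_TRNA_LENGTH_RANGE = (55, 100)


class ParseError(ValueError):
    """Raised for malformed user input (variant strings, tables, configs)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence; the carrier for all sequence data.

    ``species`` defaults to the record id when no explicit species is known.
    Sequences are normalised on construction: uppercase, U -> T.
    """

    id: str
    sequence: str
    species: str = ""
    description: str = ""

    def __post_init__(self):
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not self.species:
            object.__setattr__(self, "species", self.id)
        bad = set(seq) - _VALID_ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(alphabet is A,C,G,T,N after normalisation)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantSpec:
    """A point variant in rCRS coordinates, e.g. m.3243A>G."""

    position: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.position < 1:
            raise ParseError(f"variant position must be >= 1, got {self.position}")
        for label, base in (("ref", self.ref), ("alt", self.alt)):
            if base not in "ACGT" or len(base) != 1:
                raise ParseError(f"variant {label} base {base!r} not one of A,C,G,T")
        if self.ref == self.alt:
            raise ParseError(f"variant ref and alt are both {self.ref!r}")

    def __str__(self) -> str:
        return f"m.{self.position}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class GeneAnnotation:
    """Coordinates of one gene on one species' genome (1-based inclusive)."""

    species: str
    gene_name: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.strand not in "+-":
            raise ParseError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ParseError(
                f"gene {self.gene_name}: need 1 <= start <= end, "
                f"got start={self.start}, end={self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PanelEntry:
    species: str
    taxonomic_group: str  # primate | mammal | vertebrate | invertebrate
    accession: str
    is_reference: bool = False


@dataclass
class PanelConfig:
    """The ordered consensus panel of species used to judge conservation."""

    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self):
        names = [e.species for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ParseError(f"duplicate species in panel config: {dupes}")
        refs = [e for e in self.entries if e.is_reference]
        if len(refs) != 1:
            raise ParseError(
                f"panel config must flag exactly one reference species, found {len(refs)}"
            )

    @property
    def reference(self) -> PanelEntry:
        return next(e for e in self.entries if e.is_reference)

    @property
    def species(self) -> list[str]:
        return [e.species for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


_VARIANT_RE = re.compile(r"^m\.(\d+)([A-Za-z])>([A-Za-z])$")


def parse_variant(text: str) -> VariantSpec:
    """Parse ``m.<pos><ref>><alt>`` notation (case-insensitive bases).

    >>> parse_variant("m.3243A>G")
    VariantSpec(position=3243, ref='A', alt='G')
    """
    if not text:
        raise ParseError("empty variant string")
    if not text.startswith("m."):
        raise ParseError(f"variant {text!r}: missing 'm.' prefix")
    m = _VARIANT_RE.match(text.strip())
    if m is None:
        raise ParseError(
            f"variant {text!r}: expected m.<position><ref>><alt>, e.g. m.3243A>G"
        )
    pos, ref, alt = int(m.group(1)), m.group(2).upper(), m.group(3).upper()
    return VariantSpec(position=pos, ref=ref, alt=alt)


def _species_from_description(rec_id: str, description: str) -> str:
    m = re.search(r"\[species=([^\]]+)\]", description)
    if m:
        return m.group(1)
    # binomial names are written with underscores in FASTA ids
    return rec_id.replace("_", " ")


def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read a FASTA file into normalised records (order preserved).

    The species of each record is taken from a ``[species=...]`` tag in the
    description if present, else from the id with underscores read as
    spaces (the convention ``write_fasta`` uses for binomial names).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                sequence=str(rec.seq),
                species=_species_from_description(rec.id, rec.description),
                description=rec.description,
            )
        )
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"{path}: duplicate record ids {dupes}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path]) -> None:
    """Write records as FASTA wrapped at 70 columns."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id.replace(" ", "_"),
                  description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(seqrecs)


_DIALECTS = {"aligned_fasta": "fasta", "clustal": "clustal"}


def read_alignment(path: Union[str, Path], dialect: str = "aligned_fasta") -> Alignment:
    """Read an alignment (aligned FASTA or Clustal) into an Alignment."""
    if dialect not in _DIALECTS:
        raise ParseError(f"unknown alignment dialect {dialect!r}; use {sorted(_DIALECTS)}")
    try:
        msa = AlignIO.read(str(path), _DIALECTS[dialect])
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    rows = [str(rec.seq).upper().replace("U", "T") for rec in msa]
    ids = [rec.id for rec in msa]
    return Alignment(row_ids=ids, rows=rows)


def write_alignment(alignment: Alignment, path: Union[str, Path],
                    dialect: str = "aligned_fasta") -> None:
    if dialect not in _DIALECTS:
        raise ParseError(f"unknown alignment dialect {dialect!r}; use {sorted(_DIALECTS)}")
    msa = AlignIO.MultipleSeqAlignment(
        SeqRecord(Seq(row), id=rid, description="")
        for rid, row in zip(alignment.row_ids, alignment.rows)
    )
    AlignIO.write(msa, str(path), _DIALECTS[dialect])


_PANEL_GROUPS = frozenset({"primate", "mammal", "vertebrate", "invertebrate"})


def load_panel_config(path: Optional[Union[str, Path]] = None) -> PanelConfig:
    """Load a panel configuration; the bundled default is the 10-species panel."""
    if path is None:
        text = resources.files("trnapanel.data").joinpath("panel.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "panel" not in doc:
        raise ParseError("panel config must contain a top-level 'panel' list")
    entries = []
    for row in doc["panel"]:
        group = row.get("group", "")
        if group not in _PANEL_GROUPS:
            raise ParseError(
                f"panel entry {row.get('species')!r}: group {group!r} "
                f"not one of {sorted(_PANEL_GROUPS)}"
            )
        entries.append(
            PanelEntry(
                species=row["species"],
                taxonomic_group=group,
                accession=str(row.get("accession", "")),
                is_reference=bool(row.get("reference", False)),
            )
        )
    config = PanelConfig(entries=entries)
    if not any(e.is_reference and "sapiens" in e.species.lower() for e in config.entries):
        raise ParseError("panel config must include Homo sapiens as the reference species")
    return config


def extract_gene(genome: SequenceRecord, ann: GeneAnnotation,
                 warn: Optional[list] = None) -> SequenceRecord:
    """Extract a gene's sense-strand sequence from a genome record.

    For strand '-' the reverse complement of the genomic slice is returned, so
    the result always reads 5'->3' in the tRNA-coding orientation.
    """
    if ann.end > len(genome):
        raise ParseError(
            f"gene {ann.gene_name}: coordinates {ann.start}-{ann.end} exceed "
            f"genome length {len(genome)}"
        )
    lo, hi = _TRNA_LENGTH_RANGE
    if warn is not None and not (lo <= ann.length <= hi):
        warn.append(
            f"gene {ann.gene_name}: length {ann.length} outside the usual "
            f"tRNA range {lo}-{hi} nt"
        )
    sub = genome.sequence[ann.start - 1: ann.end]
    if ann.strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return SequenceRecord(
        id=f"{genome.id}|{ann.gene_name}",
        sequence=sub,
        species=genome.species,
        description=f"{ann.gene_name} {ann.start}-{ann.end}({ann.strand})",
    )


def read_gene_table(path: Union[str, Path]) -> list[GeneAnnotation]:
    """Read a tab-separated gene table: species, gene, start, end, strand."""
    anns = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty gene table")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {len(parts)}"
                )
            species, gene, start, end, strand = parts
            try:
                anns.append(GeneAnnotation(species, gene, int(start), int(end), strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not anns:
        raise ParseError(f"{path}: no gene rows found")
    return anns
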