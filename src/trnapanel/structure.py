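"""Cloverleaf secondary structure: stem/loop domains and base-pair typing.

Structure annotations are *inputs*, not inferences: per-position domain
labels and pairing partners are read from tab-separated tables
(``position  domain  partner``, "." meaning unpaired). The package bundles
curated tables for the human mt-tRNA genes the worked examples use, and the
synthetic-data generator emits its own consistent annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Union

__all__ = [
    "Domain",
    "STEM_DOMAINS",
    "PairClass",
    "StructureAnnotation",
    "classify_position",
    "pair_class",
    "validate_structure",
    "read_structure_table",
    "write_structure_table",
    "load_bundled_structure",
]


class Domain(str, Enum):
    ACCEPTOR_STEM = "acceptor_stem"
    D_STEM = "d_stem"
    D_LOOP = "d_loop"
    ANTICODON_STEM = "anticodon_stem"
    ANTICODON_LOOP = "anticodon_loop"
    VARIABLE_REGION = "variable_region"
    T_STEM = "t_stem"
    T_LOOP = "t_loop"
    OTHER = "other"


STEM_DOMAINS = frozenset(
    {Domain.ACCEPTOR_STEM, Domain.D_STEM, Domain.ANTICODON_STEM, Domain.T_STEM}
)


class PairClass(str, Enum):
    WATSON_CRICK = "watson_crick"
    WOBBLE = "wobble"
    OTHER = "other"


_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "T"), ("T", "G")}


@dataclass
class StructureAnnotation:
    """Per-position domain labels and pairing partners for one tRNA gene.

    Positions are 1-based offsets into the gene's sense-strand sequence.
    """

    gene_name: str
    domains: dict[int, Domain] = field(default_factory=dict)
    partners: dict[int, Optional[int]] = field(default_factory=dict)

    def __post_init__(self):
        violations = validate_structure(self)
        if violations:
            raise ValueError(
                f"inconsistent structure for {self.gene_name}: "
                + "; ".join(violations)
            )

    @property
    def length(self) -> int:
        return max(self.domains) if self.domains else 0

    @property
    def positions(self) -> list[int]:
        return sorted(self.domains)

    def domain(self, pos: int) -> Domain:
        if pos not in self.domains:
            raise IndexError(
                f"position {pos} outside structure annotation for {self.gene_name} "
                f"(1..{self.length})"
            )
        return self.domains[pos]

    def partner(self, pos: int) -> Optional[int]:
        if pos not in self.domains:
            raise IndexError(
                f"position {pos} outside structure annotation for {self.gene_name}"
            )
        return self.partners.get(pos)

    def is_stem(self, pos: int) -> bool:
        return self.domain(pos) in STEM_DOMAINS

    def stem_positions(self) -> list[int]:
        return [p for p in self.positions if self.domains[p] in STEM_DOMAINS]

    def loop_positions(self) -> list[int]:
        return [p for p in self.positions if self.domains[p] not in STEM_DOMAINS]


def classify_position(ann: StructureAnnotation, pos: int) -> tuple[Domain, bool]:
    """Domain label and stem flag for a position."""
    dom = ann.domain(pos)
    return dom, dom in STEM_DOMAINS


def pair_class(x: str, y: str, flagged: Optional[list] = None) -> PairClass:
    """Classify a base pair: Watson-Crick, wobble (G.T), or other.

    N or gap characters classify as OTHER; if ``flagged`` is given, a note is
    appended so callers can distinguish ambiguity from a genuine mismatch.
    """
    x, y = x.upper(), y.upper()
    if x not in "ACGT" or y not in "ACGT":
        if flagged is not None:
            flagged.append(f"non-base pair ({x},{y}) classified as other")
        return PairClass.OTHER
    if (x, y) in _WC_PAIRS:
        return PairClass.WATSON_CRICK
    if (x, y) in _WOBBLE_PAIRS:
        return PairClass.WOBBLE
    return PairClass.OTHER


def validate_structure(ann: StructureAnnotation) -> list[str]:
    """Check all annotation invariants; returns violations (empty iff valid)."""
    out: list[str] = []
    positions = set(ann.domains)
    for pos in sorted(positions):
        dom = ann.domains[pos]
        partner = ann.partners.get(pos)
        if partner is not None:
            if partner == pos:
                out.append(f"position {pos} pairs with itself")
                continue
            if partner not in positions:
                out.append(f"position {pos} pairs with {partner}, which is unannotated")
                continue
            back = ann.partners.get(partner)
            if back != pos:
                out.append(
                    f"asymmetric pairing: partner({pos})={partner} "
                    f"but partner({partner})={back}"
                )
        if dom in STEM_DOMAINS and partner is None:
            out.append(f"stem position {pos} ({dom.value}) has no partner")
        if dom not in STEM_DOMAINS and partner is not None:
            out.append(f"non-stem position {pos} ({dom.value}) has partner {partner}")
    if positions and sorted(positions) != list(range(1, max(positions) + 1)):
        out.append("annotated positions are not contiguous from 1")
    return out


def read_structure_table(path: Union[str, Path], gene_name: str = "") -> StructureAnnotation:
    """Read a ``position  domain  partner`` tab-separated table."""
    domains: dict[int, Domain] = {}
    partners: dict[int, Optional[int]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("position\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            pos_s, dom_s, partner_s = parts
            pos = int(pos_s)
            try:
                domains[pos] = Domain(dom_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: unknown domain {dom_s!r}")
            partners[pos] = None if partner_s == "." else int(partner_s)
    if not domains:
        raise ValueError(f"{path}: no structure rows found")
    return StructureAnnotation(
        gene_name=gene_name or path.stem, domains=domains, partners=partners
    )


def write_structure_table(ann: StructureAnnotation, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("position\tdomain\tpartner\n")
        for pos in ann.positions:
            partner = ann.partners.get(pos)
            fh.write(f"{pos}\t{ann.domains[pos].value}\t{partner if partner else '.'}\n")


def load_bundled_structure(gene_name: str) -> StructureAnnotation:
    """Load one of the curated human mt-tRNA structure tables shipped with
    the package (e.g. "MT-TL1", "MT-TI", "MT-TK")."""
    res = resources.files("trnapanel.data").joinpath(f"structures/{gene_name}.tsv")
    if not res.is_file():
        raise FileNotFoundError(
            f"no bundled structure table for {gene_name!r}"
        )
    with resources.as_file(res) as p:
        return read_structure_table(p, gene_name=gene_name)
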