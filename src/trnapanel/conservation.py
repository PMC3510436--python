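"""Conservation quantities: cross-species column profiles, intra-species
summaries, and stem/loop variation tallies.

The central quantity is the per-column change count: at the alignment column
holding a human variant position, how many of the other panel species carry
a residue different from the human reference allele. Gap policy is explicit
because the underlying convention (is an indel evidence of non-conservation?)
is a genuine choice: by default a gap in a non-reference row counts as a
change (``gap_is_change=True``).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .io_formats import GeneAnnotation, SequenceRecord, VariantSpec
from .msa import GAP, Alignment, AlignmentParams, star_msa
from .structure import Domain, PairClass, StructureAnnotation, pair_class

__all__ = [
    "ColumnProfile",
    "IntraSpeciesSummary",
    "VariationTally",
    "column_profile",
    "variant_profile",
    "pct_conserved_columns",
    "largest_identical_group",
    "reference_is_major",
    "tally_stem_loop_variation",
    "expected_tally",
    "sample_sequences",
    "DEFAULT_SAMPLE_CAP",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Sampling cap on non-reference sequences per species (34 + the reference).
DEFAULT_SAMPLE_CAP = 34


@dataclass(frozen=True)
class ColumnProfile:
    """Residues by row at one alignment column, and the change count
    relative to the reference row's residue."""

    column: int
    residue_by_species: Mapping[str, str]
    reference_species: str
    reference_residue: str
    n_changes: int
    n_gaps: int
    reference_gapped: bool = False
    gap_is_change: bool = True

    def __post_init__(self):
        n_other = len(self.residue_by_species) - 1
        if not (0 <= self.n_changes <= max(n_other, 0)):
            raise ValueError(
                f"n_changes={self.n_changes} outside 0..{n_other}"
            )


@dataclass(frozen=True)
class IntraSpeciesSummary:
    """Per species x gene intra-species conservation metrics."""

    species: str
    gene_name: str
    n_sequences: int
    pct_conserved_columns: float
    pct_largest_identical_group: float
    reference_is_major: bool

    def __post_init__(self):
        for v in (self.pct_conserved_columns, self.pct_largest_identical_group):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"percentage {v} outside 0..100")
        if self.n_sequences > 0 and (
            self.pct_largest_identical_group < 100.0 / self.n_sequences - 1e-9
        ):
            raise ValueError("largest identical group below the 100/n lower bound")


@dataclass(frozen=True)
class VariationTally:
    """Counts of varying (polymorphic) positions split by stem vs loop."""

    stem_variants: int
    loop_variants: int
    n_stem_positions: int
    n_loop_positions: int

    def __post_init__(self):
        if min(self.stem_variants, self.loop_variants,
               self.n_stem_positions, self.n_loop_positions) < 0:
            raise ValueError("tally counts must be non-negative")
        if self.stem_variants > self.n_stem_positions:
            raise ValueError("more stem variants than stem positions")
        if self.loop_variants > self.n_loop_positions:
            raise ValueError("more loop variants than loop positions")

    @property
    def total_variants(self) -> int:
        return self.stem_variants + self.loop_variants


def column_profile(alignment: Alignment, column: int, reference_row: str,
                   gap_is_change: bool = True) -> ColumnProfile:
    """Profile one column: residues per row, change count vs the reference.

    A gap in a non-reference row counts as a change under the default policy;
    with ``gap_is_change=False`` gapped rows are ignored. A gap in the
    reference row flags the profile as reference-gapped (no residue to
    compare against; changes are then counted against the gap symbol).
    """
    if not alignment.has_row(reference_row):
        raise KeyError(
            f"reference row {reference_row!r} not in alignment rows {alignment.row_ids}"
        )
    residues = alignment.column(column)
    ref_res = residues[reference_row]
    n_changes = 0
    n_gaps = 0
    for rid, res in residues.items():
        if res == GAP:
            n_gaps += 1
        if rid == reference_row:
            continue
        if res == GAP:
            if gap_is_change and ref_res != GAP:
                n_changes += 1
        elif res != ref_res:
            n_changes += 1
    return ColumnProfile(
        column=column,
        residue_by_species=dict(residues),
        reference_species=reference_row,
        reference_residue=ref_res,
        n_changes=n_changes,
        n_gaps=n_gaps,
        reference_gapped=(ref_res == GAP),
        gap_is_change=gap_is_change,
    )


def project_variant(variant: VariantSpec, ann: GeneAnnotation) -> tuple[int, str, str]:
    """Map an rCRS (heavy-strand) variant onto a gene's sense strand.

    Returns (offset, ref, alt) where offset is a 1-based position in the
    gene's 5'->3' sense sequence. For '-'-strand genes the bases are
    complemented, since "m." notation states alleles on the heavy strand.
    """
    if not (ann.start <= variant.position <= ann.end):
        raise ValueError(
            f"variant position {variant.position} outside gene "
            f"{ann.gene_name} ({ann.start}-{ann.end})"
        )
    if ann.strand == "+":
        return variant.position - ann.start + 1, variant.ref, variant.alt
    offset = ann.end - variant.position + 1
    return (offset,
            variant.ref.translate(_COMPLEMENT),
            variant.alt.translate(_COMPLEMENT))


def variant_profile(
    panel_genes: Sequence[SequenceRecord],
    gene_ann: GeneAnnotation,
    structure: StructureAnnotation,
    variant: VariantSpec,
    alignment: Optional[Alignment] = None,
    align_params: AlignmentParams = AlignmentParams(),
    gap_is_change: bool = True,
) -> tuple[ColumnProfile, Domain, bool, Optional[dict[str, PairClass]]]:
    """End-to-end profile of a variant position across the panel.

    The reference gene is the panel record whose species matches
    ``gene_ann.species``. The variant is projected onto the gene's sense
    strand, checked against the reference sequence, located in the alignment
    (``alignment`` if supplied, else a center-star alignment with the
    reference as center), and profiled. For stem positions, each species'
    base pair at (position, partner) within its own row is classified.
    """
    ref_recs = [r for r in panel_genes if r.species == gene_ann.species
                or r.id == gene_ann.species]
    if not ref_recs:
        raise ValueError(
            f"no panel record for reference species {gene_ann.species!r}"
        )
    ref_rec = ref_recs[0]
    offset, ref_base, _alt = project_variant(variant, gene_ann)
    if len(ref_rec.sequence) != gene_ann.length:
        raise ValueError(
            f"reference gene length {len(ref_rec.sequence)} does not match "
            f"annotation span {gene_ann.length}"
        )
    observed = ref_rec.sequence[offset - 1]
    if observed != ref_base:
        raise ValueError(
            f"variant {variant} expects {ref_base!r} at gene offset {offset} "
            f"of {gene_ann.gene_name}, but the reference sequence has {observed!r}"
        )
    if structure.length != gene_ann.length:
        raise ValueError(
            f"structure annotation length {structure.length} does not match "
            f"gene span {gene_ann.length}"
        )
    if alignment is None:
        alignment = star_msa(panel_genes, params=align_params, center=ref_rec.id)
    elif not alignment.has_row(ref_rec.id):
        raise ValueError(f"supplied alignment lacks reference row {ref_rec.id!r}")

    col = alignment.offset_to_column(ref_rec.id, offset)
    profile = column_profile(alignment, col, ref_rec.id, gap_is_change=gap_is_change)
    domain = structure.domain(offset)
    is_stem = structure.is_stem(offset)
    pair_by_species: Optional[dict[str, PairClass]] = None
    if is_stem:
        partner_offset = structure.partner(offset)
        partner_col = alignment.offset_to_column(ref_rec.id, partner_offset)
        pos_col = alignment.column(col)
        par_col = alignment.column(partner_col)
        pair_by_species = {
            rid: pair_class(pos_col[rid], par_col[rid]) for rid in alignment.row_ids
        }
    return profile, domain, is_stem, pair_by_species


def pct_conserved_columns(alignment: Alignment) -> float:
    """Percent of alignment columns that are monomorphic (gap = fifth state)."""
    if alignment.n_rows < 2:
        raise ValueError("need at least 2 rows to assess conservation")
    mono = sum(
        1 for c in range(1, alignment.n_columns + 1)
        if len(set(alignment.column(c).values())) == 1
    )
    return 100.0 * mono / alignment.n_columns


def largest_identical_group(records: Sequence[SequenceRecord]) -> float:
    """Percent of sequences in the largest set of exactly identical sequences."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    counts: dict[str, int] = {}
    for r in records:
        counts[r.sequence] = counts.get(r.sequence, 0) + 1
    return 100.0 * max(counts.values()) / len(records)


def reference_is_major(alignment: Alignment, reference_row: str) -> bool:
    """True iff at every polymorphic column the reference residue is modal."""
    if not alignment.has_row(reference_row):
        raise KeyError(f"reference row {reference_row!r} not in alignment")
    for c in range(1, alignment.n_columns + 1):
        col = alignment.column(c)
        values = list(col.values())
        if len(set(values)) == 1:
            continue
        ref_res = col[reference_row]
        top = max(values.count(v) for v in set(values))
        if values.count(ref_res) < top:
            return False
    return True


def reference_allele_fractions(alignment: Alignment, reference_row: str
                               ) -> dict[int, float]:
    """Per polymorphic column: fraction of rows carrying the reference residue."""
    out = {}
    for c in range(1, alignment.n_columns + 1):
        col = alignment.column(c)
        values = list(col.values())
        if len(set(values)) > 1:
            out[c] = values.count(col[reference_row]) / len(values)
    return out


def tally_stem_loop_variation(
    per_gene_alignments: Mapping[str, Alignment],
    structures: Mapping[str, StructureAnnotation],
    reference_rows: Optional[Mapping[str, str]] = None,
) -> VariationTally:
    """Count polymorphic positions per domain class across many genes.

    Positions are reference-row gene offsets (first alignment row by default);
    a position is "varying" if its alignment column is polymorphic (gaps count
    as a state). Position totals accumulate over all genes.
    """
    stem_var = loop_var = n_stem = n_loop = 0
    for gene, aln in per_gene_alignments.items():
        if gene not in structures:
            raise KeyError(f"no structure annotation for gene {gene!r}")
        ann = structures[gene]
        ref_row = reference_rows[gene] if reference_rows else aln.row_ids[0]
        gene_len = len(aln.ungapped(ref_row))
        if ann.length != gene_len:
            raise ValueError(
                f"gene {gene!r}: structure length {ann.length} does not match "
                f"reference row length {gene_len}"
            )
        n_stem += len(ann.stem_positions())
        n_loop += len(ann.loop_positions())
        for pos in ann.positions:
            col = aln.offset_to_column(ref_row, pos)
            if len(set(aln.column(col).values())) > 1:
                if ann.is_stem(pos):
                    stem_var += 1
                else:
                    loop_var += 1
    return VariationTally(
        stem_variants=stem_var,
        loop_variants=loop_var,
        n_stem_positions=n_stem,
        n_loop_positions=n_loop,
    )


def expected_tally(total_variants: int, n_stem_positions: int,
                   n_loop_positions: int) -> tuple[float, float]:
    """Expected stem/loop variant counts if variation were proportional to
    the number of positions in each class. Returns unrounded values;
    e_stem + e_loop == total_variants exactly."""
    n_total = n_stem_positions + n_loop_positions
    if n_total <= 0 or min(n_stem_positions, n_loop_positions) < 0:
        raise ValueError("position counts must be positive")
    e_stem = total_variants * n_stem_positions / n_total
    return e_stem, total_variants - e_stem


def sample_sequences(records: Sequence[SequenceRecord], cap: int, seed: int,
                     reference_id: Optional[str] = None) -> list[SequenceRecord]:
    """Seeded subsample: the reference plus at most ``cap`` other sequences.

    The reference (by id; default the first record) is always retained, so a
    set larger than the cap yields cap + 1 records. Sampling is uniform
    without replacement and deterministic for a given seed.
    """
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    records = list(records)
    if not records:
        return []
    if reference_id is None:
        reference_id = records[0].id
    ref = [r for r in records if r.id == reference_id]
    if not ref:
        raise KeyError(f"reference id {reference_id!r} not among records")
    others = [r for r in records if r.id != reference_id]
    if len(others) > cap:
        rng = random.Random(seed)
        others = rng.sample(others, cap)
    return ref[:1] + others
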