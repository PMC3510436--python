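"""Global alignment of short mt-tRNA gene sequences.

The sequences aligned here are ~65-75 nt homologues, so a simple global
aligner with linear gap costs and a center-star merge is sufficient.
Pre-computed alignments (e.g. ClustalW2 output) are accepted everywhere an
Alignment is, via :mod:`trnapanel.io_formats`.

Tie-breaking in the pairwise traceback is fixed (diagonal, then up, then
left) so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = ["AlignmentParams", "Alignment", "nw_align", "star_msa"]

GAP = "-"
_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring for global pairwise alignment (linear gap penalty)."""

    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0

    def __post_init__(self):
        if self.match_score <= self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")
        if self.gap_score >= 0:
            raise ValueError("gap_score must be negative")


class Alignment:
    """Gapped rows over common columns, with offset<->column maps.

    Offsets are 1-based residue indices within a row's ungapped sequence;
    columns are 1-based alignment column indices.
    """

    def __init__(self, row_ids: Sequence[str], rows: Sequence[str]):
        if len(row_ids) != len(rows):
            raise ValueError("row_ids and rows differ in length")
        if not rows:
            raise ValueError("alignment must have at least one row")
        if len(set(row_ids)) != len(row_ids):
            raise ValueError("duplicate row ids in alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(
                f"ragged alignment rows: lengths {sorted(len(r) for r in rows)}"
            )
        ncol = lengths.pop()
        for c in range(ncol):
            if all(r[c] == GAP for r in rows):
                raise ValueError(f"all-gap column at position {c + 1}")
        self.row_ids = list(row_ids)
        self.rows = [r.upper() for r in rows]
        self._index = {rid: i for i, rid in enumerate(self.row_ids)}
        # per-row: list of columns (1-based) holding residue k (0-based index k-1)
        self._res_cols = [
            [c + 1 for c, ch in enumerate(row) if ch != GAP] for row in self.rows
        ]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, row_id: str) -> str:
        return self.rows[self._row_index(row_id)]

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    def has_row(self, row_id: str) -> bool:
        return row_id in self._index

    def _row_index(self, row_id: str) -> int:
        try:
            return self._index[row_id]
        except KeyError:
            raise KeyError(f"no alignment row {row_id!r}; rows are {self.row_ids}")

    def offset_to_column(self, row_id: str, offset: int) -> int:
        """Column (1-based) holding residue ``offset`` (1-based) of a row."""
        cols = self._res_cols[self._row_index(row_id)]
        if not (1 <= offset <= len(cols)):
            raise IndexError(
                f"offset {offset} out of range 1..{len(cols)} for row {row_id!r}"
            )
        return cols[offset - 1]

    def column_to_offset(self, row_id: str, column: int) -> Optional[int]:
        """Residue offset at a column, or None if the row is gapped there."""
        row = self.row(row_id)
        if not (1 <= column <= self.n_columns):
            raise IndexError(f"column {column} out of range 1..{self.n_columns}")
        if row[column - 1] == GAP:
            return None
        return column - row[:column].count(GAP)

    def column(self, column: int) -> dict[str, str]:
        """Residue (or '-') per row id at a column."""
        if not (1 <= column <= self.n_columns):
            raise IndexError(f"column {column} out of range 1..{self.n_columns}")
        return {rid: row[column - 1] for rid, row in zip(self.row_ids, self.rows)}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.row_ids == other.row_ids
            and self.rows == other.rows
        )

    def __repr__(self) -> str:
        return f"Alignment({self.n_rows} rows x {self.n_columns} columns)"


def _check_alphabet(seq: str, label: str) -> None:
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"{label}: invalid characters {sorted(bad)}")


def nw_align(a: str, b: str, params: AlignmentParams = AlignmentParams()
             ) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences (Needleman-Wunsch).

    Returns (gapped_a, gapped_b, score). Traceback ties prefer the diagonal
    move, then the up move (residue of ``a`` against a gap), then left.
    """
    a, b = a.upper(), b.upper()
    _check_alphabet(a, "first sequence")
    _check_alphabet(b, "second sequence")
    n, m = len(a), len(b)
    g = params.gap_score
    # score matrix, row-major over (i, j) = consumed prefix lengths
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * g
    for j in range(1, m + 1):
        score[0][j] = j * g
    for i in range(1, n + 1):
        ai = a[i - 1]
        row, prev = score[i], score[i - 1]
        for j in range(1, m + 1):
            s = params.match_score if ai == b[j - 1] else params.mismatch_score
            row[j] = max(prev[j - 1] + s, prev[j] + g, row[j - 1] + g)
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = params.match_score if a[i - 1] == b[j - 1] else params.mismatch_score
            if score[i][j] == score[i - 1][j - 1] + s:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and score[i][j] == score[i - 1][j] + g:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
            continue
        out_a.append(GAP)
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score[n][m]


def star_msa(records, params: AlignmentParams = AlignmentParams(),
             center: Optional[str] = None) -> Alignment:
    """Center-star multiple alignment.

    The center defaults to the first record whose id or species matches
    ``center`` if given; otherwise the longest sequence. Every other record
    is aligned to the center pairwise and the pairwise alignments are merged
    under "once a gap, always a gap".
    """
    records = list(records)
    if not records:
        raise ValueError("star_msa requires at least one record")
    ids = [r.id for r in records]
    if center is not None:
        try:
            c_idx = ids.index(center)
        except ValueError:
            raise ValueError(f"center row {center!r} not among record ids {ids}")
    else:
        c_idx = max(range(len(records)), key=lambda i: (len(records[i].sequence), -i))
    center_seq = records[c_idx].sequence

    # master center row as a list of characters; parallel list of rows built so far
    master_center: list[str] = list(center_seq)
    aligned: dict[int, list[str]] = {}

    for idx, rec in enumerate(records):
        if idx == c_idx:
            continue
        gc, gr, _ = nw_align(center_seq, rec.sequence, params)
        # project gr onto the master coordinate system
        mi = 0  # index into master_center
        gi = 0  # index into gc/gr
        new_row: list[str] = []
        while gi < len(gc) or mi < len(master_center):
            master_is_res = mi < len(master_center) and master_center[mi] != GAP
            pair_is_res = gi < len(gc) and gc[gi] != GAP
            if mi < len(master_center) and not master_is_res:
                # master has a gap column introduced by an earlier merge
                new_row.append(GAP)
                mi += 1
            elif gi < len(gc) and not pair_is_res:
                # this pairwise alignment inserts a new gap column into the center
                master_center.insert(mi, GAP)
                for row in aligned.values():
                    row.insert(mi, GAP)
                new_row.append(gr[gi])
                mi += 1
                gi += 1
            else:
                # both are residue columns of the center: they correspond
                new_row.append(gr[gi])
                mi += 1
                gi += 1
        aligned[idx] = new_row

    ncol = len(master_center)
    rows = []
    for idx in range(len(records)):
        if idx == c_idx:
            rows.append("".join(master_center))
        else:
            row = aligned[idx]
            row.extend(GAP * (ncol - len(row)))
            rows.append("".join(row))
    return Alignment(row_ids=ids, rows=rows)
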