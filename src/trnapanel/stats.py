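"""Exact 2x2 statistics for the stems-vs-loops variation comparison.

The two-sided Fisher p-value is defined by probability mass: conditioning on
the table margins, sum the hypergeometric probability of every table no more
probable than the observed one (with a small relative tolerance so exact
ties are included despite floating point). Probabilities come from
scipy's hypergeometric distribution; the summation rule is explicit here so
the tie tolerance is under our control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .conservation import VariationTally

__all__ = ["ContingencyTable2x2", "fisher_exact_2x2", "stems_loops_test"]

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cells [[a, b], [c, d]]; rows are groups, columns are stems/loops."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell in {cells}")
        if any(int(x) != x for x in cells):
            raise ValueError(f"non-integer cell in {cells}")
        if sum(cells) == 0:
            raise ValueError("table total is zero")

    @classmethod
    def from_rows(cls, rows) -> "ContingencyTable2x2":
        (a, b), (c, d) = rows
        return cls(int(a), int(b), int(c), int(d))

    @property
    def rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    ``table`` is a ContingencyTable2x2 or a [[a, b], [c, d]] nest. The
    p-value is the total hypergeometric mass of tables (with the observed
    margins) whose probability does not exceed the observed table's, within
    a 1e-12 relative tolerance for ties. Always in (0, 1].
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2.from_rows(table)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    # support of the a-cell given fixed margins
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    xs = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(xs, n, col1, row1)
    p_obs = float(probs[a - lo])
    cutoff = p_obs * (1.0 + _TIE_RTOL)
    total = float(probs[probs <= cutoff].sum())
    return min(total, 1.0)


def stems_loops_test(observed: VariationTally,
                     expected: tuple[float, float]
                     ) -> tuple[ContingencyTable2x2, float]:
    """Observed vs proportionally-expected stem/loop variant counts as a 2x2.

    Expected counts are rounded to the nearest integers before tabulation
    (Fisher's test needs counts). Returns the table and its two-sided p.
    """
    e_stem, e_loop = expected
    table = ContingencyTable2x2(
        observed.stem_variants,
        observed.loop_variants,
        round(e_stem),
        round(e_loop),
    )
    return table, fisher_exact_2x2(table)
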