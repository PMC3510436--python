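"""The conservation-scoring flowchart.

A human mt-tRNA variant position earns 0, 1 or 2 conservation points toward
the overall pathogenicity score. Outside a stem the only input is how many
panel species differ from the human allele at that position. Inside a
double-stranded stem the position itself is considered first, then the base
pairing: species that changed the position but still form a paired state
with the partner position (a compensatory change) keep structural evidence
of constraint and score an intermediate point.

The numeric cutoffs are configurable; the defaults (fully conserved -> 2,
one non-stem change -> 1, otherwise 0, compensated stem changes -> 1)
reproduce the published worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

from .conservation import ColumnProfile
from .structure import Domain, PairClass

__all__ = ["ScoringThresholds", "ConservationScore", "score_variant", "explain"]


@dataclass(frozen=True)
class ScoringThresholds:
    """Cutoffs for mapping change counts to points.

    ``loop_changes_for_2``: most changes still scoring 2 outside a stem.
    ``loop_changes_for_1``: most changes still scoring 1 outside a stem.
    ``stem_changes_for_2``: most changes still scoring 2 inside a stem.
    ``compensatory_scores_1``: stem changes paired in every changed species
    score 1 instead of 0.
    ``wobble_counts_as_paired``: treat G.T as a retained paired state.
    """

    loop_changes_for_2: int = 0
    loop_changes_for_1: int = 1
    stem_changes_for_2: int = 0
    compensatory_scores_1: bool = True
    wobble_counts_as_paired: bool = False

    def __post_init__(self):
        if min(self.loop_changes_for_2, self.loop_changes_for_1,
               self.stem_changes_for_2) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.loop_changes_for_2 > self.loop_changes_for_1:
            raise ValueError(
                "loop_changes_for_2 must not exceed loop_changes_for_1"
            )

    def paired_classes(self) -> frozenset[PairClass]:
        if self.wobble_counts_as_paired:
            return frozenset({PairClass.WATSON_CRICK, PairClass.WOBBLE})
        return frozenset({PairClass.WATSON_CRICK})

    def fingerprint(self) -> str:
        return ",".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))


@dataclass(frozen=True)
class ConservationScore:
    """A 0/1/2 score plus the decision path that produced it."""

    points: int
    path: tuple[str, ...]
    context: Domain
    n_changes: int

    def __post_init__(self):
        if self.points not in (0, 1, 2):
            raise ValueError(f"points must be 0, 1 or 2, got {self.points}")
        if not self.path:
            raise ValueError("decision path must be non-empty")


def score_variant(
    profile: ColumnProfile,
    domain: Domain,
    is_stem: bool,
    pair_by_species: Optional[Mapping[str, PairClass]] = None,
    thresholds: ScoringThresholds = ScoringThresholds(),
) -> ConservationScore:
    """Walk the flowchart for one variant position.

    ``pair_by_species`` (required for stems) gives each panel species' pair
    class at (position, partner) within its own sequence; the reference
    species' entry is ignored, as are species that match the reference
    allele — only *changed* species are asked to have compensated.
    """
    n = profile.n_changes
    path = [f"domain={domain.value}", f"stem={'yes' if is_stem else 'no'}",
            f"changes={n}"]
    if not is_stem:
        if n <= thresholds.loop_changes_for_2:
            path.append(f"changes<={thresholds.loop_changes_for_2}: conserved")
            points = 2
        elif n <= thresholds.loop_changes_for_1:
            path.append(
                f"changes<={thresholds.loop_changes_for_1}: weakly conserved"
            )
            points = 1
        else:
            path.append(f"changes>{thresholds.loop_changes_for_1}: not conserved")
            points = 0
        return ConservationScore(points, tuple(path), domain, n)

    if pair_by_species is None:
        raise ValueError("stem context requires per-species pairing data")
    if n <= thresholds.stem_changes_for_2:
        path.append(f"changes<={thresholds.stem_changes_for_2}: conserved")
        return ConservationScore(2, tuple(path), domain, n)
    changed = [
        sp for sp, res in profile.residue_by_species.items()
        if sp != profile.reference_species and res != profile.reference_residue
        and (profile.gap_is_change or res != "-")
    ]
    paired_ok = thresholds.paired_classes()
    all_paired = all(pair_by_species.get(sp) in paired_ok for sp in changed)
    if thresholds.compensatory_scores_1 and all_paired and changed:
        path.append("all changed species retain a paired state: compensatory")
        return ConservationScore(1, tuple(path), domain, n)
    path.append("pairing lost in at least one changed species: not conserved"
                if changed else "changes exceed stem threshold: not conserved")
    return ConservationScore(0, tuple(path), domain, n)


def explain(score: ConservationScore) -> str:
    """Human-readable rendering of a decision path, for reports."""
    lines = [f"conservation score: {score.points} point(s)"]
    lines += [f"  - {step}" for step in score.path]
    return "\n".join(lines)
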