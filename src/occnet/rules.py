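"""Exhaustive mining of confidence-1 association rules.

A rule "A -> B" states that every sample containing fragment A also contains
fragment B, i.e. samples(A) is a subset of samples(B). Only exceptionless
rules (confidence exactly 1) are kept, so a single counterexample sample
discards the candidate. Both directions of every ordered fragment pair are
screened; with the matrix held as a boolean array the subset test for all
ordered pairs reduces to comparing the pairwise co-occurrence counts with the
origin occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data import (
    ARCHAEAL,
    BACTERIAL,
    FragmentAnnotation,
    PresenceAbsenceMatrix,
    ValidationError,
)


@dataclass(frozen=True)
class AssociationRule:
    """Directed, exceptionless origin -> target dependency."""

    origin: str
    target: str
    support_origin: int
    support_both: int
    ubiquitous_target: bool = False

    def __post_init__(self) -> None:
        if self.origin == self.target:
            raise ValidationError("rule origin and target must differ")
        if self.support_both != self.support_origin:
            raise ValidationError("confidence-1 rule requires support_both == support_origin")

    @property
    def confidence(self) -> float:
        return self.support_both / self.support_origin


@dataclass(frozen=True)
class RuleTypeBreakdown:
    """Rule counts by (origin domain, target domain), plus correlation overlap."""

    bacterium_to_bacterium: int
    bacterium_to_archaeum: int
    archaeum_to_archaeum: int
    archaeum_to_bacterium: int
    total: int
    n_also_correlated: int

    def as_dict(self) -> dict[str, int]:
        return {
            "bacterium_to_bacterium": self.bacterium_to_bacterium,
            "bacterium_to_archaeum": self.bacterium_to_archaeum,
            "archaeum_to_archaeum": self.archaeum_to_archaeum,
            "archaeum_to_bacterium": self.archaeum_to_bacterium,
            "total": self.total,
            "n_also_correlated": self.n_also_correlated,
        }


def mine_rules(m: PresenceAbsenceMatrix, min_support: int = 1) -> list[AssociationRule]:
    """All confidence-1 rules with origin occupancy >= ``min_support``.

    Emits the rule (A, B) iff samples(A) is a non-empty subset of samples(B);
    zero-occupancy origins never form rules (confidence undefined). Output is
    sorted by (origin, target) for determinism. Targets present in every
    sample are flagged ubiquitous rather than dropped.
    """
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    v = m.values.astype(np.int64)
    occ = v.sum(axis=1)
    co = v @ v.T  # co[i, j] = |samples(i) & samples(j)|
    subset = (co == occ[:, None]) & (occ[:, None] >= min_support)
    np.fill_diagonal(subset, False)
    n_samples = m.n_samples
    frags = m.fragment_ids
    rules = [
        AssociationRule(
            origin=frags[i],
            target=frags[j],
            support_origin=int(occ[i]),
            support_both=int(co[i, j]),
            ubiquitous_target=bool(occ[j] == n_samples),
        )
        for i, j in np.argwhere(subset)
    ]
    rules.sort(key=lambda r: (r.origin, r.target))
    return rules


def rule_type_breakdown(
    rules: Sequence[AssociationRule],
    annotations: Mapping[str, FragmentAnnotation],
    significant_pairs: set[frozenset] | None = None,
) -> RuleTypeBreakdown:
    """Tally rules by domain of origin and target.

    ``significant_pairs`` is the set of unordered significantly correlated
    pairs from the co-occurrence stage; a rule counts as "also correlated"
    when its unordered pair is in that set.
    """
    missing = sorted(
        {f for r in rules for f in (r.origin, r.target) if f not in annotations}
    )
    if missing:
        raise ValidationError(f"rule fragments without annotation: {missing[:10]}")
    counts = {(BACTERIAL, BACTERIAL): 0, (BACTERIAL, ARCHAEAL): 0,
              (ARCHAEAL, ARCHAEAL): 0, (ARCHAEAL, BACTERIAL): 0}
    n_corr = 0
    for r in rules:
        counts[(annotations[r.origin].domain, annotations[r.target].domain)] += 1
        if significant_pairs is not None and frozenset((r.origin, r.target)) in significant_pairs:
            n_corr += 1
    return RuleTypeBreakdown(
        bacterium_to_bacterium=counts[(BACTERIAL, BACTERIAL)],
        bacterium_to_archaeum=counts[(BACTERIAL, ARCHAEAL)],
        archaeum_to_archaeum=counts[(ARCHAEAL, ARCHAEAL)],
        archaeum_to_bacterium=counts[(ARCHAEAL, BACTERIAL)],
        total=len(rules),
        n_also_correlated=n_corr,
    )
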