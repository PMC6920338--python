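"""Mating-design enumeration for hybrid breeding.

Three-line hybrid rice uses a cytoplasmic male-sterile (A) line, its
maintainer (B) line and a restorer (R) line.  Maintainer lines share the
sterile line's nuclear genome, so crosses are enumerated with the maintainer
as a pseudo-female parent against conventional lines, restricted to
group-compatible pairs (e.g. within-subspecies Xian x Xian crosses).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

from .genotypes import hybrid_id

__all__ = [
    "ParentPanel",
    "CrossRuleSet",
    "Cross",
    "enumerate_three_line_crosses",
    "half_diallel",
    "count_all_pairs",
    "RICE_3K_GROUPS",
]

#: The five varietal groups of the 3K rice germplasm collection.
RICE_3K_GROUPS = ("Xian", "Geng", "intermediate", "aus_boro", "basmati_sadri")


class Cross(NamedTuple):
    """A single planned cross; female is the (pseudo-)male-sterile side."""

    hybrid_id: str
    female: str
    male: str


@dataclass
class ParentPanel:
    """Inbred parent panel with a varietal-group label and maintainer flag
    per parent."""

    parent_ids: list[str]
    group: dict[str, str]
    is_maintainer: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parent_ids = [str(p) for p in self.parent_ids]
        if len(set(self.parent_ids)) != len(self.parent_ids):
            raise ValueError("parent ids are not unique")
        missing = [p for p in self.parent_ids if p not in self.group]
        if missing:
            raise ValueError(f"parents without a group label: {missing[:5]}")
        for p in self.parent_ids:
            self.is_maintainer.setdefault(p, False)

    @property
    def maintainers(self) -> list[str]:
        return [p for p in self.parent_ids if self.is_maintainer[p]]

    @property
    def non_maintainers(self) -> list[str]:
        return [p for p in self.parent_ids if not self.is_maintainer[p]]


@dataclass
class CrossRuleSet:
    """Group-compatibility rules: which unordered group pairs may be crossed."""

    allowed_pairs: set[frozenset[str]]
    female_must_be_maintainer: bool = True

    def __post_init__(self) -> None:
        if not self.allowed_pairs:
            raise ValueError("allowed_pairs must be non-empty")
        self.allowed_pairs = {frozenset(p) for p in self.allowed_pairs}

    def allows(self, group_a: str, group_b: str) -> bool:
        return frozenset((group_a, group_b)) in self.allowed_pairs


def enumerate_three_line_crosses(panel: ParentPanel, rules: CrossRuleSet) -> list[Cross]:
    """All maintainer x conventional-line crosses permitted by the rules.

    Maintainer x maintainer pairs and self-crosses are excluded; each
    unordered pair appears once, with the maintainer recorded as female.
    """
    maintainers = panel.maintainers
    if rules.female_must_be_maintainer and not maintainers:
        raise ValueError("panel contains no maintainer lines")
    crosses: list[Cross] = []
    seen: set[str] = set()
    for f in maintainers:
        for m in panel.non_maintainers:
            if f == m or not rules.allows(panel.group[f], panel.group[m]):
                continue
            hid = hybrid_id(f, m)
            if hid not in seen:
                seen.add(hid)
                crosses.append(Cross(hid, f, m))
    if not crosses:
        warnings.warn("cross rules produced no permissible crosses", stacklevel=2)
    return crosses


def half_diallel(panel: ParentPanel, within_groups_only: bool = False) -> list[Cross]:
    """All unordered parent pairs, no selfs or reciprocals; optionally only
    pairs that share a group label."""
    if len(panel.parent_ids) < 2:
        raise ValueError("half diallel needs at least 2 parents")
    crosses = []
    for p1, p2 in itertools.combinations(panel.parent_ids, 2):
        if within_groups_only and panel.group[p1] != panel.group[p2]:
            continue
        crosses.append(Cross(hybrid_id(p1, p2), p1, p2))
    return crosses


def count_all_pairs(n: int) -> int:
    """Number of distinct single crosses among n inbreds: n(n-1)/2."""
    if n < 2:
        raise ValueError("need at least 2 parents")
    return n * (n - 1) // 2
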