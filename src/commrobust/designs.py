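"""Study-design enumeration and community interaction combinatorics.

The study layout is a leave-one-out (dropout) design over a nine-member
community: every species grown alone, the full nine-species mix, and each
of the nine eight-species communities with exactly one member absent.
All members are inoculated at the same optical density (OD600), so the
full-mix starting community is approximately even by biomass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CommunityDesign",
    "build_designs",
    "interaction_capacity",
    "k_subset_interactions",
    "inoculum_cfu",
    "log10_cfu",
    "designs_table",
]

#: Roles a design can play in the study layout.
ROLE_MIX = "mix"
ROLE_DROPOUT = "dropout"
ROLE_MONOCULTURE = "monoculture"


@dataclass(frozen=True)
class CommunityDesign:
    """One inoculation design: which species go in, and at what density.

    Parameters
    ----------
    design_id : str
        Human-readable label ("Mix", "-Cg", "Cg-alone", ...).
    role : str
        One of ``mix``, ``dropout``, ``monoculture``. Dropouts and
        monocultures are distinct roles even when membership coincides
        (the two-species edge case), because downstream statistics group
        by role.
    members : tuple of str
        Ordered species abbreviations included in the inoculum.
    per_member_od : float
        OD600 contributed by each member at inoculation (equal-inoculum
        designs only).
    """

    design_id: str
    role: str
    members: tuple[str, ...]
    per_member_od: float = 0.05

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a community design needs at least one member")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate members in design {self.design_id!r}")
        if self.per_member_od <= 0:
            raise ValueError("per_member_od must be positive")

    @property
    def total_od(self) -> float:
        """Total inoculum OD600 (sum over members)."""
        return self.per_member_od * len(self.members)

    def __contains__(self, abbrev: str) -> bool:
        return abbrev in self.members


def build_designs(
    species: Sequence[str], per_member_od: float = 0.05
) -> list[CommunityDesign]:
    """Enumerate the full study layout for a community.

    Returns the full mix first, then the single-species dropouts in input
    order, then the monocultures — matching the left-to-right layout used
    for reporting. For N species this is 2N+1 designs.

    Raises
    ------
    ValueError
        If fewer than two species are given or abbreviations repeat.
    """
    species = list(species)
    if len(species) < 2:
        raise ValueError("need at least two species to build a dropout layout")
    if len(set(species)) != len(species):
        raise ValueError("species abbreviations must be unique")

    designs = [
        CommunityDesign("Mix", ROLE_MIX, tuple(species), per_member_od)
    ]
    for ab in species:
        members = tuple(s for s in species if s != ab)
        designs.append(
            CommunityDesign(f"-{ab}", ROLE_DROPOUT, members, per_member_od)
        )
    for ab in species:
        designs.append(
            CommunityDesign(f"{ab}-alone", ROLE_MONOCULTURE, (ab,), per_member_od)
        )
    return designs


def interaction_capacity(n: int) -> int:
    """Number of possible multi-member subgroups of an n-member community.

    Reed's-law group-forming capacity: 2**n - n - 1, the count of all
    subsets of size >= 2. For the nine-member community this is 502.
    """
    if n < 2:
        raise ValueError("interaction capacity is defined for n >= 2")
    return 2**n - n - 1


def k_subset_interactions(n: int, k_min: int = 2, k_max: int = 3) -> int:
    """Count subgroups with between k_min and k_max members.

    The default [2, 3] restricts to pairwise and three-way interaction
    sets; for n = 9 this gives 120.
    """
    if not (2 <= k_min <= k_max <= n):
        raise ValueError("require 2 <= k_min <= k_max <= n")
    return sum(math.comb(n, k) for k in range(k_min, k_max + 1))


def inoculum_cfu(per_member_od: float, cfu_per_od: float) -> float:
    """CFU/ml contributed by one member inoculated at ``per_member_od``."""
    if per_member_od <= 0 or cfu_per_od <= 0:
        raise ValueError("per_member_od and cfu_per_od must be positive")
    return per_member_od * cfu_per_od


def log10_cfu(per_member_od: float, cfu_per_od: float) -> float:
    """log10 of the member's inoculum CFU/ml."""
    return math.log10(inoculum_cfu(per_member_od, cfu_per_od))


def designs_table(designs: Iterable[CommunityDesign]) -> pd.DataFrame:
    """Tabulate designs for the designs.tsv output."""
    return pd.DataFrame(
        {
            "design_id": [d.design_id for d in designs],
            "role": [d.role for d in designs],
            "members": ["+".join(d.members) for d in designs],
            "per_member_od": [d.per_member_od for d in designs],
            "total_od": [round(d.total_od, 10) for d in designs],
        }
    )
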