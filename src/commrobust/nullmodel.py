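"""Expected community activity from monoculture measurements.

A mixture's expected activity is computed only from its members'
monoculture activities A_i and their proportions p_i under a stated
weighting (exact inoculum fractions — 1/9 for the full mix, 1/8 for a
dropout — or measured endpoint proportions) and a stated arithmetic
convention:

``literal_divide``      E = sum_i A_i / p_i
    Each monoculture activity is divided by the member's fractional
    proportion and the corrected activities summed. Note this inflates E
    by a factor n^2 relative to the plain mean for an even n-member
    mixture.

``proportional_sum``    E = sum_i A_i * p_i
    The proportion-weighted mean, the conservative alternative: the
    community produces what its members would contribute at their
    abundances with no interaction.

Both conventions are first class; every result records which one was
used. Comparisons are reported as actual - expected, so a community
producing less than predicted is negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .designs import CommunityDesign

__all__ = [
    "CONVENTIONS",
    "WEIGHTINGS",
    "expected_activity",
    "DifferenceSummary",
    "actual_minus_expected",
    "NullModelResult",
    "build_nullmodel_table",
]

CONVENTIONS = ("literal_divide", "proportional_sum")
WEIGHTINGS = ("input_proportions", "endpoint_proportions")


def expected_activity(
    mono_activities: Mapping[str, float],
    proportions: Mapping[str, float],
    convention: str = "literal_divide",
) -> float:
    """Expected mixture activity from monoculture activities A_i.

    ``proportions`` must cover exactly the mixture members; they are
    renormalized to sum to one. Zero proportions are an error under
    ``literal_divide`` (the division is undefined) and should be excluded
    (with the remainder renormalized) before the call.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    members = list(proportions)
    if not members:
        raise ValueError("no mixture members given")
    missing = [m for m in members if m not in mono_activities]
    if missing:
        raise KeyError(f"missing monoculture activity for: {missing}")
    p = np.array([proportions[m] for m in members], dtype=float)
    a = np.array([mono_activities[m] for m in members], dtype=float)
    if np.any(a < 0):
        raise ValueError("monoculture activities must be non-negative")
    if np.any(p < 0) or p.sum() <= 0:
        raise ValueError("proportions must be non-negative with positive sum")
    p = p / p.sum()
    if convention == "literal_divide":
        if np.any(p == 0):
            zero = [m for m, pi in zip(members, p) if pi == 0]
            raise ZeroDivisionError(
                f"literal_divide undefined for zero-proportion members: {zero}"
            )
        return float((a / p).sum())
    return float((a * p).sum())


@dataclass(frozen=True)
class DifferenceSummary:
    """Per-replicate actual - expected differences with summary stats."""

    differences: tuple[float, ...]
    mean: float
    sem: float


def actual_minus_expected(
    actual_replicates: Sequence[float], expected: float
) -> DifferenceSummary:
    """Per-replicate differences (actual - expected) and their mean/SEM.

    The expected value is a constant shift, so the SEM of the differences
    equals the SEM of the measured replicates.
    """
    actual = np.asarray(list(actual_replicates), dtype=float)
    if actual.size == 0:
        raise ValueError("need at least one measured replicate")
    diffs = actual - float(expected)
    sem = float(diffs.std(ddof=1) / np.sqrt(diffs.size)) if diffs.size > 1 else 0.0
    return DifferenceSummary(
        differences=tuple(float(d) for d in diffs),
        mean=float(diffs.mean()),
        sem=sem,
    )


@dataclass(frozen=True)
class NullModelResult:
    """Expected-vs-measured record for one design and enzyme class."""

    design_id: str
    enzyme: str
    convention: str
    weighting: str
    expected: float
    actual_replicates: tuple[float, ...]
    differences: tuple[float, ...]
    mean_diff: float
    sem_diff: float


def build_nullmodel_table(
    activities: pd.DataFrame,
    designs: Sequence[CommunityDesign],
    endpoint_compositions: Mapping[str, "pd.Series"] | None = None,
    conventions: Sequence[str] = CONVENTIONS,
    weightings: Sequence[str] = ("input_proportions",),
) -> pd.DataFrame:
    """Expected/actual comparison for every multi-species design.

    ``activities`` is the canonical activity table (design_id, enzyme,
    replicate, value); monoculture A_i is the replicate mean of the
    corresponding single-species design. Endpoint weighting needs
    ``endpoint_compositions`` (design_id -> proportions over all
    species); zeros among members are excluded and the rest renormalized.
    """
    mono = {
        d.members[0]: d.design_id for d in designs if len(d.members) == 1
    }
    if not mono:
        raise ValueError("no monoculture designs found")
    mono_means: dict[str, dict[str, float]] = {}
    for enzyme, sub in activities.groupby("enzyme"):
        by_design = sub.groupby("design_id")["value"].mean()
        mono_means[enzyme] = {
            ab: float(by_design[design_id])
            for ab, design_id in mono.items()
            if design_id in by_design
        }

    rows = []
    for design in designs:
        if len(design.members) < 2:
            continue
        for enzyme in sorted(activities["enzyme"].unique()):
            actual = activities.query(
                "design_id == @design.design_id and enzyme == @enzyme"
            )["value"].to_numpy()
            if actual.size == 0:
                continue
            for weighting in weightings:
                if weighting == "input_proportions":
                    props = {ab: 1.0 / len(design.members) for ab in design.members}
                elif weighting == "endpoint_proportions":
                    if endpoint_compositions is None:
                        raise ValueError(
                            "endpoint weighting requires endpoint_compositions"
                        )
                    if design.design_id not in endpoint_compositions:
                        # endpoint proportions were only measured for some
                        # communities; skip the rest under this weighting
                        continue
                    comp = endpoint_compositions[design.design_id]
                    props = {
                        ab: float(comp[ab])
                        for ab in design.members
                        if float(comp.get(ab, 0.0)) > 0
                    }
                else:
                    raise ValueError(f"unknown weighting {weighting!r}")
                for convention in conventions:
                    expected = expected_activity(
                        mono_means[enzyme], props, convention
                    )
                    summary = actual_minus_expected(actual, expected)
                    rows.append(
                        (
                            design.design_id, enzyme, convention, weighting,
                            expected, summary.mean, summary.sem,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "design_id", "enzyme", "convention", "weighting",
            "expected", "mean_diff", "sem_diff",
        ],
    )
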