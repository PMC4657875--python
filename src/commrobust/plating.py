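"""Differential-plating: species identification and count deconvolution.

A mixed community is enumerated by plating on a panel of conditions
(temperature x antibiotic supplement) under which only known subsets of
members grow, combined with colony appearance (color, edge morphology).
Each species then has a *signature* — its growth pattern across the panel
plus its colony class — and the panel identifies the community iff all
signatures are distinct.

Given colony counts per (condition, colony class), the observed count in a
cell is proportional to the summed abundance of the species sharing that
cell, relative to everything able to grow on that plate. That yields a
homogeneous linear system in the species abundances, solved by non-negative
least squares under a unit-sum constraint.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "Condition",
    "PhenotypeMatrix",
    "PlatingObservation",
    "CompositionEstimate",
    "IdentifiabilityReport",
    "load_phenotype_matrix",
    "DEFAULT_SCHEME",
    "predict_growth",
    "species_signatures",
    "identifiability_check",
    "resolve_composition",
]

GROWTH_LEVELS = {"-": "none", "+": "slow", "++": "normal"}

#: A plating condition: (temperature in Celsius, supplement code).
Condition = tuple[int, str]

#: The package's default plating scheme. No-selection, gentamicin and
#: trimethoprim plates at both incubation temperatures separate most
#: members; the cetrimide plate at 37 C (on which only B. multivorans
#: grows) separates the two kanamycin/gentamicin-resistant white species
#: that are otherwise indistinguishable without it.
DEFAULT_SCHEME: tuple[Condition, ...] = (
    (30, "NS"),
    (37, "NS"),
    (30, "Gm25"),
    (37, "Gm25"),
    (30, "Tp100"),
    (37, "Tp100"),
    (37, "Ct200"),
)


class PhenotypeMatrix:
    """Growth phenotypes of each species across plating conditions.

    Stores a growth level (none/slow/normal) for every
    (species, condition) pair plus one colony-appearance class per
    species. Unknown lookups raise rather than defaulting.
    """

    def __init__(
        self,
        growth: Mapping[tuple[str, Condition], str],
        colony_class: Mapping[str, str],
        species_names: Mapping[str, str] | None = None,
    ) -> None:
        if not growth:
            raise ValueError("empty phenotype matrix")
        bad = {v for v in growth.values()} - set(GROWTH_LEVELS.values())
        if bad:
            raise ValueError(f"unknown growth levels: {sorted(bad)}")
        self._growth = dict(growth)
        self.colony_class = dict(colony_class)
        self.species_names = dict(species_names or {})
        self.species: tuple[str, ...] = tuple(
            dict.fromkeys(ab for ab, _ in self._growth)
        )
        self.conditions: tuple[Condition, ...] = tuple(
            dict.fromkeys(cond for _, cond in self._growth)
        )

    def level(self, abbrev: str, condition: Condition) -> str:
        try:
            return self._growth[(abbrev, condition)]
        except KeyError:
            raise KeyError(
                f"no phenotype entry for species {abbrev!r} under {condition!r}"
            ) from None

    def has_condition(self, condition: Condition) -> bool:
        return condition in self.conditions


def load_phenotype_matrix() -> PhenotypeMatrix:
    """Load the packaged differential-susceptibility matrix."""
    path = importlib.resources.files("commrobust.data") / "phenotype_matrix.tsv"
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    growth: dict[tuple[str, Condition], str] = {}
    colony: dict[str, str] = {}
    names: dict[str, str] = {}
    supplements = [
        c for c in df.columns
        if c not in ("species", "abbrev", "temp_c", "colony_class")
    ]
    for row in df.itertuples(index=False):
        colony[row.abbrev] = row.colony_class
        names[row.abbrev] = row.species
        for supp in supplements:
            code = getattr(row, supp)
            growth[(row.abbrev, (int(row.temp_c), supp))] = GROWTH_LEVELS[code]
    return PhenotypeMatrix(growth, colony, names)


def predict_growth(
    matrix: PhenotypeMatrix,
    condition: Condition,
    slow_counts_as_growth: bool = False,
) -> set[str]:
    """Species expected to form countable colonies under a condition.

    By default only normal growth (``++``) counts: slow growers form
    colonies less than half normal size and are conservatively treated as
    not scored. Set ``slow_counts_as_growth`` to include them.
    """
    if not matrix.has_condition(condition):
        raise KeyError(f"condition {condition!r} not in phenotype matrix")
    allowed = {"normal", "slow"} if slow_counts_as_growth else {"normal"}
    return {
        ab for ab in matrix.species if matrix.level(ab, condition) in allowed
    }


def species_signatures(
    matrix: PhenotypeMatrix,
    conditions: Sequence[Condition],
    use_colony_class: bool = True,
    slow_counts_as_growth: bool = False,
) -> dict[str, tuple]:
    """Growth-pattern x appearance signature for every species."""
    if not conditions:
        raise ValueError("at least one plating condition is required")
    grown = {c: predict_growth(matrix, c, slow_counts_as_growth) for c in conditions}
    sigs: dict[str, tuple] = {}
    for ab in matrix.species:
        pattern = tuple(ab in grown[c] for c in conditions)
        cls = matrix.colony_class[ab] if use_colony_class else None
        sigs[ab] = (pattern, cls)
    return sigs


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Whether a plating scheme resolves every community member."""

    identifiable: bool
    ambiguous_groups: tuple[tuple[str, ...], ...]


def identifiability_check(
    matrix: PhenotypeMatrix,
    conditions: Sequence[Condition],
    use_colony_class: bool = True,
    slow_counts_as_growth: bool = False,
) -> IdentifiabilityReport:
    """Check that signatures are pairwise distinct; list collisions."""
    sigs = species_signatures(
        matrix, conditions, use_colony_class, slow_counts_as_growth
    )
    by_sig: dict[tuple, list[str]] = {}
    for ab, sig in sigs.items():
        by_sig.setdefault(sig, []).append(ab)
    groups = tuple(
        tuple(sorted(v)) for v in by_sig.values() if len(v) > 1
    )
    return IdentifiabilityReport(identifiable=not groups, ambiguous_groups=groups)


@dataclass(frozen=True)
class PlatingObservation:
    """Colony counts for one plate, binned by colony class.

    Counts are integers when drawn from real or simulated plates; the
    noiseless expected-count mode of the generator produces fractional
    counts, which the resolver accepts. ``no_growth`` flags conditions
    under which nothing in the community was expected to grow.
    """

    condition: Condition
    counts: Mapping[str, float]
    dilution_factor: float = 1.0
    no_growth: bool = False

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("colony counts cannot be negative")
        if self.dilution_factor <= 0:
            raise ValueError("dilution factor must be positive")

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))


@dataclass(frozen=True)
class CompositionEstimate:
    """Deconvoluted species proportions with multinomial standard errors."""

    proportions: dict[str, float]
    se: dict[str, float]
    total_count: float
    residual: float

    def species_counts(self) -> dict[str, float]:
        """Implied per-species counts on the reference (total) plate."""
        return {s: p * self.total_count for s, p in self.proportions.items()}


def resolve_composition(
    observations: Iterable[PlatingObservation],
    matrix: PhenotypeMatrix,
    slow_counts_as_growth: bool = False,
    max_row_residual: float = 0.25,
) -> CompositionEstimate:
    """Deconvolute plate counts into species proportions.

    Assumes every plate received the same sample volume (up to the
    recorded dilution factor), so the dilution-corrected count in a
    (condition, colony class) cell estimates the summed per-volume count
    of the species sharing that cell:

        n_cell * dilution = sum over cell species of y_s

    with y_s the species' count in the undiluted reference volume. The
    resulting overdetermined linear system is solved by non-negative
    least squares and y normalized to proportions. Multinomial standard
    errors are attached at the panel's total counting depth.

    Raises if the conditions used do not identify the community, or if the
    counts are grossly inconsistent with the phenotype matrix (relative
    residual above ``max_row_residual``).
    """
    observations = list(observations)
    if not observations:
        raise ValueError("no plating observations given")
    conditions = [o.condition for o in observations]
    report = identifiability_check(
        matrix, conditions, use_colony_class=True,
        slow_counts_as_growth=slow_counts_as_growth,
    )
    if not report.identifiable:
        raise ValueError(
            f"plating scheme does not identify the community; ambiguous "
            f"groups: {report.ambiguous_groups}"
        )

    species = list(matrix.species)
    idx = {ab: i for i, ab in enumerate(species)}
    rows: list[np.ndarray] = []
    targets: list[float] = []
    counted = 0.0
    for obs in observations:
        growers = predict_growth(matrix, obs.condition, slow_counts_as_growth)
        if obs.no_growth or not growers:
            continue
        counted += obs.total
        cells: dict[str, list[str]] = {}
        for ab in growers:
            cells.setdefault(matrix.colony_class[ab], []).append(ab)
        observed_classes = set(obs.counts) | set(cells)
        for cls in sorted(observed_classes):
            n_cell = float(obs.counts.get(cls, 0.0))
            row = np.zeros(len(species))
            for ab in cells.get(cls, []):
                row[idx[ab]] = 1.0
            rows.append(row)
            targets.append(n_cell * obs.dilution_factor)
    if not rows or counted == 0:
        raise ValueError("no usable (non-empty) plates among the observations")

    a = np.vstack(rows)
    b = np.asarray(targets)
    y, residual = nnls(a, b)
    scale = np.linalg.norm(b)
    if scale > 0 and residual / scale > max_row_residual:
        raise ValueError(
            "plate counts are inconsistent with the phenotype matrix "
            f"(relative residual {residual / scale:.3f})"
        )
    if y.sum() <= 0:
        raise ValueError("degenerate solution: all species at zero abundance")
    y[y < 1e-10 * y.sum()] = 0.0  # solver dust: undetected means exactly zero
    x = y / y.sum()

    proportions = {ab: float(x[idx[ab]]) for ab in species}
    se = {
        ab: float(np.sqrt(max(p * (1 - p), 0.0) / counted))
        for ab, p in proportions.items()
    }
    return CompositionEstimate(
        proportions=proportions, se=se,
        total_count=float(counted), residual=float(residual),
    )
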