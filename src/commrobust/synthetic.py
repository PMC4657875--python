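"""Synthetic forward model of the community study.

Generates everything the wet study produced — endpoint compositions,
monoculture and mixed-community plate-reader signals, and selective-plate
colony counts — from explicit, seedable parameters, so every downstream
stage of the pipeline can be tested against known ground truth.

Ground-truth structure of the default parameterization:

* endpoint proportions are proportional to a per-species competitive
  fitness times multiplicative modifiers contributed by the *presence* of
  other members (the only non-neutral actor by default is C. gleum, whose
  removal releases B. cepacia and both Sphingomonads);
* fitness and the C. gleum modifiers are derived from the packaged 72-h
  composition reference, so the zero-noise full-mix and -Cg compositions
  reproduce it exactly by construction;
* three species (Ss, Bm, Bc) are the top producers of every enzyme class
  in monoculture, while mixed-community output is set by a pluggable
  mixing rule. The default ``dominant`` rule expresses functional
  redundancy: the community produces a regulated fraction of its best
  producer's capacity, so losing any single producer barely moves the
  community total — except that C. gleum's presence suppresses community
  NPPC hydrolysis, so its removal raises NPPC output, the one non-robust
  response;
* activity noise is multiplicative lognormal (activities are positive and
  replicate scatter scales with the mean); colony counts are multinomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assays import AssayConstants
from .datasets import SPECIES_ORDER, full_mix_proportions, minus_cg_proportions
from .designs import CommunityDesign
from .plating import PhenotypeMatrix, PlatingObservation, predict_growth

__all__ = [
    "ENZYME_CLASSES",
    "SpeciesProfile",
    "InteractionMatrix",
    "NoiseModel",
    "generate_default_profiles",
    "default_interaction_matrix",
    "DEFAULT_REGULATION",
    "DEFAULT_ACTIVITY_EFFECTS",
    "MIXING_RULES",
    "simulate_endpoint_composition",
    "community_activity",
    "simulate_assay_readouts",
    "simulate_plate_counts",
]

ENZYME_CLASSES = ("NPB", "NPP", "NPPC", "protease")

#: Endpoint OD600 defaults used by the signal forward model.
OD_MIXED = 0.45
OD_MONOCULTURE = 0.35
#: Assay read times: colorimetric minutes, protease minutes (4 h).
READ_MINUTES = {"NPB": 10.0, "NPP": 10.0, "NPPC": 30.0, "protease": 240.0}
#: Baseline signals (substrate-only blank A410; t=0 autofluorescence RFU).
BASELINE_SIGNAL = {"NPB": 0.05, "NPP": 0.05, "NPPC": 0.05, "protease": 400.0}


@dataclass(frozen=True)
class SpeciesProfile:
    """Identity and intrinsic properties of one community member."""

    name: str
    abbrev: str
    intrinsic_activity: Mapping[str, float]  # enzyme class -> per-OD activity
    fitness: float  # dimensionless competitive weight
    cfu_per_od: float  # CFU/ml at OD600 = 1.0
    colony_class: str

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.intrinsic_activity.values()):
            raise ValueError(f"{self.abbrev}: intrinsic activities must be >= 0")
        if self.fitness < 0:
            raise ValueError(f"{self.abbrev}: fitness must be >= 0")
        if self.cfu_per_od <= 0:
            raise ValueError(f"{self.abbrev}: cfu_per_od must be positive")


@dataclass(frozen=True)
class InteractionMatrix:
    """Presence effects on endpoint abundance.

    ``effects[(actor, target)]`` multiplies the target's endpoint weight
    whenever the actor is present in the design (1.0 = neutral). Removing
    the actor removes its modifiers; diagonal entries must be 1.
    """

    effects: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (actor, target), v in self.effects.items():
            if v <= 0:
                raise ValueError(f"modifier ({actor}->{target}) must be positive")
            if actor == target and v != 1.0:
                raise ValueError("diagonal interaction entries must be 1.0")

    def modifier(self, actor: str, target: str) -> float:
        return float(self.effects.get((actor, target), 1.0))


@dataclass(frozen=True)
class NoiseModel:
    """Noise and sampling-depth parameters for all stochastic outputs."""

    activity_cv: float = 0.15  # CV of lognormal noise on assay activities
    composition_cv: float = 0.08  # CV of lognormal noise on endpoint weights
    count_total: int = 500  # colonies counted per plating condition
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activity_cv < 0 or self.composition_cv < 0:
            raise ValueError("noise CVs must be non-negative")
        if self.count_total < 1:
            raise ValueError("count_total must be at least 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal factors with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


# Intrinsic per-OD activities (colorimetric classes in nmol/ml/min/OD600,
# protease in RFU/h/OD600). Ss, Bm and Bc lead every class; the remaining
# species span a wide low-to-middling range, as in the monoculture assays.
_INTRINSIC = {
    "Rp": {"NPB": 20.0, "NPP": 8.0, "NPPC": 2.0, "protease": 600.0},
    "Cm": {"NPB": 12.0, "NPP": 5.0, "NPPC": 1.5, "protease": 400.0},
    "Cg": {"NPB": 30.0, "NPP": 15.0, "NPPC": 3.0, "protease": 900.0},
    "Ri": {"NPB": 28.0, "NPP": 14.0, "NPPC": 6.0, "protease": 800.0},
    "Ss": {"NPB": 55.0, "NPP": 28.0, "NPPC": 14.0, "protease": 2400.0},
    "Bm": {"NPB": 52.0, "NPP": 30.0, "NPPC": 9.0, "protease": 2300.0},
    "Pm": {"NPB": 8.0, "NPP": 4.0, "NPPC": 1.0, "protease": 300.0},
    "Sp": {"NPB": 35.0, "NPP": 18.0, "NPPC": 5.0, "protease": 1100.0},
    "Bc": {"NPB": 50.0, "NPP": 32.0, "NPPC": 15.0, "protease": 2200.0},
}

_SPECIES_NAMES = {
    "Rp": "Ralstonia pickettii",
    "Cm": "Cupriavidus metallidurans",
    "Cg": "Chryseobacterium gleum",
    "Ri": "Ralstonia insidiosa",
    "Ss": "Sphingomonas sanguinis",
    "Bm": "Burkholderia multivorans",
    "Pm": "Phyllobacterium myrsianacearum",
    "Sp": "Sphingomonas paucimobilis",
    "Bc": "Burkholderia cepacia",
}

_COLONY_CLASSES = {
    "Rp": "white", "Cm": "white", "Cg": "orange", "Ri": "white_rough",
    "Ss": "yellow", "Bm": "white", "Pm": "white", "Sp": "yellow",
    "Bc": "white",
}

#: Community-level regulation: fraction of the mixing-rule output actually
#: expressed by a multi-species community (1.0 = unregulated).
DEFAULT_REGULATION = {"NPB": 0.5, "NPP": 0.5, "NPPC": 0.35, "protease": 0.5}

#: Activity-level presence effects: (actor, enzyme) -> multiplier applied
#: to the community output of that enzyme while the actor is present.
#: C. gleum suppresses community NPPC hydrolysis; the composition shift
#: alone cannot account for the observed -Cg rise.
DEFAULT_ACTIVITY_EFFECTS = {("Cg", "NPPC"): 0.55}

#: CFU/ml per OD600 unit; C. gleum sits 0.4 log10 below the others' mean.
_CFU_PER_OD_DEFAULT = 2.0e9
_CFU_PER_OD_CG = _CFU_PER_OD_DEFAULT * 10 ** (-0.4)


def generate_default_profiles() -> dict[str, SpeciesProfile]:
    """The nine default community members, keyed by abbreviation.

    Fitness values and the implied C. gleum interaction are calibrated
    against the packaged 72-h composition reference: fitness of the eight
    non-Cg members equals their -Cg endpoint proportion, and Cg's fitness
    is t/(1-t) of its full-mix share, so the zero-noise generator
    reproduces both reference columns exactly.
    """
    minus_cg = minus_cg_proportions()
    t_cg = float(full_mix_proportions()["Cg"])
    profiles: dict[str, SpeciesProfile] = {}
    for ab in SPECIES_ORDER:
        fitness = t_cg / (1.0 - t_cg) if ab == "Cg" else float(minus_cg[ab])
        profiles[ab] = SpeciesProfile(
            name=_SPECIES_NAMES[ab],
            abbrev=ab,
            intrinsic_activity=dict(_INTRINSIC[ab]),
            fitness=fitness,
            cfu_per_od=_CFU_PER_OD_CG if ab == "Cg" else _CFU_PER_OD_DEFAULT,
            colony_class=_COLONY_CLASSES[ab],
        )
    return profiles


def default_interaction_matrix() -> InteractionMatrix:
    """Presence effects reproducing the observed C. gleum release shift.

    Cg's modifier on each other member is the ratio of that member's
    full-mix share (rescaled to the non-Cg total) to its -Cg share, so
    together with the default fitness the +Cg and -Cg zero-noise endpoint
    compositions match the packaged reference exactly.
    """
    plus = full_mix_proportions()
    minus = minus_cg_proportions()
    t_cg = float(plus["Cg"])
    effects: dict[tuple[str, str], float] = {}
    for ab in SPECIES_ORDER:
        if ab == "Cg":
            continue
        effects[("Cg", ab)] = float(plus[ab] / (1.0 - t_cg) / minus[ab])
    return InteractionMatrix(effects)


def simulate_endpoint_composition(
    profiles: Mapping[str, SpeciesProfile],
    design: CommunityDesign,
    interactions: InteractionMatrix | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Endpoint proportional abundances for a design (all species indexed).

    Proportions are fitness x presence-modifiers, lognormally perturbed
    (if a noise model is given) and renormalized; species not in the
    design get exactly 0.
    """
    if not design.members:
        raise ValueError("degenerate community: design has no members")
    missing = [ab for ab in design.members if ab not in profiles]
    if missing:
        raise KeyError(f"design members without profiles: {missing}")
    interactions = interactions or InteractionMatrix()

    order = [ab for ab in profiles if ab in design.members]
    weights = np.array(
        [
            profiles[ab].fitness
            * np.prod(
                [
                    interactions.modifier(actor, ab)
                    for actor in design.members
                    if actor != ab
                ]
            )
            for ab in order
        ],
        dtype=float,
    )
    if noise is not None and noise.composition_cv > 0:
        rng = rng if rng is not None else noise.rng()
        weights = weights * _lognormal_factors(rng, noise.composition_cv, weights.size)
    if weights.sum() <= 0:
        raise ValueError("all endpoint weights are zero")
    weights = weights / weights.sum()
    comp = pd.Series(0.0, index=list(profiles))
    comp[order] = weights
    return comp


def _rule_weighted_mean(activities: np.ndarray, proportions: np.ndarray) -> float:
    return float(np.dot(activities, proportions))


def _rule_proportional_sum(activities: np.ndarray, proportions: np.ndarray) -> float:
    # prediction from even inoculum shares, ignoring the endpoint shift
    return float(activities.mean())


def _rule_dominant(activities: np.ndarray, proportions: np.ndarray) -> float:
    return float(activities.max())


#: Pluggable community mixing rules: map (member activities, member
#: endpoint proportions) -> community per-OD activity before regulation.
MIXING_RULES: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "weighted_mean": _rule_weighted_mean,
    "proportional_sum": _rule_proportional_sum,
    "dominant": _rule_dominant,
}


def community_activity(
    profiles: Mapping[str, SpeciesProfile],
    design: CommunityDesign,
    composition: pd.Series,
    enzyme: str,
    mixing_rule: str = "dominant",
    regulation: Mapping[str, float] | None = None,
    activity_effects: Mapping[tuple[str, str], float] | None = None,
) -> float:
    """Noise-free per-OD community activity for one enzyme class.

    Monocultures express their intrinsic activity unmodified: regulation
    and presence effects model community context and apply only when two
    or more species are present.
    """
    if enzyme not in ENZYME_CLASSES:
        raise ValueError(f"unknown enzyme class {enzyme!r}")
    members = list(design.members)
    acts = np.array(
        [profiles[ab].intrinsic_activity[enzyme] for ab in members]
    )
    if len(members) == 1:
        return float(acts[0])

    props = composition[members].to_numpy(dtype=float)
    total = props.sum()
    if total <= 0:
        raise ValueError("composition has zero mass on the design members")
    props = props / total
    try:
        rule = MIXING_RULES[mixing_rule]
    except KeyError:
        raise ValueError(f"unknown mixing rule {mixing_rule!r}") from None
    value = rule(acts, props)

    regulation = DEFAULT_REGULATION if regulation is None else regulation
    value *= float(regulation.get(enzyme, 1.0))
    effects = (
        DEFAULT_ACTIVITY_EFFECTS if activity_effects is None else activity_effects
    )
    for (actor, enz), factor in effects.items():
        if enz == enzyme and actor in design.members:
            value *= float(factor)
    return float(value)


def simulate_assay_readouts(
    profiles: Mapping[str, SpeciesProfile],
    design: CommunityDesign,
    composition: pd.Series,
    noise: NoiseModel | None = None,
    n_replicates: int = 9,
    mixing_rule: str = "dominant",
    regulation: Mapping[str, float] | None = None,
    activity_effects: Mapping[tuple[str, str], float] | None = None,
    constants: AssayConstants = AssayConstants(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Raw plate-reader signal table for one design.

    Inverts the assay conversions exactly: the blank-corrected signal
    delta encodes the (noisy) per-OD activity through the Beer–Lambert
    forward model for colorimetric classes and a linear fluorescence
    model for protease, so signal conversion recovers the simulated
    activity without bias at zero noise.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if noise is not None and rng is None:
        rng = noise.rng()
    od600 = OD_MONOCULTURE if len(design.members) == 1 else OD_MIXED

    rows = []
    for enzyme in ENZYME_CLASSES:
        true_activity = community_activity(
            profiles, design, composition, enzyme,
            mixing_rule=mixing_rule, regulation=regulation,
            activity_effects=activity_effects,
        )
        cv = noise.activity_cv if noise is not None else 0.0
        factors = (
            _lognormal_factors(rng, cv, n_replicates)
            if rng is not None
            else np.ones(n_replicates)
        )
        minutes = READ_MINUTES[enzyme]
        base = BASELINE_SIGNAL[enzyme]
        for rep in range(1, n_replicates + 1):
            activity = true_activity * factors[rep - 1]
            if enzyme == "protease":
                delta = activity * (minutes / 60.0) * od600
            else:
                delta = (
                    activity * minutes * od600
                    * constants.epsilon_nitrophenol * constants.pathlength_cm
                    / 1e6
                )
            rows.append(
                (design.design_id, enzyme, rep, base, base + delta, minutes, od600)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "design_id", "enzyme", "replicate",
            "signal_start", "signal_end", "minutes", "od600",
        ],
    )


def simulate_plate_counts(
    composition: pd.Series,
    matrix: PhenotypeMatrix,
    conditions: Sequence[tuple[int, str]],
    noise: NoiseModel,
    slow_counts_as_growth: bool = False,
    exact: bool = False,
    rng: np.random.Generator | None = None,
) -> list[PlatingObservation]:
    """Colony counts on each plating condition.

    Models plating the same sample volume on every plate: the volume
    contains ``count_total`` cells drawn multinomially from the full
    composition, and only the species able to grow under the condition
    form colonies — the rest are unobserved, so a selective plate's total
    count shrinks with the summed abundance of its growers. Cross-plate
    count magnitudes therefore carry abundance information (this is what
    makes a one-species plate such as cetrimide/B. multivorans a direct
    census of that species). ``exact=True`` returns the (fractional)
    expected counts instead of a draw — the zero-noise limit used for
    round-trip tests. Conditions under which no present species grows
    yield a zero-count observation flagged ``no_growth``.
    """
    rng = rng if rng is not None else noise.rng()
    observations = []
    all_species = [ab for ab in composition.index]
    probs_all = np.clip(composition.to_numpy(dtype=float), 0.0, None)
    probs_all = probs_all / probs_all.sum()
    for condition in conditions:
        growers = predict_growth(matrix, condition, slow_counts_as_growth)
        grower_mask = np.array([ab in growers for ab in all_species])
        if not np.any(grower_mask & (probs_all > 0)):
            observations.append(
                PlatingObservation(condition=condition, counts={}, no_growth=True)
            )
            continue
        if exact:
            per_species = noise.count_total * probs_all
        else:
            per_species = rng.multinomial(noise.count_total, probs_all).astype(float)
        counts: dict[str, float] = {}
        for ab, n, grows in zip(all_species, per_species, grower_mask):
            if not grows or n == 0:
                continue
            cls = matrix.colony_class[ab]
            counts[cls] = counts.get(cls, 0.0) + float(n)
        observations.append(
            PlatingObservation(condition=condition, counts=counts)
        )
    return observations
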