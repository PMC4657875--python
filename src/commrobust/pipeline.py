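"""End-to-end orchestration: simulate, convert, resolve, test, report.

``run_study`` drives a full in-silico replicate of the dropout study from
a single seedable configuration: generate the community and its designs,
simulate endpoint compositions and raw assay signals, convert signals to
activities, deconvolute plate counts into compositions, compute diversity
indices, expected-activity comparisons, Dunnett/Sidak statistics and the
robustness verdicts, and (optionally) write every stage table as a
provenance-stamped TSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assays import AssayConstants, convert_signal_table
from .datasets import SPECIES_ORDER, full_mix_proportions, minus_cg_proportions
from .designs import (
    CommunityDesign,
    ROLE_DROPOUT,
    build_designs,
    designs_table,
    interaction_capacity,
    k_subset_interactions,
)
from .diversity import diversity_report, equitability, shannon_index, simpson_index
from .io import write_tsv
from .nullmodel import build_nullmodel_table
from .plating import DEFAULT_SCHEME, load_phenotype_matrix, resolve_composition
from .stats import (
    classify_robustness,
    dunnett_vs_reference,
    sidak_composition_test,
)
from .synthetic import (
    ENZYME_CLASSES,
    NoiseModel,
    default_interaction_matrix,
    generate_default_profiles,
    simulate_assay_readouts,
    simulate_endpoint_composition,
    simulate_plate_counts,
)

__all__ = ["RunConfig", "StudyResult", "run_study", "report_characterization"]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of one study run."""

    seed: int = 0
    n_replicates: int = 9  # three experiments x three biological replicates
    n_composition_replicates: int = 3
    per_member_od: float = 0.05
    activity_cv: float = 0.15
    composition_cv: float = 0.08
    count_total: int = 500
    mixing_rule: str = "dominant"
    regulation_override: dict | None = None  # enzyme -> factor; None = defaults
    use_activity_effects: bool = True
    convention: str = "literal_divide"
    weighting: str = "input_proportions"
    alpha: float = 0.05
    epsilon_nitrophenol: float = 17700.0
    pathlength_cm: float = 1.0
    outdir: str | None = None

    def config_hash(self) -> str:
        # hash the scientific parameters only: where outputs land must not
        # change what they contain
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    def assay_constants(self) -> AssayConstants:
        return AssayConstants(
            epsilon_nitrophenol=self.epsilon_nitrophenol,
            pathlength_cm=self.pathlength_cm,
        )

    def noise(self, seed: int | None = None) -> NoiseModel:
        return NoiseModel(
            activity_cv=self.activity_cv,
            composition_cv=self.composition_cv,
            count_total=self.count_total,
            seed=self.seed if seed is None else seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class StudyResult:
    """All stage outputs of one run."""

    config: RunConfig
    designs: list[CommunityDesign]
    signals: pd.DataFrame
    activities: pd.DataFrame
    composition_estimates: dict[str, pd.DataFrame]  # design -> replicate rows
    resolved_compositions: dict[str, pd.Series]  # design -> mean proportions
    diversity: pd.DataFrame
    nullmodel: pd.DataFrame
    dunnett: pd.DataFrame
    sidak: pd.DataFrame
    verdicts: pd.DataFrame

    def verdict_for(self, enzyme: str) -> tuple[bool, tuple[str, ...]]:
        row = self.verdicts.set_index("enzyme").loc[enzyme]
        offending = tuple(x for x in str(row["offending_designs"]).split("+") if x)
        return bool(row["robust"]), offending


def _spawned_seeds(seed: int, n: int) -> list[int]:
    # independent child streams, all reproducible from the run seed
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def run_study(config: RunConfig) -> StudyResult:
    """Execute every stage of the study; deterministic given the seed."""
    profiles = generate_default_profiles()
    interactions = default_interaction_matrix()
    matrix = load_phenotype_matrix()
    designs = build_designs(list(SPECIES_ORDER), config.per_member_od)
    constants = config.assay_constants()

    seeds = _spawned_seeds(config.seed, 3)
    rng_assay = np.random.default_rng(seeds[0])
    rng_comp = np.random.default_rng(seeds[1])
    rng_plate = np.random.default_rng(seeds[2])
    noise = config.noise()

    # --- stage 1: endpoint compositions (noise-free community state) and
    # raw assay signals per design
    true_comp: dict[str, pd.Series] = {}
    signal_frames = []
    for design in designs:
        comp = simulate_endpoint_composition(profiles, design, interactions)
        true_comp[design.design_id] = comp
        signal_frames.append(
            simulate_assay_readouts(
                profiles, design, comp,
                noise=noise, n_replicates=config.n_replicates,
                mixing_rule=config.mixing_rule,
                regulation=config.regulation_override,
                activity_effects=None if config.use_activity_effects else {},
                constants=constants,
                rng=rng_assay,
            )
        )
    signals = pd.concat(signal_frames, ignore_index=True)

    # --- stage 2: signal -> activity conversion
    activities = convert_signal_table(signals, constants)

    # --- stage 3: differential plating of the full mix and the -Cg
    # community, replicate-wise, deconvoluted to composition estimates
    composition_estimates: dict[str, pd.DataFrame] = {}
    resolved: dict[str, pd.Series] = {}
    for design_id in ("Mix", "-Cg"):
        design = next(d for d in designs if d.design_id == design_id)
        rep_rows = []
        for rep in range(1, config.n_composition_replicates + 1):
            comp_rep = simulate_endpoint_composition(
                profiles, design, interactions, noise=noise, rng=rng_comp
            )
            observations = simulate_plate_counts(
                comp_rep, matrix, DEFAULT_SCHEME, noise, rng=rng_plate
            )
            estimate = resolve_composition(observations, matrix)
            for ab in SPECIES_ORDER:
                rep_rows.append(
                    (design_id, rep, ab, estimate.proportions[ab], estimate.se[ab])
                )
        frame = pd.DataFrame(
            rep_rows, columns=["design_id", "replicate", "abbrev", "proportion", "se"]
        )
        composition_estimates[design_id] = frame
        resolved[design_id] = frame.groupby("abbrev")["proportion"].mean()[
            list(SPECIES_ORDER)
        ]

    # --- stage 4: diversity indices of the resolved communities
    div_rows = []
    for design_id, comp in resolved.items():
        rep = diversity_report(comp.to_numpy())
        div_rows.append(
            (
                design_id, rep.shannon_h, rep.simpson_lambda, rep.gini_simpson,
                rep.inverse_simpson, rep.richness, rep.equitability_j,
            )
        )
    diversity = pd.DataFrame(
        div_rows,
        columns=[
            "design_id", "shannon_h", "simpson_lambda", "gini_simpson",
            "inverse_simpson", "richness", "equitability_j",
        ],
    )

    # --- stage 5: expected-activity null model. Input-proportion
    # weighting for every mixture; endpoint weighting for the two
    # communities with resolved compositions (the "-K" comparisons).
    nm_input = build_nullmodel_table(
        activities, designs, weightings=("input_proportions",)
    )
    nm_endpoint = build_nullmodel_table(
        activities, designs,
        endpoint_compositions=resolved,
        weightings=("endpoint_proportions",),
    )
    nullmodel = pd.concat([nm_input, nm_endpoint], ignore_index=True)

    # --- stage 6: many-to-one statistics per enzyme, robustness verdicts
    dropout_labels = [d.design_id for d in designs if d.role == ROLE_DROPOUT]
    dunnett_rows = []
    results_by_enzyme = {}
    for enzyme in ENZYME_CLASSES:
        sub = activities.query("enzyme == @enzyme")
        groups = {
            design_id: grp["value"].to_numpy()
            for design_id, grp in sub.groupby("design_id")
        }
        table = dunnett_vs_reference(groups, "Mix", alpha=config.alpha, rng=0)
        results_by_enzyme[enzyme] = table.comparisons
        for c in table.comparisons:
            dunnett_rows.append(
                (
                    enzyme, c.group_label, c.estimate, c.statistic,
                    c.p_adj, c.significance_tier, table.anova_f, table.anova_p,
                )
            )
    dunnett = pd.DataFrame(
        dunnett_rows,
        columns=[
            "enzyme", "design_id", "estimate", "statistic",
            "p_adj", "tier", "anova_f", "anova_p",
        ],
    )
    verdict_map = classify_robustness(results_by_enzyme, dropout_labels, config.alpha)
    verdicts = pd.DataFrame(
        {
            "enzyme": list(verdict_map),
            "robust": [v.robust for v in verdict_map.values()],
            "offending_designs": [
                "+".join(v.offending_designs) for v in verdict_map.values()
            ],
        }
    )

    # --- stage 7: +Cg vs -Cg composition comparison (two-way layout,
    # Sidak-adjusted per species)
    pivot = {
        design_id: frame.pivot(index="replicate", columns="abbrev", values="proportion")[
            list(SPECIES_ORDER)
        ]
        for design_id, frame in composition_estimates.items()
    }
    sidak_results = sidak_composition_test(
        pivot["Mix"], pivot["-Cg"], alpha=config.alpha
    )
    sidak = pd.DataFrame(
        {
            "abbrev": [c.group_label for c in sidak_results],
            "estimate": [c.estimate for c in sidak_results],
            "statistic": [c.statistic for c in sidak_results],
            "p_adj": [c.p_adj for c in sidak_results],
            "tier": [c.significance_tier for c in sidak_results],
        }
    )

    result = StudyResult(
        config=config,
        designs=designs,
        signals=signals,
        activities=activities,
        composition_estimates=composition_estimates,
        resolved_compositions=resolved,
        diversity=diversity,
        nullmodel=nullmodel,
        dunnett=dunnett,
        sidak=sidak,
        verdicts=verdicts,
    )
    if config.outdir is not None:
        _write_outputs(result)
    return result


def _write_outputs(result: StudyResult) -> None:
    outdir = Path(result.config.outdir)
    provenance = {
        "tool": f"commrobust {__version__}",
        "seed": result.config.seed,
        "config_hash": result.config.config_hash(),
    }
    write_tsv(designs_table(result.designs), outdir / "designs.tsv", provenance)
    write_tsv(result.signals, outdir / "community_signals.tsv", provenance)
    write_tsv(result.activities, outdir / "activities.tsv", provenance)
    comp = pd.concat(result.composition_estimates.values(), ignore_index=True)
    comp["pct"] = 100.0 * comp["proportion"]
    write_tsv(comp, outdir / "composition.tsv", provenance)
    write_tsv(result.diversity, outdir / "diversity.tsv", provenance)
    write_tsv(result.nullmodel, outdir / "nullmodel.tsv", provenance)
    write_tsv(result.dunnett, outdir / "stats_dropout.tsv", provenance)
    write_tsv(result.sidak, outdir / "stats_composition.tsv", provenance)
    write_tsv(result.verdicts, outdir / "robustness_verdicts.tsv", provenance)


def report_characterization() -> pd.DataFrame:
    """Recompute the community's characterization numbers from fixtures.

    Diversity and evenness of the reference endpoint compositions, the
    interaction combinatorics of a nine-member community, and the
    inoculation arithmetic of the equal-OD design.
    """
    plus = full_mix_proportions()
    minus = minus_cg_proportions()
    h_plus = shannon_index(plus.to_numpy())
    h_minus = shannon_index(minus.to_numpy())
    rows = [
        ("shannon_full_mix", h_plus),
        ("equitability_full_mix", equitability(h_plus, int((plus > 0).sum()))),
        ("simpson_lambda_full_mix", simpson_index(plus.to_numpy(), "lambda")),
        ("shannon_minus_cg", h_minus),
        ("equitability_minus_cg", equitability(h_minus, int((minus > 0).sum()))),
        ("equitability_from_h1.61_s8", equitability(1.61, 8)),
        ("interaction_capacity_n9", float(interaction_capacity(9))),
        ("interactions_2_to_3_members_n9", float(k_subset_interactions(9, 2, 3))),
        ("full_mix_total_od", build_designs(list(SPECIES_ORDER), 0.05)[0].total_od),
        ("design_count", float(len(build_designs(list(SPECIES_ORDER), 0.05)))),
    ]
    return pd.DataFrame(rows, columns=["quantity", "value"])
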