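"""Differential plating: growth prediction, identifiability, deconvolution."""

import numpy as np
import pytest

from commrobust.plating import (
    DEFAULT_SCHEME,
    PhenotypeMatrix,
    PlatingObservation,
    identifiability_check,
    load_phenotype_matrix,
    predict_growth,
    resolve_composition,
)
from commrobust.synthetic import NoiseModel, simulate_plate_counts


@pytest.fixture(scope="module")
def toy_matrix():
    """Three species, two selective conditions plus a permissive plate.

    A grows everywhere; B only on the permissive plate and condition c1;
    C only on the permissive plate, with a distinct colony color.
    """
    growth = {}
    levels = {
        "A": {"NS": "normal", "c1": "normal", "c2": "normal"},
        "B": {"NS": "normal", "c1": "normal", "c2": "none"},
        "C": {"NS": "normal", "c1": "none", "c2": "none"},
    }
    for ab, per_cond in levels.items():
        for supp, lvl in per_cond.items():
            growth[(ab, (30, supp))] = lvl
    return PhenotypeMatrix(
        growth, colony_class={"A": "white", "B": "white", "C": "blue"}
    )


class TestPredictGrowth:
    def test_cetrimide_37_selects_bm_only(self, phenotype_matrix):
        assert predict_growth(phenotype_matrix, (37, "Ct200")) == {"Bm"}

    def test_trimethoprim_37_strict(self, phenotype_matrix):
        assert predict_growth(phenotype_matrix, (37, "Tp100")) == {"Ss", "Sp", "Bc"}

    def test_slow_growers_included_on_request(self, phenotype_matrix):
        strict = predict_growth(phenotype_matrix, (30, "Gm25"))
        loose = predict_growth(phenotype_matrix, (30, "Gm25"), True)
        assert strict < loose and "Ri" in loose - strict

    def test_unknown_condition(self, phenotype_matrix):
        with pytest.raises(KeyError):
            predict_growth(phenotype_matrix, (42, "NS"))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeMatrix({}, {})


class TestIdentifiability:
    def test_default_scheme_resolves_all_nine(self, phenotype_matrix):
        report = identifiability_check(phenotype_matrix, DEFAULT_SCHEME)
        assert report.identifiable
        assert report.ambiguous_groups == ()

    def test_colony_class_needed_for_cg(self, phenotype_matrix):
        # without appearance information C. gleum's growth pattern on the
        # default panel is shared with C. metallidurans
        report = identifiability_check(
            phenotype_matrix, DEFAULT_SCHEME, use_colony_class=False
        )
        assert not report.identifiable
        assert any(
            "Cg" in grp and "Cm" in grp for grp in report.ambiguous_groups
        )

    def test_single_uninformative_condition(self, toy_matrix):
        # one permissive plate and no colony classes: all collide
        report = identifiability_check(
            toy_matrix, [(30, "NS")], use_colony_class=False
        )
        assert not report.identifiable
        assert len(report.ambiguous_groups[0]) == 3


class TestResolveComposition:
    def test_toy_back_substitution(self, toy_matrix):
        # truth A=0.5, B=0.3, C=0.2 in a 1000-cell plating volume
        obs = [
            PlatingObservation((30, "NS"), {"white": 800.0, "blue": 200.0}),
            PlatingObservation((30, "c1"), {"white": 800.0}),
            PlatingObservation((30, "c2"), {"white": 500.0}),
        ]
        est = resolve_composition(obs, toy_matrix)
        assert est.proportions == pytest.approx({"A": 0.5, "B": 0.3, "C": 0.2})

    def test_dilution_factor_scales_counts(self, toy_matrix):
        obs = [
            PlatingObservation((30, "NS"), {"white": 80.0, "blue": 20.0}, 10.0),
            PlatingObservation((30, "c1"), {"white": 800.0}),
            PlatingObservation((30, "c2"), {"white": 500.0}),
        ]
        est = resolve_composition(obs, toy_matrix)
        assert est.proportions == pytest.approx({"A": 0.5, "B": 0.3, "C": 0.2})

    def test_zero_noise_round_trip(
        self, profiles, interactions, phenotype_matrix, mix_design, minus_cg_design
    ):
        from commrobust.synthetic import simulate_endpoint_composition

        for design in (mix_design, minus_cg_design):
            comp = simulate_endpoint_composition(profiles, design, interactions)
            obs = simulate_plate_counts(
                comp, phenotype_matrix, DEFAULT_SCHEME,
                NoiseModel(count_total=1000), exact=True,
            )
            est = resolve_composition(obs, phenotype_matrix)
            for ab in comp.index:
                assert est.proportions[ab] == pytest.approx(comp[ab], abs=1e-12)

    def test_multinomial_estimates_near_unbiased(
        self, phenotype_matrix, reference_full_mix
    ):
        # 300 multinomial platings at 500 colonies each: the mean estimate
        # stays within one percentage point of the truth for every species
        # (non-negativity truncation biases the rarest species slightly up)
        rng = np.random.default_rng(11)
        noise = NoiseModel(count_total=500)
        species = list(reference_full_mix.index)
        sums = dict.fromkeys(species, 0.0)
        n_draws = 300
        for _ in range(n_draws):
            obs = simulate_plate_counts(
                reference_full_mix, phenotype_matrix, DEFAULT_SCHEME, noise, rng=rng
            )
            est = resolve_composition(obs, phenotype_matrix)
            for ab in species:
                sums[ab] += est.proportions[ab]
        for ab in species:
            bias = sums[ab] / n_draws - reference_full_mix[ab]
            assert abs(bias) < 0.01, f"{ab}: bias {bias:.4f}"

    def test_inconsistent_counts_rejected(self, toy_matrix):
        # blue colonies on a plate where no blue species can grow
        obs = [
            PlatingObservation((30, "NS"), {"white": 800.0, "blue": 200.0}),
            PlatingObservation((30, "c2"), {"white": 500.0, "blue": 2000.0}),
            PlatingObservation((30, "c1"), {"white": 800.0}),
        ]
        with pytest.raises(ValueError, match="inconsistent"):
            resolve_composition(obs, toy_matrix)

    def test_unidentifiable_panel_rejected(self, toy_matrix):
        obs = [PlatingObservation((30, "NS"), {"white": 900.0, "blue": 100.0})]
        with pytest.raises(ValueError, match="identif"):
            resolve_composition(obs, toy_matrix)

    def test_counts_validation(self):
        with pytest.raises(ValueError):
            PlatingObservation((30, "NS"), {"white": -1.0})
        with pytest.raises(ValueError):
            PlatingObservation((30, "NS"), {"white": 1.0}, dilution_factor=0.0)
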