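"""Forward-model generator: profiles, compositions, signals, plate counts."""

import numpy as np
import pandas as pd
import pytest

from commrobust.assays import convert_signal_table
from commrobust.datasets import SPECIES_ORDER
from commrobust.designs import CommunityDesign, ROLE_MIX, ROLE_MONOCULTURE
from commrobust.plating import DEFAULT_SCHEME
from commrobust.synthetic import (
    ENZYME_CLASSES,
    InteractionMatrix,
    NoiseModel,
    SpeciesProfile,
    community_activity,
    generate_default_profiles,
    simulate_assay_readouts,
    simulate_endpoint_composition,
    simulate_plate_counts,
)


class TestDefaultProfiles:
    def test_nine_profiles_with_expected_codes(self, profiles):
        assert set(profiles) == {"Rp", "Cm", "Cg", "Ri", "Ss", "Bm", "Pm", "Sp", "Bc"}
        assert len({p.abbrev for p in profiles.values()}) == 9

    @pytest.mark.parametrize("enzyme", ENZYME_CLASSES)
    def test_high_producer_trio_leads_every_class(self, profiles, enzyme):
        ranked = sorted(
            profiles, key=lambda ab: profiles[ab].intrinsic_activity[enzyme],
            reverse=True,
        )
        assert set(ranked[:3]) == {"Ss", "Bm", "Bc"}

    def test_cg_inoculum_density_offset(self, profiles):
        others = [
            np.log10(p.cfu_per_od) for ab, p in profiles.items() if ab != "Cg"
        ]
        offset = np.mean(others) - np.log10(profiles["Cg"].cfu_per_od)
        assert offset == pytest.approx(0.4)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            SpeciesProfile("x", "Xx", {"NPB": -1.0}, 1.0, 1e9, "white")
        with pytest.raises(ValueError):
            SpeciesProfile("x", "Xx", {"NPB": 1.0}, -0.1, 1e9, "white")
        with pytest.raises(ValueError):
            SpeciesProfile("x", "Xx", {"NPB": 1.0}, 1.0, 0.0, "white")

    def test_interaction_matrix_validation(self):
        with pytest.raises(ValueError):
            InteractionMatrix({("A", "B"): 0.0})
        with pytest.raises(ValueError):
            InteractionMatrix({("A", "A"): 2.0})


class TestEndpointComposition:
    def test_symmetric_community_is_uniform(self):
        profiles = {
            ab: SpeciesProfile(ab, ab, {"NPB": 1.0}, 1.0, 1e9, "white")
            for ab in "ABCDEFGHI"
        }
        design = CommunityDesign("Mix", ROLE_MIX, tuple("ABCDEFGHI"))
        comp = simulate_endpoint_composition(profiles, design)
        assert np.allclose(comp.to_numpy(), 1 / 9)

    def test_full_mix_matches_reference(
        self, profiles, interactions, mix_design, reference_full_mix
    ):
        comp = simulate_endpoint_composition(profiles, mix_design, interactions)
        assert comp["Cg"] == pytest.approx(0.2776, abs=0.001)
        for ab in SPECIES_ORDER:
            assert comp[ab] == pytest.approx(reference_full_mix[ab], abs=1e-9)

    def test_cg_removal_releases_bc(
        self, profiles, interactions, mix_design, minus_cg_design
    ):
        full = simulate_endpoint_composition(profiles, mix_design, interactions)
        dropped = simulate_endpoint_composition(profiles, minus_cg_design, interactions)
        assert dropped["Bc"] > full["Bc"]
        assert dropped["Cg"] == 0.0

    def test_excluded_species_exactly_zero_and_sum_one(
        self, profiles, interactions, minus_cg_design
    ):
        comp = simulate_endpoint_composition(
            profiles, minus_cg_design, interactions,
            noise=NoiseModel(seed=5, composition_cv=0.2),
        )
        assert comp["Cg"] == 0.0
        assert comp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fitness_monotonicity(self):
        # raising one species' fitness never lowers its endpoint share
        base = {
            ab: SpeciesProfile(ab, ab, {"NPB": 1.0}, w, 1e9, "white")
            for ab, w in zip("ABC", (1.0, 2.0, 3.0))
        }
        design = CommunityDesign("Mix", ROLE_MIX, ("A", "B", "C"))
        p_before = simulate_endpoint_composition(base, design)["A"]
        base["A"] = SpeciesProfile("A", "A", {"NPB": 1.0}, 1.5, 1e9, "white")
        p_after = simulate_endpoint_composition(base, design)["A"]
        assert p_after >= p_before

    def test_noise_determinism(self, profiles, interactions, mix_design):
        a = simulate_endpoint_composition(
            profiles, mix_design, interactions, noise=NoiseModel(seed=9)
        )
        b = simulate_endpoint_composition(
            profiles, mix_design, interactions, noise=NoiseModel(seed=9)
        )
        pd.testing.assert_series_equal(a, b)


class TestAssayReadouts:
    def test_monoculture_round_trip_exact(self, profiles):
        design = CommunityDesign("Ss-alone", ROLE_MONOCULTURE, ("Ss",))
        comp = pd.Series({ab: 1.0 if ab == "Ss" else 0.0 for ab in profiles})
        signals = simulate_assay_readouts(
            profiles, design, comp, noise=None, n_replicates=2
        )
        activities = convert_signal_table(signals)
        for enzyme in ENZYME_CLASSES:
            got = activities.query("enzyme == @enzyme")["value"].iloc[0]
            assert got == pytest.approx(
                profiles["Ss"].intrinsic_activity[enzyme], rel=1e-12
            )

    def test_zero_regulation_blanks_signals(
        self, profiles, interactions, mix_design
    ):
        comp = simulate_endpoint_composition(profiles, mix_design, interactions)
        regulation = {enz: 0.0 for enz in ENZYME_CLASSES}
        signals = simulate_assay_readouts(
            profiles, mix_design, comp, noise=None, regulation=regulation
        )
        assert (signals["signal_end"] == signals["signal_start"]).all()

    def test_replicate_cv_tracks_noise_model(self, profiles, interactions, mix_design):
        comp = simulate_endpoint_composition(profiles, mix_design, interactions)
        signals = simulate_assay_readouts(
            profiles, mix_design, comp,
            noise=NoiseModel(seed=2, activity_cv=0.2), n_replicates=9,
        )
        activities = convert_signal_table(signals)
        for _, grp in activities.groupby("enzyme"):
            cv = grp["value"].std(ddof=1) / grp["value"].mean()
            assert 0.1 <= cv <= 0.3

    def test_seed_determinism(self, profiles, interactions, mix_design):
        comp = simulate_endpoint_composition(profiles, mix_design, interactions)
        a = simulate_assay_readouts(
            profiles, mix_design, comp, noise=NoiseModel(seed=4)
        )
        b = simulate_assay_readouts(
            profiles, mix_design, comp, noise=NoiseModel(seed=4)
        )
        pd.testing.assert_frame_equal(a, b)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(activity_cv=-0.1)
        with pytest.raises(ValueError):
            NoiseModel(count_total=0)

    def test_unknown_mixing_rule(self, profiles, interactions, mix_design):
        comp = simulate_endpoint_composition(profiles, mix_design, interactions)
        with pytest.raises(ValueError):
            community_activity(profiles, mix_design, comp, "NPB", mixing_rule="magic")


class TestPlateCounts:
    def test_pure_culture_single_class(self, phenotype_matrix):
        comp = pd.Series({ab: 1.0 if ab == "Cg" else 0.0 for ab in SPECIES_ORDER})
        obs = simulate_plate_counts(
            comp, phenotype_matrix, [(30, "NS")], NoiseModel(seed=1, count_total=200)
        )
        assert set(obs[0].counts) == {"orange"}
        assert obs[0].total == 200

    def test_uniform_expected_counts_by_class(self, phenotype_matrix):
        comp = pd.Series(1 / 9, index=list(SPECIES_ORDER))
        obs = simulate_plate_counts(
            comp, phenotype_matrix, [(30, "NS")],
            NoiseModel(count_total=900), exact=True,
        )
        counts = obs[0].counts
        # white: Rp, Cm, Bm, Pm, Bc; yellow: Ss, Sp
        assert counts["white"] == pytest.approx(500.0)
        assert counts["yellow"] == pytest.approx(200.0)
        assert counts["orange"] == pytest.approx(100.0)
        assert counts["white_rough"] == pytest.approx(100.0)

    def test_cetrimide_censuses_bm(self, phenotype_matrix, reference_full_mix):
        obs = simulate_plate_counts(
            reference_full_mix, phenotype_matrix, [(37, "Ct200")],
            NoiseModel(count_total=1000), exact=True,
        )
        counts = obs[0].counts
        assert set(counts) == {"white"}
        assert counts["white"] == pytest.approx(
            1000 * reference_full_mix["Bm"]
        )

    def test_no_growth_flagged(self, phenotype_matrix):
        comp = pd.Series({ab: 1.0 if ab == "Pm" else 0.0 for ab in SPECIES_ORDER})
        obs = simulate_plate_counts(
            comp, phenotype_matrix, [(37, "NS")], NoiseModel(count_total=100)
        )
        assert obs[0].no_growth and obs[0].total == 0

    def test_multinomial_expectation(self, phenotype_matrix, reference_full_mix):
        rng = np.random.default_rng(12)
        noise = NoiseModel(count_total=500)
        totals = []
        for _ in range(400):
            obs = simulate_plate_counts(
                reference_full_mix, phenotype_matrix, [(37, "Ct200")], noise, rng=rng
            )
            totals.append(obs[0].total)
        expect = 500 * reference_full_mix["Bm"]
        sem = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - expect) < 3 * sem + 1e-9
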