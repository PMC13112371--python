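"""The synthetic study-area generator and planted archetypes."""

import numpy as np
import pandas as pd
import pytest

from healthnet import (AgglomerationSpec, SpecValidationError, StudyAreaSpec,
                       archetype_spec, generate_study_area, plant_structure,
                       read_panel, write_study_area)


def small_spec(**kw):
    defaults = dict(
        agglomerations=(AgglomerationSpec("X", 2, 1),),
        years=(2005, 2007), seed=0)
    defaults.update(kw)
    return StudyAreaSpec(**defaults)


class TestSpecValidation:
    def test_core_count_bounds(self):
        with pytest.raises(SpecValidationError, match="agglomerations"):
            small_spec(agglomerations=(AgglomerationSpec("X", 2, 3),)).validate()

    def test_years_span(self):
        with pytest.raises(SpecValidationError, match="years"):
            small_spec(years=(2005, 2006)).validate()

    def test_scale_parameters_positive(self):
        exc = pytest.raises(SpecValidationError, match="distance_median_km")
        with exc:
            small_spec(distance_median_km=-1.0).validate()

    def test_error_names_the_field(self):
        try:
            small_spec(travel_speed_kmh=0.0).validate()
        except SpecValidationError as e:
            assert e.field == "travel_speed_kmh"


class TestGenerate:
    def test_default_study_area_has_64_cities(self, default_study):
        assert default_study.spec.n_cities_total == 64
        counts = default_study.panel.membership.value_counts()
        assert counts.to_dict() == {"YRD": 26, "CY": 16, "BTH": 13, "PRD": 9}
        assert len(default_study.panel.cities) == 64

    def test_minimal_two_city_study(self):
        study = generate_study_area(small_spec())
        assert len(study.panel.values) == 2 * 3  # cities x years
        d = study.distances["X"]
        assert d.shape == (2, 2) and d.iloc[0, 1] > 0

    def test_same_seed_identical_output(self):
        s1 = generate_study_area(small_spec(seed=5))
        s2 = generate_study_area(small_spec(seed=5))
        pd.testing.assert_frame_equal(s1.panel.values, s2.panel.values)
        pd.testing.assert_frame_equal(s1.distances["X"], s2.distances["X"])
        assert np.array_equal(s1.reference_gravity["X"].values,
                              s2.reference_gravity["X"].values)

    def test_different_seeds_differ(self):
        s1 = generate_study_area(small_spec(seed=1))
        s2 = generate_study_area(small_spec(seed=2))
        assert not s1.panel.values.equals(s2.panel.values)

    @pytest.mark.parametrize("seed", range(5))
    def test_distance_matrices_symmetric_zero_diagonal(self, seed):
        study = generate_study_area(StudyAreaSpec(seed=seed))
        for mats in (study.distances, study.travel_times):
            for m in mats.values():
                a = m.to_numpy()
                assert np.allclose(a, a.T)
                assert np.allclose(np.diag(a), 0.0)

    def test_reference_gravity_strictly_positive_off_diagonal(self, default_study):
        for tensor in default_study.reference_gravity.values():
            n = len(tensor.cities)
            off = ~np.eye(n, dtype=bool)
            assert (tensor.values[:, off] > 0).all()

    def test_core_cities_have_elevated_indicators(self, default_study):
        panel = default_study.panel
        means = panel.values.groupby(level="city").mean()["beds"]
        for aggl, cores in default_study.truth["cores"].items():
            cities = panel.cities_of(aggl)
            others = [c for c in cities if c not in cores]
            assert means[cores].mean() > means[others].mean()

    def test_shock_year_dips_health_resources(self, default_study):
        beds = default_study.panel.values["beds"].groupby(level="year").mean()
        assert beds[2020] < beds[2019]
        # but the economy indicator keeps rising through the shock
        gdp = default_study.panel.values["gdp"].groupby(level="year").mean()
        assert gdp[2020] > gdp[2019]

    def test_rising_trend_before_2020(self, default_study):
        beds = default_study.panel.values["beds"].groupby(level="year").mean()
        assert beds[2019] > beds[2010] > beds[2005]

    def test_policy_pulse_years_have_more_documents(self, default_study):
        years = pd.Series([d.year for d in default_study.policies])
        pulse = years.isin([2015, 2016]).sum() / 2
        other = years[~years.isin([2015, 2016])].value_counts().mean()
        assert pulse > 2 * other

    def test_travel_times_consistent_with_distances(self, default_study):
        spec = default_study.spec
        for aggl in study_aggls(default_study):
            d = default_study.distances[aggl].to_numpy()
            t = default_study.travel_times[aggl].to_numpy()
            base = d / spec.travel_speed_kmh
            off = ~np.eye(d.shape[0], dtype=bool)
            assert (t[off] >= base[off] - 1e-12).all()
            assert (t[off] <= base[off] + spec.travel_time_noise_h + 1e-12).all()


def study_aggls(study):
    return [a.name for a in study.spec.agglomerations]


class TestPlant:
    def test_unipolar_has_exactly_one_dominant_multiplier(self):
        study = plant_structure(archetype_spec("unipolar", seed=3), "unipolar")
        mult = study.truth["multipliers"]["BTH"]
        top = max(mult.values())
        assert sum(1 for v in mult.values() if v == top) == 1
        assert all(v < top for c, v in mult.items() if c != "BTH-01")

    def test_dual_core_hub_trends_nearly_uncorrelated(self):
        study = plant_structure(archetype_spec("dual_core_segmented", seed=4),
                                "dual_core_segmented")
        pats = study.truth["hub_patterns"]["CY"]
        h1, h2 = (np.asarray(pats[c]) for c in study.truth["cores"]["CY"])
        r = np.corrcoef(h1, h2)[0, 1]
        assert abs(r) < 0.05

    def test_incompatible_core_count_rejected(self):
        spec = StudyAreaSpec(agglomerations=(AgglomerationSpec("X", 10, 1),))
        with pytest.raises(ValueError, match="core"):
            plant_structure(spec, "polycentric")

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError, match="archetype"):
            plant_structure(archetype_spec("unipolar"), "hexagonal")

    def test_truth_records_archetype_label(self):
        study = plant_structure(archetype_spec("core_periphery", seed=0),
                                "core_periphery")
        assert study.truth["labels"] == {"PRD": "core_periphery"}

    def test_dual_core_camps_are_spatially_segmented(self):
        study = plant_structure(archetype_spec("dual_core_segmented", seed=0),
                                "dual_core_segmented")
        camps = study.truth["camps"]["CY"]
        d = study.distances["CY"]
        same, cross = [], []
        cities = list(d.index)
        for i, ci in enumerate(cities):
            for cj in cities[i + 1:]:
                (same if camps[ci] == camps[cj] else cross).append(d.loc[ci, cj])
        assert np.mean(cross) > 2 * np.mean(same)


class TestRoundTrip:
    def test_write_and_read_panel(self, tmp_path):
        study = generate_study_area(small_spec())
        paths = write_study_area(study, tmp_path)
        panel = read_panel(paths["panel"])
        pd.testing.assert_frame_equal(panel.values, study.panel.values)
        assert panel.membership.to_dict() == study.panel.membership.to_dict()
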