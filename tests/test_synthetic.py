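import hashlib
from pathlib import Path

import numpy as np
import pytest

from snakevuln import oracle
from snakevuln.mess import MESS_NEGATIVE, MESS_POSITIVE
from snakevuln.synthetic import (
    LABEL_INSIDE,
    LABEL_OUT_EXTRAP,
    LABEL_OUT_INTERP,
    Scenario,
    ScenarioSpec,
    expected_vulnerable_population,
    generate_covariates,
    generate_scenario,
    read_scenario,
    write_scenario,
)


def tree_digest(d: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(d.rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(d)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestCovariates:
    def test_band_count_and_determinism(self):
        spec = ScenarioSpec(seed=9)
        a = generate_covariates(spec, np.random.default_rng(9))
        b = generate_covariates(spec, np.random.default_rng(9))
        assert len(a.bands) == spec.n_bands
        for name in a.band_names:
            np.testing.assert_array_equal(a.bands[name], b.bands[name], strict=True)

    def test_nodata_strip(self):
        spec = ScenarioSpec(seed=9)
        stack = generate_covariates(spec, np.random.default_rng(9))
        valid = stack.valid_mask()
        assert not valid[:, -spec.nodata_cols :].any()
        assert valid[:, : -spec.nodata_cols].all()


class TestPlantedGroundTruth:
    def test_training_envelope_matches_planted_records(self, scenario):
        """The envelope of covariate values at planted inside records equals
        a direct min/max scan of those cells."""
        gt = scenario.ground_truth["species"]["sp03"]
        cells = [
            scenario.grid.cell_of(r["lon"], r["lat"])
            for r in gt["records"]
            if r["label"] == LABEL_INSIDE
        ]
        for name, band in scenario.covariates.bands.items():
            vals = [band[r, c] for r, c in cells]
            assert min(vals) <= max(vals)
            assert np.isfinite(vals).all()

    def test_planted_interp_extrap_counts_recovered(self, scenario, result):
        for sid, gt in scenario.ground_truth["species"].items():
            labels = result.outside_labels.get(sid, [])
            assert labels.count(MESS_POSITIVE) == gt["n_outside_interp"]
            assert labels.count(MESS_NEGATIVE) == gt["n_outside_extrap"]

    def test_amendment_count_matches_plan(self, scenario, result):
        assert result.summary["n_amended_species"] == scenario.ground_truth["n_amendable"]
        assert scenario.ground_truth["n_amendable"] == 7  # default plan

    def test_zero_interp_species_keep_eor(self, scenario, result):
        for sid, gt in scenario.ground_truth["species"].items():
            if gt["n_outside_interp"] == 0:
                assert result.range_geometries[sid].equals(scenario.eors[sid].geometry)

    def test_record_labels_against_oracle_formula(self, scenario):
        """Every planted outside label agrees with a direct evaluation of
        the similarity formula at the record's cell."""
        bands = [scenario.covariates.bands[n] for n in scenario.covariates.band_names]
        for sid, gt in scenario.ground_truth["species"].items():
            inside_cells = [
                scenario.grid.cell_of(r["lon"], r["lat"])
                for r in gt["records"]
                if r["label"] == LABEL_INSIDE
            ]
            training = [[float(b[r, c]) for r, c in inside_cells] for b in bands]
            for rec in gt["records"]:
                if rec["label"] == LABEL_INSIDE:
                    continue
                r, c = scenario.grid.cell_of(rec["lon"], rec["lat"])
                score = oracle.min_mess_score([float(b[r, c]) for b in bands], training)
                if rec["label"] == LABEL_OUT_INTERP:
                    assert score >= 0.0
                else:
                    assert score < 0.0


class TestHealthLayers:
    def test_population_totals_conserved(self, scenario):
        gt = scenario.ground_truth
        assert scenario.population.values.sum() == pytest.approx(gt["population_total"])
        per_admin = gt["per_admin_population"]
        assert sum(per_admin.values()) == pytest.approx(gt["population_total"])
        for cid, total in gt["per_country_population"].items():
            expected = sum(v for u, v in per_admin.items() if u.startswith(cid))
            assert total == pytest.approx(expected)

    def test_travel_cell_counts(self, scenario):
        gt = scenario.ground_truth
        assert int((scenario.travel.values > 60).sum()) == gt["travel_gt60_cells"]
        assert int((scenario.travel.values > 180).sum()) == gt["travel_gt180_cells"]
        assert gt["travel_gt180_cells"] <= gt["travel_gt60_cells"]

    def test_forced_strata_present(self, scenario):
        gt = scenario.ground_truth
        assert gt["scene_country_deciles"]["C01"] == 1
        assert gt["scene_country_deciles"]["C06"] == 10
        assert gt["per_admin_travel_min"]["C01A1"] == 240.0
        assert scenario.antivenom["sp01"] is False


class TestDeterminismAndRoundTrip:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        write_scenario(generate_scenario(ScenarioSpec(seed=11)), a)
        write_scenario(generate_scenario(ScenarioSpec(seed=11)), b)
        assert tree_digest(a) == tree_digest(b)

    def test_different_seed_differs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        write_scenario(generate_scenario(ScenarioSpec(seed=11)), a)
        write_scenario(generate_scenario(ScenarioSpec(seed=12)), b)
        assert tree_digest(a) != tree_digest(b)

    def test_roundtrip_preserves_layers(self, tmp_path, scenario):
        d = tmp_path / "scen"
        write_scenario(scenario, d)
        back = read_scenario(d)
        np.testing.assert_array_equal(back.population.values, scenario.population.values)
        np.testing.assert_array_equal(back.travel.values, scenario.travel.values)
        for name in scenario.covariates.band_names:
            np.testing.assert_array_equal(
                back.covariates.bands[name], scenario.covariates.bands[name]
            )
        assert back.grid == scenario.grid
        assert back.antivenom == scenario.antivenom
        assert {s.species_id for s in back.species} == {s.species_id for s in scenario.species}
        assert len(back.occurrences) == len(scenario.occurrences)


class TestOracleReport:
    def test_empty_snake_scenario_zero_report(self, scenario):
        empty = Scenario(
            spec=scenario.spec,
            config=scenario.config,
            grid=scenario.grid,
            covariates=scenario.covariates,
            species=[],
            occurrences=[],
            eors={},
            antivenom={},
            haq_units=scenario.haq_units,
            admin_units=scenario.admin_units,
            population=scenario.population,
            travel=scenario.travel,
            ground_truth={
                "species": {},
                "scene_country_deciles": scenario.ground_truth["scene_country_deciles"],
            },
        )
        rep = expected_vulnerable_population(empty)
        assert rep["grand_total_all"] == 0.0
        assert rep["population_in_range_all"] == 0.0

    def test_report_monotone_between_strata(self, scenario):
        rep = scenario.ground_truth["report"]
        assert rep["grand_total_no_therapy"] <= rep["grand_total_all"]
        assert rep["grand_total_all"] <= rep["population_in_range_all"]
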