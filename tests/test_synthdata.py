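"""Generator tests: design counts, determinism, injected-effect recovery, nulls."""

import numpy as np
import pytest

from phenoheat import morphometry as mm
from phenoheat import stats as phs
from phenoheat import synthdata as sd


class TestBuildDesign:
    def test_full_screen_dimensions(self):
        design = sd.build_design(20, seed=1)
        assert len(design.plants) == 160
        assert design.n_trays == 8
        trays = {}
        for p in design.plants:
            trays.setdefault(p.tray, []).append(p)
        assert all(len(v) == 20 for v in trays.values())
        # balanced genotypes within each tray
        for v in trays.values():
            assert sum(p.genotype == "WT" for p in v) == 10

    def test_minimal_design(self):
        design = sd.build_design(1, seed=0)
        assert len(design.plants) == 8
        assert design.n_trays == 1

    def test_deterministic(self):
        a = sd.build_design(20, seed=5)
        b = sd.build_design(20, seed=5)
        assert [p.plant_id for p in a.plants] == [p.plant_id for p in b.plants]
        assert [p.tolerance_latent for p in a.plants] == [
            p.tolerance_latent for p in b.plants
        ]

    def test_invalid_reps(self):
        with pytest.raises(ValueError):
            sd.build_design(0, seed=0)

    def test_alive_flag_monotone(self):
        plant = sd.PlantRecord("P1", "WT", "HS9h", 1, 1, 0.5, death_das=2)
        assert plant.alive(1) and not plant.alive(2) and not plant.alive(5)


class TestLightProtocol:
    def test_defaults(self):
        lp = sd.LightProtocol()
        assert lp.actinic_intensities == (95.0, 210.0, 320.0, 440.0, 555.0, 670.0)
        assert lp.dark_adaptation_min == 15
        assert lp.n_steps == 6

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            sd.LightProtocol(actinic_intensities=(95, 95, 320))


class TestSimulateExperiment:
    def test_deterministic(self):
        params = sd.SimulationParams(seed=4)
        a = sd.simulate_experiment(sd.build_design(4, 4), params)
        b = sd.simulate_experiment(sd.build_design(4, 4), params)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert sa == sb

    def test_expected_deaths_under_severe_stress(self):
        """40 plants at death probability 0.1 -> about 4 deaths on average."""
        deaths = []
        for seed in range(30):
            params = sd.SimulationParams(seed=seed)
            design = sd.build_design(20, seed)
            sd.simulate_experiment(design, params)
            deaths.append(sum(p.death_das is not None for p in design.plants))
            assert all(
                p.death_das is None
                for p in design.plants
                if p.treatment != "HS9h"
            )
        mean = np.mean(deaths)
        assert 4.0 - 1.2 <= mean <= 4.0 + 1.2  # binomial SE ~0.35 over 30 reps

    def test_dead_plants_emit_no_further_states(self):
        params = sd.SimulationParams(seed=0, death_probability_hs9h=1.0)
        design = sd.build_design(3, 0)
        states = sd.simulate_experiment(design, params)
        dead = [p.plant_id for p in design.plants if p.death_das == 0]
        assert dead  # probability 1 under HS9h
        for s in states:
            if s.plant_id in dead:
                assert s.das < 0

    def test_zero_penalty_null_effect(self):
        """All stress knobs off: treated-vs-control rejection rate nominal.

        Traits derived from the same raw signals are correlated within a
        plant-day, so pooled counts are not binomial; instead the rejection
        rate is computed per independent replicate experiment (>= 50
        trait x day tests each) and the replicate-mean rate must cover
        alpha = 0.05 within its own t-interval.
        """
        from phenoheat import fluortraits as ft

        rates = []
        for rep in range(8):
            params = sd.null_params(seed=100 + rep)
            design = sd.build_design(10, 100 + rep)
            records = []
            for j, s in enumerate(sd.simulate_experiment(design, params)):
                raw = sd.simulate_fluorescence_day(s, design.light_protocol, params, seed=j)
                records.append(
                    {
                        "plant_id": s.plant_id,
                        "genotype": s.genotype,
                        "treatment": s.treatment,
                        "das": s.das,
                        "traits": ft.fluor_trait_dict(raw),
                    }
                )
            from phenoheat.fluortraits import assemble_trait_table

            tests = phs.treated_vs_control_tests(assemble_trait_table(records))
            assert len(tests) >= 50
            rates.append(float((tests["p"] < 0.05).mean()))
        mean = np.mean(rates)
        half = 2.36 * np.std(rates, ddof=1) / np.sqrt(len(rates))  # t(7), 95%
        assert mean - half <= 0.05 <= mean + half

    def test_stress_monotonically_reduces_final_area(self):
        params = sd.SimulationParams(seed=3, growth_noise_sd=0.0, vigor_sd=0.0)
        design = sd.build_design(12, 3)
        states = sd.states_frame(sd.simulate_experiment(design, params))
        final = states[states.das == 7].groupby("treatment")["true_area_mm2"].mean()
        assert final["control"] > final["HS3h"] > final["HS6h"] > final["HS9h"]

    def test_area_penalty_recovered_within_20pct(self):
        """Inverting the daily logistic step recovers the configured penalty.

        For the logistic growth map, r = log((K/A_d - 1)/(K/A_{d+1} - 1)),
        so per-plant daily rates are directly estimable; the group-mean
        post-stress rate deficit must match the configured per-treatment
        penalty within +-20% at n = 20 plants per group.
        """
        params = sd.SimulationParams(seed=6)
        design = sd.build_design(20, 6)
        states = sd.states_frame(sd.simulate_experiment(design, params))
        kept = {p.plant_id for p in design.plants if not p.excluded}
        wt = states[
            states.plant_id.isin(kept) & (states.genotype == "WT") & (states.das >= 0)
        ].sort_values(["plant_id", "das"])
        k_cap = params.carrying_capacity_mm2
        rates = {}
        for treat, grp in wt.groupby("treatment"):
            per_day = []
            for _, traj in grp.groupby("plant_id"):
                a = traj["true_area_mm2"].to_numpy()
                per_day.extend(np.log((k_cap / a[:-1] - 1.0) / (k_cap / a[1:] - 1.0)))
            rates[treat] = float(np.mean(per_day))
        for treat in ("HS3h", "HS6h", "HS9h"):
            recovered = 1.0 - rates[treat] / rates["control"]
            assert recovered == pytest.approx(params.growth_penalty[treat], rel=0.2)

    def test_decoupled_tolerance_gives_null_correlation(self):
        """tolerance_coupling = 0: within-stratum Fq-area correlation ~ 0."""
        from phenoheat import fluortraits as ft

        params = sd.SimulationParams(seed=8, tolerance_coupling=0.0)
        design = sd.build_design(60, 8)
        states = sd.simulate_experiment(design, params)
        fq0, a7 = {}, {}
        for j, s in enumerate(states):
            if s.treatment != "HS6h" or s.genotype != "WT":
                continue
            if s.das == 0:
                raw = sd.simulate_fluorescence_day(s, design.light_protocol, params, seed=j)
                fq0[s.plant_id] = ft.fluor_trait_dict(raw)["Fq_Lss5"]
            elif s.das == 7:
                a7[s.plant_id] = s.true_area_mm2
        common = sorted(set(fq0) & set(a7))
        r, _, n = phs.pearson_r_p(
            np.array([fq0[p] for p in common]), np.array([a7[p] for p in common])
        )
        assert n >= 50
        assert abs(r) < 2.5 / np.sqrt(n)  # within Monte-Carlo error of zero


class TestRenderMask:
    @staticmethod
    def _state(area=400.0, n_leaves=9, aspect=2.6, openness=0.45):
        return sd.PlantDayState(
            plant_id="P1", genotype="WT", treatment="control", das=0, alive=True,
            true_area_mm2=area, qymax_true=0.8, fm_factor=1.0, qp_scale=1.0,
            npq_scale=1.0, leaf_temp_offset_c=0.0, n_leaves=n_leaves,
            leaf_aspect=aspect, openness=openness, vigor=1.0, tolerance=0.5,
        )

    def test_pixel_area_matches_true_area(self):
        mask = sd.render_rosette_mask(self._state(400.0), grid=(120, 120), scale=0.5, seed=1)
        assert mask.pixel_count == pytest.approx(1600, rel=0.05)

    def test_single_round_leaf_is_near_disk(self):
        mask = sd.render_rosette_mask(
            self._state(300.0, n_leaves=1, aspect=1.0), grid=(100, 100), scale=0.6, seed=2
        )
        ecc, iso = mm.moment_shape(mask)
        assert ecc < 0.1
        assert iso > 0.95

    def test_bit_identical_for_same_state_and_seed(self):
        a = sd.render_rosette_mask(self._state(), seed=7)
        b = sd.render_rosette_mask(self._state(), seed=7)
        assert np.array_equal(a.grid, b.grid)

    def test_overflow_raises(self):
        with pytest.raises(sd.RenderOverflowError):
            sd.render_rosette_mask(self._state(5000.0), grid=(40, 40), scale=0.5, seed=0)

    def test_higher_aspect_raises_slenderness(self):
        slim = sd.render_rosette_mask(self._state(aspect=3.5), seed=3)
        fat = sd.render_rosette_mask(self._state(aspect=1.6), seed=3)
        assert mm.slenderness_of_leaves(slim) > mm.slenderness_of_leaves(fat)


class TestSimulateFluorescence:
    @staticmethod
    def _state(**kw):
        return TestRenderMask._state(**kw)

    def test_zero_noise_recovers_configured_baseline(self):
        params = sd.SimulationParams(fluor_noise_sd=0.0)
        raw = sd.simulate_fluorescence_day(self._state(), sd.LightProtocol(), params, seed=0)
        qymax = (raw.fm - raw.f0) / raw.fm
        assert qymax == pytest.approx(0.8, abs=1e-12)

    def test_six_step_protocol_emits_six_triplets(self):
        params = sd.SimulationParams()
        raw = sd.simulate_fluorescence_day(self._state(), sd.LightProtocol(), params, seed=1)
        assert len(raw.steps) == 6

    def test_fmprime_decreases_with_light_and_stress(self):
        params = sd.SimulationParams(fluor_noise_sd=0.0)
        control = self._state()
        stressed = self._state()
        stressed.fm_factor = 0.7
        stressed.qymax_true = 1.0 - 0.2 / 0.7
        raw_c = sd.simulate_fluorescence_day(control, sd.LightProtocol(), params, seed=2)
        raw_s = sd.simulate_fluorescence_day(stressed, sd.LightProtocol(), params, seed=2)
        fmp_c = [s.fmp for s in raw_c.steps]
        fmp_s = [s.fmp for s in raw_s.steps]
        assert all(a > b for a, b in zip(fmp_c, fmp_c[1:]))  # monotone in light
        assert all(s < c for s, c in zip(fmp_s, fmp_c))  # depressed under stress

    def test_signals_valid_across_random_states(self):
        from phenoheat import fluortraits as ft

        params = sd.SimulationParams(seed=0)
        design = sd.build_design(4, 0)
        for j, state in enumerate(sd.simulate_experiment(design, params)):
            raw = sd.simulate_fluorescence_day(state, design.light_protocol, params, seed=j)
            assert ft.validate_raw(raw) == []


class TestSimulateThermal:
    def test_offset_recovery(self):
        """Injected +1.5 degC offset is recovered by mask-mean extraction."""
        params = sd.SimulationParams(thermal_pixel_noise_sd=0.1, plant_temp_noise_sd=0.0)
        state_c = TestRenderMask._state()
        state_s = TestRenderMask._state()
        state_s.leaf_temp_offset_c = 1.5
        mask = sd.render_rosette_mask(state_c, seed=4)
        t_c = mm.rosette_temperature(mask, sd.simulate_thermal_day(mask, state_c, params, seed=5))
        t_s = mm.rosette_temperature(mask, sd.simulate_thermal_day(mask, state_s, params, seed=6))
        assert t_s - t_c == pytest.approx(1.5, abs=0.05)

    def test_null_offset(self):
        params = sd.SimulationParams(thermal_pixel_noise_sd=0.05, plant_temp_noise_sd=0.0)
        state = TestRenderMask._state()
        mask = sd.render_rosette_mask(state, seed=4)
        t1 = mm.rosette_temperature(mask, sd.simulate_thermal_day(mask, state, params, seed=8))
        t2 = mm.rosette_temperature(mask, sd.simulate_thermal_day(mask, state, params, seed=9))
        assert t1 - t2 == pytest.approx(0.0, abs=0.05)

    def test_empty_mask_rejected(self):
        params = sd.SimulationParams()
        empty = mm.RosetteMask.__new__(mm.RosetteMask)
        object.__setattr__(empty, "grid", np.zeros((10, 10), dtype=bool))
        object.__setattr__(empty, "scale", 1.0)
        with pytest.raises(ValueError):
            sd.simulate_thermal_day(empty, TestRenderMask._state(), params, seed=0)


def test_invalid_params_rejected():
    p = sd.SimulationParams(death_probability_hs9h=1.5)
    with pytest.raises(ValueError):
        p.validate()
    p2 = sd.SimulationParams()
    p2.growth_penalty["HS6h"] = -0.1
    with pytest.raises(ValueError):
        p2.validate()
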