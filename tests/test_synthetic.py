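"""Determinism, layout arithmetic and zero-noise identities of the generator."""

import numpy as np
import pandas as pd
import pytest

from trquant.errors import ConfigError
from trquant.flow_io import ROLE_CONTROL_100, ROLE_SAMPLE, ROLE_UNTRANSFECTED
from trquant.gating import GateConfig, apply_gates
from trquant.readthrough import quantify_wells
from trquant.synthetic import (
    BLOT_TRUTH,
    FLOW_TRUTH,
    SimConfig,
    simulate_blot,
    simulate_plate_set,
    simulate_profile,
    simulate_well,
)


class TestDeterminism:
    def test_same_seed_same_well(self, small_simconfig):
        w1 = simulate_well(small_simconfig, ROLE_SAMPLE, 0.1, 0, 5)
        w2 = simulate_well(small_simconfig, ROLE_SAMPLE, 0.1, 0, 5)
        pd.testing.assert_frame_equal(w1.events, w2.events)

    def test_different_wells_differ(self, small_simconfig):
        w1 = simulate_well(small_simconfig, ROLE_SAMPLE, 0.1, 0, 5)
        w2 = simulate_well(small_simconfig, ROLE_SAMPLE, 0.1, 0, 6)
        assert not w1.events.equals(w2.events)

    def test_blot_and_profile_determinism(self):
        lanes1 = simulate_blot(0.1, seed=3)
        lanes2 = simulate_blot(0.1, seed=3)
        assert [l.intensity_fl for l in lanes1] == [l.intensity_fl for l in lanes2]
        p1 = simulate_profile("nuclear", seed=3)
        p2 = simulate_profile("nuclear", seed=3)
        np.testing.assert_array_equal(p1.flag_signal, p2.flag_signal)


class TestLayout:
    def test_single_group_layout(self, small_simconfig):
        records = simulate_plate_set(small_simconfig)
        samples = [r for r in records if r.role == ROLE_SAMPLE]
        assert len(samples) == 9  # 3 replicates x 3 experiment plates
        plates = {r.plate_id for r in records}
        assert len(plates) == 3
        for plate in plates:
            roles = [r.role for r in records if r.plate_id == plate]
            assert roles.count(ROLE_CONTROL_100) == 3
            assert roles.count("background_rfp_only") == 3
            assert roles.count(ROLE_UNTRANSFECTED) == 3

    def test_full_panel_group_count(self):
        cfg = SimConfig(n_events_per_well=10, seed=1)
        records = simulate_plate_set(cfg)
        groups = {
            (r.construct_id, r.treatment)
            for r in records
            if r.role == ROLE_SAMPLE
        }
        assert len(groups) == 28  # 14 constructs x 2 treatments
        per_plate = len([r for r in records if r.plate_id == "P1"])
        assert per_plate == 28 * 3 + 9  # 93 wells fits a 96-well plate

    def test_layout_overflow_rejected(self):
        oversized = {(f"c{i}", "none"): 0.01 for i in range(40)}
        cfg = SimConfig(truth_table=oversized, n_events_per_well=10)
        with pytest.raises(ConfigError):
            simulate_plate_set(cfg)

    def test_invalid_role_and_truth(self):
        with pytest.raises(ConfigError):
            simulate_well(SimConfig(n_events_per_well=10), "no-such-role")
        with pytest.raises(ConfigError):
            SimConfig(truth_table={("c", "none"): 1.5})


class TestZeroNoise:
    def test_tr_zero_gives_zero_gfp_on_transfected_events(self):
        cfg = SimConfig(
            truth_table={("c", "none"): 0.0}, n_events_per_well=500
        ).zero_noise()
        well = simulate_well(cfg, ROLE_SAMPLE, tr_true=0.0)
        transfected = well.events[well.events.rfp > 0]
        assert (transfected.gfp == 0).all()

    def test_control_events_read_gain_ratio_exactly(self):
        cfg = SimConfig(n_events_per_well=500).zero_noise()
        well = simulate_well(cfg, ROLE_CONTROL_100)
        transfected = well.events[well.events.rfp > 0]
        ratio = transfected.gfp / transfected.rfp
        np.testing.assert_allclose(ratio, cfg.gain_gfp / cfg.gain_rfp)

    def test_pipeline_recovers_truth_exactly(self):
        truth = {("a", "none"): 0.05, ("b", "geneticin"): 0.4}
        cfg = SimConfig(
            truth_table=truth, n_events_per_well=1_500, seed=2
        ).zero_noise()
        _, results = quantify_wells(simulate_plate_set(cfg))
        for r in results:
            assert r.mean_tr == pytest.approx(100 * truth[(r.construct_id, r.treatment)])
            assert r.sd_tr == pytest.approx(0.0, abs=1e-9)


class TestPopulations:
    def test_untransfected_events_fall_below_inclusion_thresholds(self, small_simconfig):
        cfg = SimConfig(
            truth_table=small_simconfig.truth_table,
            n_events_per_well=20_000,
            seed=4,
        )
        well = simulate_well(cfg, ROLE_UNTRANSFECTED)
        included = apply_gates(well.events, GateConfig())
        assert len(included) / len(well.events) < 0.01

    def test_packaged_truth_tables_cover_the_panel(self):
        constructs = {c for c, _ in FLOW_TRUTH}
        assert len(constructs) == 14
        assert all(0 <= v <= 1 for v in FLOW_TRUTH.values())
        assert all(0 <= v <= 1 for v in BLOT_TRUTH.values())


class TestBlotAndProfiles:
    def test_sigma_zero_returns_truth_exactly(self):
        from trquant.densitometry import blot_readthrough

        lanes = simulate_blot(0.37, n_replicates=3, sigma=0.0)
        assert all(blot_readthrough(l) == pytest.approx(0.37) for l in lanes)

    def test_truth_one_is_wildtype_like(self):
        lanes = simulate_blot(1.0, n_replicates=2, sigma=0.1)
        assert all(l.intensity_trunc == 0.0 for l in lanes)

    @pytest.mark.parametrize(
        "cls,low,high",
        [("nuclear", 4.0, np.inf), ("cytoplasmic", 0.0, 0.25), ("mixed", 1.0, 2.0)],
    )
    def test_profile_classes_by_construction(self, cls, low, high):
        from trquant.localization import nuclear_enrichment

        profile = simulate_profile(cls, seed=7, noise_sd=0.0)
        assert low <= nuclear_enrichment(profile) <= high

    def test_unknown_profile_class(self):
        with pytest.raises(ConfigError):
            simulate_profile("membrane")
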