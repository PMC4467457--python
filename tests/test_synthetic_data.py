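"""Tests for the synthetic panel / PBM / genome generators, including a
full-stack round trip through quantification and posterior inference."""

import numpy as np
import pytest

from sifted.ddg_inference import FitConfig, fit_ddg_posterior, fit_scaling
from sifted.energy_model import canonical_anchors
from sifted.synthetic_data import (
    SimulationConfig,
    TruthContextModel,
    default_truth,
    simulate_experiment,
    simulate_genome,
    simulate_panel,
    simulate_pbm,
    truth_em,
)
from sifted.tale_core import RVD_CODES, parse_rvd_string


class TestSimulatePanel:
    def test_deterministic_and_sized(self):
        cfg = SimulationConfig(panel_size=8, seed=5)
        p1 = simulate_panel(cfg)
        p2 = simulate_panel(cfg)
        assert [p.repeats for p in p1] == [p.repeats for p in p2]
        assert len(p1) == 8
        for p in p1:
            assert 9 <= p.n_elements <= 19  # element count within configured range

    def test_all_16_ordered_pairs_present(self):
        for seed in range(5):
            panel = simulate_panel(SimulationConfig(panel_size=6, seed=seed))
            pairs = set()
            for p in panel:
                reps = p.repeats
                pairs.update(zip(reps, reps[1:]))
            assert pairs == {(a, b) for a in RVD_CODES for b in RVD_CODES}

    def test_infeasible_coverage_rejected(self):
        cfg = SimulationConfig(panel_size=2, min_repeats=4.5, max_repeats=5.5)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_panel(cfg)

    def test_coverage_can_be_disabled(self):
        panel = simulate_panel(SimulationConfig(panel_size=2, min_repeats=4.5,
                                                max_repeats=5.5,
                                                pair_coverage=False))
        assert len(panel) == 2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(panel_size=1)
        with pytest.raises(ValueError):
            SimulationConfig(replicates=0)
        with pytest.raises(ValueError):
            SimulationConfig(bsi_scale=0.0)


class TestTruthEM:
    def test_anchored_and_floored(self, truth_model):
        protein = parse_rvd_string("NI-HD-NN-NG-NI-HD")
        em = truth_em(protein, truth_model, seed=3)
        assert em.is_anchored
        off = np.ones_like(em.values, dtype=bool)
        off[np.arange(em.length), em.anchors] = False
        assert em.values[off].min() >= truth_model.floor

    def test_seed_determinism(self, truth_model):
        protein = parse_rvd_string("NI-HD-NN-NG")
        e1 = truth_em(protein, truth_model, seed=4)
        e2 = truth_em(protein, truth_model, seed=4)
        e3 = truth_em(protein, truth_model, seed=5)
        np.testing.assert_array_equal(e1.values, e2.values)
        assert not np.array_equal(e1.values, e3.values)

    def test_zero_noise_matches_hand_arithmetic(self):
        truth = default_truth(noise_sd=0.0)
        protein = parse_rvd_string("NI-NN-NG")  # site TAGT, length 4
        em = truth_em(protein, truth, seed=0)
        # NTR (base C): baseline + C-neighbour NN... the NTR's C-neighbour is
        # the first repeat NI, so no adjustment applies
        assert em.values[0, 1] == pytest.approx(2.2)
        # repeat 1 = NI at position 1 with N-neighbour NTR, C-neighbour NN;
        # base C: baseline 2.6 + pos*1*(-0.03) + len*4*(-0.03)
        assert em.values[1, 1] == pytest.approx(2.6 - 0.03 - 0.12)
        # repeat 2 = NN at position 2 with N-neighbour NI (+0.5); base T:
        # 2.9 + 2*(-0.07) + 4*(-0.08) + 0.5
        assert em.values[2, 3] == pytest.approx(2.9 - 0.14 - 0.32 + 0.5)
        # repeat 3 (half repeat) = NG with C-neighbour CTR, no NG/CTR effect;
        # base A: 2.3 + 3*(-0.06) + 4*(-0.07)
        assert em.values[3, 0] == pytest.approx(2.3 - 0.18 - 0.28)

    def test_floor_applies_after_effects(self):
        truth = TruthContextModel(
            baseline={(t, b): 0.1 for t in ["NTR", "NI", "HD", "NN", "NG"]
                      for b in "ACGT"},
            noise_sd=0.0, floor=0.3,
        )
        em = truth_em(parse_rvd_string("NI-HD"), truth, seed=0)
        off = np.ones_like(em.values, dtype=bool)
        off[np.arange(em.length), em.anchors] = False
        np.testing.assert_allclose(em.values[off], 0.3)


class TestSimulatePBM:
    @pytest.fixture()
    def noiseless_cfg(self):
        return SimulationConfig(z_noise_sd=0.0, outlier_rate=0.0, dsdna_sd=0.0,
                                cy3_noise_sd=0.0, replicates=3, seed=2)

    def test_record_layout(self, truth_model):
        protein = parse_rvd_string("NI-HD-NN-NG-NI-HD-NN-NG")
        em = truth_em(protein, truth_model, seed=1)
        cfg = SimulationConfig(seed=1)
        records, variant_map = simulate_pbm(protein, em, cfg)
        n_fg = 12 * protein.site_length - 8
        assert sum(r.role == "foreground" for r in records) == n_fg
        assert sum(r.role == "background" for r in records) == cfg.n_background
        assert len(variant_map) == n_fg
        assert all(len(r.sequence) == 60 for r in records)
        assert all(len(r.alexa_bsi) == cfg.replicates for r in records)

    def test_seed_determinism(self, truth_model):
        protein = parse_rvd_string("NI-HD-NN-NG-NI-HD-NN-NG")
        em = truth_em(protein, truth_model, seed=1)
        cfg = SimulationConfig(seed=6)
        r1, _ = simulate_pbm(protein, em, cfg)
        r2, _ = simulate_pbm(protein, em, cfg)
        for a, b in zip(r1, r2):
            assert a.sequence == b.sequence
            np.testing.assert_array_equal(a.alexa_bsi, b.alexa_bsi)
            np.testing.assert_array_equal(a.cy3_bsi, b.cy3_bsi)

    def test_zero_noise_full_path_recovers_scaling(self, truth_model,
                                                   noiseless_cfg):
        # simulate -> quantify -> z-scores must reproduce the occupancy
        # model exactly, so the scaling fit returns the generating (mu, a, b)
        protein = parse_rvd_string("NI-HD-NN-NG-NI-HD-NN-NG-NI-HD")
        em = truth_em(protein, truth_model, seed=8)
        zmap = simulate_experiment(protein, em, noiseless_cfg)
        assert len(zmap) == 12 * protein.site_length - 8
        sites = sorted(zmap)
        fitted, r2 = fit_scaling(em, sites, np.array([zmap[s] for s in sites]))
        assert fitted.mu == pytest.approx(noiseless_cfg.mu, abs=1e-4)
        assert fitted.a == pytest.approx(noiseless_cfg.a, abs=1e-4)
        assert fitted.b == pytest.approx(noiseless_cfg.b, abs=1e-4)
        assert r2 == pytest.approx(1.0, abs=1e-9)


class TestSimulateGenome:
    def test_length_name_and_gc(self):
        g = simulate_genome(20000, gc=0.6, seed=1, name="chrQ")
        assert set(g) == {"chrQ"}
        seq = g["chrQ"]
        assert len(seq) == 20000
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.6, abs=0.02)

    def test_planting_both_strands(self):
        g = simulate_genome(100, planted=[("TACGT", 10, "+"), ("TACGT", 50, "-")],
                            seed=2)
        seq = g["chrSim"]
        assert seq[10:15] == "TACGT"
        assert seq[50:55] == "ACGTA"  # reverse complement written forward

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            simulate_genome(100, planted=[("TACGT", 10, "+"), ("AAAA", 12, "+")])

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            simulate_genome(20, planted=[("TACGT", 18, "+")])

    def test_gc_validated(self):
        with pytest.raises(ValueError, match="gc"):
            simulate_genome(10, gc=1.5)

    def test_seed_determinism(self):
        assert simulate_genome(500, seed=3) == simulate_genome(500, seed=3)


class TestFullStackRoundTrip:
    def test_noisy_simulation_map_inference_recovers_em(self, truth_model):
        # default (noisy) study conditions end to end: simulate the array,
        # quantify it, fit the posterior by MAP, compare to the truth EM
        protein = parse_rvd_string("NI-HD-NN-NG-NI-HD-NN-NG-NI-HD-NN")
        em = truth_em(protein, truth_model, seed=21)
        cfg = SimulationConfig(seed=21)
        zmap = simulate_experiment(protein, em, cfg)
        res = fit_ddg_posterior(protein, zmap, FitConfig(method="map"))
        free = np.array(canonical_anchors(protein))
        mask = np.ones_like(em.values, dtype=bool)
        mask[np.arange(len(free)), free] = False
        truth_vals = em.values[mask]
        fit_vals = res.mean_em.values[mask]
        rmse = np.sqrt(np.mean((fit_vals - truth_vals) ** 2))
        r = np.corrcoef(fit_vals, truth_vals)[0, 1]
        assert rmse < 0.3
        assert r > 0.9
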