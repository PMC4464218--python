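"""Study drivers: spread statistics, zero-noise collapse, scans, and the
cross-comparison convention."""

import numpy as np
import pandas as pd
import pytest

from noisecascade.core_models import HillParams
from noisecascade.experiments import (
    StudyConfig,
    blackbox_noiseless_reference,
    blackbox_prediction_study,
    blackbox_simulation_study,
    characterize_module,
    cross_compare,
    cv_across,
    extrinsic_sweep,
    max_pct_diff,
    sensitivity_scan,
)
from noisecascade.noise import NoiseSpec
from noisecascade.population_sim import SimulationConfig


class TestSpreadStatistics:
    def test_cv_uses_sample_std_convention(self):
        # printed "(1%)" only reproduces with the n-1 denominator
        assert cv_across([3.00, 3.04, 3.06]) == pytest.approx(1.0, abs=0.02)

    def test_cv_of_printed_eta_triplet(self):
        # ddof=1 CV of the printed estimates; ddof=0 would give 11.5
        assert cv_across([1.96, 1.65, 1.49]) == pytest.approx(14.06, abs=0.05)

    def test_cv_of_identical_values_is_zero(self):
        assert cv_across([2.2, 2.2, 2.2]) == 0.0

    def test_cv_errors(self):
        with pytest.raises(ValueError):
            cv_across([1.0])
        with pytest.raises(ValueError):
            cv_across([-1.0, 1.0])  # zero mean

    def test_max_pct_diff_from_printed_triplets(self):
        assert max_pct_diff([1.96, 1.65, 1.49], 2.0) == pytest.approx(25.5, abs=0.05)
        assert max_pct_diff([0.27, 0.30, 0.32], 0.2) == pytest.approx(60.0, abs=0.05)

    def test_max_pct_diff_zero_at_truth(self):
        assert max_pct_diff([0.5, 0.5], 0.5) == 0.0
        with pytest.raises(ValueError):
            max_pct_diff([1.0], 0.0)


class TestCharacterizeModule:
    def test_zero_noise_collapse(self, params):
        cfg = StudyConfig(
            gate=params["tetr_ptet"], noise_model="constant_cv",
            entities=(0.0, 0.0, 0.0),
            sim=SimulationConfig(n_cells=100, master_seed=3),
        )
        _, summary = characterize_module(cfg)
        for p in ("alpha", "k", "eta"):
            assert summary.cv[p] == pytest.approx(0.0, abs=1e-6)
            assert summary.max_diff[p] == pytest.approx(0.0, abs=1e-4)

    def test_headline_excludes_delta(self, params):
        cfg = StudyConfig(
            gate=params["tetr_ptet"],
            entities=(0.15, 0.55),
            sim=SimulationConfig(n_cells=500, master_seed=3),
        )
        _, summary = characterize_module(cfg)
        assert set(summary.headline_cv) == {"alpha", "k", "eta"}
        assert "delta" in summary.cv  # still reported

    def test_seed_stability_of_cv_statistics(self, params):
        """Headline CVs move by less than 2 percentage points across
        master seeds at the 10,000-cell study scale."""
        cvs = []
        for seed in (1, 2, 3, 4, 5):
            cfg = StudyConfig(
                gate=params["tetr_ptet"], noise_model="constant_cv",
                entities=(0.15, 0.55, 0.75),
                sim=SimulationConfig(master_seed=seed),
            )
            _, summary = characterize_module(cfg)
            cvs.append([summary.cv[p] for p in ("alpha", "k", "eta")])
        cvs = np.array(cvs)
        assert np.all(cvs.max(axis=0) - cvs.min(axis=0) < 2.0)

    def test_estimates_table_shape(self, params):
        cfg = StudyConfig(
            gate=params["laci_plac"], entities=(0.15, 0.55, 0.75),
            sim=SimulationConfig(n_cells=2000, master_seed=4),
        )
        _, summary = characterize_module(cfg)
        assert list(summary.estimates["entity"]) == [0.15, 0.55, 0.75]
        assert summary.estimates["converged"].all()


class TestScans:
    def test_sensitivity_anchor_reproduces_default_study(self, params):
        """The eta-scan grid point at the nominal eta=2 repeats the default
        TetR study and lands near its eta CV."""
        cfg = StudyConfig(
            gate=params["tetr_ptet"], sim=SimulationConfig(master_seed=1)
        )
        table = sensitivity_scan("eta", [2.0], cfg)
        assert table.loc[0, "cv_eta"] == pytest.approx(14.2, abs=2.5)

    def test_alpha_cv_small_across_k_grid(self, params):
        cfg = StudyConfig(
            gate=params["tetr_ptet"], sim=SimulationConfig(master_seed=1)
        )
        table = sensitivity_scan("k", [0.1, 0.5, 1.0, 2.0], cfg)
        assert (table["cv_alpha"] < 2.5).all()

    def test_zero_noise_scan_is_flat_zero(self, params):
        cfg = StudyConfig(
            gate=params["tetr_ptet"], entities=(0.0, 0.0, 0.0),
            sim=SimulationConfig(n_cells=100, master_seed=2),
        )
        table = sensitivity_scan("k", [0.2, 1.0], cfg)
        assert np.allclose(table[["cv_alpha", "cv_k", "cv_eta"]], 0.0, atol=1e-5)

    def test_unknown_parameter_rejected(self, params):
        cfg = StudyConfig(gate=params["tetr_ptet"])
        with pytest.raises(ValueError):
            sensitivity_scan("alpha", [1.0], cfg)

    def test_extrinsic_sweep_k_cv_declines_with_rho(self, params):
        cfg = StudyConfig(
            gate=params["tetr_ptet"],
            output2_noise=NoiseSpec(model="constant_cv", level=0.15),
            sim=SimulationConfig(master_seed=1),
        )
        table = extrinsic_sweep([0.0, 1.0], cfg)
        assert table.loc[0, "cv_k"] > table.loc[1, "cv_k"]


class TestBlackboxStudies:
    def test_prediction_with_identical_sets_has_zero_cv(self, params):
        tet = [params["tetr_ptet"]] * 3
        lac = [params["laci_plac"]] * 3
        _, _, cv = blackbox_prediction_study(tet, lac, params["input_device"])
        for p in ("alpha", "k", "eta"):
            assert cv[p] == pytest.approx(0.0, abs=1e-6)

    def test_zero_noise_simulation_reproduces_reference(self, params):
        ref = blackbox_noiseless_reference(
            params["input_device"], params["tetr_ptet"], params["laci_plac"]
        )
        _, estimates, cv = blackbox_simulation_study(
            params["input_device"], params["tetr_ptet"], params["laci_plac"],
            entities1=(0.0,), entities2=(0.0,),
            sim=SimulationConfig(n_cells=100, master_seed=0),
        )
        assert estimates.loc[0, "k"] == pytest.approx(ref.params.k, rel=1e-6)
        assert estimates.loc[0, "eta"] == pytest.approx(ref.params.eta, rel=1e-6)

    def test_kstar_grows_with_output2_noise(self, params, full_sim):
        """End-to-end half-effect estimates increase monotonically with the
        second noise site's entity at fixed OUTPUT1 noise."""
        _, estimates, _ = blackbox_simulation_study(
            params["input_device"], params["tetr_ptet"], params["laci_plac"],
            entities1=(0.15,), entities2=(0.15, 0.55, 0.75), sim=full_sim,
        )
        ks = estimates.sort_values("cv2")["k"].to_numpy()
        assert ks[0] < ks[1] < ks[2]

    def test_cross_compare_identical_sets_all_zero(self, params):
        ref = blackbox_noiseless_reference(
            params["input_device"], params["tetr_ptet"], params["laci_plac"]
        )
        comp = cross_compare([ref] * 3, [ref] * 3)
        for p in ("alpha", "delta", "k", "eta"):
            assert comp[p]["max_pct_diff"] == 0.0
            assert comp[p]["n_pairs"] == 9

    def test_cross_compare_denominator_is_predicted_value(self):
        """Printed-cell oracle: |27.97 - 16.86| / 16.86 = 65.9%, pinning the
        predicted-set value as denominator (the simulated-denominator
        ratio would be 39.7%)."""
        pred = HillParams(alpha=1, delta=0, k=16.86, eta=1, logic="activating")
        sim = HillParams(alpha=1, delta=0, k=27.97, eta=1, logic="activating")
        comp = cross_compare([pred], [sim])
        assert comp["k"]["max_pct_diff"] == pytest.approx(65.9, abs=0.1)
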