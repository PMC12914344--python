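"""Input-channel construction, model contracts and training behaviour."""

import numpy as np
import pytest

from protonselect.engine import DoseMap, Prescription
from protonselect.predictor import (PredictorConfig, build_model,
                                    kfold_partition, make_input_channels,
                                    load_model, predict_dose, save_model,
                                    train_model)

TINY = PredictorConfig(block_counts=(1, 1, 1, 1), base_filters=4, epochs=2,
                       batch_size=4, seed=0, train_crop_margin=8)


class TestInputChannels:
    def test_dptv_values(self, dual_phantom):
        pres = Prescription(ptv2_dose=4500.0)
        cases = make_input_channels(dual_phantom, pres)
        vol = np.zeros(dual_phantom.shape)
        for c in cases:
            vol[c.slice_index] = c.input_stack[2]
        ptv1 = dual_phantom.masks["PTV1"]
        ptv2_only = dual_phantom.masks["PTV2"] & ~ptv1
        outside = ~(dual_phantom.masks["PTV2"] | ptv1)
        # a PTV1 voxel carries 1.0 (6750/6750), a PTV2-only voxel 4500/6750
        assert np.allclose(vol[ptv1], 1.0)
        assert np.allclose(vol[ptv2_only], 4500.0 / 6750.0)
        sel = outside & np.isin(np.arange(dual_phantom.shape[0]),
                                [c.slice_index for c in cases])[:, None, None]
        assert np.allclose(vol[sel], 0.0)

    def test_ct_channel_normalised(self, default_phantom):
        cases = make_input_channels(default_phantom, Prescription())
        stacks = np.stack([c.input_stack for c in cases])
        assert stacks[:, 0].min() >= 0.0 and stacks[:, 0].max() <= 1.0

    def test_structure_levels_distinct(self, dual_phantom):
        cases = make_input_channels(dual_phantom, Prescription(ptv2_dose=4500.0))
        struct = np.stack([c.input_stack[1] for c in cases])
        levels = np.unique(struct)
        assert len(levels) > 5
        assert levels.max() <= 1.0

    def test_target_and_dose_alignment(self, default_phantom):
        pres = Prescription()
        dose = DoseMap(grid=np.random.default_rng(0).uniform(0, 6750, default_phantom.shape),
                       spacing=default_phantom.spacing)
        cases = make_input_channels(default_phantom, pres, dose=dose)
        for c in cases[:3]:
            assert np.allclose(c.target * pres.ptv1_dose,
                               dose.grid[c.slice_index], atol=0.5)

    def test_missing_ptv1_rejected(self, default_phantom):
        import copy
        broken = copy.copy(default_phantom)
        broken.masks = {k: v for k, v in default_phantom.masks.items() if k != "PTV1"}
        with pytest.raises(ValueError, match="PTV1"):
            make_input_channels(broken, Prescription())


class TestModelContracts:
    def test_output_shape_matches_input(self):
        model = build_model(TINY)
        x = np.random.default_rng(0).normal(size=(2, 3, 64, 64)).astype(np.float32)
        assert model.forward(x).shape == (2, 1, 64, 64)

    def test_non_multiple_of_eight_padded(self):
        model = build_model(TINY)
        x = np.random.default_rng(0).normal(size=(1, 3, 50, 44)).astype(np.float32)
        assert model.forward(x).shape == (1, 1, 50, 44)

    def test_same_seed_identical_weights(self):
        a = build_model(TINY)
        b = build_model(TINY)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_paper_scale_config_builds(self):
        model = build_model(PredictorConfig.paper_scale())
        assert model.n_parameters > 1_000_000

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PredictorConfig(block_counts=(1, 1, 1))
        with pytest.raises(ValueError):
            PredictorConfig(downscale_factor=4)


@pytest.fixture(scope="module")
def small_training_setup():
    from protonselect.phantoms import CaseParams, generate_phantom
    from protonselect.engine import BeamConfig, plan_dose
    phantoms = [generate_phantom(CaseParams(patient_id=f"t{i}"), seed=30 + i)
                for i in range(2)]
    pres = Prescription()
    cases = []
    doses = []
    for ph in phantoms:
        dose = plan_dose(ph, pres, BeamConfig.photon(), seed=1)
        doses.append(dose)
        cases += make_input_channels(ph, pres, dose=dose, slice_selection="target",
                                     crop_margin=TINY.train_crop_margin)
    return phantoms, pres, doses, cases


class TestTraining:
    def test_loss_decreases(self, small_training_setup):
        _, _, _, cases = small_training_setup
        cfg = PredictorConfig(block_counts=(1, 1, 1, 1), base_filters=4,
                              epochs=5, batch_size=8, seed=1)
        _, history = train_model(cases, cfg)
        assert history[-1] < history[0]

    def test_deterministic_training(self, small_training_setup):
        _, _, _, cases = small_training_setup
        cfg = PredictorConfig(block_counts=(1, 1, 1, 1), base_filters=4,
                              epochs=2, batch_size=8, seed=7)
        _, h1 = train_model(cases, cfg)
        _, h2 = train_model(cases, cfg)
        assert h1 == h2

    def test_zero_learning_rate_keeps_loss_constant(self, small_training_setup):
        _, _, _, cases = small_training_setup
        cfg = PredictorConfig(block_counts=(1, 1, 1, 1), base_filters=4,
                              epochs=3, batch_size=8, seed=1, learning_rate=0.0)
        model, history = train_model(cases, cfg)
        assert history[0] == pytest.approx(history[-1], rel=1e-6)
        fresh = build_model(cfg)
        for pa, pb in zip(model.params(), fresh.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_empty_case_list_rejected(self):
        with pytest.raises(ValueError):
            train_model([], TINY)

    def test_prediction_contracts(self, small_training_setup):
        phantoms, pres, doses, cases = small_training_setup
        cfg = PredictorConfig(block_counts=(1, 1, 1, 1), base_filters=4,
                              epochs=3, batch_size=8, seed=1)
        model, _ = train_model(cases, cfg)
        pred = predict_dose(model, phantoms[0], pres)
        assert pred.grid.shape == phantoms[0].shape
        assert pred.grid.min() >= 0.0
        assert pred.provenance == "predicted"

    def test_trained_model_beats_cohort_mean_on_seen_case(self, small_training_setup):
        """Overfit one case; its prediction must beat the two-case mean map."""
        from protonselect.dosimetry import mae
        phantoms, pres, doses, _ = small_training_setup
        cfg = PredictorConfig(block_counts=(1, 1, 1, 1), base_filters=8,
                              epochs=80, batch_size=8, seed=2)
        cases = make_input_channels(phantoms[0], pres, dose=doses[0],
                                    slice_selection="target",
                                    crop_margin=cfg.train_crop_margin)
        model, _ = train_model(cases, cfg)
        pred = predict_dose(model, phantoms[0], pres)
        mean_grid = np.mean([d.grid for d in doses], axis=0)
        mask = phantoms[0].masks["rectum_wall"]
        assert mae(pred, doses[0], mask, pres.ptv1_dose) < \
            mae(mean_grid, doses[0], mask, pres.ptv1_dose)

    def test_checkpoint_roundtrip(self, small_training_setup, tmp_path):
        phantoms, pres, _, cases = small_training_setup
        cfg = PredictorConfig(block_counts=(1, 1, 1, 1), base_filters=4,
                              epochs=2, batch_size=8, seed=1)
        model, _ = train_model(cases, cfg)
        model.modality = "photon"
        save_model(model, tmp_path / "m.pkl")
        loaded = load_model(tmp_path / "m.pkl")
        a = predict_dose(model, phantoms[0], pres)
        b = predict_dose(loaded, phantoms[0], pres)
        assert np.array_equal(a.grid, b.grid)
        assert loaded.modality == "photon"


class TestKFold:
    def test_partition_laws(self):
        folds = kfold_partition(10, 5, seed=3)
        assert [len(f) for f in folds] == [2] * 5
        allidx = np.concatenate(folds)
        assert sorted(allidx) == list(range(10))

    def test_48_cases_near_equal(self):
        folds = kfold_partition(48, 5, seed=0)
        assert sorted(len(f) for f in folds) == [9, 9, 10, 10, 10]

    def test_deterministic(self):
        a = kfold_partition(20, 5, seed=9)
        b = kfold_partition(20, 5, seed=9)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa, fb)

    def test_k_less_than_two_rejected(self):
        with pytest.raises(ValueError):
            kfold_partition(10, 1, seed=0)
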