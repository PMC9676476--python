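"""Model assembly, head training, and unpromising-trial detection."""

import numpy as np
import pytest

from tdnas.space import HyperparamConfig
from tdnas.training import (COMPLETED, UNPROMISING_ABORTED, BackboneSpec,
                            EpochTrace, ReferenceCurve, build_model,
                            extract_features, train_validate,
                            unpromising_check, update_reference_curve)


class TestBackboneAndModel:
    @pytest.mark.parametrize("variant,conv", [("A", 8), ("B", 10),
                                              ("D", 13), ("E", 16)])
    def test_template_conv_depths(self, variant, conv):
        assert BackboneSpec.from_variant(variant).num_conv_layers == conv

    def test_variant_d_with_three_dense_layers_is_sixteen_weighted(self):
        bb = BackboneSpec.from_variant("D")
        cfg = HyperparamConfig(ln=3, dr=(0.6, 0.5), nn=(4096, 2048))
        assert build_model(cfg, bb, 8).num_weighted_layers == 16

    def test_minimum_head_is_output_layer_only(self, tiny_backbone):
        m = build_model(HyperparamConfig(ln=1, dr=(), nn=()), tiny_backbone, 8)
        assert m.head_widths == (8,)
        assert m.head_dropouts == (0.0,)

    def test_reported_head_widths_include_class_output(self, tiny_backbone):
        cfg = HyperparamConfig(ln=3, dr=(0.6, 0.5), nn=(4096, 2048))
        m = build_model(cfg, tiny_backbone, 8)
        assert m.head_widths == (4096, 2048, 8)

    def test_incompatible_input_size_rejected(self):
        bb = BackboneSpec.from_variant("tiny", input_size=30)
        with pytest.raises(ValueError):
            build_model(HyperparamConfig(ln=1, dr=(), nn=()), bb, 8)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            BackboneSpec.from_variant("Z")

    def test_feature_extraction_deterministic(self, tiny_backbone):
        imgs = np.random.default_rng(0).random((4, 32, 32)).astype(np.float32)
        a = extract_features(imgs, tiny_backbone, seed=3)
        b = extract_features(imgs, tiny_backbone, seed=3)
        assert np.array_equal(a, b)
        assert a.shape == (4, tiny_backbone.feature_dim())


class TestUnpromisingCheck:
    @pytest.fixture()
    def reference(self):
        return ReferenceCurve(mean_val_error=np.array([0.5, 0.4, 0.3, 0.25, 0.2]),
                              support=np.ones(5, dtype=np.int64))

    def test_below_reference_never_flags(self, reference):
        trace = EpochTrace(val_error=[0.4, 0.3, 0.2, 0.15, 0.1])
        assert not unpromising_check(trace, reference, 0.05, 3)

    def test_sustained_excess_flags(self, reference):
        trace = EpochTrace(val_error=[0.7, 0.6, 0.5, 0.45])
        assert unpromising_check(trace, reference, 0.05, 3)

    def test_brief_excess_tolerated(self, reference):
        trace = EpochTrace(val_error=[0.7, 0.3, 0.5, 0.45])
        assert not unpromising_check(trace, reference, 0.05, 3)

    def test_empty_reference_never_aborts(self):
        trace = EpochTrace(val_error=[0.9, 0.9, 0.9, 0.9])
        assert not unpromising_check(trace, ReferenceCurve(), 0.0, 1)

    def test_needs_patience_comparable_epochs(self, reference):
        trace = EpochTrace(val_error=[0.9, 0.9])
        assert not unpromising_check(trace, reference, 0.05, 3)

    def test_invalid_margin_patience(self, reference):
        trace = EpochTrace(val_error=[0.9])
        with pytest.raises(ValueError):
            unpromising_check(trace, reference, -0.1, 3)
        with pytest.raises(ValueError):
            unpromising_check(trace, reference, 0.1, 0)


class TestReferenceCurve:
    def test_single_trace_is_its_own_mean(self):
        ref = update_reference_curve([EpochTrace(val_error=[0.3, 0.2])])
        assert np.allclose(ref.mean_val_error, [0.3, 0.2])

    def test_two_trace_arithmetic_mean(self):
        ref = update_reference_curve([EpochTrace(val_error=[0.2, 0.1]),
                                      EpochTrace(val_error=[0.4, 0.3])])
        assert np.allclose(ref.mean_val_error, [0.3, 0.2])
        assert np.array_equal(ref.support, [2, 2])

    def test_unequal_lengths_use_available_support(self):
        ref = update_reference_curve([EpochTrace(val_error=[0.2, 0.1, 0.05]),
                                      EpochTrace(val_error=[0.4])])
        assert np.allclose(ref.mean_val_error, [0.3, 0.1, 0.05])
        assert np.array_equal(ref.support, [2, 1, 1])

    def test_aborted_traces_excluded(self):
        done = EpochTrace(val_error=[0.2, 0.2])
        bad = EpochTrace(val_error=[0.9, 0.9], aborted_at=2)
        ref = update_reference_curve([done, bad])
        assert np.allclose(ref.mean_val_error, [0.2, 0.2])

    def test_empty_input_empty_curve(self):
        assert update_reference_curve([]).empty


class TestTrainValidate:
    def test_separable_two_class_data_learns(self, tiny_backbone):
        from tdnas.synthetic import (SyntheticDatasetSpec, generate_dataset,
                                     split_dataset)
        d = generate_dataset(SyntheticDatasetSpec(
            num_classes=2, per_class=60, noise_sd=0.05, seed=0))
        tr, va, _ = split_dataset(d, (7, 2, 1), seed=0)
        m = build_model(HyperparamConfig(ln=2, dr=(0.2,), nn=(512,)),
                        tiny_backbone, 2)
        res, trace, status = train_validate(
            m, (tr.images, tr.labels), (va.images, va.labels),
            epochs=5, seed=0)
        assert status == COMPLETED
        assert trace.epochs_run == 5
        assert res.accuracy > 0.9

    def test_no_monitor_never_aborts(self, small_features, tiny_backbone):
        train, val = small_features
        m = build_model(HyperparamConfig(ln=1, dr=(), nn=()), tiny_backbone, 8)
        res, trace, status = train_validate(m, train, val, epochs=3, seed=1)
        assert status == COMPLETED and trace.aborted_at is None

    def test_shifted_reference_forces_abort(self, small_features, tiny_backbone):
        train, val = small_features
        m = build_model(HyperparamConfig(ln=1, dr=(), nn=()), tiny_backbone, 8)
        _, trace0, _ = train_validate(m, train, val, epochs=4, seed=2)
        # a reference 0.2 *below* this run's own curve must trigger
        ref = update_reference_curve([EpochTrace(
            val_error=[max(e - 0.2, 0.0) for e in trace0.val_error])])
        res, trace, status = train_validate(
            m, train, val, epochs=4, monitor=ref, margin=0.05, patience=2,
            seed=2)
        assert status == UNPROMISING_ABORTED
        assert trace.aborted_at is not None and trace.aborted_at <= 3

    def test_seeded_determinism(self, small_features, tiny_backbone):
        train, val = small_features
        m = build_model(HyperparamConfig(ln=2, dr=(0.3,), nn=(512,)),
                        tiny_backbone, 8)
        out1 = train_validate(m, train, val, epochs=2, seed=5)
        out2 = train_validate(m, train, val, epochs=2, seed=5)
        assert out1[1].val_error == out2[1].val_error
        assert out1[0].jc == out2[0].jc

    def test_empty_data_rejected(self, tiny_backbone):
        m = build_model(HyperparamConfig(ln=1, dr=(), nn=()), tiny_backbone, 8)
        with pytest.raises(ValueError):
            train_validate(m, (np.empty((0, 10)), np.empty(0)),
                           (np.empty((0, 10)), np.empty(0)), epochs=1)
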