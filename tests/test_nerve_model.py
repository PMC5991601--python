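"""Distance-model feature assembly and nonlinear multiregression fitting."""

import dataclasses

import numpy as np
import pytest

from nervelocate import (
    FeatureRecord,
    FitConfig,
    PredictionModel,
    assemble_features,
    fit_model,
    predict_distance,
)
from nervelocate import nerve_model as nm
from nervelocate.errors import InvalidRecord, MissingFeature, UnfittedModel


def _record(**overrides):
    base = dict(
        i_mt=1e-4, cmap_amp=2e-3, z=1e3, t_l=8e-3, theta1=4e6, theta2=-333.0,
        lin_r_squared=0.99, rs=800.0, rp=7000.0, cp=8e-9, tau_r_squared=0.97,
        distance_mm=1.0,
    )
    base.update(overrides)
    return FeatureRecord(**base)


class TestAssembleFeatures:
    def test_base_vector_direct_arithmetic(self):
        x = assemble_features(_record(), "base")
        assert np.allclose(x, [5e-5, 8e-6, 1.0])

    def test_zero_impedance_invalid(self):
        with pytest.raises(InvalidRecord):
            assemble_features(_record(z=0.0), "base")

    def test_extended_ratio_features_hand_arithmetic(self):
        r = _record()
        x = assemble_features(r, "extended")
        names = nm.EXTENDED_FEATURE_NAMES
        feats = dict(zip(names, x))
        assert feats["x1_imt_rp"] == pytest.approx(1e-4 / 7000.0)
        assert feats["x2_rs_cp"] == pytest.approx(800.0 / 8e-9)
        assert feats["r_rs"] == 800.0 and feats["r_rp"] == 7000.0
        assert feats["x1_const"] == 1.0
        assert feats["x2_tl"] == 8e-3

    def test_product_reading_switch(self):
        r = _record()
        x = assemble_features(r, "base",
                              nm.FeatureReading(latency="product"))
        assert x[1] == pytest.approx(8e-3 * 1e3)

    def test_missing_feature(self):
        with pytest.raises(MissingFeature):
            assemble_features(_record(cp=float("nan")), "extended")


def _synthetic_records(n=120, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for _ in range(n):
        recs.append(_record(
            i_mt=rng.uniform(2e-5, 3e-4),
            cmap_amp=rng.uniform(5e-4, 5e-3),
            z=rng.uniform(300, 1300),
            t_l=rng.uniform(6e-3, 10e-3),
            theta1=rng.uniform(1e6, 6e6),
            theta2=rng.uniform(-350, -300),
            lin_r_squared=rng.uniform(0.9, 1.0),
            rs=rng.uniform(300, 1200),
            rp=rng.uniform(5e3, 2e4),
            cp=rng.uniform(5e-10, 1.2e-8),
            tau_r_squared=rng.uniform(0.9, 1.0),
            distance_mm=0.0,
        ))
    return recs


def _label(records, variant, theta, seed_scaling=None):
    """Attach labels computed from a known parameter vector (scaled space)."""
    X = nm.build_design(records, variant)
    centers, scales = nm._fit_scaling(X.copy())
    Xs = (X - centers) / scales
    y = nm._model_scaled(np.asarray(theta, dtype=float), Xs, variant)
    return [dataclasses.replace(r, distance_mm=float(d))
            for r, d in zip(records, y)]


class TestBaseFit:
    def test_matches_closed_form_ols_oracle(self):
        """Base fit equals (X'X)^-1 X'y on the raw features, 50 datasets."""
        rng = np.random.default_rng(1)
        for ds in range(50):
            recs = _synthetic_records(n=30, seed=100 + ds)
            y = rng.normal(2.0, 1.0, size=30)
            recs = [dataclasses.replace(r, distance_mm=float(d))
                    for r, d in zip(recs, y)]
            model = fit_model(recs, "base")
            X = nm.build_design(recs, "base")
            expect = np.linalg.solve(X.T @ X, X.T @ y)
            lam1, lam2, eta = model.raw_base_coefficients()
            assert np.allclose([lam1, lam2, eta], expect, rtol=1e-6)
            assert np.allclose(model.predict(recs), X @ expect, atol=1e-9)

    def test_exact_recovery_of_generating_coefficients(self):
        recs = _synthetic_records(n=100, seed=2)
        X = nm.build_design(recs, "base")
        truth = np.array([3.0e4, -2.0e2, 0.7])
        y = X @ truth
        recs = [dataclasses.replace(r, distance_mm=float(d))
                for r, d in zip(recs, y)]
        model = fit_model(recs, "base")
        assert np.allclose(model.raw_base_coefficients(), truth, rtol=1e-6)

    def test_order_invariance(self):
        recs = _synthetic_records(n=40, seed=3)
        y = np.linspace(0, 4, 40)
        recs = [dataclasses.replace(r, distance_mm=float(d))
                for r, d in zip(recs, y)]
        m1 = fit_model(recs, "base")
        rng = np.random.default_rng(0)
        perm = rng.permutation(40)
        m2 = fit_model([recs[i] for i in perm], "base")
        assert np.allclose(m1.predict(recs), m2.predict(recs), atol=1e-8)


class TestExtendedFit:
    THETA = np.array([1.0, 0.5, 0.3, 0.2, -0.1, 0.1, 0.2,
                      0.1, -0.2, 0.15, 0.25, 0.5, -0.4, 0.8, -0.6])

    def test_predictions_recover_noiseless_labels(self):
        recs = _label(_synthetic_records(n=120, seed=4), "extended", self.THETA)
        model = fit_model(recs, "extended", FitConfig(seed=0))
        pred = model.predict(recs)
        y = np.array([r.distance_mm for r in recs])
        assert model.diagnostics["sse"] < 1e-6
        assert np.max(np.abs(pred - y)) < 1e-3

    def test_trivial_constant_model_predicts_constant(self):
        theta = np.zeros(15)
        theta[2] = 3.0  # coefficient of the constant X1(0) column
        recs = _label(_synthetic_records(n=40, seed=5), "extended", theta)
        model = PredictionModel(
            variant="extended", params=theta,
            centers=np.zeros(13), scales=np.ones(13), fitted=True,
        )
        assert predict_distance(model, recs[0]) == pytest.approx(3.0)

    def test_extended_sse_never_exceeds_base_sse(self):
        rng = np.random.default_rng(6)
        for ds in range(3):
            recs = _synthetic_records(n=60, seed=200 + ds)
            y = rng.normal(2.0, 1.5, size=60)
            recs = [dataclasses.replace(r, distance_mm=float(d))
                    for r, d in zip(recs, y)]
            ext = fit_model(recs, "extended", FitConfig(seed=1, n_starts=4))
            assert ext.diagnostics["sse"] <= ext.diagnostics["base_sse"] + 1e-9

    def test_seeded_fit_is_bit_reproducible(self):
        recs = _label(_synthetic_records(n=60, seed=7), "extended", self.THETA)
        m1 = fit_model(recs, "extended", FitConfig(seed=42, n_starts=4))
        m2 = fit_model(recs, "extended", FitConfig(seed=42, n_starts=4))
        assert np.array_equal(m1.params, m2.params)

    def test_unit_rescaling_absorbed_by_scaling(self):
        """Expressing Cp in nF instead of F must not change predictions."""
        recs = _label(_synthetic_records(n=60, seed=8), "extended", self.THETA)
        scaled = [dataclasses.replace(r, cp=r.cp * 1e9) for r in recs]
        m1 = fit_model(recs, "extended", FitConfig(seed=0, n_starts=2))
        m2 = fit_model(scaled, "extended", FitConfig(seed=0, n_starts=2))
        assert np.allclose(m1.predict(recs), m2.predict(scaled), atol=1e-6)


class TestModelLifecycle:
    def test_unfitted_model_raises(self):
        model = PredictionModel(variant="base", params=np.zeros(3),
                                centers=np.zeros(3), scales=np.ones(3))
        with pytest.raises(UnfittedModel):
            model.predict([_record()])

    def test_json_round_trip(self, tmp_path):
        recs = _synthetic_records(n=30, seed=9)
        y = np.linspace(0, 4, 30)
        recs = [dataclasses.replace(r, distance_mm=float(d))
                for r, d in zip(recs, y)]
        model = fit_model(recs, "base")
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = PredictionModel.from_json(path)
        assert loaded.variant == "base"
        assert np.allclose(loaded.predict(recs), model.predict(recs))
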