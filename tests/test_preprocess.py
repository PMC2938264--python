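"""Background correction, replicate summarisation and normalisation."""

from dataclasses import replace

import numpy as np
import pytest

from mirscreen import preprocess, simulate
from mirscreen.errors import (
    AlreadyCorrectedError,
    InsufficientDataError,
    SchemaError,
)


def tiny_raw(intensities, backgrounds=None, corrected=False):
    """RawArraySet from a (probes, spots, samples) array."""
    intensities = np.asarray(intensities, dtype=float)
    n_p, _, n_s = intensities.shape
    if backgrounds is None:
        backgrounds = np.zeros_like(intensities)
    samples = [
        simulate.SampleSpec(f"S{j}", "case" if j % 2 == 0 else "control")
        for j in range(n_s)
    ]
    return simulate.RawArraySet(
        probe_ids=[f"p{i}" for i in range(n_p)],
        samples=samples,
        intensities=intensities,
        backgrounds=np.asarray(backgrounds, dtype=float),
        background_corrected=corrected,
    )


class TestBackgroundCorrect:
    def test_subtraction_arithmetic(self):
        raw = tiny_raw([[[100.0]]], [[[30.0]]])
        out = preprocess.background_correct(raw, floor=0.5)
        assert out.intensities[0, 0, 0] == 70.0

    def test_floor_applies_when_background_exceeds_signal(self):
        raw = tiny_raw([[[10.0]]], [[[30.0]]])
        out = preprocess.background_correct(raw, floor=0.5)
        assert out.intensities[0, 0, 0] == 0.5

    def test_zero_background_identity(self):
        vals = np.full((3, 2, 2), 42.0)
        out = preprocess.background_correct(tiny_raw(vals), floor=0.5)
        assert np.array_equal(out.intensities, vals)

    def test_double_correction_rejected(self):
        raw = tiny_raw([[[100.0]]], [[[30.0]]])
        once = preprocess.background_correct(raw)
        with pytest.raises(AlreadyCorrectedError):
            preprocess.background_correct(once)

    def test_default_floor_stays_small(self):
        # signals far above background: the data-driven floor must not
        # censor genuine low-intensity probes
        cfg = replace(simulate.GeneratorConfig(), n_probes=100, seed=1)
        _, raw = simulate.simulate_from_config(cfg, 3, 3)
        out = preprocess.background_correct(raw)
        assert out.floor <= 0.05 * np.median(out.intensities)


class TestSummarize:
    def test_odd_count_median(self):
        spots = np.arange(1.0, 8.0).reshape(1, 7, 1)
        mat = preprocess.summarize_replicates(tiny_raw(spots, corrected=True))
        assert mat.values[0, 0] == 4.0

    def test_constant_spots(self):
        mat = preprocess.summarize_replicates(
            tiny_raw(np.full((2, 7, 1), 3.0), corrected=True)
        )
        assert np.all(mat.values == 3.0)

    def test_median_robust_to_outlier_spot(self):
        spots = np.array([1, 1, 1, 1, 1, 1, 100], dtype=float).reshape(1, 7, 1)
        mat = preprocess.summarize_replicates(tiny_raw(spots, corrected=True))
        assert mat.values[0, 0] == 1.0

    def test_requires_background_correction(self):
        with pytest.raises(SchemaError):
            preprocess.summarize_replicates(tiny_raw(np.ones((1, 7, 1))))

    def test_commutes_with_probe_reordering(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 100, (5, 7, 3))
        raw = tiny_raw(vals, corrected=True)
        mat = preprocess.summarize_replicates(raw)
        perm = rng.permutation(5)
        raw_perm = tiny_raw(vals[perm], corrected=True)
        raw_perm.probe_ids = [raw.probe_ids[i] for i in perm]
        mat_perm = preprocess.summarize_replicates(raw_perm)
        assert np.array_equal(mat_perm.values, mat.values[perm])


def _summarized(seed=0, n_probes=200, n_samples=6, labels=None):
    cfg = replace(simulate.GeneratorConfig(), n_probes=n_probes, seed=seed)
    _, raw = simulate.simulate_from_config(
        cfg, n_samples // 2, n_samples - n_samples // 2
    )
    return preprocess.summarize_replicates(preprocess.background_correct(raw))


class TestNormalization:
    def test_affine_copies_normalize_identically(self):
        rng = np.random.default_rng(1)
        base = np.sort(rng.uniform(10, 1000, 150))
        values = np.column_stack([base, 2.0 * base + 5.0, 0.5 * base + 1.0])
        mat = preprocess.ExpressionMatrix(
            probe_ids=[f"p{i}" for i in range(150)],
            sample_ids=["a", "b", "c"],
            values=values,
            labels=np.array(["case", "control", "control"]),
            stage="raw-summarized",
        )
        out = preprocess.normalize(mat)
        assert np.allclose(out.values[:, 1], out.values[:, 0], atol=5e-2)
        assert np.allclose(out.values[:, 2], out.values[:, 0], atol=5e-2)

    def test_glog_identity_at_zero(self):
        assert preprocess._glog(np.array([0.0]), 1.0)[0] == 0.0

    def test_single_sample_rejected(self):
        mat = _summarized()
        solo = preprocess.ExpressionMatrix(
            probe_ids=mat.probe_ids,
            sample_ids=mat.sample_ids[:1],
            values=mat.values[:, :1],
            labels=mat.labels[:1],
            stage="raw-summarized",
        )
        with pytest.raises(InsufficientDataError):
            preprocess.fit_normalization(solo)

    def test_variance_flat_across_intensity_deciles(self):
        # replicate arrays: post-normalisation per-probe variance should not
        # trend with intensity (max/min decile ratio < 3)
        cfg = simulate.GeneratorConfig()
        raw = simulate.simulate_replicate_pair(cfg, seed=9)
        mat = preprocess.preprocess_raw(raw)
        d_var = (mat.values[:, 0] - mat.values[:, 1]) ** 2 / 2.0
        intensity = mat.values.mean(axis=1)
        deciles = np.quantile(intensity, np.linspace(0, 1, 11))
        per_decile = []
        for lo, hi in zip(deciles[:-1], deciles[1:]):
            sel = (intensity >= lo) & (intensity <= hi)
            per_decile.append(d_var[sel].mean())
        ratio = max(per_decile) / min(per_decile)
        assert ratio < 3.0

    def test_scale_equivariance(self):
        mat = _summarized(seed=3)
        scaled_values = mat.values.copy()
        scaled_values[:, 0] *= 7.0
        scaled = preprocess.ExpressionMatrix(
            probe_ids=mat.probe_ids,
            sample_ids=mat.sample_ids,
            values=scaled_values,
            labels=mat.labels,
            stage="raw-summarized",
        )
        out = preprocess.normalize(mat)
        out_scaled = preprocess.normalize(scaled)
        assert np.allclose(out_scaled.values[:, 0], out.values[:, 0], atol=5e-2)

    def test_model_reapplication_reproduces_training_values(self):
        mat = _summarized(seed=4)
        model = preprocess.fit_normalization(mat)
        again = preprocess.apply_normalization(model, mat)
        assert np.array_equal(again.values, model.training_normalized.values)

    def test_renormalizing_output_rejected(self):
        mat = _summarized(seed=5)
        model = preprocess.fit_normalization(mat)
        with pytest.raises(AlreadyCorrectedError):
            preprocess.apply_normalization(model, model.training_normalized)

    def test_probe_mismatch_rejected(self):
        mat = _summarized(seed=6)
        model = preprocess.fit_normalization(mat)
        other = preprocess.ExpressionMatrix(
            probe_ids=[f"x{i}" for i in range(mat.n_probes)],
            sample_ids=mat.sample_ids,
            values=mat.values,
            labels=mat.labels,
            stage="raw-summarized",
        )
        with pytest.raises(SchemaError):
            preprocess.apply_normalization(model, other)

    def test_monotone_inputs_stay_monotone(self):
        mat = _summarized(seed=7)
        model = preprocess.fit_normalization(mat)
        rng = np.random.default_rng(2)
        for sid in mat.sample_ids[:2]:
            y = np.sort(rng.uniform(1, 500, mat.n_probes))
            probe = preprocess.ExpressionMatrix(
                probe_ids=mat.probe_ids,
                sample_ids=[sid],
                values=y[:, None],
                labels=np.array(["control"]),
                stage="raw-summarized",
            )
            out = preprocess.apply_normalization(model, probe)
            assert np.all(np.diff(out.values[:, 0]) >= 0)

    def test_unseen_array_calibrated_against_frozen_reference(self):
        mat = _summarized(seed=8)
        model = preprocess.fit_normalization(mat)
        new = preprocess.ExpressionMatrix(
            probe_ids=mat.probe_ids,
            sample_ids=["fresh"],
            values=(1.5 * mat.values[:, :1] + 2.0),
            labels=np.array(["control"]),
            stage="raw-summarized",
        )
        out = preprocess.apply_normalization(model, new)
        ref = model.training_normalized.values[:, 0]
        assert np.allclose(out.values[:, 0], ref, atol=5e-2)
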