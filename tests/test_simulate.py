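"""Video-level simulator behaviour: rendering, dynamics, dataset assembly."""

from dataclasses import replace

import numpy as np
import pytest

from speckleflow.conditions import FlowCondition
from speckleflow.simulate import (
    SimulationParams, desk_scale_params, generate_field, make_phantom_dataset,
    render_frame, simulate_video,
)


def _clean_params(**kw):
    """No depth degradation, no noise, no translation."""
    defaults = dict(
        height=64, width=64, duration=1 / 300, static_fraction=0.0,
        blur_sigma=0.0, noise_sigma=0.0, translation_amplitude=0.0,
        exposure_substeps=1,
    )
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestRenderFrame:
    def test_clean_frame_keeps_unit_contrast(self):
        p = _clean_params()
        fld = generate_field(p, np.random.default_rng(0))
        frame = render_frame(fld, fld, p, [fld])
        f = frame.astype(float)
        assert f.std() / f.mean() == pytest.approx(1.0, abs=0.07)

    def test_static_limit_freezes_consecutive_frames(self):
        p = replace(_clean_params(), static_fraction=0.999, velocity=100.0,
                    duration=8 / 300)
        video = simulate_video(p)
        a = video.frames[0].astype(float).ravel()
        b = video.frames[1].astype(float).ravel()
        assert np.corrcoef(a, b)[0, 1] > 0.95

    def test_contrast_decreases_monotonically_with_substeps(self):
        """Exposure integration: more intra-exposure field states, less contrast."""
        def mean_contrast(S):
            vals = []
            for seed in range(10):
                p = _clean_params(exposure_substeps=S, velocity=97.0, seed=seed)
                video = simulate_video(p)
                f = video.frames[0].astype(float)
                vals.append(f.std() / f.mean())
            return np.mean(vals)

        contrasts = [mean_contrast(S) for S in (1, 2, 4, 8, 16)]
        assert all(a > b for a, b in zip(contrasts, contrasts[1:]))

    def test_empty_substeps_rejected(self):
        p = _clean_params()
        fld = generate_field(p, np.random.default_rng(0))
        with pytest.raises(ValueError):
            render_frame(fld, fld, p, [])


class TestSimulateVideo:
    def test_zero_velocity_without_noise_is_constant(self):
        p = _clean_params(duration=5 / 300, velocity=0.0)
        video = simulate_video(p)
        assert np.all(video.frames == video.frames[0])

    def test_deterministic_given_seed(self):
        p = desk_scale_params(duration=16 / 300, velocity=30.0, seed=9)
        a = simulate_video(p)
        b = simulate_video(p)
        assert np.array_equal(a.frames, b.frames)

    def test_seed_changes_frames_not_statistics(self):
        means = []
        for seed in range(10):
            p = desk_scale_params(duration=8 / 300, velocity=30.0, seed=seed)
            means.append(simulate_video(p).frames.mean())
        for a, b in zip(means[0::2], means[1::2]):
            assert abs(a - b) / a < 0.02

    def test_high_flow_decorrelates_faster_than_low(self):
        """Lag-1 temporal autocorrelation over a 64-frame clip, HIGH vs LOW."""
        def lag1(velocity, seed):
            p = desk_scale_params(duration=64 / 300, velocity=velocity, seed=seed)
            fr = simulate_video(p).frames.astype(float)
            x = fr - fr.mean(axis=0)
            return (x[:-1] * x[1:]).sum() / (x ** 2).sum()

        for seed in (0, 1):
            assert lag1(83.0, seed) < lag1(4.2, seed)

    def test_condition_inferred_from_velocity(self):
        p = desk_scale_params(duration=1 / 300, velocity=40.0, diameter=3.0)
        assert simulate_video(p).condition == FlowCondition.MEDIUM
        p0 = desk_scale_params(duration=1 / 300, velocity=0.0)
        assert simulate_video(p0).condition == FlowCondition.ZERO


class TestSimulationParams:
    def test_frame_count_rounds_exactly(self):
        assert SimulationParams().n_frames == 9900
        with pytest.raises(ValueError):
            SimulationParams(fps=300, duration=0.0051)

    @pytest.mark.parametrize("bad", [
        dict(velocity=-1), dict(exposure_substeps=0), dict(pulse_modulation=1.0),
        dict(static_fraction=1.0), dict(decorrelation_scale=0.0),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            desk_scale_params(**bad)

    def test_depth_profiles_resolve(self):
        p5 = desk_scale_params(depth=5.0)
        assert p5.resolved_static_fraction == 0.5
        assert p5.resolved_blur_sigma == 1.0
        explicit = desk_scale_params(depth=5.0, static_fraction=0.1, blur_sigma=0.2)
        assert explicit.resolved_static_fraction == 0.1
        assert explicit.resolved_blur_sigma == 0.2


class TestMakePhantomDataset:
    def test_full_grid_counts(self, small_dataset):
        videos, manifest = small_dataset
        # single-cell grid: 4 conditions x 3 replicates
        assert len(videos) == 12
        assert (manifest["split"] == "test").sum() == 4
        assert set(manifest["condition"]) == {c.name for c in FlowCondition}

    def test_default_grid_is_sixty_videos(self):
        # count without simulating: enumerate the manifest rows of a tiny geometry
        base = desk_scale_params(height=32, width=32, duration=64 / 300)
        videos, manifest = make_phantom_dataset(seed=1, base_params=base)
        assert len(videos) == 60
        assert (manifest["split"] == "test").sum() == 20

    def test_velocities_fall_in_condition_ranges(self, small_dataset):
        _, manifest = small_dataset
        from speckleflow.conditions import VELOCITY_RANGES
        for _, row in manifest.iterrows():
            lo, hi = VELOCITY_RANGES[row["diameter_mm"]][FlowCondition[row["condition"]]]
            assert lo <= row["velocity_cm_s"] <= hi

    def test_same_seed_reproduces_manifest_and_videos(self):
        base = desk_scale_params(height=32, width=32, duration=64 / 300)
        v1, m1 = make_phantom_dataset(grid_spec=[(6.0, 0.0)], seed=3, base_params=base)
        v2, m2 = make_phantom_dataset(grid_spec=[(6.0, 0.0)], seed=3, base_params=base)
        assert m1.equals(m2)
        assert all(np.array_equal(a.frames, b.frames) for a, b in zip(v1, v2))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            make_phantom_dataset(grid_spec=[], seed=0)
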