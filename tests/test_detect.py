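"""Spot detection, sub-pixel localization, linking, and duration filtering."""

import numpy as np
import pytest

from piezospt.detect import (
    Detection,
    DetectionParams,
    detect,
    dog_filter,
    filter_min_duration,
    id_switch_diagnostic,
    link,
)
from piezospt.simulate import SimulationConfig, render_movie, simulate_brownian, simulate_immobile
from piezospt.trajectory import Trajectory


PARAMS = DetectionParams(dog_sigma_small=1.0, dog_sigma_large=3.0, threshold=None,
                         auto_threshold_k=5.0, min_duration_s=2.0)


def _gauss_frame(shape, x0, y0, sigma=1.3, amp=300.0, bg=100.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return bg + amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2))


class TestDogFilter:
    def test_constant_image_maps_to_zero(self):
        out = dog_filter(np.full((1, 32, 32), 7.0), PARAMS)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        img = rng.random((1, 32, 32))
        assert np.allclose(dog_filter(3.5 * img, PARAMS), 3.5 * dog_filter(img, PARAMS))

    def test_single_pixel_center_value(self):
        """A unit impulse returns the difference of the two Gaussian kernels'
        central weights (evaluated through the same separable filter)."""
        from scipy import ndimage

        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = dog_filter(img[None], PARAMS)[0]
        expected = (
            ndimage.gaussian_filter(img, PARAMS.dog_sigma_small)
            - ndimage.gaussian_filter(img, PARAMS.dog_sigma_large)
        )[16, 16]
        assert np.isclose(out[16, 16], expected)
        assert out[16, 16] > 0

    def test_nonfinite_rejected(self):
        img = np.full((1, 8, 8), np.nan)
        with pytest.raises(ValueError):
            dog_filter(img, PARAMS)


class TestDetect:
    def test_blank_frame_empty(self):
        frame = np.full((32, 32), 100.0)
        assert detect(dog_filter(frame[None], PARAMS)[0], frame, PARAMS) == []

    def test_subpixel_centroid_accuracy(self):
        frame = _gauss_frame((32, 32), x0=10.30, y0=5.70)
        dets = detect(dog_filter(frame[None], PARAMS)[0], frame, PARAMS)
        assert len(dets) == 1
        assert abs(dets[0].x_px - 10.30) < 0.15
        assert abs(dets[0].y_px - 5.70) < 0.15

    def test_two_separate_blobs(self):
        frame = _gauss_frame((48, 48), 12, 12) + _gauss_frame((48, 48), 34, 34) - 100.0
        dets = detect(dog_filter(frame[None], PARAMS)[0], frame, PARAMS)
        assert len(dets) == 2


class TestLink:
    def _dets(self, positions_by_frame):
        return {
            f: [Detection(frame=f, x_px=x, y_px=y, cluster_size=4, amplitude=1.0) for x, y in pts]
            for f, pts in positions_by_frame.items()
        }

    def test_stepping_spot_single_trajectory(self):
        dets = self._dets({f: [(5.0 + f, 5.0)] for f in range(10)})
        trajs = link(dets, PARAMS)
        assert len(trajs) == 1
        assert trajs[0].n_valid == 10

    def test_jump_beyond_radius_splits(self):
        """A single 4-px jump exceeds the 3-px radius and splits the track."""
        xs = [5.0, 6.0, 7.0, 11.0, 12.0, 13.0]  # 4-px jump between frames 2 and 3
        dets = self._dets({f: [(x, 5.0)] for f, x in enumerate(xs)})
        trajs = link(dets, PARAMS)
        assert len(trajs) == 2
        assert sorted(t.n_valid for t in trajs) == [3, 3]

    def test_gap_bridging_inserts_placeholder(self):
        dets = self._dets({0: [(5, 5)], 1: [(5.5, 5)], 3: [(6, 5)], 4: [(6.5, 5)]})
        trajs = link(dets, PARAMS)
        assert len(trajs) == 1
        t = trajs[0]
        assert t.frames.tolist() == [0, 1, 2, 3, 4]
        assert not t.valid_mask[2]

    def test_gap_beyond_limit_terminates(self):
        dets = self._dets({0: [(5, 5)], 1: [(5.5, 5)], 4: [(6, 5)], 5: [(6.5, 5)]})
        trajs = link(dets, PARAMS)  # max_gap_frames=1, two missing frames
        assert len(trajs) == 2

    def test_permutation_invariance_within_frame(self):
        base = {0: [(5, 5), (20, 20)], 1: [(5.5, 5), (20.5, 20)], 2: [(6, 5), (21, 20)]}
        swapped = {f: list(reversed(pts)) for f, pts in base.items()}
        a = link(self._dets(base), PARAMS)
        b = link(self._dets(swapped), PARAMS)
        key = lambda t: tuple(np.round(t.xy[np.isfinite(t.xy[:, 0])][:, 0], 6))
        assert sorted(map(key, a)) == sorted(map(key, b))

    def test_micron_conversion_exact(self):
        dets = self._dets({0: [(10.0, 20.0)], 1: [(11.0, 20.0)]})
        t = link(dets, PARAMS)[0]
        np.testing.assert_allclose(t.xy[0], [10.0 * 0.1092, 20.0 * 0.1092])


class TestFilterMinDuration:
    def test_boundary_inclusive(self):
        def traj(n):
            return Trajectory("a", np.arange(n), np.cumsum(np.ones((n, 2)) * 0.1, axis=0), 0.1)

        params = DetectionParams(min_duration_s=20.0, dt=0.1)
        durations = {50: 5.0, 199: 19.9, 200: 20.0, 400: 40.0}
        kept = filter_min_duration([traj(n) for n in durations], params)
        assert sorted(t.n_slots for t in kept) == [200, 400]
        # with the defaults, every retained trajectory has >= 200 positions
        assert all(t.n_slots >= 200 for t in kept)

    def test_empty_input(self):
        assert filter_min_duration([], PARAMS) == []


class TestEndToEndRecovery:
    def test_rendered_movie_track_and_localization_recovery(self):
        """Detection + linking on a rendered movie recovers the ground-truth
        track count with per-point localization error below 0.15 px."""
        cfg = SimulationConfig(n_traj=9, n_points=30, dt=0.1, seed=70)
        ens = simulate_brownian(cfg, D=0.02)
        stack, truth = render_movie(ens, psf_sigma=1.3, amplitude=400, background=100,
                                    noise_sd=20, image_shape=(192, 192), seed=1)
        filt = dog_filter(stack, PARAMS)
        dets = {f: detect(filt[f], stack[f].astype(float), PARAMS, f) for f in range(stack.shape[0])}
        trajs = filter_min_duration(link(dets, PARAMS), PARAMS)
        assert len(trajs) == 9
        errs = []
        for f in range(stack.shape[0]):
            sub = truth[truth.frame == f]
            for d in dets[f]:
                errs.append(np.sqrt((sub.x_px - d.x_px) ** 2 + (sub.y_px - d.y_px) ** 2).min())
        assert np.sqrt(np.mean(np.square(errs))) < 0.15


class TestIdSwitchDiagnostic:
    def _static_dets(self, positions, n_frames=5):
        return {
            f: [Detection(f, x, y, 4, 1.0) for x, y in positions] for f in range(n_frames)
        }

    def test_two_distant_spots(self):
        rep = id_switch_diagnostic(self._static_dets([(0, 0), (20, 0)]), [], PARAMS)
        assert all(np.isclose(v, 20.0) for v in rep.frame_mean_nn_px.values())
        assert rep.risk_fraction == 0.0

    def test_dense_spots_high_risk(self):
        rng = np.random.default_rng(1)
        dets = {
            f: [Detection(f, x, y, 4, 1.0) for x, y in rng.uniform(0, 30, size=(100, 2))]
            for f in range(5)
        }
        rep = id_switch_diagnostic(dets, [], PARAMS)
        assert rep.risk_fraction == 1.0  # ~1 spot per (3 px)^2

    def test_single_spot_insufficient_density(self):
        rep = id_switch_diagnostic(self._static_dets([(5, 5)]), [], PARAMS)
        assert rep.frame_mean_nn_px == {}
        assert "insufficient" in rep.note
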