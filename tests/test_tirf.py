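"""Spot detection, tracking, and the consecutive-frame co-movement rule."""

import numpy as np
import pytest

from raftcrac.synthetic import MovieSpec, gen_tirf_movie
from raftcrac.tirf import (
    FrameStack,
    Spot,
    Track,
    detect_spots,
    link_tracks,
    score_comovement,
    tracks_to_frame,
)


def gaussian_frame(shape, centers, amplitude=100.0, sigma=1.5, background=0.0):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full(shape, float(background))
    for (x, y) in centers:
        img += amplitude * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    return img


def track_from_positions(track_id, channel, positions, start=0):
    spots = [Spot(start + i, x, y, channel, 1.0)
             for i, (x, y) in enumerate(positions)]
    return Track(track_id, channel, spots)


class TestDetectSpots:
    def test_single_noiseless_spot_subpixel_accuracy(self):
        img = gaussian_frame((48, 48), [(20.0, 30.0)])
        (spots,) = detect_spots(img)
        assert len(spots) == 1
        assert spots[0].x == pytest.approx(20.0, abs=0.5)
        assert spots[0].y == pytest.approx(30.0, abs=0.5)

    def test_flat_image_no_detections(self):
        (spots,) = detect_spots(np.full((32, 32), 7.0))
        assert spots == []

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((8, 8)), sigma=0)

    def test_recall_precision_on_synthetic_movie(self):
        """At SNR ≥ 10 nearly every planted spot is found and little else."""
        spec = MovieSpec(n_frames=6, n_coloc_pairs=4, n_red_only=4,
                         n_green_only=0, spot_amplitude=100, noise_sd=2.0,
                         seed=3)
        movie = gen_tirf_movie(spec)
        truth = movie.truth_tracks
        red = truth[truth.channel == "red"]
        per_frame = detect_spots(movie.stack.red)
        tp = fp = fn = 0
        for t, spots in enumerate(per_frame):
            gt = red[red.frame == t][["x", "y"]].to_numpy()
            used = set()
            for s in spots:
                d = np.hypot(gt[:, 0] - s.x, gt[:, 1] - s.y)
                j = int(np.argmin(d))
                if d[j] <= 2.0 and j not in used:
                    tp += 1
                    used.add(j)
                else:
                    fp += 1
            fn += len(gt) - len(used)
        recall = tp / (tp + fn)
        precision = tp / (tp + fp)
        assert recall >= 0.95
        assert precision >= 0.95


class TestLinkTracks:
    def test_single_moving_spot_one_track(self):
        spots = [[Spot(t, 10.0 + t, 20.0, "red", 1.0)] for t in range(8)]
        tracks = link_tracks(spots, r_link=3.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 8

    def test_distant_static_spots_never_swap(self):
        spots = [
            [Spot(t, 10.0, 10.0, "red", 1.0), Spot(t, 30.0, 10.0, "red", 1.0)]
            for t in range(6)
        ]
        tracks = link_tracks(spots, r_link=3.0)
        assert len(tracks) == 2
        for tr in tracks:
            xs = {s.x for s in tr.spots}
            assert len(xs) == 1  # each track stays on its own spot

    def test_jump_beyond_r_link_splits_track(self):
        spots = [[Spot(0, 10.0, 10.0, "red", 1.0)],
                 [Spot(1, 30.0, 10.0, "red", 1.0)]]
        tracks = link_tracks(spots, r_link=3.0)
        assert sorted(len(t) for t in tracks) == [1, 1]

    def test_trajectory_recovery_on_synthetic_movie(self):
        """Diffusion well under r_link keeps ≥ 90% of trajectories whole."""
        spec = MovieSpec(n_frames=10, n_coloc_pairs=0, n_red_only=8,
                         n_green_only=0, diffusion_sigma=0.8, seed=5)
        movie = gen_tirf_movie(spec)
        per_frame = detect_spots(movie.stack.red)
        tracks = link_tracks(per_frame, r_link=3.0)
        full = [t for t in tracks if len(t) == spec.n_frames]
        assert len(full) >= 0.9 * 8


class TestScoreComovement:
    def test_identical_tracks_full_colocalization(self):
        pos = [(10.0 + t, 20.0) for t in range(10)]
        res = score_comovement([track_from_positions(0, "red", pos)],
                               [track_from_positions(1, "green", pos)])
        assert res.percentage == 100.0

    def test_far_tracks_zero(self):
        red = track_from_positions(0, "red", [(10.0, 10.0)] * 10)
        green = track_from_positions(1, "green", [(60.0, 60.0)] * 10)
        assert score_comovement([red], [green]).percentage == 0.0

    def test_two_frame_episodes_rejected_by_three_frame_rule(self):
        """Proximity on frames {0,1} and {4,5} only (max run 2) is not enough."""
        red_pos = [(10.0, 10.0)] * 8
        green_pos = [(10.0, 10.0), (10.0, 10.0), (50.0, 50.0), (50.0, 50.0),
                     (10.0, 10.0), (10.0, 10.0), (50.0, 50.0), (50.0, 50.0)]
        red = track_from_positions(0, "red", red_pos)
        green = track_from_positions(1, "green", green_pos)
        res = score_comovement([red], [green], r_pair=3.0, min_consecutive=3)
        assert res.percentage == 0.0
        # the same geometry passes once three consecutive frames are close
        res2 = score_comovement([red], [green], r_pair=3.0, min_consecutive=2)
        assert res2.percentage == 100.0

    def test_no_red_tracks_percentage_undefined(self):
        green = track_from_positions(0, "green", [(1.0, 1.0)] * 5)
        with pytest.warns(UserWarning):
            res = score_comovement([], [green])
        assert res.percentage is None

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        pos = [(20 + float(a), 20 + float(b))
               for a, b in rng.normal(0, 1, (10, 2))]
        red = track_from_positions(0, "red", pos)
        green = track_from_positions(1, "green", [(x + 1.0, y + 0.5)
                                                  for x, y in pos])
        base = score_comovement([red], [green])
        shifted_red = track_from_positions(0, "red",
                                           [(x + 7, y - 3) for x, y in pos])
        shifted_green = track_from_positions(
            1, "green", [(x + 8.0, y - 2.5) for x, y in pos])
        moved = score_comovement([shifted_red], [shifted_green])
        assert base.percentage == moved.percentage

    def test_monotone_in_r_pair_and_min_consecutive(self):
        rng = np.random.default_rng(11)
        reds, greens = [], []
        for i in range(6):
            pos = [(float(x), float(y)) for x, y in
                   rng.uniform(5, 55, (8, 2))]
            reds.append(track_from_positions(i, "red", pos))
            jit = [(x + float(rng.normal(0, 2)), y + float(rng.normal(0, 2)))
                   for x, y in pos]
            greens.append(track_from_positions(10 + i, "green", jit))
        p_small = score_comovement(reds, greens, r_pair=1.0).percentage
        p_big = score_comovement(reds, greens, r_pair=5.0).percentage
        assert p_big >= p_small
        p_strict = score_comovement(reds, greens, r_pair=3.0,
                                    min_consecutive=5).percentage
        p_lax = score_comovement(reds, greens, r_pair=3.0,
                                 min_consecutive=2).percentage
        assert p_lax >= p_strict

    def test_degenerate_upper_bound(self):
        red = track_from_positions(0, "red", [(1.0, 1.0)] * 3)
        green = track_from_positions(1, "green", [(90.0, 90.0)] * 3)
        res = score_comovement([red], [green], r_pair=1e9, min_consecutive=1)
        assert res.percentage == 100.0

    def test_frame_offset_compensates_channel_lag(self):
        pos = [(10.0 + t, 20.0) for t in range(10)]
        red = track_from_positions(0, "red", pos, start=1)
        green = track_from_positions(1, "green", pos, start=0)
        lagged = score_comovement([red], [green], r_pair=0.5, frame_offset=1)
        assert lagged.percentage == 100.0

    def test_end_to_end_recovery_of_planted_fraction(self):
        """Full pipeline on an SNR ≥ 10 movie recovers the planted 50%."""
        spec = MovieSpec(seed=17)  # 5 pairs + 5 red-only: planted 50%
        movie = gen_tirf_movie(spec)
        tracks = {}
        for ch in ("red", "green"):
            spots = detect_spots(movie.stack.channel(ch), channel=ch)
            tracks[ch] = link_tracks(spots, r_link=3.0)
        res = score_comovement(tracks["red"], tracks["green"])
        assert res.percentage == pytest.approx(
            100 * movie.planted_coloc_fraction, abs=10
        )


class TestContainers:
    def test_track_frames_must_be_consecutive(self):
        with pytest.raises(ValueError):
            Track(0, "red", [Spot(0, 1, 1, "red", 1.0),
                             Spot(2, 1, 1, "red", 1.0)])

    def test_stack_shape_validation(self):
        with pytest.raises(ValueError):
            FrameStack(np.zeros((3, 8, 8)), np.zeros((4, 8, 8)))

    def test_tracks_to_frame_tidy(self):
        tr = track_from_positions(4, "red", [(1.0, 2.0), (2.0, 3.0)])
        df = tracks_to_frame([tr])
        assert list(df.columns) == ["track_id", "frame", "x", "y",
                                    "channel", "intensity"]
        assert len(df) == 2


class TestSyntheticMovie:
    def test_planted_fraction_by_construction(self):
        spec = MovieSpec(n_coloc_pairs=5, n_red_only=5, n_green_only=0,
                         diffusion_sigma=0.0, noise_sd=0.0, seed=1)
        assert gen_tirf_movie(spec).planted_coloc_fraction == 0.5
        spec_all = MovieSpec(n_coloc_pairs=5, n_red_only=0, n_green_only=0,
                             diffusion_sigma=0.0, noise_sd=0.0, seed=1)
        assert gen_tirf_movie(spec_all).planted_coloc_fraction == 1.0

    def test_truth_within_bounds_and_pairs_share_path(self):
        spec = MovieSpec(seed=2, pair_jitter=0.2)
        movie = gen_tirf_movie(spec)
        t = movie.truth_tracks
        h, w = spec.image_size
        assert ((t.x >= 0) & (t.x < w) & (t.y >= 0) & (t.y < h)).all()
        pair = t[t.coloc & (t.structure_id < 2)]
        red = pair[pair.channel == "red"].sort_values("frame")
        green = pair[pair.channel == "green"].sort_values("frame")
        d = np.hypot(red.x.to_numpy() - green.x.to_numpy(),
                     red.y.to_numpy() - green.y.to_numpy())
        assert d.max() < 6 * spec.pair_jitter + 1e-9

    def test_reproducible_for_fixed_seed(self):
        a = gen_tirf_movie(MovieSpec(seed=13))
        b = gen_tirf_movie(MovieSpec(seed=13))
        assert np.array_equal(a.stack.red, b.stack.red)
        assert a.truth_tracks.equals(b.truth_tracks)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            MovieSpec(n_frames=2)

    def test_overcrowded_field_warns(self):
        with pytest.warns(UserWarning, match="ill-posed"):
            gen_tirf_movie(MovieSpec(image_size=(16, 16), n_coloc_pairs=10,
                                     n_red_only=10, n_green_only=10, seed=0))
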