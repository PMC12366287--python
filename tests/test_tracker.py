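"""Spot detection and Brownian linking against brute-force oracles."""

import itertools

import numpy as np
import pytest

from scoph import tracker
from scoph.tracker import ParticleDetection, TrackerParams

from conftest import gaussian_spot


def det(frame, x, y, m0=100.0, m2=5.0):
    return ParticleDetection(frame=frame, x=x, y=y, m0=m0, m2=m2)


class TestRestore:
    def test_constant_image_restores_to_zero(self):
        img = np.full((64, 64), 37.0)
        out = tracker.restore_image(img, radius=5)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_spot_on_flat_background_peaks_at_center(self):
        img = 10.0 + gaussian_spot((64, 64), cx=30, cy=25, amplitude=100, sigma=2.5)
        out = tracker.restore_image(img, radius=5)
        py, px = np.unravel_index(np.argmax(out), out.shape)
        assert abs(px - 30) <= 1 and abs(py - 25) <= 1

    def test_spot_survives_ramp_background(self):
        # brute-force check on a 64×64 fixture: the spot stays the global max
        ys, xs = np.mgrid[0:64, 0:64]
        img = 0.5 * xs + 0.3 * ys + gaussian_spot((64, 64), cx=28, cy=33, amplitude=80, sigma=2.5)
        out = tracker.restore_image(img, radius=5)
        py, px = np.unravel_index(np.argmax(out), out.shape)
        assert abs(px - 28) <= 1 and abs(py - 33) <= 1

    def test_radius_too_large_rejected(self):
        with pytest.raises(ValueError):
            tracker.restore_image(np.zeros((32, 32)), radius=20)


class TestDetect:
    params = TrackerParams(radius=5)

    def test_single_spot_snr10_detected_subpixel(self):
        rng = np.random.default_rng(0)
        img = gaussian_spot((64, 64), cx=30.0, cy=25.0, amplitude=100, sigma=2.0)
        img += rng.normal(0, 10, img.shape)  # SNR 10
        restored = tracker.restore_image(img, radius=5)
        dets = tracker.detect_particles(restored, self.params)
        assert len(dets) == 1
        assert np.hypot(dets[0].x - 30.0, dets[0].y - 25.0) <= 0.5

    def test_two_spots_three_radii_apart(self):
        img = gaussian_spot((64, 64), 20, 20, 100, 2.0) + gaussian_spot((64, 64), 35, 20, 100, 2.0)
        dets = tracker.detect_particles(tracker.restore_image(img, 5), self.params)
        assert len(dets) == 2

    def test_empty_image_gives_empty_list(self):
        dets = tracker.detect_particles(np.zeros((64, 64)), self.params)
        assert dets == []

    def test_recall_precision_on_random_spots(self):
        # 50 non-overlapping spots vs the placement truth table
        rng = np.random.default_rng(7)
        shape = (512, 512)
        centers = []
        while len(centers) < 50:
            c = rng.uniform(20, 492, size=2)
            if all(np.hypot(c[0] - a, c[1] - b) > 30 for a, b in centers):
                centers.append(tuple(c))
        img = np.zeros(shape)
        for cx, cy in centers:
            img += gaussian_spot(shape, cx, cy, 100, 2.0)
        img += rng.normal(0, 5, shape)
        dets = tracker.detect_particles(tracker.restore_image(img, 5), self.params)
        matched = 0
        for cx, cy in centers:
            if any(np.hypot(d.x - cx, d.y - cy) < 3 for d in dets):
                matched += 1
        recall = matched / len(centers)
        true_pos = sum(
            1 for d in dets if any(np.hypot(d.x - cx, d.y - cy) < 3 for cx, cy in centers)
        )
        precision = true_pos / len(dets)
        assert recall >= 0.95 and precision >= 0.95

    def test_translation_equivariance(self):
        img = np.zeros((128, 128))
        for cx, cy in [(40.0, 50.0), (80.0, 90.0)]:
            img += gaussian_spot(img.shape, cx, cy, 100, 2.0)
        dx, dy = 7, 11
        shifted = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
        d0 = tracker.detect_particles(tracker.restore_image(img, 5), self.params)
        d1 = tracker.detect_particles(tracker.restore_image(shifted, 5), self.params)
        assert len(d0) == len(d1) == 2
        pos0 = sorted((d.x, d.y) for d in d0)
        pos1 = sorted((d.x - dx, d.y - dy) for d in d1)
        for (x0, y0), (x1, y1) in zip(pos0, pos1):
            assert np.hypot(x1 - x0, y1 - y0) < 0.1


class TestDiscriminate:
    def test_cutoff_zero_passes_everything(self):
        dets = [det(0, i, i, m0=10 * i + 1, m2=i) for i in range(6)]
        assert tracker.discriminate(dets, cutoff=0.0) == dets

    def test_cutoff_infinity_removes_everything(self):
        dets = [det(0, i, i) for i in range(4)]
        assert tracker.discriminate(dets, cutoff=np.inf) == []

    def test_median_cutoff_keeps_about_half(self):
        # a tight cluster scores high, isolated outliers score low
        rng = np.random.default_rng(3)
        cluster = [det(0, i, i, m0=100 + rng.normal(0, 1), m2=5 + rng.normal(0, 0.1)) for i in range(5)]
        outliers = [det(0, i, i, m0=1000 + 200 * i, m2=50 + 10 * i) for i in range(5)]
        dets = cluster + outliers
        m0 = np.array([d.m0 for d in dets])
        m2 = np.array([d.m2 for d in dets])
        z = np.column_stack([(m0 - m0.mean()) / m0.std(), (m2 - m2.mean()) / m2.std()])
        d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
        scores = np.exp(-d2 / 2).mean(axis=1)
        kept = tracker.discriminate(dets, cutoff=float(np.median(scores)))
        assert set(id(d) for d in kept) == {
            id(d) for d, s in zip(dets, scores) if s >= np.median(scores)
        }
        assert 0 < len(kept) < len(dets)


class TestLinking:
    params = TrackerParams(radius=5, link_range=4, max_displacement=5.0, min_track_length=1)

    def test_single_moving_spot_one_track(self):
        frames = [[det(f, 10 + 2 * f, 20)] for f in range(10)]
        tracks = tracker.link_tracks(frames, self.params)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10

    def test_two_stationary_spots_no_identity_swap(self):
        frames = [[det(f, 10, 10), det(f, 110, 10)] for f in range(8)]
        tracks = tracker.link_tracks(frames, self.params)
        assert len(tracks) == 2
        for t in tracks:
            assert np.ptp(t.xs) < 1e-9

    def test_gap_shorter_than_link_range_bridged(self):
        # spot vanishes for 2 frames (< link_range) → one track with a gap
        frames = [[det(f, 50 + f, 50)] if f not in (4, 5) else [] for f in range(10)]
        tracks = tracker.link_tracks(frames, self.params)
        assert len(tracks) == 1
        assert set(tracks[0].frames) == set(range(10)) - {4, 5}

    def test_conservation_of_detections(self):
        rng = np.random.default_rng(5)
        frames = [
            [det(f, rng.uniform(0, 200), rng.uniform(0, 200)) for _ in range(rng.integers(0, 6))]
            for f in range(12)
        ]
        total = sum(len(d) for d in frames)
        tracks = tracker.link_tracks(frames, self.params)
        assert sum(len(t) for t in tracks) == total

    def test_matches_bruteforce_assignment_on_small_instance(self):
        # two frames, ≤10 particles: exhaustive search over all matchings
        rng = np.random.default_rng(9)
        f0 = [det(0, x, y) for x, y in rng.uniform(0, 60, size=(5, 2))]
        f1 = [det(1, d.x + rng.uniform(-3, 3), d.y + rng.uniform(-3, 3)) for d in f0]
        rng.shuffle(f1)
        tracks = tracker.link_tracks([f0, f1], self.params)
        linked = {
            (t.detections[0].x, t.detections[1].x) for t in tracks if len(t) == 2
        }

        # brute force: maximize number of feasible links, then minimize cost
        def cost(a, b):
            return (a.x - b.x) ** 2 + (a.y - b.y) ** 2

        best = None
        for perm in itertools.permutations(range(len(f1))):
            pairs = [
                (i, j)
                for i, j in enumerate(perm)
                if np.hypot(f0[i].x - f1[j].x, f0[i].y - f1[j].y) <= 5.0
            ]
            key = (-len(pairs), sum(cost(f0[i], f1[j]) for i, j in pairs))
            if best is None or key < best[0]:
                best = (key, pairs)
        expected = {(f0[i].x, f1[j].x) for i, j in best[1]}
        assert linked == expected

    def test_equals_greedy_nearest_neighbor_when_well_separated(self):
        # spots spaced ≥ 4×max_displacement with Brownian steps (SD 2 px)
        rng = np.random.default_rng(21)
        n, n_frames = 6, 15
        starts = np.array([[30 + 40 * i, 40 + 30 * (i % 2)] for i in range(n)], dtype=float)
        paths = [starts.copy()]
        for _ in range(n_frames - 1):
            paths.append(paths[-1] + rng.normal(0, 1.5, size=(n, 2)))
        frames = [[det(f, x, y) for x, y in p] for f, p in enumerate(paths)]
        tracks = tracker.link_tracks(frames, self.params)
        full = [t for t in tracks if len(t) == n_frames]
        assert len(full) == n
        # greedy nearest-neighbor oracle: each track follows its own path
        for t in full:
            start = np.array([t.xs[0], t.ys[0]])
            i = int(np.argmin(np.hypot(*(starts - start).T)))
            for f in range(n_frames):
                assert np.hypot(t.xs[f] - paths[f][i][0], t.ys[f] - paths[f][i][1]) < 1e-9


def test_track_stack_end_to_end():
    rng = np.random.default_rng(4)
    stack = np.zeros((6, 128, 128))
    pos = np.array([[40.0, 40.0], [90.0, 80.0]])
    for f in range(6):
        for cx, cy in pos:
            stack[f] += gaussian_spot((128, 128), cx, cy, 120, 2.0)
        pos += rng.normal(0, 1.0, pos.shape)
    tracks = tracker.track_stack(stack, TrackerParams(radius=5, min_track_length=1), channel="GREEN")
    long_tracks = [t for t in tracks if len(t) == 6]
    assert len(long_tracks) == 2
    df = tracker.tracks_to_dataframe(tracks)
    assert set(df["channel"]) == {"GREEN"}
    assert len(df) == sum(len(t) for t in tracks)
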