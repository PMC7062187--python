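import warnings

import numpy as np
import pytest

from mitoscreen import (
    assign_puncta,
    detect_puncta,
    segment_nuclei,
    simulate_timelapse,
    track_and_group,
)
from mitoscreen.timelapse import CellTrack, NucleusDetection, peak_window


def render_disc(shape, center, radius, value=100.0):
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2] = value
    return img


class TestSegmentNuclei:
    def test_blank_image_warns_empty(self):
        with pytest.warns(UserWarning, match="blank"):
            assert segment_nuclei(np.zeros((64, 64))) == []

    def test_five_disjoint_nuclei_recovered(self):
        img = np.zeros((200, 200))
        centers = [(30, 30), (30, 160), (100, 100), (170, 40), (170, 170)]
        for c in centers:
            img += render_disc((200, 200), c, 10)
        detections = segment_nuclei(img)
        assert len(detections) == 5
        for c in centers:
            best = min(np.hypot(d.centroid[0] - c[0], d.centroid[1] - c[1]) for d in detections)
            assert best < 2.0

    def test_circle_diameter_from_major_axis(self):
        img = render_disc((100, 100), (50, 50), 15)  # diameter 30 px
        (det,) = segment_nuclei(img)
        assert det.major_axis == pytest.approx(30, abs=2)
        assert det.minor_axis == pytest.approx(30, abs=2)

    def test_small_specks_discarded(self):
        img = render_disc((100, 100), (50, 50), 12)
        img[5, 5] = 200  # single hot pixel
        assert len(segment_nuclei(img)) == 1


class TestDetectPuncta:
    def plateau_image(self, n_pixels):
        img = np.zeros((40, 40))
        img.flat[:0] = 0
        img[20, 10 : 10 + n_pixels] = 100.0
        return img

    def test_area_exactly_five_rejected(self):
        img = self.plateau_image(5)
        assert detect_puncta(img, h=50, smooth_sigma=0) == []

    def test_area_ten_accepted(self):
        img = self.plateau_image(10)
        out = detect_puncta(img, h=50, smooth_sigma=0)
        assert len(out) == 1
        assert out[0][1] == 10

    def test_area_2000_rejected(self):
        img = np.zeros((80, 80))
        img[10:50, 10:60] = 100.0  # 2000-pixel plateau: strict upper bound
        assert detect_puncta(img, h=50, smooth_sigma=0) == []

    def test_blank_image_empty(self):
        assert detect_puncta(np.zeros((32, 32))) == []

    def test_rendered_spots_counted(self, rng):
        img = np.full((120, 120), 8.0)
        yy, xx = np.mgrid[0:120, 0:120]
        for py, px in [(30, 30), (60, 90), (95, 40)]:
            img += 120 * np.exp(-((yy - py) ** 2 + (xx - px) ** 2) / (2 * 2.0**2))
        img += rng.normal(0, 2, img.shape)
        out = detect_puncta(img)
        assert len(out) == 3
        for _, area in out:
            assert 5 < area < 2000

    def test_intensity_rescaling_invariance(self, rng):
        img = np.full((100, 100), 8.0)
        yy, xx = np.mgrid[0:100, 0:100]
        for py, px in [(25, 25), (70, 60)]:
            img += 120 * np.exp(-((yy - py) ** 2 + (xx - px) ** 2) / (2 * 2.0**2))
        img += rng.normal(0, 1, img.shape)
        base = detect_puncta(img)
        scaled = detect_puncta(img * 7.5)
        assert len(base) == len(scaled) == 2


class TestAssignPuncta:
    def nucleus(self, y, x, diameter=20.0):
        return NucleusDetection((y, x), major_axis=diameter, minor_axis=diameter * 0.8, orientation=0)

    def test_distance_exactly_one_diameter_inclusive(self):
        counts, assignment = assign_puncta([((50.0, 70.0), 10)], [self.nucleus(50, 50)])
        assert counts == [1] and assignment == [0]

    def test_beyond_every_diameter_unattributed(self):
        counts, assignment = assign_puncta([((50.0, 71.0), 10)], [self.nucleus(50, 50)])
        assert counts == [0] and assignment == [None]

    def test_nearest_of_two_eligible_wins(self):
        # punctum at x=53: 13 px from nucleus 0, 11 px from nucleus 1,
        # within one diameter of both -> nearest (index 1) wins
        nuclei = [self.nucleus(50, 40), self.nucleus(50, 64)]
        counts, assignment = assign_puncta([((50.0, 53.0), 10)], nuclei)
        assert assignment == [1]
        assert counts == [0, 1]

    def test_attribution_partition(self, rng):
        nuclei = [self.nucleus(30, 30), self.nucleus(80, 80)]
        puncta = [((float(y), float(x)), 10) for y, x in rng.uniform(0, 110, (40, 2))]
        counts, assignment = assign_puncta(puncta, nuclei)
        assert sum(counts) + sum(a is None for a in assignment) == len(puncta)


class TestPeakWindows:
    @pytest.mark.parametrize(
        "frame,window",
        [(0, "h0_2"), (7, "h0_2"), (8, "h0_2"), (9, "h2_4"), (10, "h2_4"),
         (16, "h2_4"), (17, "h4_6"), (24, "h4_6")],
    )
    def test_window_arithmetic_at_15_min_cadence(self, frame, window):
        assert peak_window(frame * 15) == window

    def test_track_peaking_at_frame_10_is_h2_4(self):
        counts = [1] * 25
        counts[10] = 9  # t = 150 min
        track = CellTrack(0, [(0, 0)] * 25, [20.0] * 25, counts)
        assert track.peak_window == "h2_4"

    def test_monotonic_counts_peak_in_last_window(self):
        track = CellTrack(0, [(0, 0)] * 25, [20.0] * 25, list(range(25)))
        assert track.peak_window == "h4_6"

    def test_tie_takes_earliest_frame(self):
        counts = [1] * 25
        counts[8] = counts[17] = 5
        track = CellTrack(0, [(0, 0)] * 25, [20.0] * 25, counts)
        assert track.peak_frame == 8 and track.peak_window == "h0_2"

    def test_max_fold_change(self):
        track = CellTrack(0, [(0, 0)] * 3, [20.0] * 3, [2, 8, 3], interval_min=15)
        assert track.max_fold_change == pytest.approx(4.0)
        zero_base = CellTrack(0, [(0, 0)] * 3, [20.0] * 3, [0, 6, 1], interval_min=15)
        assert zero_base.max_fold_change == pytest.approx(6.0)


class TestSimulateTimelapse:
    def test_empty_stack(self):
        stack, tracks = simulate_timelapse(0, seed=0)
        assert tracks == []
        assert stack.n_frames == 25  # 6 h at 15-min cadence including t=0

    def test_assigned_window_respected(self):
        _, tracks = simulate_timelapse(3, peak_window_assignment=["h2_4"] * 3, seed=1)
        for tr in tracks:
            assert 9 <= tr.peak_frame <= 16
            assert tr.peak_window == "h2_4"

    def test_determinism(self):
        s1, t1 = simulate_timelapse(2, seed=5)
        s2, t2 = simulate_timelapse(2, seed=5)
        np.testing.assert_array_equal(s1.frames, s2.frames)
        assert [t.counts for t in t1] == [t.counts for t in t2]

    def test_span_must_cover_windows(self):
        with pytest.raises(ValueError):
            simulate_timelapse(1, frames=10, interval_min=15)


@pytest.fixture(scope="module")
def stack_and_truth():
    assignment = ["h0_2"] * 3 + ["h2_4"] * 3 + ["h4_6"] * 2
    return simulate_timelapse(8, peak_window_assignment=assignment, seed=3), assignment


class TestTrackAndGroup:

    def test_counts_accurate_per_frame(self, stack_and_truth):
        (stack, truth), _ = stack_and_truth
        errors = []
        for t in range(stack.n_frames):
            nuclei = segment_nuclei(stack.nuclear(t))
            counts, _ = assign_puncta(detect_puncta(stack.reporter(t)), nuclei)
            for tr in truth:
                cy, cx = tr.centroids[t]
                j = int(np.argmin([np.hypot(n.centroid[0] - cy, n.centroid[1] - cx) for n in nuclei]))
                errors.append(abs(counts[j] - tr.counts[t]))
        assert np.mean(np.asarray(errors) <= 1) >= 0.95

    def test_window_fractions_recovered(self, stack_and_truth):
        (stack, truth), assignment = stack_and_truth
        tracks, summary = track_and_group(stack)
        true_frac = {w: assignment.count(w) / len(assignment) for w in ("h0_2", "h2_4", "h4_6")}
        for w, frac in true_frac.items():
            assert summary[w] == pytest.approx(frac, abs=0.05)

    def test_all_tracks_complete_on_static_cells(self, stack_and_truth):
        (stack, _), _ = stack_and_truth
        tracks, _ = track_and_group(stack)
        assert len(tracks) == 8
        assert all(tr.complete for tr in tracks)

    def test_lost_cell_terminates_track(self, stack_and_truth):
        (stack, _), _ = stack_and_truth
        frames = stack.frames.copy()
        # blank one nucleus out of the nuclear channel midway through
        tracks0, _ = track_and_group(stack)
        cy, cx = tracks0[0].centroids[12]
        frames[12:, 0, int(cy) - 15 : int(cy) + 15, int(cx) - 15 : int(cx) + 15] = 5.0
        from mitoscreen.timelapse import TimelapseStack

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tracks, _ = track_and_group(TimelapseStack(frames, stack.interval_min))
        assert sum(not tr.complete for tr in tracks) >= 1

    def test_too_few_frames_rejected(self, stack_and_truth):
        (stack, _), _ = stack_and_truth
        from mitoscreen.timelapse import TimelapseStack

        with pytest.raises(ValueError):
            track_and_group(TimelapseStack(stack.frames[:1], 15))
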