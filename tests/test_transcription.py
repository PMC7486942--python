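"""Spot calling: shell geometry against brute-force enumeration, rank-based
candidate thresholds, integrated-intensity recovery, pulses and mitosis
alignment."""

import numpy as np
import pandas as pd
import pytest

from locreset import transcription as tx
from locreset.synthetic import BurstProgram, SceneConfig, generate_spot_movie


class TestShellGeometry:
    def test_disk_and_shell_counts_match_brute_force(self):
        # independent enumeration over a wide integer window
        disk = shell = 0
        for dy in range(-10, 11):
            for dx in range(-10, 11):
                r = np.hypot(dy, dx)
                disk += r < 3.5
                shell += 3.5 <= r < 4.5
        assert len(tx.disk_offsets()) == disk == 37
        assert len(tx.shell_offsets()) == shell == 32

    def test_disk_and_shell_disjoint(self):
        d = {tuple(p) for p in tx.disk_offsets()}
        s = {tuple(p) for p in tx.shell_offsets()}
        assert not d & s


def flat_nucleus(shape=(80, 80), lo=10, hi=70, value=100.0):
    lab = np.zeros(shape, dtype=np.int32)
    lab[lo:hi, lo:hi] = 1
    img = np.zeros(shape)
    img[lab == 1] = value
    return img, lab


def add_gaussian(img, cy, cx, amplitude, sigma=1.5):
    yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
    img = img + amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                                   / (2 * sigma**2))
    return img


class TestDetectCandidates:
    def test_rank_threshold_keeps_at_most_three_pixels_per_10000(self):
        rng = np.random.default_rng(0)
        lab = np.zeros((110, 110), dtype=np.int32)
        lab[5:105, 5:105] = 1  # 10000 pixels
        img = np.zeros((110, 110))
        img[lab == 1] = rng.permutation(10000).astype(float)  # all distinct
        thr = np.percentile(img[lab == 1], 99.97)
        assert np.sum(img[lab == 1] > thr) <= 3

    def test_single_spot_localized_within_one_pixel(self):
        img, lab = flat_nucleus()
        noise = np.random.default_rng(1).normal(0, 2.0, img.shape)
        img = add_gaussian(img + noise, 40, 37, amplitude=20.0)  # 10 sigma
        cands = tx.detect_candidates(img, lab)
        assert len(cands) == 1
        y, x = cands[0]["position"]
        assert abs(y - 40) <= 1 and abs(x - 37) <= 1

    def test_empty_frame_gives_empty_list(self):
        img = np.zeros((50, 50))
        lab = np.zeros((50, 50), dtype=np.int32)
        assert tx.detect_candidates(img, lab) == []

    def test_candidate_set_invariant_under_affine_rescale(self):
        img, lab = flat_nucleus()
        img = add_gaussian(img, 40, 40, 25.0)
        img += np.random.default_rng(2).normal(0, 1.0, img.shape)
        c1 = tx.detect_candidates(img, lab)
        c2 = tx.detect_candidates(4.0 * img + 77.0, lab)
        assert [c["position"] for c in c1] == [c["position"] for c in c2]


class TestFilterSpots:
    def test_uniform_nucleus_rejected(self):
        img, lab = flat_nucleus()
        cand = [{"nucleus_label": 1, "position": (40, 40)}]
        spots = tx.filter_spots(cand, img, intensity_threshold=10.0)
        assert len(spots) == 1
        assert spots[0].integrated_intensity == pytest.approx(0.0, abs=1e-9)
        assert not spots[0].passed

    def test_programmed_photon_count_recovered(self):
        # analytic Gaussian mass inside r < 3.5 px for sigma = 1.5
        sigma, photons = 1.5, 5000.0
        img, lab = flat_nucleus()
        yy, xx = np.mgrid[:80, :80]
        g = np.exp(-((yy - 40.0) ** 2 + (xx - 40.0) ** 2) / (2 * sigma**2))
        img = img + photons * g / g.sum()
        cand = [{"nucleus_label": 1, "position": (40, 40)}]
        spot = tx.filter_spots(cand, img, intensity_threshold=1.0)[0]
        # net estimate = mass inside r < 3.5 minus the PSF tail that the
        # shell-background subtraction removes (37 px at the annulus mean)
        mass_in = 1 - np.exp(-(3.5**2) / (2 * sigma**2))
        mass_shell = (np.exp(-(3.5**2) / (2 * sigma**2))
                      - np.exp(-(4.5**2) / (2 * sigma**2)))
        shell_area = np.pi * (4.5**2 - 3.5**2)
        expected = photons * (mass_in - 37 * mass_shell / shell_area)
        assert spot.integrated_intensity == pytest.approx(expected, rel=0.03)
        assert spot.passed

    def test_border_clipped_candidate_excluded(self):
        img, lab = flat_nucleus()
        cand = [{"nucleus_label": 1, "position": (2, 40)}]
        assert tx.filter_spots(cand, img, intensity_threshold=0.0) == []


class TestPulses:
    def test_single_frame_spot_is_duration_one_pulse(self):
        spots = pd.DataFrame({"cell_id": [1], "frame": [5], "intensity": [9.0]})
        pulses = tx.track_pulses(spots)
        assert len(pulses) == 1 and pulses[0].duration == 1

    def test_gap_tolerance_merges_single_missed_frame(self):
        spots = pd.DataFrame({"cell_id": [1] * 4, "frame": [3, 4, 6, 7],
                              "intensity": [1.0] * 4})
        pulses = tx.track_pulses(spots, gap_tolerance=1)
        assert len(pulses) == 1 and pulses[0].duration == 5
        pulses0 = tx.track_pulses(spots, gap_tolerance=0)
        assert len(pulses0) == 2

    def test_two_concurrent_spots_stay_distinct_threads(self):
        spots = pd.DataFrame({"cell_id": [1, 2], "frame": [0, 0],
                              "intensity": [1.0, 2.0]})
        assert len(tx.track_pulses(spots)) == 2

    def test_telegraph_mean_on_time_recovered_from_spot_movie(self):
        # full detection chain on a synthetic burst movie at high spot SNR
        cfg = SceneConfig(shape=(40, 1, 200, 200), n_cells=6,
                          read_noise_sd=2.0, step_sigma_px=0.0,
                          nucleolus_fraction=0.0, seed=23)
        bursts = BurstProgram.uniform(6, on_rate=0.2, off_rate=0.2,
                                      intensity=4000.0)
        movie, gt = generate_spot_movie(cfg, bursts)
        # calibration pass on a matched spot-free scene
        dark = BurstProgram.uniform(6, on_rate=0.2, off_rate=0.2, intensity=0.0)
        movie0, gt0 = generate_spot_movie(cfg, dark)
        thr = tx.calibrate_intensity_threshold(
            [movie0.channel("spot")[0, 0]], [gt0.labels[0, 0]], seed=1)
        spot_ch = movie.channel("spot")
        rows = []
        for t in range(40):
            img = spot_ch[t, 0]
            lab = gt.labels[t, 0]
            cands = tx.detect_candidates(img, lab)
            for s in tx.filter_spots(cands, img, intensity_threshold=thr,
                                     frame_index=t):
                if s.passed:
                    rows.append({"cell_id": s.nucleus_label, "frame": s.frame,
                                 "intensity": s.integrated_intensity})
        pulses = tx.track_pulses(pd.DataFrame(rows), gap_tolerance=0)
        mean_dur = np.mean([p.duration for p in pulses])
        # ground-truth mean on-run length from the realized state sequences
        runs = []
        for st in gt.burst_states:
            run = 0
            for v in np.r_[st, False]:
                if v:
                    run += 1
                elif run:
                    runs.append(run)
                    run = 0
        assert mean_dur == pytest.approx(np.mean(runs), rel=0.15)


class TestActivity:
    @staticmethod
    def cohort(active_by_frame):
        rows = []
        for f, actives in enumerate(active_by_frame):
            for cid, a in enumerate(actives):
                rows.append({"frame": f, "cell_id": cid, "active": a})
        return pd.DataFrame(rows)

    def test_all_transcribing_flat_one(self):
        df = self.cohort([[True, True]] * 5)
        assert (tx.activity_timecourse(df) == 1.0).all()

    def test_window_normalization_arithmetic(self):
        df = self.cohort([[True, False, False, False, False]] * 4
                         + [[True, True, False, False, False]] * 2)
        trace = tx.activity_timecourse(df, normalization_window=(0, 4))
        assert trace.iloc[-1] == pytest.approx(2.0)

    def test_step_cohort_normalizes_to_step_ratio(self, rng):
        # programmed on-fraction steps 0.1 -> 0.4: normalized trace ~ 1 -> 4
        n_cells, n_pre, n_post = 400, 10, 10
        frames = []
        for f in range(n_pre + n_post):
            p = 0.1 if f < n_pre else 0.4
            frames.append(rng.random(n_cells) < p)
        df = self.cohort(frames)
        trace = tx.activity_timecourse(df, normalization_window=(0, n_pre))
        post = trace.iloc[n_pre:].mean()
        sd = 3 * np.sqrt(0.4 * 0.6 / (n_cells * n_post)) / 0.1
        assert post == pytest.approx(4.0, abs=sd + 0.2)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            tx.activity_timecourse(pd.DataFrame(columns=["frame", "cell_id",
                                                         "active"]))


class TestAlignMitosis:
    @staticmethod
    def simple_cohort(parent_active, d1_active, d2_active, cyto=5, n=10):
        rows = []
        for f in range(cyto):
            rows.append({"cell_id": 1, "frame": f, "active": parent_active})
        for f in range(cyto, n):
            rows.append({"cell_id": 2, "frame": f, "active": d1_active})
            rows.append({"cell_id": 3, "frame": f, "active": d2_active})
        return pd.DataFrame(rows)

    def test_constant_activity_aligns_to_unity(self):
        df = self.simple_cohort(True, True, False)
        ann = [tx.DivisionAnnotation(1, 2, 3, 5)]
        out = tx.align_mitosis(ann, df)
        assert (out["normalized_activity"] == 1.0).all()

    def test_or_rule_dominates_single_daughters(self):
        df = self.simple_cohort(True, False, True)
        ann = [tx.DivisionAnnotation(1, 2, 3, 5)]
        out = tx.align_mitosis(ann, df)
        post = out["activity"][out["activity"].index >= 0]
        assert (post == 1.0).all()  # OR(False, True) = True

    def test_nc_concatenation_uses_daughter_mean(self):
        df = self.simple_cohort(True, True, True)
        ann = [tx.DivisionAnnotation(1, 2, 3, 5)]
        nc = {1: pd.Series(2.0, index=range(5)),
              2: pd.Series(1.0, index=range(5, 10)),
              3: pd.Series(3.0, index=range(5, 10))}
        out = tx.align_mitosis(ann, df, nc_traces=nc)
        trace = out["nc_aligned"][1]
        assert trace.loc[-1] == pytest.approx(2.0)
        assert trace.loc[0] == pytest.approx(2.0)  # mean of 1.0 and 3.0

    def test_missing_daughter_skipped_and_counted(self):
        df = self.simple_cohort(True, True, True)
        ann = [tx.DivisionAnnotation(1, 2, 3, 5),
               tx.DivisionAnnotation(4, 8, 9, 5)]
        out = tx.align_mitosis(ann, df)
        assert out["skipped_divisions"] == 1

    def test_post_division_burst_shows_programmed_peak(self, rng):
        # on-fraction triples for a window after division; aligned activity
        # peaks near 3 in that window
        rows, anns = [], []
        n_div, cyto, n = 300, 10, 30
        for k in range(n_div):
            p_id, d1, d2 = 3 * k + 1, 3 * k + 2, 3 * k + 3
            anns.append(tx.DivisionAnnotation(p_id, d1, d2, cyto))
            for f in range(cyto):
                rows.append({"cell_id": p_id, "frame": f,
                             "active": bool(rng.random() < 0.2)})
            for f in range(cyto, n):
                p = 0.6 if f < cyto + 8 else 0.2
                # per-daughter probability chosen so OR ~ p
                q = 1 - np.sqrt(1 - p)
                rows.append({"cell_id": d1, "frame": f,
                             "active": bool(rng.random() < q)})
                rows.append({"cell_id": d2, "frame": f,
                             "active": bool(rng.random() < q)})
        out = tx.align_mitosis(anns, pd.DataFrame(rows))
        norm = out["normalized_activity"]
        peak = norm[(norm.index > 0) & (norm.index <= 7)].mean()
        assert peak == pytest.approx(3.0, rel=0.15)
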