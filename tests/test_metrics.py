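"""Tests for the RDF / segregation-score / MSD quantification stack."""

import numpy as np
import pytest

import adhesim as A
from adhesim import fixtures, metrics
from adhesim.metrics import (PeakWindow, compute_rdf, disc_distance_pdf,
                             peak_area, segregation_score,
                             symmetry_split_scores, window_sensitivity_scan)


def csr_frame(n=500, seed=0, R=500.0):
    spec = fixtures.FixtureSpec(n_points=n, seed=seed, field_radius=R)
    return fixtures.generate(spec)


class TestDiscDistancePdf:
    def test_integrates_to_one(self):
        d = np.linspace(0, 1000, 4001)
        total = np.trapezoid(disc_distance_pdf(d, 500.0), d)
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_mc_and_analytic_normalisations_agree(self):
        pts, labs = csr_frame(400, seed=3)
        g_mc = compute_rdf((pts, labs), normalization="mc",
                           rng=np.random.default_rng(1))
        g_an = compute_rdf((pts, labs), normalization="analytic")
        for cls in ("RR", "GG", "RG"):
            # identical observed counts, so differences are purely the
            # Monte-Carlo error of the CSR expectation
            sel = g_an.g(cls) > 0
            ratio = g_mc.g(cls)[sel] / g_an.g(cls)[sel]
            assert np.abs(np.median(ratio) - 1) < 0.05


class TestComputeRdf:
    def test_csr_is_flat_at_one(self):
        frames = [csr_frame(500, seed=s) for s in range(6)]
        rdf = compute_rdf(frames, normalization="analytic")
        for cls in ("RR", "GG", "RG"):
            g = rdf.g(cls)[2:]  # first bins have few pairs
            assert abs(g.mean() - 1.0) < 0.05
            assert g.max() < 1.6

    def test_two_far_clusters_show_like_peaks_and_no_mixed_contacts(self):
        rng = np.random.default_rng(0)
        red = rng.normal(0, 15, size=(60, 2)) + [-250, 0]
        grn = rng.normal(0, 15, size=(60, 2)) + [250, 0]
        pts = np.vstack([red, grn])
        labs = np.array([0] * 60 + [1] * 60)
        rdf = compute_rdf((pts, labs), normalization="analytic")
        win = PeakWindow()
        assert peak_area(rdf, win, "RR") > 10
        assert peak_area(rdf, win, "GG") > 10
        assert peak_area(rdf, win, "RG") == 0.0

    def test_empty_class_rejected(self):
        pts = np.zeros((10, 2))
        labs = np.zeros(10, dtype=int)  # all RED
        with pytest.raises(ValueError):
            compute_rdf((pts, labs))

    def test_bad_bin_width_rejected(self):
        pts, labs = csr_frame(50)
        with pytest.raises(ValueError):
            compute_rdf((pts, labs), bin_width=0.0)


class TestPeakArea:
    def test_constant_unity_curve_gives_three(self):
        edges = np.arange(0, 120.1, 20 / 3)
        ones = np.ones(len(edges) - 1)
        rdf = metrics.RdfResult(edges, ones, ones, ones)
        assert peak_area(rdf, PeakWindow(), "RR") == pytest.approx(3.0)

    def test_zero_window_gives_zero(self):
        edges = np.arange(0, 120.1, 20 / 3)
        g = np.ones(len(edges) - 1)
        g[3:6] = 0.0  # bins covering [20, 40)
        rdf = metrics.RdfResult(edges, g, g, g)
        assert peak_area(rdf, PeakWindow(), "GG") == 0.0

    def test_agrees_with_brute_force_pair_count(self):
        """peak_area on a small field equals a direct pairwise-distance
        count divided by the analytic CSR expectation, bin by bin."""
        pts, labs = csr_frame(40, seed=9)
        rdf = compute_rdf((pts, labs), normalization="analytic")
        win = PeakWindow()
        red = pts[labs == 0]
        # brute force: count red-red pairs per bin, divide by expectation
        expected_prob = metrics._csr_bin_probs_analytic(rdf.bin_edges, 500.0)
        n_pairs = len(red) * (len(red) - 1) / 2
        count = np.zeros(len(rdf.bin_edges) - 1)
        for i in range(len(red)):
            for j in range(i + 1, len(red)):
                d = np.hypot(*(red[i] - red[j]))
                k = int(d // (20 / 3))
                if k < len(count):
                    count[k] += 1
        centres = rdf.bin_centres
        sel = (centres > win.start) & (centres < win.stop)
        brute = (count[sel] / (n_pairs * expected_prob[sel])).sum()
        assert peak_area(rdf, win, "RR") == pytest.approx(brute, rel=1e-9)

    def test_window_outside_range_rejected(self):
        pts, labs = csr_frame(50)
        rdf = compute_rdf((pts, labs), normalization="analytic", r_max=60.0)
        with pytest.raises(ValueError):
            peak_area(rdf, PeakWindow(start=55.0), "RR")


class TestSegregationScore:
    def test_equal_areas_give_two(self):
        edges = np.arange(0, 120.1, 20 / 3)
        ones = np.ones(len(edges) - 1)
        rdf = metrics.RdfResult(edges, 2 * ones, 2 * ones, 2 * ones)
        assert segregation_score(rdf).S == pytest.approx(2.0)

    def test_zero_mixed_area_flagged_undefined(self):
        edges = np.arange(0, 120.1, 20 / 3)
        ones = np.ones(len(edges) - 1)
        rdf = metrics.RdfResult(edges, ones, ones, 0 * ones)
        res = segregation_score(rdf)
        assert res.undefined
        assert np.isnan(res.S)

    def test_csr_mixture_scores_two(self):
        """Random labels on random points: S = 2.0 +/- 0.3 averaged
        over ten 500-point fields."""
        scores = []
        for s in range(10):
            res = metrics.score_frames(csr_frame(500, seed=100 + s),
                                       normalization="analytic")
            scores.append(res.S)
        assert np.mean(scores) == pytest.approx(2.0, abs=0.3)

    def test_invariant_under_rotation_reflection_and_label_swap(self):
        pts, labs = csr_frame(300, seed=5)
        base = metrics.score_frames((pts, labs),
                                    normalization="analytic").S
        th = 1.1
        rot = pts @ np.array([[np.cos(th), -np.sin(th)],
                              [np.sin(th), np.cos(th)]]).T
        refl = pts * [1, -1]
        assert metrics.score_frames((rot, labs),
                                    normalization="analytic").S \
            == pytest.approx(base, rel=1e-9)
        assert metrics.score_frames((refl, labs),
                                    normalization="analytic").S \
            == pytest.approx(base, rel=1e-9)
        swapped = 1 - labs
        assert metrics.score_frames((pts, swapped),
                                    normalization="analytic").S \
            == pytest.approx(base, rel=1e-9)

    def test_split_halves_scores_order_of_hundred(self):
        """A fully split two-colour field at confluent spacing scores
        two orders of magnitude above the random baseline."""
        spec = fixtures.FixtureSpec(n_points=500, pattern="SPLIT_HALVES",
                                    min_separation=30.0, seed=2)
        res = metrics.score_frames(fixtures.generate(spec),
                                   normalization="analytic")
        assert res.undefined or res.S > 30.0


class TestMsd:
    def test_stationary_cells_have_zero_slope(self):
        xy = np.zeros((10, 5, 2))
        stack = A.FrameStack(np.arange(10), xy, np.zeros(5, dtype=int),
                             units="units")
        fit = A.compute_msd(stack)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_random_walk_slope_recovered(self):
        stack = fixtures.generate_walk(400, 300, step_sigma=0.1, seed=3)
        fit = A.compute_msd(stack, max_lag=50)
        assert fit.slope == pytest.approx(4 * 0.1**2, rel=0.05)
        assert fit.is_linear

    def test_ballistic_motion_flagged_nonlinear(self):
        t = np.arange(40)
        v = 0.5
        xy = np.zeros((40, 3, 2))
        xy[:, :, 0] = v * t[:, None]
        stack = A.FrameStack(t, xy, np.zeros(3, dtype=int), units="units")
        fit = A.compute_msd(stack)
        assert fit.alpha == pytest.approx(2.0, abs=0.1)
        assert not fit.is_linear

    def test_single_frame_rejected(self):
        stack = A.FrameStack([0], np.zeros((1, 3, 2)),
                             np.zeros(3, dtype=int))
        with pytest.raises(ValueError):
            A.compute_msd(stack)


class TestSymmetrySplits:
    def test_mirror_symmetric_input_reproduces_full_score(self):
        rng = np.random.default_rng(4)
        half = rng.uniform([-400, -400], [0, 400], size=(150, 2))
        inside = np.linalg.norm(half, axis=1) <= 500
        half = half[inside]
        labs_half = (np.arange(len(half)) % 2)
        pts = np.vstack([half, half * [-1, 1]])
        labs = np.concatenate([labs_half, labs_half])
        full = metrics.score_frames((pts, labs),
                                    normalization="analytic").S
        res = symmetry_split_scores((pts, labs), normalization="analytic")
        assert res["left"].S == pytest.approx(full, rel=1e-9)
        assert res["right"].S == pytest.approx(full, rel=1e-9)

    def test_csr_halves_score_near_two(self):
        pts, labs = csr_frame(600, seed=8)
        res = symmetry_split_scores((pts, labs), normalization="analytic")
        assert set(res) == {"left", "right", "top", "bottom"}
        for r in res.values():
            assert r.S == pytest.approx(2.0, abs=0.8)


class TestWindowScan:
    def test_constant_curves_score_two_everywhere(self):
        edges = np.arange(0, 120.1, 20 / 3)
        ones = np.ones(len(edges) - 1)
        rdf = metrics.RdfResult(edges, ones, ones, ones)
        grid, best = window_sensitivity_scan(rdf, widths=[10, 20],
                                             displacements=[-5, 0, 5])
        assert np.allclose(grid[np.isfinite(grid)], 2.0)
        assert best == pytest.approx(2.0)

    def test_maximum_at_least_default_score(self):
        pts, labs = csr_frame(300, seed=12)
        rdf = compute_rdf((pts, labs), normalization="analytic")
        default = segregation_score(rdf).S
        _, best = window_sensitivity_scan(rdf, widths=[20],
                                          displacements=[-5, 0, 5])
        assert best >= default - 1e-12


class TestDensityTrend:
    def test_like_peak_height_decreases_with_density(self):
        """Adhered populations at low density show a far larger
        like-type contact peak (relative to chance) than dense ones."""
        from adhesim import engine
        peaks = []
        for n_cells in (100, 400, 800):
            cfg = A.SimConfig(n_cells=n_cells, n_steps=1500,
                              snapshot_every=100, seed=33,
                              adhesion=A.AdhesionParams(unhook=5e-5))
            stack = engine.run(cfg)
            rdf = compute_rdf(stack.tail(3), normalization="analytic")
            win = PeakWindow()
            peaks.append(peak_area(rdf, win, "RR")
                         + peak_area(rdf, win, "GG"))
        assert peaks[0] > peaks[1] > peaks[2]
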