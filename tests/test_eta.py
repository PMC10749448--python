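import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import lpshells as lps
from lpshells.core_geometry import Frame, Trajectory


def brute_force_pair(frame, w, lp_index, h_index):
    """Independent recomputation of (r_lp_h, alpha, beta, eta) using plain
    math on raw coordinates (box assumed large enough that no wrap occurs,
    which holds for the synthetic fixtures)."""
    def mi(v, box=frame.box_edge):
        return tuple(c - box * math.floor(c / box + 0.5) for c in v)

    def sub(a, b):
        return mi((a[0] - b[0], a[1] - b[1], a[2] - b[2]))

    def norm(v):
        return math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)

    def ang(u, v):
        c = (u[0] * v[0] + u[1] * v[1] + u[2] * v[2]) / (norm(u) * norm(v))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    h = frame.h1_xyz[w] if h_index == 0 else frame.h2_xyz[w]
    o, ion, lp = frame.o_xyz[w], frame.ion_xyz, frame.lp_xyz[lp_index]
    alpha = ang(sub(lp, ion), sub(h, ion))
    beta = ang(sub(h, o), sub(lp, h))
    r = norm(sub(lp, h))
    eta = r / (
        math.cos(math.radians(alpha) / 2) * math.cos(math.radians(beta) / 2)
    )
    return r, alpha, beta, eta


def linear_hbond_frame(r_xh=2.2, d_lp=0.5, box=14.0, perpendicular_h=False):
    """Ion at center; single water on the +x lone-pair axis (or with H at
    90 degrees off-axis)."""
    ion = np.full(3, box / 2)
    axis = np.array([1.0, 0.0, 0.0])
    lp = ion + d_lp * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
    )
    if perpendicular_h:
        h1 = ion + r_xh * np.array([0.0, 1.0, 0.0])
        o = h1 + 0.97 * np.array([0.0, 1.0, 0.0])
    else:
        h1 = ion + r_xh * axis
        o = h1 + 0.97 * axis
    # second H well out of the way
    h2 = o + 0.97 * np.array([0.0, 1.0, 0.0])
    return Frame(
        time=0.0, box_edge=box, ion_xyz=ion, lp_xyz=lp,
        o_xyz=o[None], h1_xyz=h1[None], h2_xyz=h2[None],
        water_ids=np.array([0]),
    )


class TestEtaValue:
    def test_linear_limit_equals_bare_distance(self):
        assert lps.eta_value(2.0, 0.0, 0.0) == pytest.approx(2.0)

    def test_strictly_increasing_in_distance(self):
        assert lps.eta_value(4.0, 25.0, 40.0) > lps.eta_value(2.0, 25.0, 40.0)

    def test_proportional_in_distance(self):
        # the distance dependence is purely multiplicative
        assert lps.eta_value(4.0, 30.0, 60.0) == pytest.approx(
            2 * lps.eta_value(2.0, 30.0, 60.0)
        )

    @given(
        st.floats(0.5, 6.0),
        st.floats(0.0, 175.0),
        st.floats(0.0, 175.0),
        st.floats(1.0, 1.1),
        st.floats(0.1, 4.0),
    )
    def test_monotone_in_each_argument(self, r, a, b, fr, da):
        base = lps.eta_value(r, a, b)
        assert lps.eta_value(r * fr, a, b) >= base
        assert lps.eta_value(r, min(a + da, 180.0), b) >= base
        assert lps.eta_value(r, a, min(b + da, 180.0)) >= base

    def test_angles_outside_range_rejected(self):
        with pytest.raises(lps.DomainError):
            lps.eta_value(2.0, -1.0, 0.0)
        with pytest.raises(lps.DomainError):
            lps.eta_value(2.0, 0.0, 180.5)
        with pytest.raises(lps.DomainError):
            lps.eta_value(-2.0, 0.0, 0.0)


class TestPairGeometry:
    def test_ideal_linear_bond_has_zero_angles(self):
        frame = linear_hbond_frame()
        pg = lps.pair_geometry(frame, 0, 0, 0)
        assert pg.alpha == pytest.approx(0.0, abs=1e-9)
        assert pg.beta == pytest.approx(0.0, abs=1e-9)
        assert pg.r_lp_h == pytest.approx(2.2 - 0.5)
        assert pg.eta == pytest.approx(2.2 - 0.5)

    def test_perpendicular_hydrogen_gives_alpha_90(self):
        frame = linear_hbond_frame(perpendicular_h=True)
        pg = lps.pair_geometry(frame, 0, 0, 0)
        assert pg.alpha == pytest.approx(90.0, abs=1e-9)

    def test_matches_independent_recomputation(self, small_traj):
        for frame in small_traj.frames[::25]:
            for w in range(frame.n_waters):
                for lp_index in range(4):
                    for h_index in range(2):
                        pg = lps.pair_geometry(frame, w, lp_index, h_index)
                        r, a, b, e = brute_force_pair(frame, w, lp_index, h_index)
                        assert pg.r_lp_h == pytest.approx(r, abs=1e-10)
                        assert pg.alpha == pytest.approx(a, abs=1e-8)
                        assert pg.beta == pytest.approx(b, abs=1e-8)
                        assert pg.eta == pytest.approx(e, abs=1e-8)


class TestEtaIonWater:
    def test_minimum_over_eight_combinations(self, small_traj):
        for frame in small_traj.frames[::10]:
            for w in range(frame.n_waters):
                best = lps.eta_ion_water(frame, w)
                all_etas = [
                    brute_force_pair(frame, w, lp, h)[3]
                    for lp in range(4)
                    for h in range(2)
                ]
                assert best.eta == pytest.approx(min(all_etas), abs=1e-10)

    def test_tie_breaks_to_lowest_lp_then_h(self):
        # symmetric construction: H1 equidistant/equiangular to LP on +y and +z
        box = 14.0
        ion = np.full(3, box / 2)
        lp = ion + 0.5 * np.array(
            [[0, 1, 0], [0, 0, 1], [0, -1, 0], [0, 0, -1]], dtype=float
        )
        d = np.array([0.0, 1.0, 1.0]) / np.sqrt(2)
        h1 = ion + 2.2 * d
        o = h1 + 0.97 * d
        h2 = o + 0.97 * np.array([1.0, 0.0, 0.0])
        frame = Frame(
            time=0.0, box_edge=box, ion_xyz=ion, lp_xyz=lp,
            o_xyz=o[None], h1_xyz=h1[None], h2_xyz=h2[None],
            water_ids=np.array([0]),
        )
        g0 = lps.pair_geometry(frame, 0, 0, 0)
        g1 = lps.pair_geometry(frame, 0, 1, 0)
        assert g0.eta == pytest.approx(g1.eta, abs=1e-9)
        assert lps.eta_ion_water(frame, 0).lp_index == 0

    def test_eta_series_agrees_with_scalar_path(self, small_traj):
        etas, r_xo = lps.eta_series(small_traj)
        for fi in range(0, small_traj.n_frames, 25):
            frame = small_traj.frames[fi]
            for w in range(frame.n_waters):
                pg = lps.eta_ion_water(frame, w)
                assert etas[fi, w] == pytest.approx(pg.eta, abs=1e-10)
                assert r_xo[fi, w] == pytest.approx(pg.r_xo, abs=1e-10)

    def test_invariant_under_rigid_motion_and_lp_relabeling(self, noise_free_traj):
        # compact configuration: no pair needs rewrapping before or after
        # the motion, so minimum-image distances are genuinely invariant
        frame = noise_free_traj.frames[0]
        rot = Rotation.from_rotvec([0.3, -0.5, 0.7])
        pivot = frame.ion_xyz
        shift = np.array([1.0, -2.0, 0.5])

        def move(x):
            return rot.apply(x - pivot) + pivot + shift

        frame2 = Frame(
            time=0.0, box_edge=frame.box_edge,
            ion_xyz=move(frame.ion_xyz),
            lp_xyz=move(frame.lp_xyz)[::-1],   # relabeled lone pairs
            o_xyz=move(frame.o_xyz),
            h1_xyz=move(frame.h1_xyz),
            h2_xyz=move(frame.h2_xyz),
            water_ids=frame.water_ids,
        )
        for w in range(frame.n_waters):
            e0 = lps.eta_ion_water(frame, w).eta
            e1 = lps.eta_ion_water(frame2, w).eta
            assert e1 == pytest.approx(e0, abs=1e-9)


class TestEtaDistribution:
    def test_identical_geometries_occupy_single_bin(self):
        # r_tight_mean chosen so the constant η (r_XH - d_lp = 1.75) sits in
        # the middle of a bin rather than on an edge
        params = lps.chloride_preset(
            n_tight=4, n_loose=0, n_bulk=0, angular_noise_deg=0.0,
            r_tight_sigma=0.0, r_tight_mean=2.25,
            k_TL=0.0, k_LT=0.0, k_LB=0.0, k_BL=0.0, n_frames=20, seed=7,
        )
        traj = lps.generate_trajectory(params)
        dist = lps.eta_distribution(traj, "all", eta_range=(0.0, 4.0))
        # 4 identical tight waters per frame: all mass in one bin
        assert np.count_nonzero(dist.p) == 1
        assert np.sum(dist.p) * dist.bin_width == pytest.approx(1.0)

    def test_rank_selections_count_seven_waters_per_frame(self, default_traj):
        d14 = lps.eta_distribution(default_traj, "rank14")
        d57 = lps.eta_distribution(default_traj, "rank57")
        assert d14.n_samples == 4 * default_traj.n_frames
        assert d57.n_samples == 3 * default_traj.n_frames

    def test_rank14_mode_near_tight_eta(self, default_traj):
        """The rank 1-4 distribution peaks near the geometric tight-water η
        implied by the generator: (r_XH - d_lp) at the linear limit."""
        params = default_traj.metadata["params"]
        d14 = lps.eta_distribution(default_traj, "rank14")
        expected = params.r_tight_mean - params.d_lp
        assert lps.eta_peak(d14) == pytest.approx(expected, abs=0.15)

    def test_empty_selection_rejected(self, small_traj):
        mask = np.zeros((small_traj.n_frames, 10), dtype=bool)
        with pytest.raises(lps.ContractError):
            lps.eta_distribution(small_traj, mask)

    def test_normalization(self, default_traj):
        d = lps.eta_distribution(default_traj, "all")
        assert np.sum(d.p) * d.bin_width == pytest.approx(1.0)


class TestCutoffFromIntersection:
    def _gaussian_dist(self, mean, sd, tag, bins=np.arange(0.0, 6.0, 0.02)):
        centers = bins + 0.01
        p = np.exp(-((centers - mean) ** 2) / (2 * sd**2)) / (sd * np.sqrt(2 * np.pi))
        return lps.EtaDistribution(centers, p, tag, 0.02, 10_000)

    def test_recovers_analytic_gaussian_crossing(self):
        d14 = self._gaussian_dist(2.0, 0.2, "rank14")
        d57 = self._gaussian_dist(3.5, 0.5, "rank57")
        # closed-form: solve log p1(x) = log p2(x) between the means
        a = 1 / (2 * 0.2**2) - 1 / (2 * 0.5**2)
        b = -2.0 / 0.2**2 + 3.5 / 0.5**2
        c = 2.0**2 / (2 * 0.2**2) - 3.5**2 / (2 * 0.5**2) + np.log(0.2 / 0.5)
        roots = np.roots([a, b, c])
        analytic = roots[(roots > 2.0) & (roots < 3.5)][0]
        found = lps.eta_cutoff_from_intersection(d14, d57)
        assert found == pytest.approx(analytic, abs=0.02)

    def test_identical_distributions_never_cross(self):
        d = self._gaussian_dist(2.0, 0.3, "rank14")
        with pytest.raises(lps.NoIntersectionError):
            lps.eta_cutoff_from_intersection(d, d)

    def test_disjoint_supports_never_cross(self):
        bins = np.arange(0.0, 6.0, 0.02)
        centers = bins + 0.01
        p1 = np.where(centers < 2.0, 1.0, 0.0)
        p2 = np.where(centers > 4.0, 1.0, 0.0)
        d14 = lps.EtaDistribution(centers, p1, "rank14", 0.02, 100)
        d57 = lps.EtaDistribution(centers, p2, "rank57", 0.02, 100)
        with pytest.raises(lps.NoIntersectionError):
            lps.eta_cutoff_from_intersection(d14, d57)


class TestEtaPeak:
    def test_single_spike(self):
        centers = np.arange(0.01, 4.0, 0.02)
        p = np.zeros_like(centers)
        p[100] = 50.0
        d = lps.EtaDistribution(centers, p, "all", 0.02, 100)
        assert lps.eta_peak(d) == pytest.approx(centers[100])

    def test_gaussian_histogram_peaks_at_mean(self, rng):
        samples = rng.normal(2.5, 0.3, 50_000)
        centers = np.arange(0.01, 5.0, 0.02)
        counts, _ = np.histogram(samples, bins=np.arange(0.0, 5.02, 0.02))
        d = lps.EtaDistribution(centers, counts / (counts.sum() * 0.02), "all", 0.02, 50_000)
        assert lps.eta_peak(d) == pytest.approx(2.5, abs=0.02)

    def test_equal_peaks_tie_to_smaller_eta(self):
        centers = np.arange(0.01, 4.0, 0.02)
        p = np.zeros_like(centers)
        p[[50, 120]] = 10.0
        d = lps.EtaDistribution(centers, p, "all", 0.02, 100)
        assert lps.eta_peak(d) == pytest.approx(centers[50])
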