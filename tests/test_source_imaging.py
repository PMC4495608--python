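import numpy as np
import pytest

from ssepmap.data import EpochSet, Evoked
from ssepmap.forward import DipoleSource, forward_topography
from ssepmap.segmentation import Labeling
from ssepmap.source_imaging import (build_source_space, cd_stats,
                                    compute_leadfield, estimate_cd,
                                    loreta_operator, window_average_t)


def _avg_ref_evoked(montage, data, rate=5000.0, window=(0.0, None)):
    w1 = window[1] if window[1] is not None else data.shape[1] * 1000.0 / rate
    return Evoked(data, rate, (window[0], w1), montage,
                  reference_mode="average",
                  channel_ids=list(montage.electrode_ids))


class TestSourceSpace:
    def test_target_3000_count_and_containment(self, head):
        sp = build_source_space(head, 3000)
        assert 2900 <= sp.n_sources <= 3100
        r = np.linalg.norm(sp.points, axis=1)
        assert np.all(r < 0.68 * head.scalp_radius)

    def test_deterministic(self, head):
        a = build_source_space(head, 3000)
        b = build_source_space(head, 3000)
        assert a.spacing == b.spacing
        assert np.array_equal(a.points, b.points)

    def test_doubling_spacing_eighths_the_count(self, head, small_space):
        # fix the spacing at 2x and count points directly
        r = np.linalg.norm(small_space.points, axis=1).max() + 1e-9
        h2 = 2 * small_space.spacing
        half = int(np.floor(r / h2))
        ax = np.arange(-half, half + 1) * h2
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        cnt = int((X ** 2 + Y ** 2 + Z ** 2 < r ** 2).sum())
        assert cnt == pytest.approx(small_space.n_sources / 8, rel=0.2)

    def test_neighbors_are_mutual_and_at_spacing(self, small_space):
        for s in range(0, small_space.n_sources, 97):
            for t in small_space.neighbors[s]:
                d = np.linalg.norm(small_space.points[s] -
                                   small_space.points[t])
                assert d == pytest.approx(small_space.spacing, rel=1e-9)
                assert s in small_space.neighbors[t]

    def test_tiny_target_rejected(self, head):
        with pytest.raises(ValueError):
            build_source_space(head, 5)


class TestLeadField:
    def test_matches_simulator_forward(self, head, montage, small_space,
                                       small_leadfield):
        """The inverse-side gain and the simulator's forward topography
        share one model: identical columns."""
        for s in (0, 100, small_space.n_sources - 1):
            for o, m in enumerate(np.eye(3)):
                dip = DipoleSource(small_space.points[s], m)
                v = forward_topography(head, montage, dip)
                col = small_leadfield.gain[:, 3 * s + o]
                assert np.allclose(v, col, atol=1e-10)

    def test_columns_average_referenced(self, small_leadfield):
        assert np.abs(small_leadfield.gain.sum(axis=0)).max() < 1e-12

    def test_central_source_n1_closed_form(self, head, montage):
        """For a source at the head centre only the first harmonic
        survives: the raw gain row at each electrode is F_1 * e_hat
        / (4 pi sigma R^2), independent of orientation frame (sphere
        theory closed form)."""
        from ssepmap.forward import _shell_coeffs, dipole_gain

        ep = montage.positions * head.scalp_radius
        g = dipole_gain(head, ep, np.zeros((1, 3)))[:, 0, :]
        F = _shell_coeffs(head.shell_fractions, head.conductivities,
                          head.n_terms)
        pref = F[1] / (4 * np.pi * head.conductivities[0]
                       * head.scalp_radius ** 2)
        assert np.allclose(g, pref * montage.positions, rtol=1e-12)


class TestLoretaOperator:
    def test_thirteen_increasing_alphas(self, small_operator):
        assert small_operator.n_alphas == 13
        assert np.all(np.diff(small_operator.alphas) > 0)

    def test_ridge_limit_shrinks_solution(self, small_operator):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(33)
        v -= v.mean()
        norms = [np.linalg.norm(small_operator.transforms[i] @ v)
                 for i in range(small_operator.n_alphas)]
        assert np.all(np.diff(norms) < 0)

    def test_normal_equations_residual(self, small_leadfield, small_operator,
                                       small_space):
        """Algebraic oracle: T(alpha) (K W^-1 K^T + alpha H) = W^-1 K^T,
        with W^-1 K^T rebuilt independently by a dense solve."""
        K = small_leadfield.gain
        n_e = K.shape[0]
        n_s = small_space.n_sources
        # independent dense reconstruction of W^-1 K^T
        B = np.eye(n_s)
        for s, nb in enumerate(small_space.neighbors):
            B[s, nb] = -1.0 / 6.0
        W_s = B.T @ B
        Kt = K.T.reshape(n_s, 3, n_e)
        Xw = np.empty_like(Kt)
        for o in range(3):
            Xw[:, o, :] = np.linalg.solve(W_s, Kt[:, o, :])
        Xw = Xw.reshape(3 * n_s, n_e)
        M = K @ Xw
        H = np.eye(n_e) - np.full((n_e, n_e), 1.0 / n_e)
        scale = np.linalg.norm(Xw)
        for i in (0, 6, 12):
            a = small_operator.alphas[i]
            T = small_operator.transforms[i]
            resid = np.linalg.norm(T @ (M + a * H) - Xw) / scale
            assert resid < 1e-8, i

    def test_localization_recovery(self, head, montage, small_space,
                                   small_operator):
        """Noise-free data from one planted source peaks within two grid
        spacings of the truth at small regularisation."""
        rng = np.random.default_rng(1)
        errs = []
        for _ in range(5):
            s = int(rng.integers(small_space.n_sources))
            dip = DipoleSource(small_space.points[s], rng.normal(size=3))
            v = forward_topography(head, montage, dip)
            ev = _avg_ref_evoked(montage, v[:, None])
            cds = estimate_cd(small_operator, ev, alpha_select="fixed",
                              alpha_index=0)
            peak = int(np.argmax(cds.cd[:, 0]))
            errs.append(np.linalg.norm(small_space.points[peak] -
                                       small_space.points[s]) /
                        small_space.spacing)
        assert np.median(errs) <= 2.0


class TestEstimateCd:
    def test_zero_input_zero_cd(self, montage, small_operator):
        ev = _avg_ref_evoked(montage, np.zeros((33, 5)))
        cds = estimate_cd(small_operator, ev, alpha_select="fixed",
                          alpha_index=3)
        assert np.all(cds.cd == 0)

    def test_scaling_linearity(self, head, montage, small_operator):
        dip = DipoleSource([3.0, -2.0, 8.0], [1.0, 0.5, 0.2])
        v = forward_topography(head, montage, dip)
        ev1 = _avg_ref_evoked(montage, v[:, None])
        ev3 = _avg_ref_evoked(montage, -3.0 * v[:, None])
        c1 = estimate_cd(small_operator, ev1, "fixed", alpha_index=4)
        c3 = estimate_cd(small_operator, ev3, "fixed", alpha_index=4)
        assert np.allclose(c3.cd, 3.0 * c1.cd, rtol=1e-9)

    def test_epoch_average_equals_average_cd_components(self, head, montage,
                                                        small_operator):
        """With fixed alpha the transform is linear, so the oriented
        solution of the average equals the average of solutions; the
        reported magnitude of the average is bounded by the average
        magnitude (triangle inequality)."""
        rng = np.random.default_rng(2)
        data = rng.normal(size=(4, 33, 6))
        data -= data.mean(axis=1, keepdims=True)
        ep = EpochSet(data, 5000.0, (-0.0004 * 1000, 0.0008 * 1000), montage,
                      reference_mode="average")
        ce = estimate_cd(small_operator, ep, "fixed", alpha_index=5)
        ev = _avg_ref_evoked(montage, data.mean(axis=0),
                             window=(-0.4, None))
        ca = estimate_cd(small_operator, ev, "fixed", alpha_index=5)
        assert np.all(ca.cd <= ce.cd.mean(axis=0) + 1e-12)

    def test_gcv_alpha_increases_with_noise(self, head, montage,
                                            small_operator):
        """Noisier inputs select the same or heavier regularisation
        (monotone trend over seeds)."""
        dip = DipoleSource([4.0, 1.0, 9.0], [0.5, 1.0, 0.3])
        v = forward_topography(head, montage, dip)
        picks_low, picks_high = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            for level, out in ((0.02, picks_low), (2.0, picks_high)):
                noise = rng.normal(size=(33, 10)) * level * np.abs(v).max()
                d = v[:, None] + noise
                d -= d.mean(axis=0)
                ev = _avg_ref_evoked(montage, d)
                out.append(estimate_cd(small_operator, ev).alpha_index)
        assert np.mean(picks_high) >= np.mean(picks_low)

    def test_vertex_input_rejected(self, montage, small_operator):
        ev = Evoked(np.zeros((32, 4)), 5000.0, (0.0, 0.8), montage)
        with pytest.raises(ValueError, match="average-referenced"):
            estimate_cd(small_operator, ev, "fixed", alpha_index=0)


class TestCdStats:
    def _noise_cd(self, montage, small_operator, n_ep=40, n_fr=100,
                  rate=500.0, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(n_ep, 33, n_fr))
        data -= data.mean(axis=1, keepdims=True)
        ep = EpochSet(data, rate, (-100.0, n_fr * 1000.0 / rate - 100.0),
                      montage, reference_mode="average")
        return estimate_cd(small_operator, ep, "fixed", alpha_index=6)

    def test_identical_baseline_and_post_gives_t_zero(self, montage,
                                                      small_operator):
        cds = self._noise_cd(montage, small_operator, n_ep=5, n_fr=100)
        # make every post frame equal the baseline mean
        times = cds.times
        bsel = (times >= -100) & (times < 0)
        base = cds.cd[:, :, bsel].mean(axis=2)
        cds.cd[:, :, ~bsel] = base[:, :, None]
        stat = cd_stats(cds)
        assert np.allclose(stat.t, 0.0)
        assert not stat.mask.any()
        assert stat.degenerate.all()

    def test_planted_source_detected(self, head, montage, small_space,
                                     small_operator):
        """A strong post-stimulus source yields a significant cluster
        containing the true location."""
        rng = np.random.default_rng(3)
        s = int(rng.integers(small_space.n_sources))
        dip = DipoleSource(small_space.points[s], rng.normal(size=3))
        v = forward_topography(head, montage, dip)
        n_ep, n_fr, rate = 30, 60, 500.0
        data = rng.normal(size=(n_ep, 33, n_fr)) * np.abs(v).max() / 5.0
        data -= data.mean(axis=1, keepdims=True)
        post = slice(30, 60)
        data[:, :, post] += v[None, :, None]
        ep = EpochSet(data, rate, (-60.0, 60.0), montage,
                      reference_mode="average")
        cds = estimate_cd(small_operator, ep, "fixed", alpha_index=4)
        stat = cd_stats(cds, baseline=(-60.0, 0.0), post=(0.0, 60.0))
        sig_any = stat.mask.any(axis=1)
        assert sig_any[s] or any(
            sig_any[t] for t in small_space.neighbors[s])

    def test_too_few_epochs_rejected(self, montage, small_operator):
        cds = self._noise_cd(montage, small_operator, n_ep=5)
        cds.cd = cds.cd[:1]
        with pytest.raises(ValueError, match="epochs"):
            cd_stats(cds)


class TestWindowAverageT:
    def _stat(self, montage, small_operator, seed=4):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(20, 33, 100))
        data -= data.mean(axis=1, keepdims=True)
        ep = EpochSet(data, 500.0, (-100.0, 100.0), montage,
                      reference_mode="average")
        cds = estimate_cd(small_operator, ep, "fixed", alpha_index=6)
        return cd_stats(cds, post=(0.0, 100.0))

    def test_single_map_covering_all_frames(self, montage, small_operator):
        stat = self._stat(montage, small_operator)
        lab = Labeling(np.zeros(stat.times.size, dtype=int),
                       (0.0, 100.0), 500.0)
        t_mean, _ = window_average_t(stat, lab)
        assert np.allclose(t_mean[0], stat.t.mean(axis=1), atol=1e-12)

    def test_two_disjoint_maps_match_brute_force(self, montage,
                                                 small_operator):
        stat = self._stat(montage, small_operator)
        n = stat.times.size
        labels = np.array([0] * (n // 2) + [1] * (n - n // 2))
        lab = Labeling(labels, (0.0, 100.0), 500.0)
        t_mean, _ = window_average_t(stat, lab)
        assert np.allclose(t_mean[0], stat.t[:, :n // 2].mean(axis=1))
        assert np.allclose(t_mean[1], stat.t[:, n // 2:].mean(axis=1))

    def test_nonsignificant_map_is_empty(self, montage, small_operator):
        stat = self._stat(montage, small_operator)
        stat.mask[:] = False     # the "ns" case
        lab = Labeling(np.zeros(stat.times.size, dtype=int),
                       (0.0, 100.0), 500.0)
        _, t_masked = window_average_t(stat, lab)
        assert np.all(np.isnan(t_masked))
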