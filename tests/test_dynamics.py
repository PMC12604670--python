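"""Linking, COM tracking, g2/dMSD statistics and stiffness estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kdnatools import dynamics as dyn
from kdnatools import synth
from kdnatools.units import kbt_pn_um


def _flat_com(n):
    return pd.DataFrame({"frame": np.arange(n), "x_um": 0.0, "y_um": 0.0})


class TestLinkSpots:
    def test_two_separated_emitters_two_pure_tracks(self):
        tracks, _ = synth.make_confined_tracks(
            n_qd=2, kappa=0.5, n_frames=120, seed=1,
            centers=np.array([[0.0, 0.0], [5.0, 5.0]]))
        spots = synth.make_blinking(tracks, off_prob=0.0, seed=2)
        linked = dyn.link_spots(spots, max_disp=1.0, memory=3)
        assert len(linked) == 2
        # identity purity: every linked track coincides with one true id
        for _, g in linked.data.groupby("track_id"):
            merged = g.merge(spots, on="frame")
            hit = merged[np.hypot(merged.x_um_x - merged.x_um_y,
                                  merged.y_um_x - merged.y_um_y) < 1e-9]
            assert hit["id"].nunique() == 1

    def test_gap_closed_within_memory(self):
        tracks, _ = synth.make_confined_tracks(n_qd=1, kappa=0.5,
                                               n_frames=100, seed=3)
        spots = synth.make_blinking(tracks, off_prob=0.0, seed=0)
        gapped = spots[~spots["frame"].isin([40, 41])]
        assert len(dyn.link_spots(gapped, max_disp=1.0, memory=3)) == 1
        assert len(dyn.link_spots(gapped, max_disp=1.0, memory=0)) == 2

    def test_needs_two_frames(self):
        spots = pd.DataFrame({"frame": [0], "x_um": [0.0], "y_um": [0.0]})
        with pytest.raises(ValueError):
            dyn.link_spots(spots, max_disp=1.0)


class TestTrackCom:
    def test_static_structure_constant_com(self):
        movie, _ = synth.make_kdna_image(n_emitters=0, n_frames=3, seed=4)
        com = dyn.track_com(movie.dna_channel)
        assert com["x_um"].std() < 0.2 and com["y_um"].std() < 0.2

    def test_translation_recovered(self):
        movie, _ = synth.make_kdna_image(n_emitters=0, seed=5)
        f0 = movie.dna_channel[0]
        f1 = np.roll(np.roll(f0, 2, axis=0), 1, axis=1)
        com = dyn.track_com(np.stack([f0, f1]))
        assert com["x_um"].diff()[1] == pytest.approx(1, abs=0.1)
        assert com["y_um"].diff()[1] == pytest.approx(2, abs=0.1)

    def test_unsegmentable_frame_interpolated(self):
        movie, _ = synth.make_kdna_image(n_emitters=0, seed=6)
        f = movie.dna_channel[0]
        stack = np.stack([f, np.zeros_like(f), f])
        with pytest.warns(UserWarning, match="interpolated"):
            com = dyn.track_com(stack)
        assert np.isfinite(com[["x_um", "y_um"]].to_numpy()).all()


class TestG2:
    def test_stationary_everything_gives_zero(self):
        rows = [(0, f, 1.0, 2.0) for f in range(50)]
        ts = dyn.TrackSet(pd.DataFrame(
            rows, columns=["track_id", "frame", "x_um", "y_um"]),
            frame_interval=0.125)
        curve = dyn.g2(ts, com=_flat_com(50))
        assert np.all(curve.values == 0)

    def test_lag_zero_is_zero_and_counts_decrease(self):
        tracks, _ = synth.make_confined_tracks(n_qd=3, kappa=0.2,
                                               n_frames=200, seed=7)
        curve = dyn.g2(tracks)
        assert curve.lags[0] == 0 and curve.values[0] == 0
        assert np.all(np.diff(curve.counts[1:]) <= 0)
        assert np.all(curve.values >= 0)

    def test_ou_plateau_matches_equipartition(self):
        """Long-time g2 of a harmonic trap equals 4 k_B T / k per-axis."""
        k_axis = 0.1
        tracks, _ = synth.make_confined_tracks(n_qd=25, kappa=k_axis,
                                               n_frames=500, seed=8)
        plat = dyn.plateau(dyn.g2(tracks), t_min=10)
        assert plat.reliable
        assert plat.value == pytest.approx(4 * kbt_pn_um(298) / k_axis,
                                           rel=0.1)

    def test_rigid_translation_invariance(self):
        tracks, _ = synth.make_confined_tracks(n_qd=4, kappa=0.2,
                                               n_frames=300, seed=9)
        base = dyn.g2(tracks)
        shifted = tracks.data.copy()
        shift = np.sin(shifted["frame"].to_numpy() * 0.1)
        shifted["x_um"] += shift
        com2 = tracks.com.copy()
        com2["x_um"] += np.sin(com2["frame"].to_numpy() * 0.1)
        moved = dyn.TrackSet(shifted, frame_interval=tracks.frame_interval,
                             com=com2)
        assert np.allclose(dyn.g2(moved).values, base.values, rtol=1e-9)


class TestDmsd:
    def test_rigid_pair_gives_zero(self):
        rng = np.random.default_rng(0)
        drift = np.cumsum(rng.normal(size=(100, 2)), axis=0)
        rows = []
        for k, off in enumerate([(0, 0), (3, 1)]):
            rows += [(k, f, drift[f, 0] + off[0], drift[f, 1] + off[1])
                     for f in range(100)]
        ts = dyn.TrackSet(pd.DataFrame(
            rows, columns=["track_id", "frame", "x_um", "y_um"]),
            frame_interval=0.125)
        curve, stats = dyn.dmsd(ts)
        assert np.abs(curve.values).max() < 1e-12
        assert stats.mean_sd == pytest.approx(0, abs=1e-12)

    def test_independent_brownian_pair_is_8dt(self):
        tracks, _ = synth.make_confined_tracks(n_qd=60, kappa=0.0,
                                               n_frames=150, seed=10)
        curve, _ = dyn.dmsd(tracks)
        D = kbt_pn_um(298) / synth.DEFAULT_DRAG
        sel = (curve.lags > 0) & (curve.lags < 2)
        assert np.mean(curve.values[sel] / (8 * D * curve.lags[sel])) == \
            pytest.approx(1.0, abs=0.05)

    def test_jittered_pair_distance_spread_recovered(self):
        """Gaussian jitter σ per axis per particle gives Var(d) ≈ 2σ²."""
        rng = np.random.default_rng(1)
        sigma = 0.05
        n = 4000
        base = np.array([0.0, 0.0]), np.array([3.0, 0.0])
        rows = []
        for k, b in enumerate(base):
            pos = b + rng.normal(0, sigma, size=(n, 2))
            rows += [(k, f, pos[f, 0], pos[f, 1]) for f in range(n)]
        ts = dyn.TrackSet(pd.DataFrame(
            rows, columns=["track_id", "frame", "x_um", "y_um"]),
            frame_interval=0.125)
        _, stats = dyn.dmsd(ts)
        assert stats.mean_sd == pytest.approx(np.sqrt(2) * sigma, rel=0.1)

    def test_normalised_curve_scales_by_mean_distance(self):
        tracks, _ = synth.make_confined_tracks(
            n_qd=2, kappa=0.3, n_frames=300, seed=11,
            centers=np.array([[0.0, 0.0], [2.0, 0.0]]))
        raw, stats = dyn.dmsd(tracks, normalise=False)
        norm, _ = dyn.dmsd(tracks, normalise=True)
        assert np.allclose(norm.values[1:],
                           raw.values[1:] / stats.pairs["mean_d"][0] ** 2)

    def test_global_drift_cancels_exactly(self):
        kw = dict(n_qd=5, kappa=0.2, n_frames=200, seed=12,
                  centers=np.random.default_rng(3).uniform(-1, 1, (5, 2)))
        a, _ = synth.make_confined_tracks(drift_velocity=(0, 0), **kw)
        b, _ = synth.make_confined_tracks(drift_velocity=(1.0, -0.5), **kw)
        ca, _ = dyn.dmsd(a)
        cb, _ = dyn.dmsd(b)
        assert np.allclose(ca.values, cb.values, rtol=1e-9, atol=1e-12)


class TestFitExponent:
    @given(alpha=st.floats(0.1, 1.5), c=st.floats(0.01, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_exact_power_law_recovered(self, alpha, c):
        lags = np.concatenate([[0.0], np.linspace(0.125, 5, 40)])
        vals = np.concatenate([[0.0], c * np.linspace(0.125, 5, 40) ** alpha])
        curve = dyn.MsdCurve(lags=lags, values=vals,
                             counts=np.ones_like(lags), kind="g2")
        fit = dyn.fit_exponent(curve, (0.125, 5.0))
        assert fit.alpha == pytest.approx(alpha, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_linear_curve_alpha_one(self):
        lags = np.concatenate([[0.0], np.linspace(0.125, 5, 20)])
        vals = 4 * 0.1 * lags
        curve = dyn.MsdCurve(lags=lags, values=vals,
                             counts=np.ones_like(lags), kind="g2")
        assert dyn.fit_exponent(curve, (0.1, 5)).alpha == pytest.approx(1.0)

    def test_fgn_alpha_quarter_recovered(self):
        tracks, _ = synth.make_subdiffusive_tracks(n_tracks=100, alpha=0.25,
                                                   n_frames=300, seed=13)
        curve = dyn.g2(tracks, com=_flat_com(300))
        fit = dyn.fit_exponent(curve, (0.125, 2.0))
        assert fit.alpha == pytest.approx(0.25, abs=0.05)

    def test_guards(self):
        lags = np.array([0.0, 0.125, 0.25])
        curve = dyn.MsdCurve(lags=lags, values=np.array([0.0, 1.0, 1.0]),
                             counts=np.ones(3), kind="g2")
        with pytest.raises(ValueError, match=">= 4"):
            dyn.fit_exponent(curve, (0.1, 1.0))


class TestPlateau:
    def test_constant_curve(self):
        lags = np.concatenate([[0.0], np.linspace(1, 60, 30)])
        vals = np.concatenate([[0.0], np.full(30, 0.2)])
        curve = dyn.MsdCurve(lags=lags, values=vals,
                             counts=np.ones_like(lags), kind="g2")
        plat = dyn.plateau(curve, t_min=10)
        assert plat.value == pytest.approx(0.2)
        assert plat.reliable

    def test_rising_curve_flagged_unreliable(self):
        lags = np.concatenate([[0.0], np.linspace(1, 60, 30)])
        vals = 0.05 * lags
        curve = dyn.MsdCurve(lags=lags, values=vals,
                             counts=np.ones_like(lags), kind="g2")
        assert not dyn.plateau(curve, t_min=10).reliable

    def test_needs_enough_lags(self):
        lags = np.array([0.0, 5.0, 20.0])
        curve = dyn.MsdCurve(lags=lags, values=np.array([0.0, 0.1, 0.1]),
                             counts=np.ones(3), kind="g2")
        with pytest.raises(ValueError):
            dyn.plateau(curve, t_min=10)


class TestStiffness:
    def test_plateau_route_identity(self):
        est = dyn.stiffness_from_plateau(2 * kbt_pn_um(298))
        assert est.kappa == pytest.approx(1.0)

    def test_plateau_halved_kappa_doubled(self):
        a = dyn.stiffness_from_plateau(0.2)
        b = dyn.stiffness_from_plateau(0.1)
        assert b.kappa == pytest.approx(2 * a.kappa)

    def test_pair_route_identity(self):
        est = dyn.stiffness_from_pairs(np.sqrt(2 * kbt_pn_um(298)))
        assert est.kappa == pytest.approx(1.0)

    def test_kappa_times_input_is_2kbt(self):
        est = dyn.stiffness_from_plateau(0.37, temperature=310)
        assert est.kappa * 0.37 == pytest.approx(2 * kbt_pn_um(310))

    def test_two_bead_spring_recovery(self):
        """A pair tied by a spring of stiffness k_pair has Var(d per axis)
        = k_B T/k_pair; the pair-route estimator applied to σ(d) therefore
        recovers ≈ 2 k_pair for small transverse fluctuations."""
        rng = np.random.default_rng(2)
        k_pair = 0.5
        sd_rel = np.sqrt(kbt_pn_um(298) / k_pair)
        n = 20000
        d0 = 5.0
        sep = np.column_stack([d0 + rng.normal(0, sd_rel, n),
                               rng.normal(0, sd_rel, n)])
        d = np.linalg.norm(sep, axis=1)
        est = dyn.stiffness_from_pairs(d.std(ddof=1))
        assert est.kappa == pytest.approx(2 * k_pair, rel=0.1)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            dyn.stiffness_from_plateau(0.0)
        with pytest.raises(ValueError):
            dyn.stiffness_from_pairs(-0.1)
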