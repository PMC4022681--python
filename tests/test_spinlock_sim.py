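"""Spin-lock Bloch physics: rotations, lock evolution vs an independent
ODE integrator, cluster behavior, and the synthetic phantom."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t1rhomap import (
    PhantomSpec,
    PrepCluster,
    hard_pulse_rotation,
    make_phantom,
    prep_cluster_signal,
    simulate_tsl_series,
    spinlock_evolve,
)
from t1rhomap.core_io import LABEL_DEEP, LABEL_MIDDLE, LABEL_SUPERFICIAL


def bloch_rk4(m0, b1sl_hz, dw_hz, b1rel, lock_phase_deg, duration_ms, t1rho_ms, t2rho_ms, dt_us=1.0):
    """Independent oracle: RK4 integration of the rotating-frame Bloch equation.

    dm/dt = omega x m - m_par/T1rho - m_perp/T2rho with omega the effective
    field; stepped at ``dt_us`` microseconds.
    """
    phi = np.deg2rad(lock_phase_deg)
    w = 2 * np.pi * np.array(
        [b1sl_hz * b1rel * np.cos(phi), b1sl_hz * b1rel * np.sin(phi), dw_hz]
    )
    wn = np.linalg.norm(w)
    u = w / wn if wn > 0 else np.zeros(3)
    r1, r2 = 1.0 / (t1rho_ms * 1e-3), 1.0 / (t2rho_ms * 1e-3)

    def deriv(m):
        par = np.dot(u, m) * u
        return np.cross(w, m) - r1 * par - r2 * (m - par)

    dt = dt_us * 1e-6
    n = int(round(duration_ms * 1e-3 / dt))
    m = np.array(m0, dtype=float)
    for _ in range(n):
        k1 = deriv(m)
        k2 = deriv(m + 0.5 * dt * k1)
        k3 = deriv(m + 0.5 * dt * k2)
        k4 = deriv(m + dt * k3)
        m = m + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return m


class TestHardPulse:
    def test_quarter_turn_convention(self):
        m = hard_pulse_rotation(np.array([0.0, 0.0, 1.0]), 90.0, 0.0, 1.0)
        np.testing.assert_allclose(m, [0, -1, 0], atol=1e-12)

    def test_full_turn_is_identity(self):
        m0 = np.array([0.3, -0.5, 0.8])
        np.testing.assert_allclose(hard_pulse_rotation(m0, 360.0, 37.0, 1.0), m0, atol=1e-12)

    def test_b1rel_scales_the_flip(self):
        m = hard_pulse_rotation(np.array([0.0, 0.0, 1.0]), 90.0, 0.0, 0.9)
        assert m[2] == pytest.approx(np.cos(np.deg2rad(81.0)), abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        flip=st.floats(0, 360),
        phase=st.floats(0, 360),
        b1rel=st.floats(0.5, 1.5),
    )
    def test_rotation_conserves_norm(self, flip, phase, b1rel):
        m0 = np.array([0.2, 0.3, 0.9])
        m = hard_pulse_rotation(m0, flip, phase, b1rel)
        assert np.linalg.norm(m) == pytest.approx(np.linalg.norm(m0), abs=1e-9)


class TestSpinlockEvolve:
    def test_on_resonance_locked_decay_is_mono_exponential(self):
        prep = PrepCluster(tsl_ms=40, t1rho_ms=40)
        m0 = np.array([0.0, 1.0, 0.0])  # along the +y lock axis
        m = spinlock_evolve(m0, prep, dw_hz=0.0, b1rel=1.0, lock_phase_deg=90.0, duration_ms=40.0)
        np.testing.assert_allclose(m, [0, np.exp(-1.0), 0], atol=1e-12)

    def test_zero_duration_is_identity(self):
        prep = PrepCluster(t1rho_ms=40)
        m0 = np.array([0.1, -0.7, 0.7])
        np.testing.assert_allclose(
            spinlock_evolve(m0, prep, 50.0, 0.95, 90.0, 0.0), m0, atol=1e-12
        )

    def test_effective_field_tilt_at_patellar_offset(self):
        # 139 Hz bulk offset at B1sl=500 Hz tilts the lock axis 15.54 deg out of plane
        assert np.degrees(np.arctan(139.0 / 500.0)) == pytest.approx(15.54, abs=0.01)

    @pytest.mark.parametrize(
        "dw,b1rel,dur", [(139.0, 1.0, 40.0), (-80.0, 0.9, 20.0), (30.0, 1.1, 10.0)]
    )
    def test_matches_rk4_bloch_integration(self, dw, b1rel, dur):
        prep = PrepCluster(b1sl_hz=500.0, t1rho_ms=40.0, t2rho_ms=30.0)
        m0 = np.array([0.1, 0.9, 0.2])
        fast = spinlock_evolve(m0, prep, dw, b1rel, 90.0, dur)
        slow = bloch_rk4(m0, 500.0, dw, b1rel, 90.0, dur, 40.0, 30.0)
        np.testing.assert_allclose(fast, slow, atol=1e-4)

    def test_relaxation_strictly_decreases_locked_component(self):
        prep = PrepCluster(t1rho_ms=40)
        m = np.array([0.0, 1.0, 0.0])
        prev = 1.0
        for dur in (5.0, 10.0, 20.0):
            cur = spinlock_evolve(m, prep, 0.0, 1.0, 90.0, dur)[1]
            assert cur < prev
            prev = cur


class TestPrepCluster:
    @pytest.mark.parametrize("mode", ["compensated", "simple"])
    def test_on_resonance_closed_form(self, mode):
        prep = PrepCluster(mode=mode, tsl_ms=20.0, t1rho_ms=40.0)
        assert prep_cluster_signal(prep, 0.0, 1.0) == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_zero_tsl_retains_everything(self):
        prep = PrepCluster(tsl_ms=0.0, t1rho_ms=40.0)
        assert prep_cluster_signal(prep, 0.0, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_modes_agree_exactly_on_resonance(self):
        for tsl in (0.0, 10.0, 40.0):
            a = prep_cluster_signal(PrepCluster(mode="compensated", tsl_ms=tsl, t1rho_ms=35))
            b = prep_cluster_signal(PrepCluster(mode="simple", tsl_ms=tsl, t1rho_ms=35))
            assert a == pytest.approx(b, abs=1e-12)

    def test_compensated_mode_reduces_off_resonance_artifact(self):
        dw = np.linspace(-200, 200, 41)
        b1 = np.linspace(0.85, 1.15, 7)[:, None]
        ideal = np.exp(-20.0 / 40.0)
        errs = {}
        for mode in ("compensated", "simple"):
            prep = PrepCluster(mode=mode, tsl_ms=20.0, t1rho_ms=40.0)
            sig = prep_cluster_signal(prep, dw * np.ones_like(b1), b1 * np.ones_like(dw))
            errs[mode] = np.abs(sig - ideal).max()
        assert errs["compensated"] < errs["simple"]


class TestPhantom:
    def test_equal_fractions_split_band_into_equal_thirds(self):
        spec = PhantomSpec(zone_fractions=(1 / 3, 1 / 3, 1 / 3), r_inner=28, r_outer=37)
        mask, _, _, _ = make_phantom(spec)
        # every radial profile of the 9-voxel band carries 3 voxels per zone
        counts = [np.sum(mask.labels == c) for c in (LABEL_DEEP, LABEL_MIDDLE, LABEL_SUPERFICIAL)]
        total = sum(counts)
        for c in counts:
            assert c == pytest.approx(total / 3, rel=0.12)  # outer rings hold more voxels

    def test_fixed_seed_is_bit_identical(self):
        a = make_phantom(PhantomSpec(seed=5))
        b = make_phantom(PhantomSpec(seed=5))
        np.testing.assert_array_equal(a[0].labels, b[0].labels)
        np.testing.assert_array_equal(a[2].values, b[2].values)
        np.testing.assert_array_equal(a[3].values, b[3].values)

    def test_b0_jitter_sd_matches_spec(self, phantom_snr90):
        spec, mask, _, b0, _, _ = phantom_snr90
        cart = mask.cartilage
        assert cart.sum() >= 3000
        assert b0.values[cart].std() == pytest.approx(30.0, abs=3.0)

    def test_b1rel_field_statistics(self, phantom_snr90):
        spec, mask, _, _, b1, _ = phantom_snr90
        cart = mask.cartilage
        assert b1.values[cart].mean() == pytest.approx(1.0, abs=0.03)
        assert b1.values[cart].std() == pytest.approx(0.1, abs=0.02)

    def test_geometry_outside_grid_errors(self):
        with pytest.raises(ValueError, match="geometry"):
            PhantomSpec(shape=(40, 40, 4), center_xy=(20, 20), r_inner=28, r_outer=37)

    def test_zone_t1rho_ordering_deep_to_superficial(self):
        _, t1rho, _, _ = make_phantom(PhantomSpec())
        mask, _, _, _ = make_phantom(PhantomSpec())
        deep = np.nanmean(t1rho[mask.labels == LABEL_DEEP])
        sup = np.nanmean(t1rho[mask.labels == LABEL_SUPERFICIAL])
        assert deep < sup < 60.0  # healthy ordering and range


class TestSimulatedSeries:
    def test_noiseless_on_resonance_signals_are_exact(self):
        spec = PhantomSpec(b0_bulk_hz=0, b0_gradient_hz=0, b0_jitter_sd_hz=0,
                           b1_gradient=0, b1_jitter_sd=0, seed=0)
        series = simulate_tsl_series(spec, PrepCluster(mode="compensated"), noise=False)
        mask, t1rho, _, _ = make_phantom(spec)
        cart = mask.cartilage
        for k, tsl in enumerate(series.tsl_ms):
            expected = spec.cartilage_amp * np.exp(-tsl / t1rho[cart])
            np.testing.assert_allclose(series.volumes[..., k][cart], expected, atol=1e-10)

    def test_background_magnitude_has_rayleigh_mean(self):
        spec = PhantomSpec(base_snr=90.0, seed=3)
        series = simulate_tsl_series(spec, PrepCluster())
        mask, _, _, _ = make_phantom(spec)
        bg = series.volumes[..., 0][mask.labels == 0]
        sigma = spec.cartilage_amp / spec.base_snr
        assert bg.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)

    def test_snr_decays_with_lock_time(self):
        # base SNR 240 and T1rho ~44 ms: SNR at TSL=40 lands near 97
        spec = PhantomSpec(base_snr=240.0, zone_t1rho_ms=(44.1, 44.1, 44.1), seed=4)
        series = simulate_tsl_series(spec, PrepCluster())
        mask, _, _, _ = make_phantom(spec)
        cart, bg = mask.cartilage, mask.labels == 0
        sigma_ch = series.volumes[..., -1][bg].std() / np.sqrt(2 - np.pi / 2)
        measured = series.volumes[..., -1][cart].mean() / sigma_ch
        assert measured == pytest.approx(240 * np.exp(-40 / 44.1), rel=0.06)
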