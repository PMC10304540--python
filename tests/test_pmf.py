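"""WHAM reconstruction, reference conventions, symmetrization, barriers."""

import numpy as np
import pytest

from memperm.constants import rt
from memperm.pmf import (
    BarrierSet,
    CoverageGapError,
    FreeEnergyProfile,
    UmbrellaWindow,
    WhamConvergenceError,
    convergence_scan,
    extract_barriers,
    histogram_windows,
    set_reference,
    split_half_uncertainty,
    symmetrize,
    wham_solve,
)
from memperm.synthgen import CallablePmf

from conftest import make_windows

RT = rt()


class TestHistograms:
    def test_counts_conserved(self, flat_pmf):
        windows = make_windows(flat_pmf, [-0.1, 0.0, 0.1], k=300.0, n=1000)
        hist = histogram_windows(windows)
        assert hist.counts.sum() == sum(w.n for w in windows)
        np.testing.assert_array_equal(hist.counts.sum(axis=1), [1000, 1000, 1000])

    def test_single_window_single_bin(self):
        w = UmbrellaWindow(z0=0.0, k=3000.0, dt=1.0, samples=np.full(50, 0.101))
        hist = histogram_windows([w], bin_width=0.02)
        assert (hist.counts > 0).sum() == 1
        assert hist.counts.max() == 50

    def test_disjoint_windows_flag_gap(self):
        a = UmbrellaWindow(0.0, 3000.0, 1.0, np.random.default_rng(0).normal(0, 0.02, 100))
        b = UmbrellaWindow(1.0, 3000.0, 1.0, np.random.default_rng(1).normal(1, 0.02, 100))
        with pytest.warns(UserWarning, match="uncovered"):
            hist = histogram_windows([a, b])
        assert len(hist.gaps) == 1
        lo, hi = hist.gaps[0]
        # the uncovered stretch spans from a's support edge to b's
        assert 0.0 < lo < 0.2 and 0.8 < hi < 1.0


class TestWham:
    def test_single_flat_window_recovers_flat_profile(self, flat_pmf):
        windows = make_windows(flat_pmf, [0.0], k=200.0, n=100_000)
        prof = wham_solve(windows)
        sh = split_half_uncertainty(windows)
        # deviation from flatness bounded by the split-half noise scale
        assert np.ptp(prof.G) < max(3 * sh.err.max(), 0.3)

    def test_harmonic_generating_potential_recovered(self, harmonic_pmf):
        windows = make_windows(harmonic_pmf, np.arange(-1.0, 1.01, 0.1), n=20_000, seed0=50)
        prof = wham_solve(windows)
        resid = prof.G - 0.5 * 10.0 * prof.z**2
        resid -= resid.mean()
        assert np.sqrt(np.mean(resid**2)) < 0.25

    def test_unreachable_tolerance_fails_explicitly(self, flat_pmf):
        windows = make_windows(flat_pmf, [-0.1, 0.0, 0.1], n=500)
        with pytest.raises(WhamConvergenceError) as err:
            wham_solve(windows, tol=0.0, max_iter=50)
        assert err.value.residual >= 0

    def test_disjoint_windows_fail_with_gap(self):
        a = UmbrellaWindow(0.0, 3000.0, 1.0, np.random.default_rng(0).normal(0, 0.02, 500))
        b = UmbrellaWindow(1.0, 3000.0, 1.0, np.random.default_rng(1).normal(1, 0.02, 500))
        with pytest.warns(UserWarning):
            with pytest.raises(CoverageGapError):
                wham_solve([a, b], min_edge_count=1)


class TestReference:
    def _profile(self):
        z = np.linspace(-4, 4, 401)
        G = 10 * np.exp(-(z**2)) - 30 * np.exp(-((np.abs(z) - 1.8) ** 2) / 0.2) + 30
        return FreeEnergyProfile(z=z, G=G, reference="bilayer_center", T=298.15)

    def test_global_minimum_zeroes_min(self):
        p = set_reference(self._profile(), "global_minimum")
        assert p.G.min() == pytest.approx(0.0, abs=1e-12)

    def test_conventions_differ_by_constant(self):
        base = self._profile()
        shifted = [set_reference(base, c) for c in ("bulk_water", "global_minimum", "bilayer_center")]
        for p in shifted:
            diff = p.G - base.G
            assert np.ptp(diff) < 1e-10  # one additive constant

    def test_bulk_water_removes_plateau(self):
        z = np.linspace(-4, 4, 801)
        G = np.where(np.abs(z) >= 3.0, 30.0, 0.0)
        p = FreeEnergyProfile(z=z, G=G, reference="bilayer_center")
        out = set_reference(p, "bulk_water", z_bulk=3.5)
        assert np.abs(out.G[np.abs(z) >= 3.5]).max() < 1e-12
        assert out.G[np.abs(z) < 2.9].mean() == pytest.approx(-30.0)

    def test_missing_plateau_rejected(self):
        z = np.linspace(-1, 1, 51)
        p = FreeEnergyProfile(z=z, G=np.zeros_like(z))
        with pytest.raises(ValueError, match="bulk-water"):
            set_reference(p, "bulk_water", z_bulk=3.5)


class TestSymmetrize:
    def test_odd_profile_cancels(self):
        z = np.linspace(-2, 2, 101)
        p = FreeEnergyProfile(z=z, G=z.copy())
        out = symmetrize(p)
        np.testing.assert_allclose(out.G, 0.0, atol=1e-12)

    def test_idempotent(self):
        z = np.linspace(-2, 2, 101)
        rng = np.random.default_rng(0)
        p = FreeEnergyProfile(z=z, G=rng.normal(size=z.size))
        once = symmetrize(p)
        twice = symmetrize(once)
        np.testing.assert_allclose(once.G, twice.G, atol=1e-12)
        np.testing.assert_allclose(once.z, twice.z)

    def test_mean_preserved_on_symmetric_grid(self):
        z = np.linspace(-2, 2, 101)
        p = FreeEnergyProfile(z=z, G=np.cos(z) + z**3)
        assert symmetrize(p).G.mean() == pytest.approx(p.G.mean())

    def test_one_leaflet_profile_is_reflected(self):
        z = np.linspace(0.0, 2.0, 51)
        p = FreeEnergyProfile(z=z, G=z**2)
        out = symmetrize(p)
        assert out.z[0] == pytest.approx(-2.0)
        np.testing.assert_allclose(out.G, out.z**2, atol=1e-12)


class TestSplitHalf:
    def test_identical_halves_give_zero(self):
        rng = np.random.default_rng(4)
        windows = []
        for z0 in (-0.1, 0.0, 0.1):
            half = rng.normal(z0, 0.03, 400)
            windows.append(
                UmbrellaWindow(z0, 3000.0, 1.0, np.concatenate([half, half]))
            )
        sh = split_half_uncertainty(windows)
        np.testing.assert_allclose(sh.err, 0.0, atol=1e-9)

    def test_uncertainty_non_negative(self, flat_pmf):
        windows = make_windows(flat_pmf, [-0.1, 0.0, 0.1], n=800, seed0=20)
        assert np.all(split_half_uncertainty(windows).err >= 0)

    def test_short_window_rejected(self):
        w = UmbrellaWindow(0.0, 3000.0, 1.0, np.array([0.1]))
        with pytest.raises(ValueError, match="short"):
            split_half_uncertainty([w])


class TestConvergenceScan:
    def _windows(self, flat_pmf):
        return make_windows(flat_pmf, [-0.1, 0.0, 0.1], n=1000, seed0=30, dt=1.0)

    def test_scheme_i_endpoint_equals_full_solve(self, flat_pmf):
        windows = self._windows(flat_pmf)
        scan = convergence_scan(windows, "i", step=250.0)
        full = wham_solve(windows)
        np.testing.assert_allclose(scan[-1][1].G, full.G, atol=1e-9)
        assert scan[-1][0] == pytest.approx(1000.0)

    def test_scheme_iii_profile_count(self, flat_pmf):
        windows = self._windows(flat_pmf)
        scan = convergence_scan(windows, "iii", step=100.0, analysis_span=500.0)
        assert len(scan) == (1000 - 500) // 100 + 1

    def test_schemes_agree_for_stationary_data(self, flat_pmf):
        windows = self._windows(flat_pmf)
        sh = split_half_uncertainty(windows)
        noise = max(2 * sh.err.max(), 0.2)
        p1 = convergence_scan(windows, "i", step=500.0)[-1][1]
        p2 = convergence_scan(windows, "ii", step=500.0)[1][1]  # 500 ps discarded
        lo, hi = max(p1.z[0], p2.z[0]), min(p1.z[-1], p2.z[-1])
        m = (p1.z >= lo) & (p1.z <= hi)
        d = p1.G[m] - np.interp(p1.z[m], p2.z, p2.G)
        assert np.ptp(d - d.mean()) < 2 * noise

    def test_span_longer_than_data_rejected(self, flat_pmf):
        with pytest.raises(ValueError, match="analysis_span"):
            convergence_scan(self._windows(flat_pmf), "iii", step=100.0, analysis_span=2000.0)

    def test_bad_step_rejected(self, flat_pmf):
        with pytest.raises(ValueError, match="step"):
            convergence_scan(self._windows(flat_pmf), "i", step=300.0)


class TestBarriers:
    def _profile(self, g_min=0.0, g_center=20.0, g_bulk=30.0):
        z = np.linspace(-4, 4, 801)
        well = (g_min - g_bulk) * np.exp(-((np.abs(z) - 1.5) ** 2) / 0.18)
        center = (g_center - g_bulk) * np.exp(-(z**2) / 0.5)
        G = g_bulk + well + center
        # anchor exact values at the landmarks
        G[np.argmin(np.abs(z - 1.5))] = g_min
        G[np.argmin(np.abs(z + 1.5))] = g_min
        G[np.argmin(np.abs(z))] = g_center
        return FreeEnergyProfile(z=z, G=G, reference="global_minimum")

    def test_direct_readout(self):
        b = extract_barriers(self._profile())
        assert b.dG_translocation == pytest.approx(20.0, abs=0.5)
        assert b.dG_desorption == pytest.approx(30.0, abs=0.5)
        assert abs(b.z_eq) == pytest.approx(1.5, abs=0.1)
        assert not b.degenerate

    def test_flat_profile_degenerate(self):
        z = np.linspace(-4, 4, 201)
        b = extract_barriers(FreeEnergyProfile(z=z, G=np.zeros_like(z)))
        assert b.degenerate
        assert b.dG_translocation == pytest.approx(0.0)
        assert b.dG_desorption == pytest.approx(0.0)

    def test_barriers_invariant_under_reference_change(self):
        base = self._profile()
        for conv in ("bulk_water", "global_minimum", "bilayer_center"):
            b = extract_barriers(set_reference(base, conv))
            ref = extract_barriers(base)
            assert b.dG_translocation == pytest.approx(ref.dG_translocation, abs=1e-9)
            assert b.dG_desorption == pytest.approx(ref.dG_desorption, abs=1e-9)

    def test_asymmetric_profile_reports_leaflets(self):
        z = np.linspace(-4, 4, 801)
        G = 30 - 30 * np.exp(-((z - 1.5) ** 2) / 0.18) - 20 * np.exp(-((z + 1.5) ** 2) / 0.18)
        b = extract_barriers(FreeEnergyProfile(z=z, G=G))
        assert b.per_leaflet is not None
        assert set(b.per_leaflet) == {"lower", "upper"}
        assert b.per_leaflet["upper"].dG_desorption > b.per_leaflet["lower"].dG_desorption
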