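"""Partition, resistance and permeability algebra of the solubility-diffusion model."""

import numpy as np
import pytest

from memperm.constants import rt
from memperm.diffusion import DepthProfile
from memperm.permeance import (
    classify_regime,
    cumulative_resistance,
    decompose_resistance,
    local_resistance,
    partition_profile,
    permeability,
)
from memperm.pmf import BarrierSet, FreeEnergyProfile
from memperm.synthgen import default_diffusion_truth, make_pmf_model

RT = rt()


def flat_diffusion(z, value=1e-3):
    return DepthProfile(z=z, values=np.full(z.size, value), quantity="diffusion")


class TestPartition:
    @pytest.mark.parametrize(
        "dG,expected", [(0.0, 1.0), (RT, np.e**-1), (-RT, np.e)]
    )
    def test_boltzmann_values(self, dG, expected):
        z = np.linspace(-1, 1, 11)
        p = FreeEnergyProfile(z=z, G=np.full(z.size, dG), reference="bulk_water")
        np.testing.assert_allclose(partition_profile(p).values, expected, rtol=1e-12)

    def test_extreme_profiles_do_not_overflow(self):
        z = np.linspace(-1, 1, 5)
        p = FreeEnergyProfile(z=z, G=np.full(z.size, -1e5), reference="bulk_water")
        assert np.all(np.isfinite(partition_profile(p).values))


class TestLocalResistance:
    def test_flat_case(self):
        z = np.linspace(-2, 2, 41)
        G = FreeEnergyProfile(z=z, G=np.zeros(z.size), reference="bulk_water")
        rho = local_resistance(G, flat_diffusion(z))
        np.testing.assert_allclose(rho.values, 1000.0, rtol=1e-12)

    def test_constant_shift_scales_exponentially(self):
        z = np.linspace(-2, 2, 41)
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 5, z.size)
        r1 = local_resistance(FreeEnergyProfile(z=z, G=base), flat_diffusion(z))
        r2 = local_resistance(
            FreeEnergyProfile(z=z, G=base + RT * np.log(10)), flat_diffusion(z)
        )
        np.testing.assert_allclose(r2.values, 10 * r1.values, rtol=1e-10)

    def test_resistance_peak_tracks_pmf_peak_for_flat_D(self):
        z = np.linspace(-2, 2, 201)
        G = 12 * np.exp(-(z - 0.3) ** 2 / 0.1)
        rho = local_resistance(FreeEnergyProfile(z=z, G=G), flat_diffusion(z))
        assert rho.z[np.argmax(rho.values)] == pytest.approx(z[np.argmax(G)])

    def test_disjoint_grids_rejected(self):
        G = FreeEnergyProfile(z=np.linspace(-2, -1, 11), G=np.zeros(11))
        D = flat_diffusion(np.linspace(1, 2, 11))
        with pytest.raises(ValueError, match="overlap"):
            local_resistance(G, D)


class TestCumulativeResistance:
    def _uniform(self):
        z = np.linspace(-2, 2, 81)
        return DepthProfile(z=z, values=np.full(z.size, 1000.0), quantity="resistance_density")

    def test_rectangle(self):
        cum = cumulative_resistance(self._uniform(), (-2, 2))
        assert cum.values[-1] == pytest.approx(4000.0)

    def test_monotone(self):
        rng = np.random.default_rng(1)
        z = np.linspace(-2, 2, 81)
        rho = DepthProfile(z=z, values=rng.uniform(1, 100, z.size), quantity="resistance_density")
        cum = cumulative_resistance(rho, (-2, 2))
        assert np.all(np.diff(cum.values) >= 0)

    def test_flat_where_resistance_negligible(self):
        z = np.linspace(-2, 2, 401)
        rho_vals = np.where(np.abs(z) < 0.2, 1e6, 1e-3)
        rho = DepthProfile(z=z, values=rho_vals, quantity="resistance_density")
        cum = cumulative_resistance(rho, (-2, 2))
        low = np.abs(cum.z) > 0.5
        rises = np.diff(cum.values)
        assert rises[low[:-1]].sum() < 1e-4 * cum.values[-1]

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            cumulative_resistance(self._uniform(), (2, -2))


class TestPermeability:
    def test_flat_profile_closed_form(self):
        z = np.linspace(-2, 2, 4001)
        G = FreeEnergyProfile(z=z, G=np.zeros(z.size), reference="bulk_water")
        res = permeability(G, flat_diffusion(z), bounds=(-2, 2), z_bulk=1.9)
        assert res.P == pytest.approx(25.0, rel=1e-6)  # P = D/d
        assert res.R_total == pytest.approx(4000.0, rel=1e-6)

    def test_square_barrier_closed_form(self):
        z = np.linspace(-2, 2, 20001)
        Gv = np.where(np.abs(z) <= 0.5, RT * np.log(100.0), 0.0)
        G = FreeEnergyProfile(z=z, G=Gv, reference="bulk_water")
        res = permeability(G, flat_diffusion(z), bounds=(-2, 2), z_bulk=1.9)
        expected = 1e5 / (3000.0 + 1e5)  # 3 nm free + 1 nm of 100× resistance
        assert res.P == pytest.approx(expected, rel=1e-3)

    def test_reference_shift_law_exact(self):
        z = np.linspace(-4, 4, 2001)
        model = make_pmf_model(n_carbons=12)
        G = FreeEnergyProfile(z=z, G=np.asarray(model(z)), reference="bulk_water")
        D = DepthProfile(z=z, values=np.asarray(default_diffusion_truth()(z)), quantity="diffusion")
        pw = permeability(G, D, reference="bulk_water")
        pm = permeability(G, D, reference="global_minimum")
        gap = G.G[np.abs(G.z) >= 3.5].mean() - G.G.min()
        assert pm.P / pw.P == pytest.approx(np.exp(-gap / RT), rel=1e-12)
        assert pm.notes  # water-phase inflation artifact is reported

    def test_grid_refinement_stability(self):
        model = make_pmf_model(n_carbons=8)
        Dfn = default_diffusion_truth()
        values = []
        for npts in (801, 1601):
            z = np.linspace(-4, 4, npts)
            G = FreeEnergyProfile(z=z, G=np.asarray(model(z)), reference="bulk_water")
            D = DepthProfile(z=z, values=np.asarray(Dfn(z)), quantity="diffusion")
            values.append(permeability(G, D, reference="bulk_water").P)
        assert abs(values[1] / values[0] - 1) < 0.005


class TestRegime:
    def test_desorption_limited(self):
        b = BarrierSet(z_eq=1.5, dG_desorption=30.0, dG_translocation=20.0)
        assert classify_regime(b, margin=1.0) == "desorption_limited"

    def test_translocation_limited(self):
        b = BarrierSet(z_eq=1.5, dG_desorption=20.0, dG_translocation=30.0)
        assert classify_regime(b, margin=1.0) == "translocation_limited"

    def test_equal_barriers_indeterminate(self):
        b = BarrierSet(z_eq=1.5, dG_desorption=25.0, dG_translocation=25.0)
        assert classify_regime(b) == "indeterminate"

    def test_degenerate_propagates(self):
        b = BarrierSet(z_eq=0.0, dG_desorption=10.0, dG_translocation=0.0, degenerate=True)
        assert classify_regime(b) == "indeterminate"


class TestDecomposition:
    def _uniform_cum(self):
        z = np.linspace(-2, 2, 161)
        rho = DepthProfile(z=z, values=np.full(z.size, 100.0), quantity="resistance_density")
        return cumulative_resistance(rho, (-2, 2))

    def test_uniform_quarters(self):
        d = decompose_resistance(self._uniform_cum(), (-1.0, 1.0))
        assert d.fractions == pytest.approx((0.25, 0.5, 0.25), abs=1e-9)

    def test_central_spike_dominates(self):
        z = np.linspace(-2, 2, 801)
        rho = DepthProfile(
            z=z,
            values=1e-6 + 1e4 * np.exp(-(z**2) / 0.01),
            quantity="resistance_density",
        )
        cum = cumulative_resistance(rho, (-2, 2))
        d = decompose_resistance(cum, (-1.0, 1.0))
        assert d.fractions[1] > 0.999

    def test_sum_equals_total_exactly(self):
        cum = self._uniform_cum()
        d = decompose_resistance(cum, (-0.7, 0.7))
        assert d.total == pytest.approx(cum.values[-1], rel=1e-14)

    def test_asymmetric_edges_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            decompose_resistance(self._uniform_cum(), (-1.0, 0.5))
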