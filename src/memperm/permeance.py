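"""Membrane permeability from the inhomogeneous solubility-diffusion model.

The ISDM treats permeation as depth-resolved partition plus diffusion: with
the depth-dependent partition coefficient K(z) = exp(−ΔG(z)/RT) and local
diffusion coefficient D(z), the overall resistance to permeation is

    R = 1/P = ∫ dz / [K(z) D(z)] = ∫ exp(ΔG(z)/RT) / D(z) dz,

integrated across the membrane. P is reported in cm/s (1 nm/ps = 10⁵ cm/s).

Because R depends exponentially on where ΔG is set to zero, the reference
convention is part of the result: referencing at bulk water is the standard
choice, while referencing at the solute's equilibrium position in the bilayer
is a heuristic that restores the qualitative chain-length trend for
hydrophobic amphiphiles whose permeation is desorption-limited. The second
choice inflates the apparent resistance of the aqueous phase; this artifact
is reported in the result metadata rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import NM_PER_PS_TO_CM_PER_S, rt
from .diffusion import DepthProfile
from .pmf import (
    DEFAULT_Z_BULK,
    BarrierSet,
    FreeEnergyProfile,
    extract_barriers,
    set_reference,
)

REGIMES = ("desorption_limited", "translocation_limited", "indeterminate")

#: Default regime-classification margin, kJ/mol (≈ RT; below PMF noise floor).
DEFAULT_REGIME_MARGIN = 2.0

#: Maximum |ΔG|/RT fed to exp(); beyond this the profile is unphysical anyway.
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class PermeabilityResult:
    """ISDM permeability with its resistance integral and provenance."""

    P: float  # cm/s
    R_total: float  # ps/nm
    reference: str
    regime: str
    integration_bounds: tuple
    notes: tuple = ()


@dataclass(frozen=True)
class ResistanceDecomposition:
    """Split of R_total into entrance, center and desorption-side regions."""

    entrance: float
    center: float
    desorption: float

    @property
    def total(self) -> float:
        return self.entrance + self.center + self.desorption

    @property
    def fractions(self) -> tuple:
        t = self.total
        return (self.entrance / t, self.center / t, self.desorption / t)


def partition_profile(G: FreeEnergyProfile) -> DepthProfile:
    """Depth-dependent partition coefficient K(z) = exp(−ΔG(z)/RT)."""
    RT = rt(G.T)
    expo = np.clip(-G.G / RT, -_EXP_CLIP, _EXP_CLIP)
    return DepthProfile(
        z=G.z.copy(),
        values=np.exp(expo),
        quantity="partition",
        meta={"T": G.T, "reference": G.reference},
    )


def local_resistance(G: FreeEnergyProfile, D: DepthProfile) -> DepthProfile:
    """Local resistance density ℛ(z) = exp(ΔG(z)/RT) / D(z), ps/nm².

    D is linearly interpolated onto the PMF grid (window centers are sparse
    relative to the histogram grid). The grids must overlap; the result lives
    on the overlapping part of the PMF grid.
    """
    if D.quantity != "diffusion":
        raise ValueError(f"expected a diffusion profile, got {D.quantity!r}")
    lo = max(G.z[0], D.z[0])
    hi = min(G.z[-1], D.z[-1])
    if lo >= hi:
        raise ValueError(
            f"PMF grid [{G.z[0]:.3f}, {G.z[-1]:.3f}] and diffusion grid "
            f"[{D.z[0]:.3f}, {D.z[-1]:.3f}] nm do not overlap"
        )
    mask = (G.z >= lo - 1e-12) & (G.z <= hi + 1e-12)
    z = G.z[mask]
    d_on_grid = D.interp(z)
    if np.any(d_on_grid <= 0):
        raise ValueError("diffusion coefficient must be positive everywhere")
    RT = rt(G.T)
    expo = np.clip(G.G[mask] / RT, -_EXP_CLIP, _EXP_CLIP)
    return DepthProfile(
        z=z,
        values=np.exp(expo) / d_on_grid,
        quantity="resistance_density",
        meta={"T": G.T, "reference": G.reference},
    )


def cumulative_resistance(rho: DepthProfile, bounds: tuple) -> DepthProfile:
    """Cumulative trapezoidal integral of ℛ from the lower bound, ps/nm.

    Non-decreasing by construction; its value at the upper bound is R_total.
    """
    if rho.quantity != "resistance_density":
        raise ValueError(f"expected a resistance-density profile, got {rho.quantity!r}")
    lo, hi = bounds
    if lo >= hi:
        raise ValueError(f"inverted integration bounds {bounds}")
    if lo < rho.z[0] - 1e-9 or hi > rho.z[-1] + 1e-9:
        raise ValueError(
            f"bounds {bounds} exceed the resistance grid "
            f"[{rho.z[0]:.3f}, {rho.z[-1]:.3f}] nm"
        )
    inner = rho.z[(rho.z > lo) & (rho.z < hi)]
    z = np.unique(np.concatenate(([lo], inner, [hi])))
    vals = rho.interp(z)
    cum = cumulative_trapezoid(vals, z, initial=0.0)
    return DepthProfile(
        z=z, values=cum, quantity="cumulative_resistance", meta=dict(rho.meta)
    )


def permeability(
    G: FreeEnergyProfile,
    D: DepthProfile,
    bounds: tuple | None = None,
    reference: str = "bulk_water",
    z_bulk: float = DEFAULT_Z_BULK,
    regime_margin: float = DEFAULT_REGIME_MARGIN,
) -> PermeabilityResult:
    """ISDM permeability coefficient under a stated reference convention.

    Applies ``reference`` to the PMF, integrates the local resistance over
    ``bounds`` (default: the overlap of the PMF and diffusion grids) and
    inverts. Shifting the reference by a constant c rescales P by exp(−c/RT)
    exactly. The rate-limiting regime is classified from the PMF's barriers
    when the profile reaches the bulk region.
    """
    G_ref = set_reference(G, reference, z_bulk=z_bulk)
    rho = local_resistance(G_ref, D)
    if bounds is None:
        bounds = (float(rho.z[0]), float(rho.z[-1]))
    cum = cumulative_resistance(rho, bounds)
    R_total = float(cum.values[-1])
    P = NM_PER_PS_TO_CM_PER_S / R_total

    try:
        barriers = extract_barriers(G_ref, z_bulk=z_bulk)
        regime = classify_regime(barriers, margin=regime_margin)
    except ValueError:
        regime = "indeterminate"
    notes = ()
    if reference == "global_minimum":
        notes = (
            "minimum-referenced PMF inflates the apparent resistance of the "
            "aqueous phase; reported uncorrected",
        )
    return PermeabilityResult(
        P=P,
        R_total=R_total,
        reference=reference,
        regime=regime,
        integration_bounds=(float(bounds[0]), float(bounds[1])),
        notes=notes,
    )


def classify_regime(
    barriers: BarrierSet, margin: float = DEFAULT_REGIME_MARGIN
) -> str:
    """Which barrier limits permeation, within a noise margin (kJ/mol)."""
    if barriers.degenerate:
        return "indeterminate"
    diff = barriers.dG_desorption - barriers.dG_translocation
    if diff > margin:
        return "desorption_limited"
    if diff < -margin:
        return "translocation_limited"
    return "indeterminate"


def decompose_resistance(
    cum: DepthProfile, region_edges: tuple = (-1.0, 1.0)
) -> ResistanceDecomposition:
    """Split R_total into entrance / center / desorption-side contributions.

    ``region_edges`` = (−e, +e) must be symmetric about z = 0 and lie inside
    the integration bounds; the three contributions sum to R_total exactly.
    """
    if cum.quantity != "cumulative_resistance":
        raise ValueError(f"expected a cumulative-resistance profile, got {cum.quantity!r}")
    lo_edge, hi_edge = region_edges
    if abs(lo_edge + hi_edge) > 1e-9 or lo_edge >= hi_edge:
        raise ValueError(f"region edges {region_edges} must be symmetric about 0")
    if lo_edge < cum.z[0] - 1e-9 or hi_edge > cum.z[-1] + 1e-9:
        raise ValueError(
            f"region edges {region_edges} outside integration bounds "
            f"[{cum.z[0]:.3f}, {cum.z[-1]:.3f}] nm"
        )
    c_lo = float(cum.interp(lo_edge))
    c_hi = float(cum.interp(hi_edge))
    total = float(cum.values[-1])
    return ResistanceDecomposition(
        entrance=c_lo - float(cum.values[0]),
        center=c_hi - c_lo,
        desorption=total - c_hi,
    )
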