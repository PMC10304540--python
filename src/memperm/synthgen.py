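"""Synthetic umbrella-sampling inputs with known ground truth.

Everything downstream (WHAM, diffusion, ISDM permeability) is exercised on
data drawn from models whose answers are known in closed form:

* :class:`PmfModel` — a parametric free-energy surface G(z) along the bilayer
  normal: a bulk-water plateau, an interfacial minimum per leaflet, a central
  translocation barrier measured from that minimum, and an optional local dip
  at the midplane (seen in cholesterol-rich bilayers). Across a homologous
  family the desorption barrier grows affinely with the carbon number of the
  alkyl chain (hydrophobic-effect scaling) while the translocation barrier is
  held fixed, since the polar group that must cross the midplane is shared by
  the family. The surface is a monotone (PCHIP) interpolant through anchor
  points, so the stated barrier heights are exact by construction.

* Umbrella windows — exact stationary draws from the biased Boltzmann density
  ∝ exp(−[G(z) + k/2 (z − z0)²]/RT) by inverse-CDF sampling on a fine grid
  (no Markov chain, no burn-in ambiguity).

* Restraint-force series — stationary Ornstein–Uhlenbeck processes with
  prescribed variance σ² and correlation time τ, for which the static
  friction is ξ = σ²τ/RT exactly.

All randomness flows through one seeded generator per call; the seed is a
required argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import PchipInterpolator
from scipy.signal import lfilter

from .constants import T_DEFAULT, rt
from .diffusion import WindowForceSeries
from .membrane import MembraneFrame
from .pmf import UmbrellaWindow

#: Umbrella bias force constant, kJ mol⁻¹ nm⁻².
DEFAULT_FORCE_CONSTANT = 3000.0
#: Umbrella window spacing, nm (1 Å).
DEFAULT_WINDOW_SPACING = 0.1
#: Depth range covered by the generator, nm (both leaflets plus bulk water).
DEFAULT_Z_RANGE = (-4.0, 4.0)
#: Inverse-CDF sampling grid resolution, nm.
SAMPLING_GRID_STEP = 1e-3


@dataclass
class PmfModel:
    """Parametric free-energy surface for a membrane-bound amphiphile.

    Parameters
    ----------
    water_level : float
        Free energy of the bulk-water plateau, kJ/mol.
    minima : list of (z, depth, width)
        Interfacial minima (one per leaflet after mirroring): position (nm),
        depth below the water plateau (kJ/mol), half-width (nm). The first
        entry is the principal minimum; its depth is overridden by
        ``chain_coupling`` when ``n_carbons`` is set.
    center_barrier : float
        Translocation barrier height measured from the global minimum, kJ/mol.
    center_dip : float
        Optional local minimum depth at z = 0, measured down from the barrier
        top, kJ/mol (0 ≤ dip ≤ barrier).
    z_range : (float, float)
        Covered depth interval, nm; must span both leaflets.
    chain_coupling : (float, float) or None
        (intercept, slope): the principal desorption barrier for a chain of
        n carbons is intercept + slope·n, kJ/mol.
    n_carbons : int or None
        Chain length selecting a member of the homologous family.
    asymmetry : float
        Extra depth (kJ/mol) added to the minima of the z < 0 leaflet; 0 for
        a symmetric bilayer.
    """

    water_level: float = 0.0
    minima: list = field(default_factory=lambda: [(1.8, 20.0, 0.4)])
    center_barrier: float = 25.0
    center_dip: float = 0.0
    z_range: tuple = DEFAULT_Z_RANGE
    chain_coupling: tuple | None = None
    n_carbons: int | None = None
    asymmetry: float = 0.0

    def __post_init__(self):
        z_lo, z_hi = self.z_range
        if not (z_lo < 0 < z_hi):
            raise ValueError(f"z_range {self.z_range} must span both leaflets")
        if not self.minima:
            raise ValueError("need at least one interfacial minimum")
        if self.center_barrier < 0:
            raise ValueError("center_barrier must be non-negative")
        if not 0 <= self.center_dip <= self.center_barrier:
            raise ValueError(
                "center_dip must lie in [0, center_barrier]; "
                f"got {self.center_dip} vs {self.center_barrier}"
            )
        z_reach = min(z_hi, -z_lo)
        for z_min, depth, width in self.minima:
            if width <= 0:
                raise ValueError(f"minimum width must be positive, got {width}")
            if not 0 < z_min < z_reach:
                raise ValueError(
                    f"minimum position {z_min} nm outside (0, {z_reach}) nm; "
                    "z_range must contain the mirrored minima"
                )
        self._build()

    # -- construction -----------------------------------------------------

    def _depths(self) -> list:
        depths = [d for (_, d, _) in self.minima]
        if self.chain_coupling is not None and self.n_carbons is not None:
            intercept, slope = self.chain_coupling
            depths[0] = intercept + slope * self.n_carbons
        return depths

    def _build(self):
        z_lo, z_hi = self.z_range
        depths = self._depths()
        deepest = max(max(depths), max(depths) + self.asymmetry)
        g_floor = self.water_level - deepest
        g_top = g_floor + self.center_barrier

        anchors = {0.0: g_top - self.center_dip}
        z_first = min(z for (z, _, _) in self.minima)
        if self.center_dip > 0:
            w_d = min(0.15, 0.25 * z_first)
            anchors[w_d] = g_top
            anchors[-w_d] = g_top
        for side in (+1, -1):
            extra = self.asymmetry if side < 0 else 0.0
            z_edge = z_hi if side > 0 else -z_lo
            for (z_min, _, width), depth in zip(self.minima, depths):
                anchors[side * z_min] = self.water_level - depth - extra
                z_plat = z_min + 3 * width
                if z_plat < z_edge - 1e-9:
                    anchors[side * z_plat] = self.water_level
            anchors[side * z_edge] = self.water_level
        zs = np.array(sorted(anchors))
        gs = np.array([anchors[z] for z in zs])
        self._interp = PchipInterpolator(zs, gs, extrapolate=False)
        self._anchor_min = float(gs.min())

    # -- evaluation -------------------------------------------------------

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        z_lo, z_hi = self.z_range
        if np.any(z < z_lo - 1e-12) or np.any(z > z_hi + 1e-12):
            raise ValueError(f"z outside covered range {self.z_range} nm")
        return self._interp(np.clip(z, z_lo, z_hi))

    def grid(self, step: float = SAMPLING_GRID_STEP) -> np.ndarray:
        z_lo, z_hi = self.z_range
        n = int(round((z_hi - z_lo) / step))
        return np.linspace(z_lo, z_hi, n + 1)

    def desorption_barrier(self) -> float:
        """Water plateau minus the global minimum, kJ/mol (exact)."""
        return self.water_level - self._anchor_min

    def translocation_barrier(self) -> float:
        """G(0) minus the global minimum, kJ/mol (exact)."""
        return float(self(0.0)) - self._anchor_min


@dataclass
class CallablePmf:
    """Adapter turning any G(z) callable into a sampleable surface.

    Useful for generating-potential oracles (flat, linear, harmonic, ...)
    whose recovered profile can be compared against the known input.
    """

    f: object
    z_range: tuple = DEFAULT_Z_RANGE

    def __call__(self, z):
        return np.asarray(self.f(np.asarray(z, dtype=float)), dtype=float)

    def grid(self, step: float = SAMPLING_GRID_STEP) -> np.ndarray:
        z_lo, z_hi = self.z_range
        n = int(round((z_hi - z_lo) / step))
        return np.linspace(z_lo, z_hi, n + 1)


def make_pmf_model(params: dict | None = None, n_carbons: int | None = None) -> PmfModel:
    """Build a family member: the desorption barrier is intercept + slope·n."""
    params = dict(params or {})
    params.setdefault("chain_coupling", (10.0, 2.5))
    return PmfModel(n_carbons=n_carbons, **params)


@dataclass(frozen=True)
class OuSpec:
    """Stationary Ornstein–Uhlenbeck force-series parameters.

    The implied static friction is ξ = σ²τ/RT and the implied local diffusion
    coefficient D = RT/ξ = RT²/(σ²τ).
    """

    variance: float  # (kJ mol⁻¹ nm⁻¹)²
    tau: float  # ps
    dt: float  # ps
    n_samples: int
    seed: int

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError(f"variance must be non-negative, got {self.variance}")
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")

    def implied_friction(self, T: float = T_DEFAULT) -> float:
        """ξ = σ²τ/RT, kJ mol⁻¹ nm⁻² ps."""
        return self.variance * self.tau / rt(T)

    def implied_diffusion(self, T: float = T_DEFAULT) -> float:
        """D = RT/ξ, nm²/ps."""
        return rt(T) / self.implied_friction(T)


def sample_umbrella_window(
    model: PmfModel,
    z0: float,
    k: float = DEFAULT_FORCE_CONSTANT,
    n: int = 2000,
    T: float = T_DEFAULT,
    seed: int = 0,
    dt: float = 40.0,
    grid_step: float = SAMPLING_GRID_STEP,
) -> UmbrellaWindow:
    """Exact stationary draws from one harmonically biased window.

    Samples the density ∝ exp(−[G(z) + k/2 (z − z0)²]/RT) by inverse-CDF
    lookup on a ``grid_step`` grid over the model's range. A fixed seed
    reproduces the series exactly.
    """
    if k <= 0:
        raise ValueError(f"force constant must be positive, got {k}")
    if n < 1:
        raise ValueError("need at least one sample")
    z = model.grid(grid_step)
    if z.size < 2:
        raise ValueError("degenerate z_range")
    RT = rt(T)
    energy = model(z) + 0.5 * k * (z - z0) ** 2
    weight = np.exp(-(energy - energy.min()) / RT)
    cdf = np.concatenate(([0.0], cumulative_trapezoid(weight, z)))
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    samples = np.interp(rng.random(n), cdf, z)
    return UmbrellaWindow(z0=z0, k=k, dt=dt, samples=samples)


def gen_force_series(
    spec: OuSpec, T: float = T_DEFAULT, z0: float = 0.0
) -> WindowForceSeries:
    """Stationary OU restraint-force fluctuation series at depth ``z0``.

    Uses the exact discrete OU update x_{t+1} = a x_t + √(σ²(1 − a²)) η with
    a = exp(−dt/τ) and a stationary initial draw, so every marginal has
    variance σ² and the lag autocovariance is σ² exp(−t/τ).
    """
    if spec.dt >= spec.tau:
        warnings.warn(
            f"dt = {spec.dt} ps ≥ tau = {spec.tau} ps: discretization too "
            "coarse to resolve the ACF decay",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(spec.variance)
    if sigma == 0:
        return WindowForceSeries(z0=z0, dt=spec.dt, F=np.zeros(spec.n_samples))
    a = np.exp(-spec.dt / spec.tau)
    eta = rng.standard_normal(spec.n_samples)
    eta[1:] *= sigma * np.sqrt(1 - a * a)
    eta[0] *= sigma  # stationary initialization
    F = lfilter([1.0], [1.0, -a], eta)
    return WindowForceSeries(z0=z0, dt=spec.dt, F=F)


def gen_membrane_frame(
    n_lipid: int,
    x_chol: float,
    n_water: int,
    a_box: float,
    v_box: float,
    target_scd: float,
    seed: int,
    n_carbons: int = 16,
    z_head: float = 1.9,
    rise_per_carbon: float = 0.127,
) -> MembraneFrame:
    """Fixture frame with chain vectors at the fixed tilt matching a target S_CD.

    Every C–D vector is placed at the polar angle θ* solving
    (3 cos²θ* − 1)/2 = target_scd (random azimuths), so the computed order
    parameter equals the target for every carbon. Labeled positions describe
    an all-trans chain along the normal (head at ``z_head``, terminal carbon
    ``rise_per_carbon``·(n_carbons − 1) below it) and phosphate analogs at
    ±``z_head``.
    """
    if not -0.5 <= target_scd <= 1.0:
        raise ValueError(f"target_scd must be in [-0.5, 1], got {target_scd}")
    rng = np.random.default_rng(seed)
    cos_theta = np.sqrt((2 * target_scd + 1) / 3)
    sin_theta = np.sqrt(max(0.0, 1 - cos_theta**2))
    chain_vectors = {}
    for c in range(1, n_carbons + 1):
        phi = rng.uniform(0, 2 * np.pi, size=n_lipid)
        chain_vectors[c] = np.column_stack(
            [
                sin_theta * np.cos(phi),
                sin_theta * np.sin(phi),
                np.full(n_lipid, cos_theta),
            ]
        )
    length = rise_per_carbon * (n_carbons - 1)
    labeled = {
        "head": np.array([0.0, 0.0, z_head]),
        "Cter": np.array([0.0, 0.0, z_head - length]),
        "P_upper": np.array([0.0, 0.0, z_head]),
        "P_lower": np.array([0.0, 0.0, -z_head]),
    }
    n_chol = int(round(x_chol * n_lipid))
    labels = ["CHOL"] * n_chol + ["PL"] * (n_lipid - n_chol)
    return MembraneFrame(
        a_box=a_box,
        v_box=v_box,
        n_water=n_water,
        n_lipid=n_lipid,
        x_chol=x_chol,
        chain_vectors=chain_vectors,
        labeled_positions=labeled,
        composition_labels=labels,
    )


def default_diffusion_truth():
    """Ground-truth D(z) emulating an amphiphile in a hydrated bilayer.

    ~8×10⁻⁴ nm²/ps (≈10⁻⁵ cm²/s) in bulk water, a minimum near the dense
    interfacial region, and a partial recovery at the low-density midplane.
    Returns a callable D(z) in nm²/ps, symmetric in z.
    """
    z_knots = np.array([0.0, 0.8, 1.6, 2.4, 3.2, 4.0])
    d_knots = np.array([3e-4, 1.5e-4, 1.0e-4, 3e-4, 8e-4, 8e-4])
    interp = PchipInterpolator(z_knots, d_knots, extrapolate=False)

    def D(z):
        return interp(np.clip(np.abs(z), 0.0, z_knots[-1]))

    return D


def make_force_spec_for_diffusion(
    D: float,
    tau: float = 0.1,
    dt: float = 0.01,
    n_samples: int = 100_000,
    seed: int = 0,
    T: float = T_DEFAULT,
) -> OuSpec:
    """OU spec whose implied diffusion coefficient is exactly ``D`` (nm²/ps)."""
    RT = rt(T)
    variance = RT * RT / (D * tau)
    return OuSpec(variance=variance, tau=tau, dt=dt, n_samples=n_samples, seed=seed)


def window_centers(
    spacing: float = DEFAULT_WINDOW_SPACING,
    z_range: tuple = DEFAULT_Z_RANGE,
    one_leaflet: bool = False,
) -> np.ndarray:
    """Bias centers on a regular grid (optionally z ≥ 0 only)."""
    lo, hi = (0.0, z_range[1]) if one_leaflet else z_range
    n = int(round((hi - lo) / spacing))
    return lo + spacing * np.arange(n + 1)


def write_dataset(
    outdir,
    model: PmfModel,
    seed: int,
    centers: np.ndarray | None = None,
    k: float = DEFAULT_FORCE_CONSTANT,
    n_window_samples: int = 2000,
    window_dt: float = 40.0,
    diffusion_truth=None,
    tau: float = 0.1,
    force_dt: float = 0.01,
    n_force_samples: int = 100_000,
    T: float = T_DEFAULT,
) -> dict:
    """Write a complete synthetic dataset (window + force XVG files).

    One ``window_<z0>.xvg`` and one ``force_<z0>.xvg`` per bias center, with
    z0, k, seed and dt recorded in ``#`` metadata headers. Per-file seeds are
    spawned deterministically from ``seed``. Returns the file manifest.
    """
    from .io import write_timeseries  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if centers is None:
        centers = window_centers(z_range=model.z_range)
    if diffusion_truth is None:
        diffusion_truth = default_diffusion_truth()
    master = np.random.default_rng(seed)
    manifest = {"windows": [], "forces": [], "seed": seed}
    for z0 in centers:
        w_seed = int(master.integers(0, 2**31))
        f_seed = int(master.integers(0, 2**31))
        win = sample_umbrella_window(
            model, z0=z0, k=k, n=n_window_samples, T=T, seed=w_seed, dt=window_dt
        )
        wpath = outdir / f"window_{z0:+.2f}.xvg"
        write_timeseries(
            wpath, win.dt, win.samples, meta={"z0": z0, "k": k, "seed": w_seed}
        )
        spec = make_force_spec_for_diffusion(
            float(diffusion_truth(z0)),
            tau=tau,
            dt=force_dt,
            n_samples=n_force_samples,
            seed=f_seed,
            T=T,
        )
        fser = gen_force_series(spec, T=T, z0=z0)
        fpath = outdir / f"force_{z0:+.2f}.xvg"
        write_timeseries(
            fpath, fser.dt, fser.F, meta={"z0": z0, "k": k, "seed": f_seed}
        )
        manifest["windows"].append(str(wpath))
        manifest["forces"].append(str(fpath))
    return manifest
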