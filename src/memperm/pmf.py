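"""Free-energy profiles from umbrella-sampling windows.

The potential of mean force (PMF) G(z) along the bilayer normal is
reconstructed from harmonically biased windows with the weighted histogram
analysis method (WHAM). Each window i restrains the solute at depth z0_i with
a bias U_i(z) = k/2 (z − z0_i)², and WHAM solves self-consistently for the
unbiased density ρ(z) and the per-window free energies f_i:

    ρ(b) = Σ_i n_i(b) / Σ_i N_i exp[(f_i − U_i(z_b)) / RT]
    f_i  = −RT ln Σ_b ρ(b) exp[−U_i(z_b) / RT]

with G(z) = −RT ln ρ(z), defined up to an additive constant fixed by an
explicit reference convention (bulk water, global minimum, or bilayer center).

Supporting diagnostics: split-half uncertainty (the profile difference between
the two halves of the sampling time), three truncation-based convergence
schemes, symmetrization for symmetric bilayers, and barrier extraction
(equilibrium depth, translocation and desorption barriers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.special import logsumexp

from .constants import T_DEFAULT, rt

REFERENCE_CONVENTIONS = ("bulk_water", "global_minimum", "bilayer_center")

#: Default histogram bin width, nm. Resolves the harmonic-bias width
#: sqrt(RT/k) ≈ 0.029 nm at k = 3000 kJ mol⁻¹ nm⁻².
DEFAULT_BIN_WIDTH = 0.02

#: Default innermost depth (nm) considered bulk water.
DEFAULT_Z_BULK = 3.5


class WhamError(RuntimeError):
    """Base class for WHAM failures."""


class CoverageGapError(WhamError):
    """Window histograms leave an interior stretch of the grid unsampled."""


class WhamConvergenceError(WhamError):
    """Self-consistent iteration did not reach tolerance."""

    def __init__(self, residual: float, n_iter: int):
        self.residual = residual
        self.n_iter = n_iter
        super().__init__(
            f"WHAM did not converge after {n_iter} iterations "
            f"(last residual {residual:.3e} kJ/mol)"
        )


@dataclass(frozen=True)
class UmbrellaWindow:
    """One biased umbrella-sampling window.

    Parameters
    ----------
    z0 : float
        Bias center along the bilayer normal, nm.
    k : float
        Harmonic force constant, kJ mol⁻¹ nm⁻².
    dt : float
        Sampling interval of the stored reaction-coordinate series, ps.
    samples : np.ndarray
        Ordered reaction-coordinate values, nm.
    """

    z0: float
    k: float
    dt: float
    samples: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.k <= 0:
            raise ValueError(f"force constant must be positive, got {self.k}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.samples.size == 0:
            raise ValueError("window has no samples")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    def truncated(self, start: int = 0, stop: int | None = None) -> "UmbrellaWindow":
        sub = self.samples[start:stop]
        if sub.size == 0:
            raise ValueError(
                f"truncation [{start}:{stop}] leaves window at z0={self.z0} empty"
            )
        return replace(self, samples=sub)


@dataclass
class FreeEnergyProfile:
    """Free energy G(z) on a depth grid with an explicit zero convention."""

    z: np.ndarray
    G: np.ndarray
    reference: str = "bilayer_center"
    T: float = T_DEFAULT
    uncertainty: np.ndarray | None = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.z.ndim != 1 or self.z.size == 0:
            raise ValueError("z grid must be a non-empty 1D array")
        if self.z.size != self.G.size:
            raise ValueError("z and G must have equal length")
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("z grid must be strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G must be finite on the covered grid")
        if self.reference not in REFERENCE_CONVENTIONS:
            raise ValueError(
                f"unknown reference {self.reference!r}; "
                f"expected one of {REFERENCE_CONVENTIONS}"
            )
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
            if self.uncertainty.size != self.z.size:
                raise ValueError("uncertainty must match the grid length")

    def interp(self, z: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation of G at depth(s) z (clamped at grid ends)."""
        return np.interp(z, self.z, self.G)


@dataclass(frozen=True)
class BarrierSet:
    """Equilibrium depth and the two permeation barriers read off a PMF.

    ``dG_translocation`` is G(0) − G(z_eq) (cost of reaching the bilayer
    midplane); ``dG_desorption`` is G(bulk water) − G(z_eq) (cost of leaving
    the membrane). ``per_leaflet`` carries (z_eq, translocation, desorption)
    per side for asymmetric profiles.
    """

    z_eq: float
    dG_desorption: float
    dG_translocation: float
    degenerate: bool = False
    per_leaflet: dict | None = None


@dataclass
class HistogramSet:
    """Per-window histograms on a shared grid, plus coverage diagnostics."""

    edges: np.ndarray
    centers: np.ndarray
    counts: np.ndarray  # (n_windows, n_bins)
    gaps: list = field(default_factory=list)

    @property
    def total(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def histogram_windows(windows, bin_width: float = DEFAULT_BIN_WIDTH) -> HistogramSet:
    """Histogram every window onto one shared grid spanning all supports.

    Records, as diagnostics, any interval between the supports of consecutive
    windows (sorted by sample range) that no window covers.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if not windows:
        raise ValueError("need at least one window")
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    # Snap edges to multiples of bin_width so grids are reproducible.
    first = np.floor(lo / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((hi - first) / bin_width)))
    edges = first + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.empty((len(windows), n_bins))
    for i, w in enumerate(windows):
        counts[i], _ = np.histogram(w.samples, bins=edges)

    gaps = []
    supports = sorted((w.samples.min(), w.samples.max()) for w in windows)
    reach = supports[0][1]
    for smin, smax in supports[1:]:
        if smin > reach:
            gaps.append((reach, smin))
        reach = max(reach, smax)
    if gaps:
        warnings.warn(
            f"window supports leave uncovered interval(s): {gaps}", stacklevel=2
        )
    return HistogramSet(edges=edges, centers=centers, counts=counts, gaps=gaps)


def wham_solve(
    windows,
    T: float = T_DEFAULT,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_edge_count: float | None = None,
) -> FreeEnergyProfile:
    """Self-consistent WHAM estimate of the unbiased free-energy profile.

    Iterates the density/window-free-energy equations in log space until the
    largest per-iteration change of any window free energy falls below ``tol``
    (kJ/mol, strict inequality). The returned profile is restricted to the
    contiguous well-sampled grid: edge bins holding fewer than
    ``min_edge_count`` samples (default: 0.5% of the fullest bin, at least 2)
    are trimmed, since a free energy read off a handful of extreme-tail
    samples is dominated by shot noise. The profile is referenced at the
    bilayer center.

    Raises
    ------
    CoverageGapError
        If interior histogram bins receive no samples from any window.
    WhamConvergenceError
        If ``tol`` is not reached within ``max_iter`` iterations.
    """
    hist = histogram_windows(windows, bin_width)
    total = hist.total
    if min_edge_count is None:
        min_edge_count = max(2.0, 0.005 * total.max())
    covered = np.nonzero(total >= min_edge_count)[0]
    if covered.size == 0:
        covered = np.nonzero(total > 0)[0]
    first, last = covered[0], covered[-1]
    interior = total[first : last + 1]
    if np.any(interior == 0):
        holes = hist.centers[first : last + 1][interior == 0]
        raise CoverageGapError(
            f"{holes.size} empty interior bin(s) near z = {holes[:5]} nm; "
            "window overlap insufficient"
        )
    centers = hist.centers[first : last + 1]
    counts = hist.counts[:, first : last + 1]

    RT = rt(T)
    z0 = np.array([w.z0 for w in windows])
    k = np.array([w.k for w in windows])
    N = counts.sum(axis=1)  # samples landing on the kept grid
    ln_N = np.log(N)
    ln_total = np.log(interior.astype(float))
    # B[i, b] = −U_i(z_b)/RT
    B = -(0.5 * k[:, None] * (centers[None, :] - z0[:, None]) ** 2) / RT

    # Warm start: the WHAM equations are the stationarity condition of a
    # convex objective in the window free energies; a quasi-Newton pass gets
    # within polish distance in a few dozen evaluations, after which the
    # documented self-consistent iteration runs until its own tolerance.
    f = _wham_warm_start(B, ln_N, interior.astype(float), RT)
    converged = False
    for it in range(max_iter):
        ln_denom = logsumexp(B + (ln_N + f / RT)[:, None], axis=0)
        ln_rho = ln_total - ln_denom
        f_new = -RT * logsumexp(B + ln_rho[None, :], axis=1)
        f_new -= f_new[0]  # gauge fixing: profile is defined up to a constant
        residual = np.max(np.abs(f_new - f))
        f = f_new
        if residual < tol:
            converged = True
            break
    if not converged:
        raise WhamConvergenceError(residual, max_iter)

    ln_denom = logsumexp(B + (ln_N + f / RT)[:, None], axis=0)
    G = -RT * (ln_total - ln_denom)
    profile = FreeEnergyProfile(z=centers, G=G, reference="bilayer_center", T=T)
    return set_reference(profile, "bilayer_center")


def _wham_warm_start(B, ln_N, counts, RT):
    """Minimize the convex WHAM objective over reduced free energies f/RT."""
    from scipy.optimize import minimize

    N = np.exp(ln_N)
    total = counts

    def obj(g):
        M = B + (ln_N + g)[:, None]
        ln_denom = logsumexp(M, axis=0)
        val = float(total @ ln_denom - N @ g)
        p = np.exp(M - ln_denom[None, :])  # window occupancy probabilities
        grad = p @ total - N
        return val, grad

    res = minimize(obj, np.zeros(ln_N.size), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10})
    g = res.x - res.x[0]
    return g * RT


def set_reference(
    profile: FreeEnergyProfile,
    convention: str,
    z_bulk: float = DEFAULT_Z_BULK,
) -> FreeEnergyProfile:
    """Shift a profile to a zero convention; pairwise ΔG are preserved.

    ``bulk_water`` zeroes the mean of G over |z| ≥ z_bulk, ``global_minimum``
    zeroes min(G), ``bilayer_center`` zeroes G at the grid point nearest z = 0.
    """
    if convention not in REFERENCE_CONVENTIONS:
        raise ValueError(f"unknown reference convention {convention!r}")
    if convention == "bulk_water":
        mask = np.abs(profile.z) >= z_bulk
        if not mask.any():
            raise ValueError(
                f"grid (|z| ≤ {np.abs(profile.z).max():.3f} nm) does not reach "
                f"the bulk-water region |z| ≥ {z_bulk} nm"
            )
        shift = profile.G[mask].mean()
    elif convention == "global_minimum":
        shift = profile.G.min()
    else:
        shift = profile.G[np.argmin(np.abs(profile.z))]
    return FreeEnergyProfile(
        z=profile.z.copy(),
        G=profile.G - shift,
        reference=convention,
        T=profile.T,
        uncertainty=None if profile.uncertainty is None else profile.uncertainty.copy(),
    )


def mirror_average(z_query, z, values):
    """Mean of the defined values among {v(z), v(−z)} by linear interpolation.

    Where only one of the pair lies inside the covered range, that value is
    used alone; this reflects a one-leaflet profile and averages a two-leaflet
    one.
    """
    z_query = np.asarray(z_query, dtype=float)
    inside = lambda x: (x >= z[0] - 1e-12) & (x <= z[-1] + 1e-12)  # noqa: E731
    here = np.where(inside(z_query), np.interp(z_query, z, values), np.nan)
    mirr = np.where(inside(-z_query), np.interp(-z_query, z, values), np.nan)
    both = np.column_stack([here, mirr])
    if np.all(np.isnan(both), axis=1).any():
        raise ValueError("query point outside both the grid and its mirror")
    return np.nanmean(both, axis=1)


def symmetrize(profile: FreeEnergyProfile) -> FreeEnergyProfile:
    """Make the profile mirror-symmetric: G_sym(z) = [G(z) + G(−z)] / 2.

    The output grid is the union of the input grid and its reflection. Where
    both leaflets were sampled the two values are averaged; where only one
    was (a one-leaflet profile) it is reflected onto the other side, the
    usual presentation for symmetric bilayers. Idempotent.
    """
    z = np.union1d(profile.z, -profile.z)
    # merge floating-point near-duplicates (a grid and its reflection rarely
    # coincide bitwise); the merged set stays exactly mirror-symmetric
    tol = 1e-9 * max(1.0, float(np.abs(z).max()))
    starts = np.flatnonzero(np.concatenate(([True], np.diff(z) > tol)))
    ends = np.append(starts[1:], z.size)
    z = np.array([z[s:e].mean() for s, e in zip(starts, ends)])
    G = mirror_average(z, profile.z, profile.G)
    return FreeEnergyProfile(
        z=z,
        G=G,
        reference=profile.reference,
        T=profile.T,
    )


@dataclass(frozen=True)
class SplitHalfResult:
    """Per-depth |ΔG| between PMFs from the two halves of the sampling time."""

    z: np.ndarray
    err: np.ndarray

    @property
    def median(self) -> float:
        return float(np.median(self.err))


def split_half_uncertainty(
    windows, T: float = T_DEFAULT, **wham_kwargs
) -> SplitHalfResult:
    """PMF uncertainty from the first vs second half of each window's series.

    Both half-profiles are aligned (each shifted to zero mean over the common
    grid) before taking the pointwise absolute difference.
    """
    for w in windows:
        if w.n < 2:
            raise ValueError(f"window at z0={w.z0} too short to split (n={w.n})")
    halves = []
    for part in (0, 1):
        sub = [
            w.truncated(0, w.n // 2) if part == 0 else w.truncated(w.n // 2, None)
            for w in windows
        ]
        halves.append(wham_solve(sub, T=T, **wham_kwargs))
    a, b = halves
    lo = max(a.z[0], b.z[0])
    hi = min(a.z[-1], b.z[-1])
    mask = (a.z >= lo) & (a.z <= hi)
    z = a.z[mask]
    ga = a.G[mask]
    gb = np.interp(z, b.z, b.G)
    ga = ga - ga.mean()
    gb = gb - gb.mean()
    return SplitHalfResult(z=z, err=np.abs(ga - gb))


def convergence_scan(
    windows,
    scheme: str,
    step: float,
    analysis_span: float | None = None,
    T: float = T_DEFAULT,
    **wham_kwargs,
):
    """PMFs from systematically truncated window data.

    Three truncation schemes probe equilibration and sampling convergence:

    - ``"i"``   — analyse growing prefixes [0, m·step];
    - ``"ii"``  — discard a growing equilibration prefix, analyse the rest;
    - ``"iii"`` — discard a growing prefix, analyse a fixed span after it
      (``analysis_span``, ps, required).

    ``step`` (ps) must divide the common series length. Returns a list of
    ``(t_mark_ps, FreeEnergyProfile)`` where ``t_mark_ps`` is the end of the
    analysed stretch (scheme i) or the equilibration time discarded (ii, iii).
    """
    if scheme not in ("i", "ii", "iii"):
        raise ValueError(f"scheme must be 'i', 'ii' or 'iii', got {scheme!r}")
    dt = windows[0].dt
    n = min(w.n for w in windows)
    total = n * dt
    n_step = int(round(step / dt))
    if n_step <= 0 or abs(n_step * dt - step) > 1e-9 * max(step, dt):
        raise ValueError(f"step {step} ps is not a multiple of dt {dt} ps")
    if n % n_step != 0:
        raise ValueError(
            f"step {step} ps does not divide the series length {total} ps"
        )
    out = []
    if scheme == "i":
        for m in range(1, n // n_step + 1):
            subs = [w.truncated(0, m * n_step) for w in windows]
            out.append((m * n_step * dt, wham_solve(subs, T=T, **wham_kwargs)))
    elif scheme == "ii":
        for m in range(0, n // n_step):
            start = m * n_step
            subs = [w.truncated(start, None) for w in windows]
            out.append((start * dt, wham_solve(subs, T=T, **wham_kwargs)))
    else:
        if analysis_span is None:
            raise ValueError("scheme iii requires analysis_span")
        n_span = int(round(analysis_span / dt))
        if n_span > n:
            raise ValueError(
                f"analysis_span {analysis_span} ps exceeds series length {total} ps"
            )
        n_points = (n - n_span) // n_step + 1
        for m in range(n_points):
            start = m * n_step
            subs = [w.truncated(start, start + n_span) for w in windows]
            out.append((start * dt, wham_solve(subs, T=T, **wham_kwargs)))
    return out


def extract_barriers(
    profile: FreeEnergyProfile,
    z_bulk: float = DEFAULT_Z_BULK,
    smooth_window: float = 0.3,
) -> BarrierSet:
    """Equilibrium depth plus translocation and desorption barriers.

    The equilibrium depth is the argmin of a moving-average-smoothed G
    (window ``smooth_window`` nm; raw argmin is unstable on rugged PMFs), with
    ties broken toward smaller |z|. Barrier values are read off the raw
    profile: translocation = G(0) − G(z_eq), desorption = Ḡ_bulk − G(z_eq)
    with Ḡ_bulk the mean of G over |z| ≥ z_bulk. Monotone or flat interiors
    are flagged degenerate and reported against the grid endpoints.

    For asymmetric profiles covering both leaflets, per-leaflet values are
    returned alongside the global ones.
    """
    z, G = profile.z, profile.G
    dz = np.median(np.diff(z))
    width = max(1, int(round(smooth_window / dz)))
    G_smooth = uniform_filter1d(G, size=width, mode="nearest")

    bulk_mask = np.abs(z) >= z_bulk
    if not bulk_mask.any():
        raise ValueError(f"profile does not reach the bulk region |z| ≥ {z_bulk} nm")
    interior = ~bulk_mask

    def _one_side(mask):
        idx = np.nonzero(mask)[0]
        gs = G_smooth[idx]
        gmin = gs.min()
        cand = idx[gs <= gmin + 1e-12]
        i_eq = cand[np.argmin(np.abs(z[cand]))]
        # degenerate if the smoothed minimum sits at the edge of the searched
        # region (monotone) or the profile is essentially flat
        at_edge = i_eq in (idx[0], idx[-1])
        flat = (G.max() - G.min()) < 1e-9
        return i_eq, bool(at_edge or flat)

    i_eq, degenerate = _one_side(interior if interior.any() else np.ones_like(G, bool))
    z_eq = float(z[i_eq])
    g_eq = float(G[i_eq])
    g_center = float(G[np.argmin(np.abs(z))])
    g_bulk = float(G[bulk_mask].mean())
    result = BarrierSet(
        z_eq=z_eq,
        dG_desorption=g_bulk - g_eq,
        dG_translocation=g_center - g_eq,
        degenerate=degenerate,
    )

    # per-leaflet values when the profile covers both sides and is asymmetric
    covers_both = z[0] < 0 < z[-1]
    if covers_both:
        g_mirror = np.interp(-z, z, G)
        if np.max(np.abs(G - g_mirror)) > 1e-9:
            per = {}
            for name, side in (("lower", z < 0), ("upper", z > 0)):
                m = side & interior
                if not m.any() or not (side & bulk_mask).any():
                    continue
                i_s, deg_s = _one_side(m)
                per[name] = BarrierSet(
                    z_eq=float(z[i_s]),
                    dG_desorption=float(G[side & bulk_mask].mean() - G[i_s]),
                    dG_translocation=float(g_center - G[i_s]),
                    degenerate=deg_s,
                )
            result = replace(result, per_leaflet=per)
    return result
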