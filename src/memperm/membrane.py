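"""Bilayer and amphiphile descriptors for cholesterol-containing membranes.

Implements the volume-based decomposition of the box area into per-species
cross-sectional areas for a phospholipid/cholesterol mixture,

    A_Chol = 2 A_box V_Chol / (V_box − N_W V_W)
    A_PL   = 2 A_box (V_box − N_W V_W − x N_lipid V_Chol)
             / [(V_box − N_W V_W) (1 − x) N_lipid],

which conserves (1−x) N A_PL + x N A_Chol = 2 A_box exactly; deuterium order
parameters S_CD = ⟨(3 cos²θ − 1)/2⟩ for C–D bond vectors against the bilayer
normal; and the simple geometric descriptors used to follow an amphiphile
along the permeation path (group-axis orientation histograms, chain
elongation, transverse distances, geometric hydrogen-bond counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

#: Volume of one water molecule, nm³.
V_WATER_DEFAULT = 0.0312
#: Volume of one cholesterol molecule, nm³.
V_CHOL_DEFAULT = 0.593


@dataclass
class MembraneFrame:
    """One snapshot of a hydrated bilayer with labeled geometry.

    ``chain_vectors`` maps carbon index → (n, 3) array of C–D unit vectors;
    ``labeled_positions`` maps a label (e.g. ``"head"``, ``"Cter"``,
    ``"P_upper"``) to a 3-vector in nm. The bilayer normal defaults to +z.
    """

    a_box: float  # nm², xy box area
    v_box: float  # nm³, box volume
    n_water: int
    n_lipid: int
    x_chol: float
    v_water: float = V_WATER_DEFAULT
    v_chol: float = V_CHOL_DEFAULT
    chain_vectors: dict = field(default_factory=dict)
    labeled_positions: dict = field(default_factory=dict)
    normal: np.ndarray = None
    composition_labels: list = field(default_factory=list)

    def __post_init__(self):
        if self.normal is None:
            self.normal = np.array([0.0, 0.0, 1.0])
        self.normal = np.asarray(self.normal, dtype=float)
        self.normal = self.normal / np.linalg.norm(self.normal)
        if not 0 <= self.x_chol <= 1:
            raise ValueError(f"cholesterol fraction must be in [0, 1], got {self.x_chol}")
        if self.v_box <= self.n_water * self.v_water:
            raise ValueError(
                f"box volume {self.v_box} nm³ does not exceed the water volume "
                f"{self.n_water * self.v_water} nm³"
            )
        for c, vecs in self.chain_vectors.items():
            vecs = np.atleast_2d(np.asarray(vecs, dtype=float))
            norms = np.linalg.norm(vecs, axis=1)
            if np.any(norms < 1e-12):
                raise ValueError(f"zero-length C–D vector at carbon {c}")
            self.chain_vectors[c] = vecs / norms[:, None]

    @property
    def lipid_volume(self) -> float:
        """Non-water volume of the box, nm³."""
        return self.v_box - self.n_water * self.v_water


@dataclass(frozen=True)
class AreaResult:
    """Per-species cross-sectional areas, nm²."""

    a_pl: float
    a_chol: float
    a_inst: float  # instant box area per lipid in one monolayer


def area_decomposition(frame: MembraneFrame) -> AreaResult:
    """Volume-weighted split of the box area into per-lipid-species areas."""
    x = frame.x_chol
    v_lip = frame.lipid_volume
    if x >= 1:
        raise ValueError("no phospholipid present (x_chol = 1); A_PL undefined")
    v_pl_total = v_lip - x * frame.n_lipid * frame.v_chol
    if v_pl_total <= 0:
        raise ValueError(
            "implied phospholipid volume is non-positive; composition and box "
            "volume are inconsistent"
        )
    a_chol = 2 * frame.a_box * frame.v_chol / v_lip
    a_pl = 2 * frame.a_box * v_pl_total / (v_lip * (1 - x) * frame.n_lipid)
    a_inst = frame.a_box / (frame.n_lipid / 2)
    return AreaResult(a_pl=a_pl, a_chol=a_chol, a_inst=a_inst)


def order_parameter_profile(frame: MembraneFrame) -> dict:
    """Deuterium order parameter S_CD per carbon index.

    S_CD = ⟨(3 cos²θ − 1)/2⟩ over all C–D vectors sharing a carbon index,
    with θ the angle to the bilayer normal. Bounded in [−0.5, 1].
    """
    if not frame.chain_vectors:
        raise ValueError("frame carries no chain vectors")
    out = {}
    for c in sorted(frame.chain_vectors):
        cos = frame.chain_vectors[c] @ frame.normal
        out[c] = float(np.mean(1.5 * cos**2 - 0.5))
    return out


@dataclass(frozen=True)
class AngleHistogram:
    """Normalized distribution of axis–normal angles in degrees on [0, 180]."""

    edges: np.ndarray
    mass: np.ndarray  # sums to 1
    modal_angle: float


def orientation_histogram(axes, normal, bins: int = 36) -> AngleHistogram:
    """Histogram of angles between group axes and the bilayer normal."""
    if bins < 2:
        raise ValueError(f"need at least 2 bins, got {bins}")
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    norms = np.linalg.norm(axes, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length axis vector")
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    cos = np.clip((axes / norms[:, None]) @ normal, -1.0, 1.0)
    angles = np.degrees(np.arccos(cos))
    mass, edges = np.histogram(angles, bins=bins, range=(0.0, 180.0))
    mass = mass / mass.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AngleHistogram(edges=edges, mass=mass, modal_angle=float(centers[np.argmax(mass)]))


def _position(frame: MembraneFrame, label: str) -> np.ndarray:
    try:
        return np.asarray(frame.labeled_positions[label], dtype=float)
    except KeyError:
        raise KeyError(
            f"label {label!r} missing; available: {sorted(frame.labeled_positions)}"
        ) from None


def chain_elongation(frame: MembraneFrame, head: str = "head", tail: str = "Cter") -> float:
    """Euclidean head-group-to-terminal-carbon distance, nm."""
    return float(np.linalg.norm(_position(frame, head) - _position(frame, tail)))


def transverse_distance(frame: MembraneFrame, label_a: str, label_b: str) -> float:
    """Separation of two labeled points along the bilayer normal, nm."""
    delta = _position(frame, label_a) - _position(frame, label_b)
    return float(abs(delta @ frame.normal))


def hbond_count(
    donors,
    hydrogens,
    acceptors,
    d_cut: float = 0.35,
    angle_cut: float = 30.0,
) -> int:
    """Geometric hydrogen-bond count.

    A (donor, acceptor) pair is bonded when the donor–acceptor distance is
    ≤ ``d_cut`` (nm) and the hydrogen–donor–acceptor angle is ≤ ``angle_cut``
    (degrees). Each pair is counted at most once (via its paired hydrogen).
    """
    donors = np.atleast_2d(np.asarray(donors, dtype=float))
    hydrogens = np.atleast_2d(np.asarray(hydrogens, dtype=float))
    acceptors = np.atleast_2d(np.asarray(acceptors, dtype=float))
    if donors.shape != hydrogens.shape:
        raise ValueError(
            f"donor/hydrogen lists must pair up: {donors.shape} vs {hydrogens.shape}"
        )
    if donors.size == 0 or acceptors.size == 0:
        return 0
    tree = cKDTree(acceptors)
    cos_cut = np.cos(np.radians(angle_cut))
    count = 0
    for d, h in zip(donors, hydrogens):
        for j in tree.query_ball_point(d, d_cut):
            a = acceptors[j]
            dh = h - d
            da = a - d
            n1, n2 = np.linalg.norm(dh), np.linalg.norm(da)
            if n2 < 1e-12:
                continue
            if n1 < 1e-12:
                cos_angle = 1.0  # hydrogen on the donor: angle defined as 0
            else:
                cos_angle = float(dh @ da) / (n1 * n2)
            if cos_angle >= cos_cut:
                count += 1
    return count
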