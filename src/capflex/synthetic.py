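"""Synthetic two-domain Calpha structures with planted rigid motions.

These generators produce exactly the statistical structure the analysis
pipeline assumes — two rigid bodies related by a known screw motion across
two conformations, with optional isotropic Gaussian coordinate noise — so
every estimator (domain partition, screw angle and axis, elastic-network
hinge axis) can be tested against planted ground truth without any
structure downloads.

The bodies are packed random point clouds ("blobs"), not polymer chains:
the superposition, domain-decomposition and elastic-network analyses
depend only on point geometry.  The default two-domain placement stacks
the blobs along the planted axis with a narrow seam between them, so the
axis crosses the domain boundary and runs through both bodies — the
geometry of the capping protein's inter-domain twist axis.  The softest
internal mode of the resulting elastic network is the relative torsion of
the blobs about that axis (tangential sliding at the seam costs far less
spring energy than prying it open), and the residues that barely move in
the mode form a column along the axis — which is what makes planted-axis
recovery through the mode-analysis path a meaningful test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .domains import DomainPartition
from .structure_io import CaModel, ResidueKey

#: Calpha-like minimum point spacing, Angstrom
DEFAULT_MIN_SPACING = 3.6
#: seam gap between the two blobs, Angstrom (well inside the default
#: elastic-network cutoff so the assembly is one connected network)
SEAM_GAP = 4.0


class DensityError(RuntimeError):
    """Rejection sampling could not place all points at the requested
    spacing within the attempt budget."""


@dataclass
class PlantedMotion:
    """Ground truth for a generated two-conformation pair."""

    angle: float  # degrees, [0, 180]
    axis_direction: np.ndarray = None  # unit 3-vector; default +x
    axis_point: np.ndarray = None  # 3-vector, Angstrom; default origin
    noise_sigma: float = 0.0  # Angstrom, per coordinate
    seed: int = 0
    partition: DomainPartition | None = None  # filled by the generator

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle <= 180.0:
            raise ValueError("angle must be in [0, 180] degrees")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.axis_direction is None:
            self.axis_direction = np.array([1.0, 0.0, 0.0])
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        norm = np.linalg.norm(self.axis_direction)
        if norm < 1e-12:
            raise ValueError("axis_direction must be non-zero")
        self.axis_direction = self.axis_direction / norm
        if self.axis_point is None:
            self.axis_point = np.zeros(3)
        self.axis_point = np.asarray(self.axis_point, dtype=float)


def generate_rigid_blob(
    n: int,
    seed: int,
    min_spacing: float = DEFAULT_MIN_SPACING,
    chain_id: str = "A",
    name: str = "blob",
) -> CaModel:
    """Packed Gaussian point cloud with pairwise spacing >= min_spacing.

    Points are rejection-sampled from an isotropic Gaussian whose width
    scales as n^(1/3) so the packing stays feasible at any size; residues
    are numbered sequentially from 1 on a single chain.  Deterministic per
    seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    # width set by protein-like packing (~1 residue per 120 A^3 at the
    # default 3.6 A spacing); candidates beyond 1.5 sigma are rejected so
    # the cloud has no sparse tail that would disconnect the elastic
    # network at typical cutoffs
    per_point_volume = 120.0 * (min_spacing / 3.6) ** 3
    radius = (3.0 * max(n, 2) * per_point_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    sigma = radius / 1.5
    pts: list[np.ndarray] = []
    budget = 2000 * n
    while len(pts) < n:
        if budget <= 0:
            raise DensityError(
                f"could not pack {n} points at spacing {min_spacing}"
            )
        budget -= 1
        cand = rng.normal(scale=sigma, size=3)
        if np.linalg.norm(cand) > radius:
            continue
        if all(np.linalg.norm(cand - p) >= min_spacing for p in pts):
            pts.append(cand)
    coords = np.array(pts).reshape(n, 3)
    residues = [
        ResidueKey(chain_id=chain_id, residue_number=i + 1, residue_name="ALA")
        for i in range(n)
    ]
    return CaModel(name=name, residues=residues, coords=coords)


def _rotate_about(coords: np.ndarray, angle_deg: float,
                  axis: np.ndarray, point: np.ndarray) -> np.ndarray:
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
    return (coords - point) @ R.T + point


def generate_two_domain_pair(
    n1: int,
    n2: int,
    motion: PlantedMotion,
    min_spacing: float = DEFAULT_MIN_SPACING,
) -> tuple[CaModel, CaModel, PlantedMotion]:
    """Two conformations of a two-blob assembly with a planted screw.

    Conformation A stacks blob 1 (chain A, n1 residues) and blob 2
    (chain B, n2 residues) along the planted axis with a ~4 Angstrom seam
    between them; the axis passes through ``motion.axis_point`` and
    through both bodies.  Conformation B equals A with chain B rotated by
    ``motion.angle`` about the planted axis; independent
    Gaussian noise of width ``motion.noise_sigma`` is then added to every
    coordinate of both conformations.  Returns (A, B, motion) with
    ``motion.partition`` set to the generating two-domain partition.
    """
    if n1 < 10 or n2 < 10:
        raise ValueError("need n1, n2 >= 10")
    ss = np.random.SeedSequence(motion.seed)
    s1, s2, s3 = (int(s) for s in ss.generate_state(3))
    blob1 = generate_rigid_blob(n1, s1, min_spacing, chain_id="A")
    blob2 = generate_rigid_blob(n2, s2, min_spacing, chain_id="B")

    # build in a local frame with the blobs stacked along +x (the twist
    # axis passes through both bodies and crosses the seam, as the
    # capping protein's inter-domain axis crosses the domain boundary),
    # then map the local x-axis onto the requested planted axis
    c1 = blob1.coords - blob1.coords.mean(axis=0)
    c2 = blob2.coords - blob2.coords.mean(axis=0)
    c1[:, 0] -= c1[:, 0].max() + SEAM_GAP / 2.0  # blob 1 below the seam
    c2[:, 0] -= c2[:, 0].min() - SEAM_GAP / 2.0  # blob 2 above the seam

    frame = _frame_from_axis(motion.axis_direction)
    c1 = c1 @ frame.T + motion.axis_point
    c2 = c2 @ frame.T + motion.axis_point

    residues = blob1.residues + blob2.residues
    coords_a = np.vstack([c1, c2])
    model_a = CaModel(name="synthA", residues=list(residues), coords=coords_a)

    c2_rot = _rotate_about(c2, motion.angle, motion.axis_direction,
                           motion.axis_point)
    coords_b = np.vstack([c1, c2_rot])

    if motion.noise_sigma > 0:
        noise_rng = np.random.default_rng(s3)
        coords_a = coords_a + noise_rng.normal(
            scale=motion.noise_sigma, size=coords_a.shape)
        coords_b = coords_b + noise_rng.normal(
            scale=motion.noise_sigma, size=coords_b.shape)
        model_a = CaModel(name="synthA", residues=list(residues),
                          coords=coords_a)
    model_b = CaModel(name="synthB", residues=list(residues), coords=coords_b)

    partition = DomainPartition(
        domains=[frozenset(blob1.residues), frozenset(blob2.residues)],
        method_metadata={"source": "planted"},
    )
    return model_a, model_b, replace(motion, partition=partition)


def _frame_from_axis(axis: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame whose first column is ``axis``."""
    x = axis / np.linalg.norm(axis)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(x @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    y = np.cross(helper, x)
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    return np.column_stack([x, y, z])


def generate_dimer_model(
    n_per_chain: int,
    seed: int,
    min_spacing: float = DEFAULT_MIN_SPACING,
) -> CaModel:
    """One two-chain model: two adjacent blobs labelled A and B forming a
    single connected elastic network at the default cutoff — the topology
    of a heterodimer, for chain-composition reporting tests."""
    if n_per_chain < 10:
        raise ValueError("need n_per_chain >= 10")
    model_a, _, _ = generate_two_domain_pair(
        n_per_chain, n_per_chain,
        PlantedMotion(angle=0.0, seed=seed),
        min_spacing=min_spacing,
    )
    return CaModel(name="dimer", residues=model_a.residues,
                   coords=model_a.coords)
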