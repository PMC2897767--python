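"""Elastic-network (anisotropic, Calpha) normal modes and rotation-axis
extraction from low-displacement residues.

The protein is a bead-spring network: every Calpha pair closer than a
cutoff R_c in the native structure is joined by a Hookean spring of uniform
stiffness C, giving the potential

    E = (C/2) * sum_edges (|r_ij| - |r0_ij|)^2 .

Diagonalising the 3N x 3N Hessian of E at the native structure yields the
normal modes; a connected network has exactly six zero modes (rigid-body
translations/rotations), and the lowest non-rigid mode describes the
softest intrinsic motion.  For hinge/twist proteins that motion is a
rotation, and its axis can be read off geometrically: residues that barely
move in the mode lie along the rotation axis, so collecting residues whose
squared displacement falls below a threshold, splitting them into spatial
groups, and taking each group's first principal component recovers the
axis (or axes) of the intrinsic rotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .structure_io import CaModel, ResidueKey

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 12.0  # Angstrom
DEFAULT_LINK_DISTANCE = 8.0  # Angstrom, spatial grouping of anchor residues


class NotPositiveSemidefiniteError(ValueError):
    """A significantly negative eigenvalue: the Hessian is wrong."""


class InsufficientAnchorError(ValueError):
    """Fewer than 3 residues below the displacement threshold."""


@dataclass
class ElasticNetwork:
    """Bead-spring network on a Calpha model."""

    model: CaModel
    cutoff: float
    spring_constant: float
    edges: np.ndarray  # (E, 2) int, i < j
    connected: bool

    @property
    def n_atoms(self) -> int:
        return len(self.model)


@dataclass
class ModeSet:
    """Full normal-mode spectrum, ascending; rigid-body modes flagged."""

    eigenvalues: np.ndarray  # (3N,), ascending
    eigenvectors: np.ndarray  # (3N, 3N), columns orthonormal
    n_rigid: int
    spring_constant: float = 1.0

    @property
    def lowest_internal_index(self) -> int:
        return self.n_rigid

    @property
    def n_atoms(self) -> int:
        return self.eigenvalues.size // 3


@dataclass
class DisplacementField:
    """Per-residue displacement of one mode, scaled by 1/eigenvalue."""

    vectors: np.ndarray  # (N, 3)
    squared_magnitudes: np.ndarray  # (N,), squared displacement per residue
    mode_index: int
    eigenvalue: float


@dataclass
class AxisGroup:
    """One spatial group of low-displacement residues and its PCA axis."""

    residue_keys: list[ResidueKey]
    centroid: np.ndarray  # (3,)
    axis_direction: np.ndarray  # (3,), unit
    variance_explained: float
    chain_composition: dict[str, int] = field(default_factory=dict)


@dataclass
class RotationAxisResult:
    groups: list[AxisGroup]
    threshold_used: float


# ---------------------------------------------------------------------------


def build_network(
    model: CaModel,
    cutoff: float = DEFAULT_CUTOFF,
    spring_constant: float = 1.0,
) -> ElasticNetwork:
    """Connect all Calpha pairs with native distance < cutoff.

    A disconnected network is permitted (modes remain computable) but is
    flagged and warned about: each extra component adds six more zero
    modes.
    """
    n = len(model)
    if n < 3:
        raise ValueError("need at least 3 atoms")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dists = squareform(pdist(model.coords))
    iu, ju = np.triu_indices(n, k=1)
    hit = dists[iu, ju] < cutoff
    edges = np.column_stack([iu[hit], ju[hit]])
    adj = np.zeros((n, n), dtype=bool)
    adj[edges[:, 0], edges[:, 1]] = True
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        logger.warning(
            "%s: elastic network has %d components at cutoff %.1f A",
            model.name, n_comp, cutoff,
        )
    return ElasticNetwork(
        model=model, cutoff=cutoff, spring_constant=spring_constant,
        edges=edges, connected=(n_comp == 1),
    )


def build_hessian(network: ElasticNetwork) -> np.ndarray:
    """3N x 3N Hessian of the network energy at the native structure.

    For each spring (i, j) with native unit vector u, the off-diagonal
    3x3 block is -C u u^T and the diagonal blocks accumulate +C u u^T:
    the standard anisotropic-network Hessian, symmetric and positive
    semi-definite.
    """
    coords = network.model.coords
    n = network.n_atoms
    C = network.spring_constant
    H = np.zeros((3 * n, 3 * n))
    for i, j in network.edges:
        rij = coords[j] - coords[i]
        dist = np.linalg.norm(rij)
        if dist < 1e-6:
            raise ValueError(
                f"atoms {i} and {j} are coincident; Hessian undefined"
            )
        u = rij / dist
        block = C * np.outer(u, u)
        sl_i = slice(3 * i, 3 * i + 3)
        sl_j = slice(3 * j, 3 * j + 3)
        H[sl_i, sl_i] += block
        H[sl_j, sl_j] += block
        H[sl_i, sl_j] -= block
        H[sl_j, sl_i] -= block
    return H


def network_energy(network: ElasticNetwork, coords: np.ndarray) -> float:
    """E = (C/2) sum_edges (|r_ij| - |r0_ij|)^2 at arbitrary coordinates."""
    ref = network.model.coords
    coords = np.asarray(coords, dtype=float).reshape(ref.shape)
    i, j = network.edges[:, 0], network.edges[:, 1]
    d = np.linalg.norm(coords[j] - coords[i], axis=1)
    d0 = np.linalg.norm(ref[j] - ref[i], axis=1)
    return float(0.5 * network.spring_constant * np.sum((d - d0) ** 2))


def solve_modes(
    hessian: np.ndarray,
    zero_tolerance: float = 1e-8,
    spring_constant: float = 1.0,
) -> ModeSet:
    """Diagonalise the Hessian; flag near-zero (rigid-body) modes.

    Eigenvalues below ``zero_tolerance * lambda_max`` are rigid; a
    connected non-degenerate 3D network yields exactly six.  A
    significantly negative eigenvalue signals a broken Hessian and raises.
    """
    H = np.asarray(hessian, dtype=float)
    if not np.allclose(H, H.T, atol=1e-10):
        raise ValueError("Hessian must be symmetric")
    evals, evecs = scipy.linalg.eigh(H)
    lam_max = float(evals[-1]) if evals.size else 0.0
    tol = zero_tolerance * max(lam_max, 1.0e-300)
    if evals[0] < -tol:
        raise NotPositiveSemidefiniteError(
            f"eigenvalue {evals[0]:.3e} < -{tol:.3e}"
        )
    n_rigid = int(np.sum(np.abs(evals) < tol))
    return ModeSet(
        eigenvalues=evals, eigenvectors=evecs, n_rigid=n_rigid,
        spring_constant=spring_constant,
    )


def mode_displacements(modes: ModeSet, mode_index: int) -> DisplacementField:
    """Displacement field of one internal mode: eigenvector / eigenvalue.

    Scaling by the reciprocal eigenvalue makes soft modes large, mirroring
    the thermal amplitude ordering; rigid modes would divide by ~0 and are
    rejected.
    """
    if mode_index < modes.n_rigid:
        raise ValueError(
            f"mode {mode_index} is a rigid-body mode "
            f"(first internal mode is {modes.n_rigid})"
        )
    lam = float(modes.eigenvalues[mode_index])
    vec = modes.eigenvectors[:, mode_index].reshape(-1, 3) / lam
    return DisplacementField(
        vectors=vec,
        squared_magnitudes=np.sum(vec**2, axis=1),
        mode_index=mode_index,
        eigenvalue=lam,
    )


def extract_rotation_axes(
    model: CaModel,
    displacement_field: DisplacementField,
    threshold: float = 2.0,
    threshold_mode: str = "absolute",
    quantile: float = 0.15,
    link_distance: float = DEFAULT_LINK_DISTANCE,
    min_group_size: int = 3,
) -> RotationAxisResult:
    """Rotation axes of a mode from its low-displacement residues.

    Residues whose squared displacement is below ``threshold`` (or, with
    ``threshold_mode="quantile"``, below the ``quantile`` fraction of the
    displacement distribution — a scale-free alternative, since absolute
    displacement units depend on the spring constant) are collected,
    single-linkage clustered in space at ``link_distance``, and each group
    of at least ``min_group_size`` residues contributes one axis: the first
    principal component of its member coordinates, anchored at the group
    centroid.  Chain composition per group is reported so the caller can
    check whether groups segregate by subunit.
    """
    sq = displacement_field.squared_magnitudes
    if threshold_mode == "quantile":
        if not 0.0 < quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")
        threshold = float(np.quantile(sq, quantile))
    elif threshold_mode != "absolute":
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    anchor = sq < threshold
    if anchor.sum() < min_group_size:
        raise InsufficientAnchorError(
            f"only {int(anchor.sum())} residues below threshold "
            f"{threshold:.3g} A^2"
        )
    idx = np.flatnonzero(anchor)
    coords = model.coords[idx]
    if len(idx) == 1:
        labels = np.array([1])
    else:
        tree = linkage(pdist(coords), method="single")
        labels = fcluster(tree, t=link_distance, criterion="distance")

    groups: list[AxisGroup] = []
    for lab in np.unique(labels):
        members = idx[labels == lab]
        if len(members) < min_group_size:
            continue
        pts = model.coords[members]
        centroid = pts.mean(axis=0)
        # first principal component of member coordinates = axis direction
        _, svals, vt = np.linalg.svd(pts - centroid, full_matrices=False)
        axis = vt[0]
        # deterministic sign: largest-magnitude component positive
        if axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
        total = float(np.sum(svals**2))
        groups.append(AxisGroup(
            residue_keys=[model.residues[i] for i in members],
            centroid=centroid,
            axis_direction=axis,
            variance_explained=float(svals[0] ** 2 / total) if total else 1.0,
            chain_composition=_chain_counts(model, members),
        ))
    if not groups:
        raise InsufficientAnchorError(
            f"no spatial group of >= {min_group_size} anchor residues"
        )
    groups.sort(key=lambda g: -len(g.residue_keys))
    return RotationAxisResult(groups=groups, threshold_used=float(threshold))


def _chain_counts(model: CaModel, indices: np.ndarray) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in indices:
        chain = model.residues[i].chain_id
        counts[chain] = counts.get(chain, 0) + 1
    return counts


def axis_angle_between(a: np.ndarray, b: np.ndarray) -> float:
    """Acute angle between two undirected axes, degrees in [0, 90]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero-length axis")
    cosang = abs(float(a @ b)) / (na * nb)
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
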