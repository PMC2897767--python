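"""Rigid-domain decomposition of a conformational change and its screw axis.

Given two conformations of the same molecule, residues are partitioned into
k rigid domains using the difference distance matrix (residue pairs whose
internal distance is conserved belong to the same rigid body), and the
relative motion of one domain against another is reduced to its Chasles
screw: a rotation angle about an axis plus a translation along it.  For the
actin capping protein this is the machinery that turns "the two crystal
forms differ" into "the small domain twists ~10 degrees about an axis along
the beta-subunit".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .structure_io import CaModel, PairedCoords, ResidueKey, Selection, pair_models
from .superpose import DegenerateFitError, RigidTransform, kabsch_fit

logger = logging.getLogger(__name__)

#: below this rotation angle the screw axis direction is numerically
#: meaningless and is reported as undefined
MIN_DEFINED_ANGLE_DEG = 0.1


class DegenerateDomainError(ValueError):
    """Refinement drove a domain below 3 residues (or collinear)."""


@dataclass
class DomainPartition:
    """Disjoint residue-key sets covering the paired residues, k domains.

    Domains are ordered by decreasing size, so index 0 is the larger
    ("CP-L-like") domain and index 1 the smaller.
    """

    domains: list[frozenset[ResidueKey]]
    method_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.domains = [frozenset(d) for d in self.domains]
        all_keys = [k for d in self.domains for k in d]
        if len(all_keys) != len(set(all_keys)):
            raise ValueError("domains are not disjoint")
        if any(len(d) < 3 for d in self.domains):
            raise DegenerateDomainError(
                f"domain sizes {[len(d) for d in self.domains]}: all must be >= 3"
            )

    @property
    def k(self) -> int:
        return len(self.domains)

    def labels(self, keys: list[ResidueKey]) -> np.ndarray:
        """Domain index per key (-1 for keys outside every domain)."""
        out = np.full(len(keys), -1, dtype=int)
        for d, members in enumerate(self.domains):
            for i, key in enumerate(keys):
                if key in members:
                    out[i] = d
        return out

    @classmethod
    def from_selections(
        cls, keys: list[ResidueKey], selections: list[Selection]
    ) -> "DomainPartition":
        """Build a partition from residue-range selections (e.g. published
        domain boundaries), restricted to ``keys``; keys matching no
        selection are dropped from the partition."""
        domains = []
        for sel in selections:
            domains.append(frozenset(k for k in keys if sel.contains(k)))
        return cls(domains=list(domains), method_metadata={"source": "selections"})


def partition_agreement(
    a: DomainPartition, b: DomainPartition, keys: list[ResidueKey]
) -> float:
    """Fraction of ``keys`` on which two partitions agree, maximised over
    relabelling of ``b``'s domains (domain identity is nominal)."""
    from itertools import permutations

    la = a.labels(keys)
    lb = b.labels(keys)
    best = 0.0
    for perm in permutations(range(b.k)):
        relabel = np.array(perm)
        agree = np.mean((la >= 0) & (lb >= 0) & (la == relabel[lb]))
        best = max(best, float(agree))
    return best


@dataclass
class ScrewMotion:
    """Chasles decomposition of a rigid transform.

    ``angle`` in [0, 180] degrees; ``axis_direction`` is the unit rotation
    axis (None when the rotation is too small to define one);
    ``axis_point`` is a point on the axis; ``parallel_translation`` is the
    slide along the axis in Angstrom.
    """

    angle: float
    axis_direction: np.ndarray | None
    axis_point: np.ndarray | None
    parallel_translation: float

    @property
    def axis_defined(self) -> bool:
        return self.axis_direction is not None

    def to_transform(self) -> RigidTransform:
        """Reconstruct the rigid transform this screw describes."""
        if not self.axis_defined:
            return RigidTransform.identity()
        n = np.asarray(self.axis_direction, dtype=float)
        p = np.asarray(self.axis_point, dtype=float)
        R = Rotation.from_rotvec(np.radians(self.angle) * n).as_matrix()
        t = (np.eye(3) - R) @ p + self.parallel_translation * n
        return RigidTransform(rotation=R, translation=t)


def screw_from_transform(
    transform: RigidTransform, near_point: np.ndarray | None = None
) -> ScrewMotion:
    """Decompose a rigid transform into its screw parameters.

    The rotation angle/axis come from the matrix's rotation vector; the
    axis anchor point is the least-norm solution of (I - R) p = t_perp,
    then slid along the axis to the closest point to ``near_point`` (for
    reportability next to the moving body) when one is given.
    """
    rotvec = Rotation.from_matrix(transform.rotation).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    t = transform.translation
    if angle < MIN_DEFINED_ANGLE_DEG:
        return ScrewMotion(
            angle=angle,
            axis_direction=None,
            axis_point=None,
            parallel_translation=float(np.linalg.norm(t)),
        )
    n = rotvec / np.linalg.norm(rotvec)
    d_par = float(n @ t)
    t_perp = t - d_par * n
    # (I - R) annihilates n; pinv gives the least-norm (perpendicular) anchor
    p0 = np.linalg.pinv(np.eye(3) - transform.rotation) @ t_perp
    if near_point is not None:
        p0 = p0 + ((np.asarray(near_point) - p0) @ n) * n
    return ScrewMotion(
        angle=angle, axis_direction=n, axis_point=p0,
        parallel_translation=d_par,
    )


# ---------------------------------------------------------------------------
# difference distance matrix and domain decomposition


def difference_distance_matrix(pair: PairedCoords) -> np.ndarray:
    """| d_ij(A) - d_ij(B) | for all residue pairs; rigid regions show
    near-zero blocks because rigid motions preserve internal distances."""
    if len(pair) < 2:
        raise ValueError("need at least 2 paired residues")
    da = np.linalg.norm(pair.coords_a[:, None] - pair.coords_a[None, :], axis=-1)
    db = np.linalg.norm(pair.coords_b[:, None] - pair.coords_b[None, :], axis=-1)
    return np.abs(da - db)


def decompose_rigid_domains(
    pair: PairedCoords,
    k: int = 2,
    max_iterations: int = 50,
    linkage_method: str = "average",
) -> DomainPartition:
    """Partition paired residues into ``k`` rigid domains.

    Average-linkage agglomerative clustering on the difference distance
    matrix seeds the partition; iterative refinement then superposes each
    domain separately and reassigns every residue to the domain whose fit
    leaves it the smallest deviation, until the assignment is stable.  Ties
    keep the current assignment, making the procedure deterministic.
    """
    m = len(pair)
    if m < 3 * 2 * k:
        raise ValueError(f"{m} pairs is too few for k={k} domains")
    ddm = difference_distance_matrix(pair)
    labels = _initial_labels(ddm, k, linkage_method)

    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        devs = np.full((k, m), np.inf)
        for d in range(k):
            mask = labels == d
            if mask.sum() < 3:
                raise DegenerateDomainError(
                    f"domain {d} shrank to {int(mask.sum())} residues"
                )
            sub = PairedCoords(
                keys=[key for key, hit in zip(pair.keys, mask) if hit],
                coords_a=pair.coords_a[mask],
                coords_b=pair.coords_b[mask],
            )
            try:
                result = kabsch_fit(sub)
            except DegenerateFitError as exc:
                raise DegenerateDomainError(f"domain {d}: {exc}") from exc
            moved = result.transform.apply(pair.coords_b)
            devs[d] = np.linalg.norm(pair.coords_a - moved, axis=1)
        # strict improvement only: ties keep the current assignment
        best = np.argmin(devs, axis=0)
        current = devs[labels, np.arange(m)]
        improved = devs[best, np.arange(m)] < current - 1e-12
        new_labels = np.where(improved, best, labels)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels

    order = np.argsort([-(labels == d).sum() for d in range(k)], kind="stable")
    domains = [
        frozenset(key for key, lab in zip(pair.keys, labels) if lab == d)
        for d in order
    ]
    logger.info(
        "domain decomposition: sizes %s after %d refinement iterations",
        [len(d) for d in domains], n_iter,
    )
    return DomainPartition(
        domains=domains,
        method_metadata={
            "linkage": linkage_method,
            "refinement_iterations": n_iter,
            "k": k,
        },
    )


def _initial_labels(ddm: np.ndarray, k: int, linkage_method: str) -> np.ndarray:
    """Seed labels from hierarchical clustering of the dissimilarity matrix.

    Coordinate noise can make the k-cluster cut isolate a couple of
    outlier residues as their own "domain"; in that case the tree is cut
    deeper until k clusters of at least 3 residues exist, the k largest
    are kept, and every remaining residue joins the kept cluster with the
    smallest mean dissimilarity.  Deterministic throughout.
    """
    m = ddm.shape[0]
    tree = linkage(squareform(ddm, checks=False), method=linkage_method)
    for n_cut in range(k, min(k + 20, m)):
        raw = fcluster(tree, t=n_cut, criterion="maxclust") - 1
        ids, sizes = np.unique(raw, return_counts=True)
        big = ids[sizes >= 3]
        if len(big) >= k:
            keep = big[np.argsort(-sizes[sizes >= 3], kind="stable")[:k]]
            labels = np.full(m, -1, dtype=int)
            for new, old in enumerate(keep):
                labels[raw == old] = new
            for i in np.flatnonzero(labels == -1):
                mean_diss = [ddm[i, labels == d].mean() for d in range(k)]
                labels[i] = int(np.argmin(mean_diss))
            return labels
    raise DegenerateDomainError(
        f"could not seed {k} domains of >= 3 residues from the "
        "difference distance matrix"
    )


def interdomain_screw(
    pair: PairedCoords,
    partition: DomainPartition,
    reference_domain: int = 0,
    moving_domain: int = 1,
) -> ScrewMotion:
    """Screw motion of one domain relative to another between conformations.

    The structures are superposed on the reference domain; the residual
    rigid transform that carries the moving domain of A onto the moving
    domain of (superposed) B is then decomposed into rotation angle, axis
    and parallel translation.  The axis anchor point is reported nearest
    the moving domain's centroid.
    """
    keys = pair.keys
    ref_mask = np.array([k in partition.domains[reference_domain] for k in keys])
    mov_mask = np.array([k in partition.domains[moving_domain] for k in keys])
    if ref_mask.sum() < 3 or mov_mask.sum() < 3:
        raise DegenerateDomainError("reference/moving domain below 3 residues")

    ref_fit = kabsch_fit(_subpair(pair, ref_mask))
    b_on_a = ref_fit.transform.apply(pair.coords_b)

    mov_sub = PairedCoords(
        keys=[k for k, hit in zip(keys, mov_mask) if hit],
        coords_a=b_on_a[mov_mask],  # target: B's moving domain in A's frame
        coords_b=pair.coords_a[mov_mask],  # carried: A's moving domain
    )
    residual = kabsch_fit(mov_sub).transform
    centroid = pair.coords_a[mov_mask].mean(axis=0)
    return screw_from_transform(residual, near_point=centroid)


def rmsd_matrix(
    models: list[CaModel], selection: Selection | None = None
) -> np.ndarray:
    """Symmetric matrix of pairwise superposition RMSDs (Angstrom)."""
    n = len(models)
    if n < 2:
        raise ValueError("need at least 2 models")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                pr = pair_models(models[i], models[j], selection)
                out[i, j] = out[j, i] = kabsch_fit(pr).rmsd
            except (ValueError, DegenerateFitError) as exc:
                raise type(exc)(
                    f"pair ({models[i].name}, {models[j].name}): {exc}"
                ) from exc
    return out


def _subpair(pair: PairedCoords, mask: np.ndarray) -> PairedCoords:
    return PairedCoords(
        keys=[k for k, hit in zip(pair.keys, mask) if hit],
        coords_a=pair.coords_a[mask],
        coords_b=pair.coords_b[mask],
    )
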