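"""Least-squares rigid superposition, RMSD, and small geometry utilities.

The optimal rotation is obtained by the Kabsch procedure: SVD of the
cross-covariance of the centred point sets with a determinant-sign guard so
the result is always a proper rotation (no reflection).  Fitting and
measuring are decoupled: one may fit on one residue set and report
deviations over another — the standard way to visualise which parts of a
structure move after anchoring on a rigid core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import CaModel, PairedCoords, ResidueKey, Selection


class DegenerateFitError(ValueError):
    """Fewer than 3 pairs, or a collinear fit set: rotation underdetermined."""


@dataclass
class RigidTransform:
    """x -> rotation @ x + translation, Angstrom."""

    rotation: np.ndarray  # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthogonal (max dev {err:.2e})")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation has det != +1 (improper)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            rotation=self.rotation.T,
            translation=-self.rotation.T @ self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclass
class SuperpositionResult:
    """Outcome of one superposition.

    ``transform`` maps model B onto model A.  ``rmsd`` and
    ``per_residue_deviation`` are reported over all ``n_pairs`` pairs even
    when the fit used a subset.
    """

    transform: RigidTransform
    rmsd: float
    n_pairs: int
    per_residue_deviation: np.ndarray  # (M,), Angstrom
    fit_rmsd: float  # RMSD over the fit subset itself


def _kabsch(ref: np.ndarray, mov: np.ndarray) -> RigidTransform:
    """Proper rotation + translation minimising ||ref - (R mov + t)||^2."""
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    H = (mov - mov_c).T @ (ref - ref_c)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(rotation=R, translation=ref_c - R @ mov_c)


def kabsch_fit(
    pair: PairedCoords, fit_selection: Selection | None = None
) -> SuperpositionResult:
    """Superpose B onto A, fitting on ``fit_selection`` (default: all pairs).

    Deviations and the headline RMSD cover *all* pairs after the transform,
    so the caller can anchor on a rigid region and read off how far the
    rest moves.
    """
    mask = pair.subset_mask(fit_selection)
    m = int(mask.sum())
    if m < 3:
        raise DegenerateFitError(f"only {m} pairs in fit set (need >= 3)")
    a_fit = pair.coords_a[mask]
    b_fit = pair.coords_b[mask]
    # collinearity: rank of the centred fit set must be >= 2
    if np.linalg.matrix_rank(a_fit - a_fit.mean(axis=0), tol=1e-8) < 2:
        raise DegenerateFitError("fit set is collinear")
    transform = _kabsch(a_fit, b_fit)
    moved = transform.apply(pair.coords_b)
    dev = np.linalg.norm(pair.coords_a - moved, axis=1)
    return SuperpositionResult(
        transform=transform,
        rmsd=float(np.sqrt(np.mean(dev**2))),
        n_pairs=len(pair),
        per_residue_deviation=dev,
        fit_rmsd=float(np.sqrt(np.mean(dev[mask] ** 2))),
    )


def rmsd_after(transform: RigidTransform, pair: PairedCoords) -> float:
    """RMSD of transformed B vs A under a fixed transform (no re-fitting)."""
    diff = pair.coords_a - transform.apply(pair.coords_b)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def steric_contact_count(a: CaModel, b: CaModel, cutoff: float) -> int:
    """Number of inter-model Calpha pairs closer than ``cutoff`` Angstrom.

    A crude but monotone surrogate for steric overlap between two rigid
    bodies (e.g. an inhibitor held against a filament model): zero means no
    clash at that radius.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree = cKDTree(b.coords)
    return int(sum(len(hits) for hits in
                   tree.query_ball_point(a.coords, cutoff - 1e-12)))


def bend_angle(model: CaModel, pivot: ResidueKey, n_flank: int = 5) -> float:
    """Bend at a pivot residue, degrees in [0, 180].

    The angle at the pivot Calpha between the centroid of the ``n_flank``
    preceding residues and the centroid of the ``n_flank`` following
    residues, all within the pivot's chain.  180 deg is straight; an
    elongated peptide kinked at a central proline shows up as a sharp
    intermediate value.
    """
    chain = [i for i, k in enumerate(model.residues)
             if k.chain_id == pivot.chain_id]
    try:
        pos = chain.index(model.index_of(pivot))
    except ValueError as exc:
        raise KeyError(f"pivot {pivot} not in model") from exc
    if pos < n_flank or pos + n_flank >= len(chain):
        raise ValueError(
            f"need {n_flank} residues on each side of {pivot}; have "
            f"{pos} before and {len(chain) - pos - 1} after"
        )
    idx = model.coords[chain]
    center = idx[pos]
    u = idx[pos - n_flank : pos].mean(axis=0) - center
    v = idx[pos + 1 : pos + 1 + n_flank].mean(axis=0) - center
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
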