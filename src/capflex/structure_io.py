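"""Calpha-only structure models, residue selections and residue pairing.

All downstream analyses (superposition, domain decomposition, elastic
network modes) operate on the alpha-carbon trace only, addressed by author
residue numbering exactly as deposited — no renumbering is ever applied,
so residues can be cited the way crystallographers cite them (e.g. the
capping-protein "basic triad" alpha-Lys256/Arg260/Arg266).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)


class StructureFormatError(ValueError):
    """The source could not be parsed in the requested dialect."""


class EmptyModelError(ValueError):
    """No Calpha atoms survived parsing/selection/pairing."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue: chain, author number, insertion code, name.

    ``residue_name`` is carried for reporting but deliberately excluded from
    equality/hashing — two crystal forms of the same protein pair by
    (chain, number, icode) even if one file records a modified residue name.
    """

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    residue_name: str = field(default="", compare=False)

    def __str__(self) -> str:  # e.g. "A:266" or "B:52A"
        return f"{self.chain_id}:{self.residue_number}{self.insertion_code}"


@dataclass
class CaModel:
    """Ordered Calpha coarse model: one residue key per coordinate row (A)."""

    name: str
    residues: list[ResidueKey]
    coords: np.ndarray  # (N, 3) float64, Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.residues) != self.coords.shape[0]:
            raise ValueError(
                f"{len(self.residues)} residues vs {self.coords.shape[0]} "
                "coordinate rows"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("duplicate residue keys in model")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain labels in order of first appearance."""
        seen: dict[str, None] = {}
        for key in self.residues:
            seen.setdefault(key.chain_id, None)
        return list(seen)

    def index_of(self, key: ResidueKey) -> int:
        return self.residues.index(key)


@dataclass
class Selection:
    """Chain-scoped inclusive residue ranges, author numbering.

    ``ranges`` entries are (chain_id, start, end) with start <= end, both
    inclusive. Selecting residues that are absent from a model is allowed
    (crystal forms differ in what is resolved); it simply matches nothing.
    """

    ranges: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chain, start, end in self.ranges:
            if start > end:
                raise ValueError(f"range {chain}:{start}-{end} has start > end")

    def contains(self, key: ResidueKey) -> bool:
        return any(
            key.chain_id == chain and start <= key.residue_number <= end
            for chain, start, end in self.ranges
        )

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse ``CHAIN:START-END[,CHAIN:START-END...]``.

        A bare ``CHAIN:N`` selects the single residue N.  Negative residue
        numbers (legal in PDB author numbering) are supported:
        ``A:-2-10`` runs from -2 to 10.
        """
        ranges = []
        for part in text.split(","):
            part = part.strip()
            if not part:
                continue
            chain, _, span = part.partition(":")
            if not chain or not span:
                raise ValueError(f"cannot parse selection component {part!r}")
            # split on the last '-' that is not a leading sign
            lo, hi = _parse_span(span)
            ranges.append((chain, lo, hi))
        return cls(ranges)

    def __str__(self) -> str:
        return ",".join(
            f"{c}:{a}-{b}" if a != b else f"{c}:{a}" for c, a, b in self.ranges
        )


def _parse_span(span: str) -> tuple[int, int]:
    for i in range(len(span) - 1, 0, -1):
        if span[i] == "-" and span[i - 1].isdigit():
            return int(span[:i]), int(span[i + 1 :])
    return int(span), int(span)


@dataclass
class PairedCoords:
    """Row-aligned coordinates of the residues two models share."""

    keys: list[ResidueKey]
    coords_a: np.ndarray  # (M, 3)
    coords_b: np.ndarray  # (M, 3)

    def __post_init__(self) -> None:
        self.coords_a = np.asarray(self.coords_a, dtype=float).reshape(-1, 3)
        self.coords_b = np.asarray(self.coords_b, dtype=float).reshape(-1, 3)
        if not (len(self.keys) == len(self.coords_a) == len(self.coords_b)):
            raise ValueError("keys and coordinate arrays disagree in length")

    def __len__(self) -> int:
        return len(self.keys)

    def subset_mask(self, selection: Selection | None) -> np.ndarray:
        """Boolean mask of rows whose key falls in ``selection`` (all if None)."""
        if selection is None:
            return np.ones(len(self.keys), dtype=bool)
        return np.array([selection.contains(k) for k in self.keys], dtype=bool)


# ---------------------------------------------------------------------------
# reading


def read_ca_model(
    path_or_text: str | Path,
    dialect: str | None = None,
    name: str | None = None,
) -> CaModel:
    """Read a structure file (PDB or mmCIF) into a Calpha-only model.

    One entry per residue bearing a CA atom; HETATM records and waters are
    excluded.  Alternate locations resolve to the highest-occupancy
    conformer (first in file order on a tie).  Multi-model files use the
    first model, with a warning.  ``dialect`` may be ``"pdb"`` or
    ``"mmcif"``; by default it is inferred from the file suffix/content.
    """
    text: str | None = None
    raw = str(path_or_text)
    if isinstance(path_or_text, Path) or ("\n" not in raw and len(raw) < 4096):
        path = Path(path_or_text)
        source_name = path.stem
    else:
        text = raw
        source_name = "structure"
        path = None

    try:
        if path is not None:
            if dialect == "pdb":
                structure = gemmi.read_pdb(str(path))
            elif dialect == "mmcif":
                structure = gemmi.make_structure_from_block(
                    gemmi.cif.read(str(path)).sole_block()
                )
            else:
                structure = gemmi.read_structure(str(path))
        else:
            if dialect == "mmcif":
                structure = gemmi.make_structure_from_block(
                    gemmi.cif.read_string(text).sole_block()
                )
            else:
                structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse structure source: {exc}") from exc

    if len(structure) == 0:
        raise EmptyModelError("structure contains no models")
    if len(structure) > 1:
        logger.warning(
            "%s has %d models; using the first", source_name, len(structure)
        )

    model = structure[0]
    residues: list[ResidueKey] = []
    coords: list[tuple[float, float, float]] = []
    for chain in model:
        for residue in chain:
            if residue.het_flag == "H" or residue.is_water():
                continue
            ca = _pick_ca(residue)
            if ca is None:
                continue
            key = ResidueKey(
                chain_id=chain.name,
                residue_number=residue.seqid.num,
                insertion_code=(residue.seqid.icode or " ").strip(),
                residue_name=residue.name,
            )
            if key in residues:  # altloc split across residue objects
                continue
            residues.append(key)
            coords.append((ca.pos.x, ca.pos.y, ca.pos.z))

    if not residues:
        raise EmptyModelError(f"{source_name}: no Calpha atoms found")
    return CaModel(name=name or source_name, residues=residues,
                   coords=np.array(coords))


def _pick_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy CA conformer; first in file order on a tie."""
    best = None
    for atom in residue:
        if atom.name != "CA" or atom.element.name != "C":
            continue
        if best is None or atom.occ > best.occ + 1e-9:
            best = atom
    return best


# ---------------------------------------------------------------------------
# writing


def write_ca_model(
    model: CaModel,
    path: str | Path | None = None,
    scores: Sequence[float] | None = None,
) -> str:
    """Render a CaModel as PDB ATOM records (CA atoms only).

    ``scores``, if given, is one real per residue written into the B-factor
    column (clamped to the fixed ``%6.2f`` field, i.e. to [-99.99, 999.99]).
    Returns the text; also writes it to ``path`` if provided.
    """
    if scores is not None and len(scores) != len(model):
        raise ValueError(
            f"{len(scores)} scores for {len(model)} residues"
        )
    lines = []
    for i, (key, xyz) in enumerate(zip(model.residues, model.coords)):
        b = 0.0 if scores is None else float(np.clip(scores[i], -99.99, 999.99))
        resname = (key.residue_name or "ALA")[:3]
        lines.append(
            f"ATOM  {i + 1:>5d}  CA  {resname:>3s} {key.chain_id[:1]:1s}"
            f"{key.residue_number:>4d}{key.insertion_code or ' ':1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{b:6.2f}"
            f"           C"
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# selection and pairing


def select_residues(model: CaModel, selection: Selection) -> CaModel:
    """Residues whose (chain, number) fall in any range, original order."""
    mask = [selection.contains(key) for key in model.residues]
    n_hit = sum(mask)
    if n_hit == 0:
        logger.info("selection %s matched nothing in %s", selection, model.name)
    keys = [k for k, m in zip(model.residues, mask) if m]
    return CaModel(name=model.name, residues=keys, coords=model.coords[mask])


def pair_models(
    a: CaModel, b: CaModel, selection: Selection | None = None
) -> PairedCoords:
    """Pair two models on their shared residue keys, in ``a``'s order.

    Residue-name mismatches at a shared (chain, number, icode) are logged as
    warnings but still paired — author numbering is the identity that
    matters when comparing crystal forms of the same protein.
    """
    if selection is not None:
        a = select_residues(a, selection)
        b = select_residues(b, selection)
    b_index = {key: i for i, key in enumerate(b.residues)}
    keys, ia, ib = [], [], []
    for i, key in enumerate(a.residues):
        j = b_index.get(key)
        if j is None:
            continue
        other = b.residues[j]
        if other.residue_name and key.residue_name and \
                other.residue_name != key.residue_name:
            logger.warning(
                "residue name mismatch at %s: %s vs %s",
                key, key.residue_name, other.residue_name,
            )
        keys.append(key)
        ia.append(i)
        ib.append(j)
    if not keys:
        raise EmptyModelError(
            f"models {a.name} and {b.name} share no residues"
        )
    logger.info(
        "paired %d residues (%s: %d, %s: %d)",
        len(keys), a.name, len(a), b.name, len(b),
    )
    return PairedCoords(keys=keys, coords_a=a.coords[ia], coords_b=b.coords[ib])
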