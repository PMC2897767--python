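"""Orchestration: configuration, structure fetching/caching, full analysis.

``run_full_analysis`` chains the individual stages the way the capping
protein study chains them: pairwise RMSD matrix over all supplied
conformations -> rigid-domain decomposition of the most-different pair ->
screw (twist) quantification of the small domain against the large ->
elastic-network modes of a designated free structure -> agreement between
the mode-derived rotation axis and the crystal-derived screw axis.  Stage
failures are recorded per stage; independent later stages still run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
import urllib.request
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .domains import (
    DomainPartition,
    decompose_rigid_domains,
    interdomain_screw,
    rmsd_matrix,
)
from .enm import (
    build_hessian,
    build_network,
    extract_rotation_axes,
    axis_angle_between,
    mode_displacements,
    solve_modes,
)
from .structure_io import CaModel, Selection, pair_models

logger = logging.getLogger(__name__)

_version = "0.1.0"

RCSB_URL = "https://files.rcsb.org/download/{accession}.pdb"
_ACCESSION_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")


@dataclass
class EnmParams:
    cutoff: float = 12.0
    spring_constant: float = 1.0
    threshold: float = 2.0
    threshold_mode: str = "absolute"  # or "quantile"
    quantile: float = 0.15


@dataclass
class DomainParams:
    k: int = 2
    linkage: str = "average"
    max_iterations: int = 50


@dataclass
class AnalysisConfig:
    """Everything a full analysis run needs beyond the structures."""

    chain_map: dict[str, str] = field(default_factory=dict)  # chain -> role
    selections: dict[str, Selection] = field(default_factory=dict)
    enm: EnmParams = field(default_factory=EnmParams)
    domain: DomainParams = field(default_factory=DomainParams)
    seed: int = 0
    free_structure: str | None = None  # model name for the ENM stage

    # ---- flat key-value config text -------------------------------------
    @classmethod
    def from_text(cls, text: str) -> "AnalysisConfig":
        """Parse the flat ``key = value`` config dialect.

        Recognised keys: ``chain_map`` (``A=alpha,B=beta[,C=ligand]``),
        ``selection.<name>`` (``A:9-275,B:3-244``), ``enm.<param>``,
        ``domain.<param>``, ``seed``, ``free_structure``.  Lines starting
        with ``#`` are comments.
        """
        cfg = cls()
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: no '=' in {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "chain_map":
                cfg.chain_map = dict(
                    item.split("=", 1) for item in
                    (s.strip() for s in value.split(",")) if item
                )
            elif key.startswith("selection."):
                cfg.selections[key.removeprefix("selection.")] = \
                    Selection.parse(value)
            elif key.startswith("enm."):
                _set_typed(cfg.enm, key.removeprefix("enm."), value)
            elif key.startswith("domain."):
                _set_typed(cfg.domain, key.removeprefix("domain."), value)
            elif key == "seed":
                cfg.seed = int(value)
            elif key == "free_structure":
                cfg.free_structure = value
            else:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_text(Path(path).read_text())

    @classmethod
    def packaged_default(cls) -> "AnalysisConfig":
        """The shipped capping-protein defaults: the published whole-CP /
        CP-L / CP-S residue selections and per-accession chain roles."""
        text = resources.files("capflex.data").joinpath(
            "cp_defaults.cfg").read_text()
        return cls.from_text(text)

    def echo(self) -> dict:
        return {
            "chain_map": dict(self.chain_map),
            "selections": {k: str(v) for k, v in self.selections.items()},
            "enm": vars(self.enm).copy(),
            "domain": vars(self.domain).copy(),
            "seed": self.seed,
            "free_structure": self.free_structure,
        }


def _set_typed(obj, attr: str, value: str) -> None:
    if not hasattr(obj, attr):
        raise ValueError(f"unknown parameter {attr!r}")
    current = getattr(obj, attr)
    if isinstance(current, bool):
        setattr(obj, attr, value.lower() in ("1", "true", "yes"))
    elif isinstance(current, int):
        setattr(obj, attr, int(value))
    elif isinstance(current, float):
        setattr(obj, attr, float(value))
    else:
        setattr(obj, attr, value)


@dataclass
class Report:
    """Machine-readable record of one full analysis run."""

    inputs: list[str]
    parameters: dict
    results: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    version: str = _version
    timestamp: str = ""

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({
            "inputs": self.inputs,
            "parameters": self.parameters,
            "results": self.results,
            "errors": self.errors,
            "version": self.version,
            "timestamp": self.timestamp,
        }, indent=indent, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(str(k) for k in obj)
    return str(obj)


def run_full_analysis(
    config: AnalysisConfig, models: list[CaModel]
) -> Report:
    """Execute the whole comparison/decomposition/mode pipeline.

    Stages: (1) RMSD matrix over the ``whole`` selection (or all residues);
    (2) two-domain decomposition of the most-different pair; (3) screw
    motion of the smaller domain against the larger; (4) elastic-network
    modes of the designated free structure, with rotation-axis extraction;
    (5) angle between the mode axis of the group richest in beta-role-chain
    residues and the crystal-derived screw axis.  Each stage's failure is
    recorded under ``errors`` and later independent stages still run.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    report = Report(
        inputs=[m.name for m in models],
        parameters=config.echo(),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    selection = config.selections.get("whole_cp") or \
        config.selections.get("whole")

    # stage 1: RMSD matrix ------------------------------------------------
    matrix = None
    try:
        matrix = rmsd_matrix(models, selection)
        report.results["rmsd_matrix"] = {
            "names": [m.name for m in models],
            "values_angstrom": matrix,
        }
    except Exception as exc:  # noqa: BLE001 - stage isolation by design
        report.errors["rmsd_matrix"] = str(exc)

    # stage 2: domain decomposition of the most-different pair ------------
    partition = None
    pair = None
    if matrix is not None:
        i, j = np.unravel_index(int(np.argmax(matrix)), matrix.shape)
        max_rmsd = float(matrix[i, j])
        report.results["most_different_pair"] = {
            "names": [models[i].name, models[j].name],
            "rmsd_angstrom": max_rmsd,
        }
        if max_rmsd < 1e-6:
            report.results["no_conformational_change"] = True
            logger.info("all conformations identical; skipping decomposition")
        else:
            try:
                pair = pair_models(models[i], models[j], selection)
                partition = decompose_rigid_domains(
                    pair, k=config.domain.k,
                    max_iterations=config.domain.max_iterations,
                    linkage_method=config.domain.linkage,
                )
                report.results["partition"] = {
                    "sizes": [len(d) for d in partition.domains],
                    "domains": [sorted(str(k) for k in d)
                                for d in partition.domains],
                    "metadata": partition.method_metadata,
                }
            except Exception as exc:  # noqa: BLE001
                report.errors["partition"] = str(exc)

    # stage 3: interdomain screw ------------------------------------------
    screw = None
    if partition is not None and pair is not None:
        try:
            screw = interdomain_screw(pair, partition, 0, 1)
            report.results["screw"] = {
                "angle_deg": screw.angle,
                "axis_direction": screw.axis_direction,
                "axis_point": screw.axis_point,
                "parallel_translation_angstrom": screw.parallel_translation,
                "axis_defined": screw.axis_defined,
            }
        except Exception as exc:  # noqa: BLE001
            report.errors["screw"] = str(exc)
    elif pair is None and matrix is not None and \
            report.results.get("no_conformational_change"):
        report.results["screw"] = {"angle_deg": 0.0, "axis_defined": False}

    # stage 4: ENM on the designated free structure ------------------------
    axes = None
    free = _pick_free(models, config.free_structure)
    try:
        network = build_network(free, cutoff=config.enm.cutoff,
                                spring_constant=config.enm.spring_constant)
        modes = solve_modes(build_hessian(network),
                            spring_constant=config.enm.spring_constant)
        field_ = mode_displacements(modes, modes.lowest_internal_index)
        axes = extract_rotation_axes(
            free, field_,
            threshold=config.enm.threshold,
            threshold_mode=config.enm.threshold_mode,
            quantile=config.enm.quantile,
        )
        report.results["enm"] = {
            "free_structure": free.name,
            "n_rigid_modes": modes.n_rigid,
            "lowest_internal_eigenvalue": float(
                modes.eigenvalues[modes.lowest_internal_index]),
            "spectrum_head": modes.eigenvalues[:12],
            "threshold_used": axes.threshold_used,
            "groups": [
                {
                    "n_residues": len(g.residue_keys),
                    "axis_direction": g.axis_direction,
                    "centroid": g.centroid,
                    "variance_explained": g.variance_explained,
                    "chain_composition": g.chain_composition,
                }
                for g in axes.groups
            ],
        }
    except Exception as exc:  # noqa: BLE001
        report.errors["enm"] = str(exc)

    # stage 5: mode-axis vs screw-axis agreement ---------------------------
    if axes is not None and screw is not None and screw.axis_defined:
        try:
            group = _beta_group(axes, config, partition)
            report.results["axis_agreement"] = {
                "angle_deg": axis_angle_between(
                    group.axis_direction, screw.axis_direction),
                "group_chain_composition": group.chain_composition,
            }
        except Exception as exc:  # noqa: BLE001
            report.errors["axis_agreement"] = str(exc)

    return report


def _pick_free(models: list[CaModel], name: str | None) -> CaModel:
    if name is None:
        return models[0]
    for m in models:
        if m.name == name:
            return m
    raise ValueError(f"free_structure {name!r} not among supplied models")


def _beta_group(axes, config: AnalysisConfig, partition):
    """The extracted group richest in beta-role-chain residues.

    The beta chain is the one mapped to the role ``beta`` in the chain
    map; if no map is given, the chain holding the majority of the smaller
    (moving) domain's residues stands in for it.
    """
    beta_chain = None
    for chain, role in config.chain_map.items():
        if role == "beta":
            beta_chain = chain
            break
    if beta_chain is None and partition is not None:
        chains = [k.chain_id for k in partition.domains[-1]]
        beta_chain = max(set(chains), key=chains.count)
    if beta_chain is None:
        return axes.groups[0]

    def beta_fraction(g):
        n = sum(1 for k in g.residue_keys if k.chain_id == beta_chain)
        return n / len(g.residue_keys)

    return max(axes.groups, key=beta_fraction)


# ---------------------------------------------------------------------------
# accession fetching


def fetch_structure(accession: str, cache_dir: str | Path) -> Path:
    """Download a PDB entry (or reuse the cached copy) and return its path.

    The accession is validated before any network use; a warm cache never
    touches the network; a cold cache without network raises a clear error
    naming the accession.
    """
    if not _ACCESSION_RE.match(accession or ""):
        raise ValueError(f"malformed PDB accession {accession!r}")
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    target = cache / f"{accession.lower()}.pdb"
    if target.exists():
        logger.info("cache hit for %s (sha256 %s)", accession,
                    _sha256(target)[:12])
        return target
    url = RCSB_URL.format(accession=accession.upper())
    try:
        with urllib.request.urlopen(url, timeout=30) as response:
            data = response.read()
    except Exception as exc:
        raise ConnectionError(
            f"cannot fetch accession {accession}: no cached copy at "
            f"{target} and download failed ({exc})"
        ) from exc
    target.write_bytes(data)
    logger.info("fetched %s (sha256 %s)", accession, _sha256(target)[:12])
    return target


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
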