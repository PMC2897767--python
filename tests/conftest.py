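"""Shared fixtures: random models, synthetic pairs, cached accession data.

Accession-dependent fixtures try the local download cache first, then the
network; when both are unavailable the dependent tests skip (the
quantitative surface they check needs the deposited crystal structures).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from capflex import (
    CaModel,
    ResidueKey,
    fetch_structure,
    generate_two_domain_pair,
    read_ca_model,
)
from capflex.synthetic import PlantedMotion

CACHE_DIR = Path(__file__).resolve().parent.parent / "pdb_cache"

CP_ACCESSIONS = {
    "1IZN": "cp_full",
    "3AAA": "cp_v1",
    "3AA7": "cp_bdc",
    "3AA0": "cp_ca21",
    "3AA6": "cp_cd23",
    "3AA1": "cp_ck23",
}


def random_model(
    n: int, seed: int, chain_id: str = "A", spread: float = 20.0
) -> CaModel:
    """Unstructured random cloud (no spacing guarantee) for geometry tests."""
    rng = np.random.default_rng(seed)
    return CaModel(
        name=f"random{seed}",
        residues=[ResidueKey(chain_id, i + 1, residue_name="GLY")
                  for i in range(n)],
        coords=rng.uniform(-spread, spread, size=(n, 3)),
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via normalised quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture(scope="session")
def clean_pair():
    """Noise-free synthetic pair with a planted 20-degree twist."""
    return generate_two_domain_pair(
        120, 80, PlantedMotion(angle=20.0, seed=101))


@pytest.fixture(scope="session")
def noisy_pair():
    """Synthetic pair: planted 10-degree twist, 0.2 A coordinate noise."""
    return generate_two_domain_pair(
        150, 100, PlantedMotion(angle=10.0, noise_sigma=0.2, seed=202))


@pytest.fixture(scope="session")
def cp_structures():
    """The six deposited capping-protein structures, from cache or network.

    Skips (never fails) when neither a cached copy nor the network is
    available.
    """
    models = {}
    for accession, label in CP_ACCESSIONS.items():
        try:
            path = fetch_structure(accession, CACHE_DIR)
        except (ConnectionError, OSError) as exc:
            pytest.skip(f"accession {accession} unavailable offline: {exc}")
        models[label] = read_ca_model(path, name=label)
    return models
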