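"""Reproduce the capping-protein numbers from the deposited structures.

Needs network access (or a warm ``pdb_cache/``) to download the six PDB
entries: free CP (1IZN), CP/V-1 (3AAA), beta-tentacle-truncated CP (3AA7)
and the three CP/CARMIL-peptide complexes (3AA0, 3AA6, 3AA1).  Prints the
pairwise whole-CP RMSD matrix, the CP-L/CP-S twist angle between free and
V-1-bound CP, and the agreement of the elastic-network axis with the
crystal-derived twist axis.
"""

import sys

from capflex import (
    AnalysisConfig,
    fetch_structure,
    read_ca_model,
    run_full_analysis,
)

ACCESSIONS = ["1IZN", "3AAA", "3AA7", "3AA0", "3AA6", "3AA1"]

try:
    paths = {acc: fetch_structure(acc, "pdb_cache") for acc in ACCESSIONS}
except ConnectionError as exc:
    sys.exit(f"cannot run the crystal reproduction offline: {exc}")

models = [read_ca_model(path, name=acc) for acc, path in paths.items()]
config = AnalysisConfig.packaged_default()
report = run_full_analysis(config, models)
print(report.to_json())
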