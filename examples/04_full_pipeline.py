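"""One-call orchestration: RMSD matrix -> domains -> screw -> modes.

Runs the full analysis chain on a synthetic conformational pair and prints
the highlights of the machine-readable report, including the agreement
between the crystal-comparison twist axis and the mode-analysis axis —
the package's headline cross-validation.
"""

import numpy as np

from capflex import AnalysisConfig, run_full_analysis
from capflex.synthetic import PlantedMotion, generate_two_domain_pair

model_a, model_b, motion = generate_two_domain_pair(
    150, 100, PlantedMotion(angle=10.0, noise_sigma=0.2, seed=42))

config = AnalysisConfig(chain_map={"A": "alpha", "B": "beta"})
config.enm.threshold_mode = "quantile"
report = run_full_analysis(config, [model_a, model_b])

rmsd = np.asarray(report.results["rmsd_matrix"]["values_angstrom"])
print(f"pairwise RMSD: {rmsd[0, 1]:.2f} A")
print(f"domain sizes: {report.results['partition']['sizes']}")
print(f"inter-domain twist: "
      f"{report.results['screw']['angle_deg']:.2f} deg")
print(f"rigid modes: {report.results['enm']['n_rigid_modes']}")
print(f"mode axis vs screw axis: "
      f"{report.results['axis_agreement']['angle_deg']:.1f} deg apart")
print("Two independent routes — comparing crystal-like conformations and "
      "analysing the vibrations of a single structure — point at the same "
      "twist axis.")
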