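"""Superpose two conformations of a synthetic two-domain protein.

Builds a 250-residue assembly with a planted 10-degree inter-domain twist
plus 0.2 A coordinate noise, superposes the two conformations, and prints
the whole-molecule RMSD and the effect of anchoring the fit on the static
domain only.
"""

from capflex import Selection, kabsch_fit, pair_models
from capflex.synthetic import PlantedMotion, generate_two_domain_pair

model_a, model_b, motion = generate_two_domain_pair(
    150, 100, PlantedMotion(angle=10.0, noise_sigma=0.2, seed=42))
pair = pair_models(model_a, model_b)

overall = kabsch_fit(pair)
print(f"whole-molecule fit: RMSD = {overall.rmsd:.2f} A "
      f"over {overall.n_pairs} residues")

anchored = kabsch_fit(pair, fit_selection=Selection.parse("A:1-150"))
static = pair.subset_mask(Selection.parse("A:1-150"))
print(f"fit anchored on the static domain: "
      f"static-domain deviation = "
      f"{anchored.per_residue_deviation[static].mean():.2f} A, "
      f"moving-domain deviation = "
      f"{anchored.per_residue_deviation[~static].mean():.2f} A")
print("A whole-molecule RMSD near 1 A hides a rigid 10-degree twist; "
      "anchoring on one domain exposes the other domain's displacement.")
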