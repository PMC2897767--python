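"""Recover rigid domains and the inter-domain screw from two conformations.

The generator plants a 10-degree twist of the smaller domain about a known
axis; the decomposition is blind to that truth and must rediscover both
the residue partition and the screw parameters.
"""

import numpy as np

from capflex import (
    decompose_rigid_domains,
    interdomain_screw,
    pair_models,
)
from capflex.domains import partition_agreement
from capflex.synthetic import PlantedMotion, generate_two_domain_pair

model_a, model_b, motion = generate_two_domain_pair(
    150, 100, PlantedMotion(angle=10.0, noise_sigma=0.2, seed=42))
pair = pair_models(model_a, model_b)

partition = decompose_rigid_domains(pair, k=2)
agreement = partition_agreement(partition, motion.partition, pair.keys)
print(f"blind two-domain partition: sizes "
      f"{[len(d) for d in partition.domains]}, "
      f"{100 * agreement:.1f}% agreement with the planted split")

screw = interdomain_screw(pair, partition, reference_domain=0,
                          moving_domain=1)
axis_err = np.degrees(np.arccos(
    abs(screw.axis_direction @ motion.axis_direction)))
print(f"screw decomposition: angle = {screw.angle:.2f} deg "
      f"(planted {motion.angle:.0f}), axis off by {axis_err:.1f} deg, "
      f"slide along axis = {screw.parallel_translation:.2f} A")
print("The conformational change reduces to a near-pure rotation of the "
      "small domain about the planted twist axis.")
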