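"""Elastic-network modes of a two-domain assembly and axis extraction.

The softest internal mode of a two-lobed elastic network is the torsion of
one lobe against the other; residues that barely move in that mode trace
the rotation axis.  The example checks the extracted axis against the axis
the generator actually used.
"""

from capflex import (
    axis_angle_between,
    build_hessian,
    build_network,
    extract_rotation_axes,
    mode_displacements,
    solve_modes,
)
from capflex.synthetic import PlantedMotion, generate_two_domain_pair

model, _, motion = generate_two_domain_pair(
    150, 100, PlantedMotion(angle=10.0, seed=42))

network = build_network(model, cutoff=12.0)
modes = solve_modes(build_hessian(network))
print(f"elastic network: {len(network.edges)} springs, "
      f"{modes.n_rigid} rigid-body modes (6 expected for a connected "
      f"network)")
print(f"lowest internal eigenvalue: "
      f"{modes.eigenvalues[modes.lowest_internal_index]:.4f} "
      f"(arbitrary units, spring constant C = 1)")

field = mode_displacements(modes, modes.lowest_internal_index)
axes = extract_rotation_axes(model, field, threshold_mode="quantile",
                             quantile=0.15)
group = axes.groups[0]
err = axis_angle_between(group.axis_direction, motion.axis_direction)
print(f"low-displacement group: {len(group.residue_keys)} residues, "
      f"chains {group.chain_composition}, "
      f"PCA axis within {err:.1f} deg of the planted hinge axis "
      f"(variance explained {group.variance_explained:.2f})")
print("The mode analysis finds the same twist axis that was built into "
      "the structure, without ever seeing the second conformation.")
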