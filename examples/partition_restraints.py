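"""Partition NOE distance restraints between two conformational states.

Builds the two-conformation toy system (rigid core + mobile segment
displaced 20 A between states), derives methyl-methyl restraints from
its geometry, and classifies each restraint by which state satisfies it
— the analysis that separates state-specific contacts from shared ones.
"""

from lidex.restraints import partition_two_states
from lidex.synthetic_data import gen_toy_system, make_state_restraints

system = gen_toy_system(n_core=30, displacement=20.0, seed=0)
a_specific, b_specific, shared = make_state_restraints(system)
restraints = a_specific + b_specific + shared
print(f"toy system: {len(system.core_resids)} core + "
      f"{len(system.mobile_resids)} mobile residues, "
      f"{len(system.methyl_groups)} methyl groups, "
      f"{len(restraints)} restraints")

part = partition_two_states(
    restraints, system.ensemble("A"), system.ensemble("B"), tolerance=0.5
)
a, b, both, neither = part.counts
print(f"satisfied only in state A: {a}")
print(f"satisfied only in state B: {b}")
print(f"satisfied in both states:  {both}")
print(f"satisfied in neither:      {neither}")
print()
print("State-specific restraints are the fingerprint of each conformation:")
print("contacts that exist only when the mobile segment is docked one way.")
print(f"The generator built {len(a_specific)}/{len(b_specific)}/{len(shared)}")
print("A-specific/B-specific/shared pairs, which the partition recovers.")
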