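"""Bottom-up construction of the many-body interaction graph.

Starts with the classic three-monomer scenario (dimer BC screened out) and
then shows how the missing-parent allowance M shapes a larger graph.
"""

from mbescreen.graph import (
    InteractionGraph,
    NodeStatus,
    SubsystemKey,
    build_layer_grandparents,
    build_layer_plus_one,
    build_layer_propose_and_check,
    select_algorithm,
    subsystem_count,
)

# --- worked example: monomers {A,B,C}, dimers AB and AC retained ----------
g = InteractionGraph(3, M=1, n_max=3)
g.add_layer(2, [SubsystemKey((0, 1)), SubsystemKey((0, 2))],
            [(SubsystemKey((1, 2)), NodeStatus.REMOVED_ENERGY)])

abc = SubsystemKey((0, 1, 2))
print("three-monomer example (BC eliminated, M=1):")
print("  propose-and-check:", sorted(map(tuple, build_layer_propose_and_check(g, 3))))
print("  plus-one:         ", sorted(map(tuple, build_layer_plus_one(g, 3))))
print("  grandparents:     ", sorted(map(tuple, build_layer_grandparents(g, 3))))
print(f"  ABC has m = {g.missing_parent_count(abc)} missing parent(s); "
      f"admitted because m <= M")
print(f"  algorithm auto-selected for (k=3, M=1): {select_algorithm(3, 1)}")

# --- the combinatorial wall the graph avoids ------------------------------
print("\nwhy screening matters: complete subsystem counts C(N, 8)")
for N in (64, 160):
    print(f"  N={N}: {subsystem_count(N, 8):,} octamers")

# --- allowance M on a larger random state ---------------------------------
import numpy as np

rng = np.random.default_rng(0)
for M in (0, 1, 2):
    gm = InteractionGraph(8, M=M, n_max=3)
    dimers = sorted(build_layer_propose_and_check(gm, 2))
    keep = rng.random(len(dimers)) < 0.5  # same eliminations for every M
    gm.add_layer(2, [d for d, k in zip(dimers, keep) if k],
                 [(d, NodeStatus.REMOVED_ENERGY) for d, k in zip(dimers, keep) if not k])
    rng = np.random.default_rng(0)  # reset so each M sees identical dimers
    print(f"  M={M}: {len(build_layer_plus_one(gm, 3))} trimer candidates "
          f"(of {subsystem_count(8, 3)} possible)")

# Larger M admits more children of partially screened parents; M=1 is the
# standard compromise between sparsity and completeness.
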