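"""Distance and energy screening on a molecular cluster.

Generates a 12-fragment condensed cluster and shows how the two screens
thin out the dimer and trimer layers before any target-level energy is
spent.
"""

from mbescreen import EnergyStore, ToyBackend
from mbescreen.fixtures import FixtureSpec, make_cluster
from mbescreen.graph import subsystem_count
from mbescreen.pipeline import build_screened_graph
from mbescreen.screening import ScreeningConfig

_atoms, scheme, potential = make_cluster(FixtureSpec(kind="cluster", N=12, seed=42))
backend = ToyBackend(potential)

for label, config in [
    ("no screening", ScreeningConfig(tau_by_order={}, d_by_order={}, M=1)),
    ("distance d2=6, d3=5", ScreeningConfig(tau_by_order={}, d_by_order={2: 6.0, 3: 5.0}, M=1)),
    ("energy tau2=0.1, tau3=0.05", ScreeningConfig(tau_by_order={2: 0.1, 3: 0.05}, d_by_order={}, M=1)),
    ("both", ScreeningConfig(tau_by_order={2: 0.1, 3: 0.05}, d_by_order={2: 6.0, 3: 5.0}, M=1)),
]:
    graph = build_screened_graph(scheme, config, 3, backend, EnergyStore())
    counts = graph.status_counts()
    print(f"{label}:")
    for k in (2, 3):
        c = counts[k]
        print(f"  order {k}: retained {c['retained']:3d} / {subsystem_count(scheme.N, k):3d}   "
              f"removed: parents {c['removed_parents']}, distance {c['removed_distance']}, "
              f"energy {c['removed_energy']}")

# Distance screening removes spatially extended subsystems; energy screening
# removes those whose low-level n-body correction is below tau (they cannot
# contribute meaningfully at the target level either).  The filters are
# independent predicates, so their combination is order-insensitive.
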