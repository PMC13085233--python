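"""Layered many-body interaction graph.

The many-body expansion over N fragments is organised as a directed acyclic
graph whose nodes are subsystems (k-mers of fragment ids) and whose edges
connect each k-mer *child* to its k parents of order k-1: every child is the
union of its parents.  The graph is built bottom-up, layer by layer, starting
from the monomers.  As subsystems are eliminated by distance or energy
screening, their would-be children may be missing parents; a child with more
than ``M`` missing parents is never admitted, which is what makes high-order
expansions tractable.

Three equivalent construction algorithms are provided for the missing-parent
(parental) screen:

``propose_and_check``
    enumerate every C(N, k) candidate and count its retained parents.
``plus_one``
    grow each retained (k-1)-mer by one monomer and count how often each
    unique k-mer is generated; a k-mer with p retained parents is generated
    exactly p times.
``grandparents``
    form pairwise unions of retained (k-1)-mers that share a (k-2)-subset;
    a k-mer with p retained parents occurs exactly C(p, 2) times, so the
    acceptance threshold becomes (k-M)(k-M-1)/2.

All three return the identical candidate set on any graph state; they differ
only in cost.  ``select_algorithm`` picks the cheapest applicable one.
"""

from __future__ import annotations

import enum
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, TextIO


class SubsystemKey(tuple):
    """Canonical identifier of a subsystem: a strictly increasing tuple of
    fragment ids.  Hash and equality are inherited from ``tuple``, so keys
    built from any ordering of the same ids compare equal."""

    __slots__ = ()

    def __new__(cls, ids: Iterable[int]) -> "SubsystemKey":
        t = tuple(sorted(ids))
        if not t:
            raise ValueError("subsystem key must contain at least one fragment id")
        if len(set(t)) != len(t):
            raise ValueError(f"duplicate fragment ids in subsystem key: {t}")
        return tuple.__new__(cls, t)

    @property
    def order(self) -> int:
        return len(self)

    def union(self, other: Iterable[int]) -> "SubsystemKey":
        return SubsystemKey(set(self) | set(other))

    def parents(self) -> Iterator["SubsystemKey"]:
        """The ``k`` subsystems of order k-1 obtained by dropping one id."""
        for i in range(len(self)):
            rest = self[:i] + self[i + 1 :]
            if rest:
                yield SubsystemKey(rest)

    def subsets(self, include_self: bool = True) -> Iterator["SubsystemKey"]:
        """All nonempty subsets, smallest first (2^k - 1 keys)."""
        top = len(self) if include_self else len(self) - 1
        for r in range(1, top + 1):
            for combo in combinations(self, r):
                yield SubsystemKey(combo)

    def contains(self, fragment_id: int) -> bool:
        return fragment_id in self

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SubsystemKey({','.join(map(str, self))})"


class NodeStatus(enum.Enum):
    RETAINED = "retained"
    REMOVED_PARENTS = "removed_parents"
    REMOVED_DISTANCE = "removed_distance"
    REMOVED_ENERGY = "removed_energy"


@dataclass(frozen=True)
class GraphNode:
    key: SubsystemKey
    missing_parents: int
    status: NodeStatus


def subsystem_count(n_fragments: int, k: int) -> int:
    """Exact number of order-k subsystems over ``n_fragments`` primary
    fragments, C(N_P, k), evaluated in arbitrary-precision integers."""
    if k < 0 or k > n_fragments:
        raise ValueError(f"order k={k} outside 0..{n_fragments}")
    return math.comb(n_fragments, k)


@dataclass
class InteractionGraph:
    """Layered DAG of subsystems with per-node status.

    Layer 1 always holds all N monomers (retained: monomers are never subject
    to parental screening).  Higher layers are populated by the caller, via
    :meth:`add_node`, after running one of the construction algorithms and
    any distance/energy screens.
    """

    n_fragments: int
    M: int = 1
    n_max: int = 2
    layers: dict[int, dict[SubsystemKey, GraphNode]] = field(default_factory=dict)
    #: candidates implicitly discarded by the parental screen, per order
    #: (they are counted, never materialised as nodes).
    parent_rejected: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if not self.layers:
            monomers = {
                SubsystemKey((i,)): GraphNode(SubsystemKey((i,)), 0, NodeStatus.RETAINED)
                for i in range(self.n_fragments)
            }
            self.layers = {1: monomers}

    # -- queries -----------------------------------------------------------

    def retained(self, k: int) -> list[SubsystemKey]:
        """Retained keys of order k, lexicographically sorted."""
        layer = self.layers.get(k, {})
        return sorted(
            key for key, node in layer.items() if node.status is NodeStatus.RETAINED
        )

    def retained_set(self, k: int) -> set[SubsystemKey]:
        layer = self.layers.get(k, {})
        return {key for key, node in layer.items() if node.status is NodeStatus.RETAINED}

    def all_retained(self, up_to: int | None = None) -> list[SubsystemKey]:
        up_to = self.n_max if up_to is None else up_to
        out: list[SubsystemKey] = []
        for k in sorted(self.layers):
            if k <= up_to:
                out.extend(self.retained(k))
        return out

    def missing_parent_count(self, key: SubsystemKey) -> int:
        """m = k minus the number of retained parents present at order k-1."""
        k = key.order
        if k == 1:
            return 0
        retained_prev = self.retained_set(k - 1)
        present = sum(1 for p in key.parents() if p in retained_prev)
        return k - present

    # -- mutation ----------------------------------------------------------

    def add_node(self, key: SubsystemKey, status: NodeStatus) -> GraphNode:
        k = key.order
        if any(key in layer for o, layer in self.layers.items() if o != k):
            raise ValueError(f"key {key} already present in another layer")
        node = GraphNode(key, self.missing_parent_count(key), status)
        self.layers.setdefault(k, {})[key] = node
        return node

    def add_layer(
        self,
        k: int,
        retained: Iterable[SubsystemKey],
        removed: Iterable[tuple[SubsystemKey, NodeStatus]] = (),
        parent_rejected: int | None = None,
    ) -> None:
        self.layers.setdefault(k, {})  # a fully screened layer is still built
        for key in sorted(retained):
            self.add_node(key, NodeStatus.RETAINED)
        for key, status in sorted(removed, key=lambda kv: kv[0]):
            self.add_node(key, status)
        if parent_rejected is not None:
            self.parent_rejected[k] = parent_rejected

    # -- audit -------------------------------------------------------------

    def status_counts(self) -> dict[int, dict[str, int]]:
        """Per-order node counts by status, plus implicit parental rejections."""
        out: dict[int, dict[str, int]] = {}
        for k in sorted(self.layers):
            counts = Counter(node.status.value for node in self.layers[k].values())
            row = {status.value: counts.get(status.value, 0) for status in NodeStatus}
            row["removed_parents"] += self.parent_rejected.get(k, 0)
            out[k] = row
        return out

    # -- text dump / load --------------------------------------------------

    def dump(self, stream: TextIO) -> None:
        stream.write(f"# mbescreen graph N={self.n_fragments} M={self.M} n_max={self.n_max}\n")
        for k in sorted(self.layers):
            for key in sorted(self.layers[k]):
                node = self.layers[k][key]
                ids = ",".join(map(str, key))
                stream.write(f"{k}\t{ids}\t{node.missing_parents}\t{node.status.value}\n")

    @classmethod
    def load(cls, stream: TextIO) -> "InteractionGraph":
        header = stream.readline().strip()
        if not header.startswith("# mbescreen graph"):
            raise ValueError("not a graph dump")
        meta = dict(tok.split("=") for tok in header.split()[3:])
        graph = cls(int(meta["N"]), int(meta["M"]), int(meta["n_max"]))
        graph.layers = {1: {}}
        for line in stream:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k_s, ids_s, m_s, status_s = line.split("\t")
            key = SubsystemKey(int(t) for t in ids_s.split(","))
            node = GraphNode(key, int(m_s), NodeStatus(status_s))
            graph.layers.setdefault(int(k_s), {})[key] = node
        return graph


# ---------------------------------------------------------------------------
# Construction algorithms for the missing-parent screen
# ---------------------------------------------------------------------------


def build_layer_propose_and_check(graph: InteractionGraph, k: int) -> set[SubsystemKey]:
    """Enumerate all C(N, k) candidates; keep those with >= k - M retained
    parents at order k-1.  Exhaustive reference algorithm, cost C(N, k)."""
    _check_layer_preconditions(graph, k)
    retained_prev = graph.retained_set(k - 1)
    need = k - graph.M
    out: set[SubsystemKey] = set()
    for combo in combinations(range(graph.n_fragments), k):
        key = SubsystemKey(combo)
        present = sum(1 for p in key.parents() if p in retained_prev)
        if present >= need:
            out.add(key)
    return out


def build_layer_plus_one(graph: InteractionGraph, k: int) -> set[SubsystemKey]:
    """Union each monomer with each retained (k-1)-mer; a unique k-mer
    generated at least k - M times (= its retained-parent count) is kept."""
    _check_layer_preconditions(graph, k)
    need = k - graph.M
    if need <= 0:
        # every candidate is admissible, including ones no retained parent can
        # generate; only exhaustive enumeration has the right semantics here
        return build_layer_propose_and_check(graph, k)
    counts: Counter[SubsystemKey] = Counter()
    for parent in graph.retained(k - 1):
        members = set(parent)
        for a in range(graph.n_fragments):
            if a not in members:
                counts[parent.union((a,))] += 1
    return {key for key, n in counts.items() if n >= need}


def build_layer_grandparents(graph: InteractionGraph, k: int) -> set[SubsystemKey]:
    """Pairwise unions of retained (k-1)-mers sharing an order-(k-2)
    grandparent; a k-mer with p retained parents occurs C(p, 2) times, and
    those occurring at least (k-M)(k-M-1)/2 times are kept.

    Grouping is by every (k-2)-subset of the retained parents (the subset
    lattice) rather than by retained (k-2) graph nodes only; this keeps the
    occurrence count exactly C(p, 2) even when a shared grandparent was
    itself screened out, so the result always matches the other algorithms.
    """
    if k < 3 or k - graph.M <= 1:
        raise ValueError(
            "grandparents algorithm requires k >= 3 and k - M > 1 "
            f"(got k={k}, M={graph.M}); use plus_one instead"
        )
    _check_layer_preconditions(graph, k)
    children_of: defaultdict[tuple[int, ...], list[SubsystemKey]] = defaultdict(list)
    for parent in graph.retained(k - 1):
        for g in combinations(parent, k - 2):
            children_of[g].append(parent)
    counts: Counter[SubsystemKey] = Counter()
    for kids in children_of.values():
        for p1, p2 in combinations(kids, 2):
            counts[p1.union(p2)] += 1
    need = (k - graph.M) * (k - graph.M - 1) // 2
    return {key for key, n in counts.items() if n >= need}


_ALGORITHMS = {
    "propose_and_check": build_layer_propose_and_check,
    "plus_one": build_layer_plus_one,
    "grandparents": build_layer_grandparents,
}


def select_algorithm(k: int, M: int) -> str:
    """Cheapest applicable construction algorithm for layer ``k``:
    grandparents whenever k >= 3 and k - M > 1, else plus-one.
    (propose_and_check is available by explicit override only.)"""
    if k < 2:
        raise ValueError("layers are constructed from order 2 upward")
    if k >= 3 and k - M > 1:
        return "grandparents"
    return "plus_one"


def build_layer(graph: InteractionGraph, k: int, algorithm: str | None = None) -> set[SubsystemKey]:
    """Run the chosen (or automatically selected) construction algorithm."""
    name = algorithm or select_algorithm(k, graph.M)
    try:
        fn = _ALGORITHMS[name]
    except KeyError:
        raise ValueError(f"unknown construction algorithm {name!r}") from None
    return fn(graph, k)


def _check_layer_preconditions(graph: InteractionGraph, k: int) -> None:
    if k < 2:
        raise ValueError("layer construction starts at order 2")
    for j in range(1, k):
        if j not in graph.layers:
            raise ValueError(f"layer {j} must be built before layer {k}")
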