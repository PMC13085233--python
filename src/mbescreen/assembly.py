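"""Energy assembly: n-body corrections, resummation, MBE(n) totals, and the
protein-ligand interaction energy.

The truncated many-body expansion over fragments A, B, C, ... is

    E_MBE(n) = sum_A E_A + sum_{A<B} dE_AB + sum_{A<B<C} dE_ABC + ...   (to order n)

with each correction defined by inclusion-exclusion over the subsystem's
subsets, dE_S = sum_{T subset S, T nonempty} (-1)^{|S|-|T|} E_T; for orders
two and three this reduces to the familiar dE_AB = E_AB - E_A - E_B and
dE_ABC = E_ABC - dE_AB - dE_AC - dE_BC - E_A - E_B - E_C.

Naively each dE term re-references many lower-order subsystem energies.
Resummation expands every retained dE symbolically into signed unit
contributions on its subset keys and accumulates *exact integer
coefficients* per unique subsystem, so that the whole MBE(n) collapses to
sum_S c_S E_S and each distinct subsystem energy is computed exactly once.
For the complete (unscreened) expansion the coefficient of a k-mer has the
closed form (-1)^(n-k) C(N-k-1, n-k).

The supramolecular interaction energy dE_int = E_P:L - E_P - E_L simplifies
a priori: every dE term whose fragments lie entirely within the protein
appears identically in E_P:L and E_P and cancels, and the intact-ligand
monomer cancels against E_L, so only ligand-containing terms of order >= 2
survive.  Both the shortcut and the explicit three-expansion difference are
implemented; they agree to accumulation tolerance by construction and the
test suite asserts it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from .backends import Backend, EnergyStore, store_get_or_compute
from .errors import DependencyError, EvaluationError, InputError
from .graph import InteractionGraph, SubsystemKey
from .structure import FragmentationScheme


def n_body_correction(key: SubsystemKey, energies: Mapping[SubsystemKey, float]) -> float:
    """Inclusion-exclusion k-body correction dE_S from subset energies.

    ``energies`` must contain every nonempty subset of ``key`` (order-1 keys
    need only themselves, for which dE_A = E_A).
    """
    key = key if isinstance(key, SubsystemKey) else SubsystemKey(key)
    terms = []
    k = key.order
    for sub in key.subsets():
        try:
            e = energies[sub]
        except KeyError:
            raise DependencyError(
                f"missing subset energy for {tuple(sub)} required by dE of {tuple(key)}"
            ) from None
        sign = -1.0 if (k - sub.order) % 2 else 1.0
        terms.append(sign * e)
    return math.fsum(terms)


@dataclass
class CoefficientLedger:
    """Integer coefficient per unique subsystem after analytic resummation."""

    entries: dict[SubsystemKey, int] = field(default_factory=dict)

    def add_delta_term(self, key: SubsystemKey, weight: int = 1) -> None:
        """Accumulate the signed unit expansion of one dE term."""
        k = key.order
        for sub in key.subsets():
            sign = -1 if (k - sub.order) % 2 else 1
            new = self.entries.get(sub, 0) + weight * sign
            if new == 0:
                self.entries.pop(sub, None)
            else:
                self.entries[sub] = new

    def coefficient(self, key: SubsystemKey) -> int:
        return self.entries.get(key, 0)

    def support(self) -> list[SubsystemKey]:
        """Subsystems with nonzero coefficient (the distinct evaluations)."""
        return sorted(self.entries)

    def support_by_order(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for key in self.entries:
            out[key.order] = out.get(key.order, 0) + 1
        return out

    def evaluate(self, energy_of: Callable[[SubsystemKey], float]) -> float:
        """sum_S c_S E_S with compensated summation."""
        return math.fsum(c * energy_of(key) for key, c in sorted(self.entries.items()))


def resum(retained: Iterable[SubsystemKey]) -> CoefficientLedger:
    """Resummation of the retained dE terms (all orders, monomers included)
    into the unique-subsystem coefficient ledger."""
    ledger = CoefficientLedger()
    for key in retained:
        ledger.add_delta_term(key)
    return ledger


def complete_mbe_coefficient(n_fragments: int, n: int, k: int) -> int:
    """Closed-form ledger coefficient of any k-mer in the complete
    (unscreened) MBE(n) over N fragments: (-1)^(n-k) C(N-k-1, n-k)."""
    if not 1 <= k <= n <= n_fragments:
        return 0
    if n == k:
        return 1
    top = n_fragments - k - 1
    if top < 0:
        return 0
    sign = -1 if (n - k) % 2 else 1
    return sign * math.comb(top, n - k)


@dataclass
class NBodyBreakdown:
    per_order_sums: dict[int, float] = field(default_factory=dict)
    per_term_values: list[tuple[SubsystemKey, float]] = field(default_factory=list)

    @property
    def total(self) -> float:
        return math.fsum(self.per_order_sums.values())


@dataclass
class InteractionEnergyResult:
    delta_E_int: float
    per_order_contributions: dict[int, float]
    n_subsystems_evaluated: int
    audit: dict[int, dict[str, int]]
    breakdown: NBodyBreakdown


def _store_energy_of(
    scheme: FragmentationScheme, backend: Backend, store: EnergyStore, level: str = "target"
) -> Callable[[SubsystemKey], float]:
    def energy_of(key: SubsystemKey) -> float:
        rec = store_get_or_compute(store, key, level, backend, scheme)
        if not rec.converged:
            raise EvaluationError(f"backend energy for {tuple(key)} did not converge")
        return rec.energy

    return energy_of


def mbe_energy(
    retained: Iterable[SubsystemKey],
    scheme: FragmentationScheme,
    backend: Backend,
    store: EnergyStore | None = None,
    level: str = "target",
) -> tuple[float, NBodyBreakdown, CoefficientLedger]:
    """Assemble the MBE total energy from retained subsystems.

    Returns the resummed total sum_S c_S E_S, an n-body breakdown recomputed
    term-by-term from the dE definitions (its total agrees with the ledger
    total to accumulation tolerance), and the ledger itself.
    """
    retained = sorted(retained)
    store = store if store is not None else EnergyStore()
    energy_of = _store_energy_of(scheme, backend, store, level)
    ledger = resum(retained)
    total = ledger.evaluate(energy_of)

    breakdown = NBodyBreakdown()
    cache: dict[SubsystemKey, float] = {}

    def cached(key: SubsystemKey) -> float:
        if key not in cache:
            cache[key] = energy_of(key)
        return cache[key]

    per_order: dict[int, list[float]] = {}
    for key in retained:
        energies = {sub: cached(sub) for sub in key.subsets()}
        delta = n_body_correction(key, energies)
        per_order.setdefault(key.order, []).append(delta)
        breakdown.per_term_values.append((key, delta))
    breakdown.per_order_sums = {k: math.fsum(v) for k, v in sorted(per_order.items())}
    return total, breakdown, ledger


def interaction_energy(
    scheme: FragmentationScheme,
    graph: InteractionGraph,
    backend: Backend,
    store: EnergyStore | None = None,
    level: str = "target",
    method: str = "cancellation",
) -> InteractionEnergyResult:
    """Supramolecular dE_int = E_P:L - E_P - E_L under a consistent MBE(n).

    method="cancellation" (default) assembles only retained ligand-containing
    dE terms of order >= 2, exploiting the a priori cancellation of
    protein-only terms.  method="explicit" evaluates the three truncated
    expansions and subtracts; screening decisions are shared (the P graph is
    the P:L graph restricted to ligand-free keys), so the two routes agree
    to accumulation tolerance.
    """
    ligand = scheme.ligand_id
    if ligand is None:
        raise InputError("interaction energy requires a scheme with a ligand fragment")
    store = store if store is not None else EnergyStore()
    retained = graph.all_retained()
    ligand_keys = [k for k in retained if ligand in k and k.order >= 2]
    protein_keys = [k for k in retained if ligand not in k]
    energy_of = _store_energy_of(scheme, backend, store, level)

    breakdown = NBodyBreakdown()
    cache: dict[SubsystemKey, float] = {}

    def cached(key: SubsystemKey) -> float:
        if key not in cache:
            cache[key] = energy_of(key)
        return cache[key]

    # order 1: the intact-ligand monomer of P:L and the standalone E_L are
    # the same geometry, so their difference is asserted zero, not assumed
    lig_key = SubsystemKey((ligand,))
    order1 = cached(lig_key) - cached(lig_key)
    if order1 != 0.0:
        raise EvaluationError("ligand monomer failed to cancel against E_L")
    per_order: dict[int, list[float]] = {1: [order1]}
    for key in sorted(ligand_keys):
        energies = {sub: cached(sub) for sub in key.subsets()}
        delta = n_body_correction(key, energies)
        per_order.setdefault(key.order, []).append(delta)
        breakdown.per_term_values.append((key, delta))
    breakdown.per_order_sums = {k: math.fsum(v) for k, v in sorted(per_order.items())}

    ligand_ledger = resum(ligand_keys)
    n_evaluated = len(ligand_ledger.support())

    if method == "cancellation":
        delta_e = breakdown.total
    elif method == "explicit":
        e_pl, _, _ = mbe_energy(retained, scheme, backend, store, level)
        e_p, _, _ = mbe_energy(protein_keys, scheme, backend, store, level)
        e_l = cached(lig_key)
        delta_e = e_pl - e_p - e_l
    else:
        raise InputError(f"unknown interaction-energy method {method!r}")

    return InteractionEnergyResult(
        delta_E_int=delta_e,
        per_order_contributions=dict(breakdown.per_order_sums),
        n_subsystems_evaluated=n_evaluated,
        audit=graph.status_counts(),
        breakdown=breakdown,
    )


@dataclass
class TermDistribution:
    histograms: dict[int, tuple[np.ndarray, np.ndarray]]  # order -> (counts, edges)
    flagged: list[tuple[SubsystemKey, float]]  # |dE| above the flag threshold
    flag_threshold: float


def term_distribution(
    breakdown: NBodyBreakdown, bin_width: float = 1.0, flag_threshold: float = 20.0
) -> TermDistribution:
    """Per-order histograms of dE values, flagging unusually large terms
    (|dE| > 20 kcal/mol by default, the scale at which individual
    contributions dominate a protein-ligand interaction energy)."""
    if bin_width <= 0:
        raise InputError("bin width must be positive")
    by_order: dict[int, list[float]] = {}
    for key, delta in breakdown.per_term_values:
        by_order.setdefault(key.order, []).append(delta)
    histograms = {}
    for order, values in sorted(by_order.items()):
        lo = math.floor(min(values) / bin_width) * bin_width
        hi = math.ceil(max(values) / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(values, bins=edges)
        histograms[order] = (counts, edges)
    flagged = [
        (key, delta)
        for key, delta in breakdown.per_term_values
        if abs(delta) > flag_threshold
    ]
    flagged.sort(key=lambda kv: -abs(kv[1]))
    return TermDistribution(histograms, flagged, flag_threshold)
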