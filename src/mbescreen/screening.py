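"""Distance and energy screening of candidate subsystems.

After the missing-parent (parental) screen admits a candidate k-mer, two
further, independent filters may remove it before any target-level energy is
spent on it:

* **distance screening** compares the subsystem extent R -- the maximum over
  fragment pairs of the minimum interatomic distance -- against a per-order
  cutoff d_k.  The default sense retains subsystems *within* the cutoff
  (remove iff R > d_k), which is the physically consistent reading: distant
  fragments interact weakly and only residues near the ligand matter.  The
  literal sense (remove iff R < d_k) is available for auditability via
  ``ScreeningConfig.distance_sense = "literal"``.

* **energy screening** computes the k-body correction at a cheap low level
  of theory and removes the candidate iff |dE_low| < tau_k (strict).  The
  correction is an inclusion-exclusion sum over *all* subsets of the key,
  whose low-level energies are fetched from the energy store regardless of
  the subsets' own graph status -- the definition of dE requires them to
  exist even when the corresponding nodes were screened out.

Both filters are pure predicates on a candidate, so the final retained set
is independent of the order in which the screens are applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from .backends import Backend, EnergyStore, store_get_or_compute
from .errors import InputError
from .graph import SubsystemKey
from .structure import FragmentationScheme

logger = logging.getLogger(__name__)


@dataclass
class ScreeningConfig:
    """Thresholds of the screening protocol.

    Absent entries in either map mean "no screening at that order".  The
    defaults mirror the best-performing published settings: tau_3B = 0.05
    kcal/mol, d_2 = 8 A, M = 1.  A two-body energy threshold has no single
    default (useful values span 0.05-1.00 kcal/mol) and must be configured.
    """

    tau_by_order: dict[int, float] = field(default_factory=lambda: {3: 0.05})
    d_by_order: dict[int, float] = field(default_factory=lambda: {2: 8.0})
    M: int = 1
    distance_sense: str = "physical"  # or "literal"

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.tau_by_order.values()):
            raise InputError("energy thresholds must be >= 0")
        if any(d < 0 for d in self.d_by_order.values()):
            raise InputError("distance cutoffs must be >= 0")
        if self.distance_sense not in ("physical", "literal"):
            raise InputError("distance_sense must be 'physical' or 'literal'")


class DistanceCalculator:
    """Caches minimum interfragment atom-atom distances for one scheme.

    Cap hydrogens are excluded: they are bookkeeping artifacts of the cut,
    not part of the chemical fragment.
    """

    def __init__(self, scheme: FragmentationScheme):
        self.scheme = scheme
        self._coords = [f.coords for f in scheme.fragments]
        self._pair_cache: dict[tuple[int, int], float] = {}

    def pair(self, a: int, b: int) -> float:
        if a == b:
            raise InputError("pair distance requires two distinct fragments")
        ij = (a, b) if a < b else (b, a)
        if ij not in self._pair_cache:
            self._pair_cache[ij] = float(cdist(self._coords[ij[0]], self._coords[ij[1]]).min())
        return self._pair_cache[ij]

    def subsystem(self, key: Iterable[int]) -> float:
        ids = tuple(key)
        if len(ids) < 2:
            raise InputError("subsystem distance is defined for order >= 2")
        return max(self.pair(a, b) for a, b in combinations(ids, 2))


def pair_distance(scheme: FragmentationScheme, a: int, b: int) -> float:
    """R_AB: minimum distance between any member atom of A and of B (A)."""
    return DistanceCalculator(scheme).pair(a, b)


def subsystem_distance(scheme: FragmentationScheme, key: Iterable[int]) -> float:
    """R of a k-mer: the maximum of R_AB over all fragment pairs in the key."""
    return DistanceCalculator(scheme).subsystem(key)


def distance_screen(
    candidates: Iterable[SubsystemKey],
    scheme: FragmentationScheme,
    config: ScreeningConfig,
    calculator: DistanceCalculator | None = None,
) -> tuple[set[SubsystemKey], set[SubsystemKey]]:
    """Partition candidates into (retained, removed_distance).

    Orders with no configured cutoff pass through untouched.  In the default
    physical sense a candidate is removed iff its subsystem distance exceeds
    d_k; strict inequality either way, so boundary values survive.
    """
    calc = calculator or DistanceCalculator(scheme)
    retained: set[SubsystemKey] = set()
    removed: set[SubsystemKey] = set()
    for key in candidates:
        d_k = config.d_by_order.get(key.order)
        if d_k is None:
            retained.add(key)
            continue
        r = calc.subsystem(key)
        if config.distance_sense == "physical":
            (removed if r > d_k else retained).add(key)
        else:
            (removed if r < d_k else retained).add(key)
    return retained, removed


def energy_screen(
    candidates: Iterable[SubsystemKey],
    scheme: FragmentationScheme,
    low_backend: Backend,
    config: ScreeningConfig,
    store: EnergyStore | None = None,
) -> tuple[set[SubsystemKey], set[SubsystemKey]]:
    """Partition candidates into (retained, removed_energy).

    A candidate of order k is removed iff |dE_low| < tau_k with dE_low the
    k-body correction by inclusion-exclusion over all subsets, evaluated at
    the low level through the (shared, deduplicating) energy store.  If any
    required subset energy fails to converge the candidate is retained
    conservatively and the incident is logged.
    """
    from .assembly import n_body_correction  # local import: avoid module cycle

    store = store if store is not None else EnergyStore()
    retained: set[SubsystemKey] = set()
    removed: set[SubsystemKey] = set()
    for key in sorted(candidates):
        tau = config.tau_by_order.get(key.order)
        if tau is None:
            retained.add(key)
            continue
        energies: dict[SubsystemKey, float] = {}
        ok = True
        for sub in key.subsets():
            rec = store_get_or_compute(store, sub, "low", low_backend, scheme)
            if not rec.converged:
                logger.warning(
                    "low-level energy of %s failed to converge; retaining %s unscreened",
                    tuple(sub), tuple(key),
                )
                ok = False
                break
            energies[sub] = rec.energy
        if not ok:
            retained.add(key)
            continue
        delta = n_body_correction(key, energies)
        (removed if abs(delta) < tau else retained).add(key)
    return retained, removed


def screening_report_rows(
    keys_with_status: Iterable[tuple[SubsystemKey, str, str]],
    scheme: FragmentationScheme,
    low_backend: Backend | None = None,
    store: EnergyStore | None = None,
) -> list[dict]:
    """Tabulate screening decisions: key, order, R, dE_low, decision, reason."""
    from .assembly import n_body_correction

    calc = DistanceCalculator(scheme)
    rows = []
    for key, decision, reason in keys_with_status:
        r = calc.subsystem(key) if key.order >= 2 else 0.0
        delta = float("nan")
        if low_backend is not None and store is not None:
            energies = {}
            for sub in key.subsets():
                rec = store_get_or_compute(store, sub, "low", low_backend, scheme)
                if not rec.converged:
                    break
                energies[sub] = rec.energy
            else:
                delta = n_body_correction(key, energies)
        rows.append(
            {
                "key": "+".join(map(str, key)),
                "order": key.order,
                "R_angstrom": round(r, 6),
                "dE_low_kcal": None if delta != delta else round(delta, 8),
                "decision": decision,
                "reason": reason,
            }
        )
    return rows
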