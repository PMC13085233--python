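"""Inclusion-exclusion corrections, resummation coefficients, MBE totals,
and the protein-ligand interaction energy."""

from itertools import combinations

import numpy as np
import pytest

from mbescreen.assembly import (
    complete_mbe_coefficient,
    interaction_energy,
    mbe_energy,
    n_body_correction,
    resum,
    term_distribution,
)
from mbescreen.backends import EnergyStore, ToyBackend, ToyPotentialSpec, store_get_or_compute
from mbescreen.errors import DependencyError, InputError
from mbescreen.fixtures import FixtureSpec, make_cluster, make_toy_complex
from mbescreen.graph import InteractionGraph, SubsystemKey, subsystem_count
from mbescreen.pipeline import build_screened_graph
from mbescreen.screening import ScreeningConfig

from conftest import random_screened_graph


def _unscreened_graph(n, n_max):
    from mbescreen.graph import build_layer_propose_and_check

    g = InteractionGraph(n, M=n, n_max=n_max)
    for k in range(2, n_max + 1):
        g.add_layer(k, build_layer_propose_and_check(g, k))
    return g


def _recursive_delta(key, energies, memo=None):
    """Independent oracle: dE_S = E_S - sum of all lower dE_T, T strict
    nonempty subset -- the explicit low-order pattern extended upward."""
    memo = {} if memo is None else memo
    if key in memo:
        return memo[key]
    total = energies[key]
    for sub in key.subsets(include_self=False):
        total -= _recursive_delta(sub, energies, memo)
    memo[key] = total
    return total


class TestNBodyCorrection:
    def test_two_body_arithmetic(self):
        energies = {
            SubsystemKey((0,)): 1.0,
            SubsystemKey((1,)): 2.0,
            SubsystemKey((0, 1)): 4.0,
        }
        assert n_body_correction(SubsystemKey((0, 1)), energies) == pytest.approx(1.0)

    def test_three_body_matches_explicit_formula(self):
        rng = np.random.default_rng(1)
        energies = {SubsystemKey(c): float(rng.normal()) for r in (1, 2, 3)
                    for c in combinations(range(3), r)}
        e = lambda *ids: energies[SubsystemKey(ids)]
        d_ab = e(0, 1) - e(0) - e(1)
        d_ac = e(0, 2) - e(0) - e(2)
        d_bc = e(1, 2) - e(1) - e(2)
        explicit = e(0, 1, 2) - d_ab - d_ac - d_bc - e(0) - e(1) - e(2)
        assert n_body_correction(SubsystemKey((0, 1, 2)), energies) == pytest.approx(explicit)

    def test_order_five_matches_recursive_oracle(self):
        rng = np.random.default_rng(2)
        key = SubsystemKey(range(5))
        energies = {sub: float(rng.normal()) for sub in key.subsets()}
        expected = _recursive_delta(key, energies)
        assert n_body_correction(key, energies) == pytest.approx(expected, abs=1e-10)

    def test_missing_subset_names_the_culprit(self):
        energies = {SubsystemKey((0,)): 1.0, SubsystemKey((0, 1)): 4.0}
        with pytest.raises(DependencyError, match=r"\(1,\)"):
            n_body_correction(SubsystemKey((0, 1)), energies)

    def test_pairwise_additive_energies_have_zero_trimer_correction(self):
        # E(S) built as a pure sum of pair terms
        pair = {(a, b): float(np.random.default_rng(a * 10 + b).normal())
                for a, b in combinations(range(3), 2)}
        energies = {}
        for r in (1, 2, 3):
            for c in combinations(range(3), r):
                energies[SubsystemKey(c)] = sum(
                    v for (a, b), v in pair.items() if a in c and b in c
                )
        assert n_body_correction(SubsystemKey((0, 1, 2)), energies) == pytest.approx(0.0, abs=1e-12)


class TestResummation:
    def test_complete_mbe2_three_fragments(self):
        g = _unscreened_graph(3, 2)
        ledger = resum(g.all_retained(2))
        for dimer in combinations(range(3), 2):
            assert ledger.coefficient(SubsystemKey(dimer)) == 1
        for mono in range(3):
            assert ledger.coefficient(SubsystemKey((mono,))) == -1

    def test_full_order_telescopes_to_supersystem_only(self):
        for n in (3, 5, 7):
            g = _unscreened_graph(n, n)
            ledger = resum(g.all_retained(n))
            assert ledger.entries == {SubsystemKey(range(n)): 1}

    @pytest.mark.parametrize("N", [4, 6, 10])
    def test_closed_form_coefficients_all_orders(self, N):
        for n in range(1, N + 1):
            g = _unscreened_graph(N, n)
            ledger = resum(g.all_retained(n))
            for k in range(1, n + 1):
                expected = complete_mbe_coefficient(N, n, k)
                for combo in combinations(range(N), k):
                    assert ledger.coefficient(SubsystemKey(combo)) == expected

    def test_screened_ledger_equals_term_by_term_sum(self, cluster8):
        _atoms, scheme, potential = cluster8
        rng = np.random.default_rng(23)
        g = random_screened_graph(scheme.N, 4, 1, rng)
        backend = ToyBackend(potential)
        store = EnergyStore()
        retained = g.all_retained(4)
        total, breakdown, ledger = mbe_energy(retained, scheme, backend, store)
        assert total == pytest.approx(breakdown.total, abs=1e-9)
        assert sum(breakdown.per_order_sums.values()) == pytest.approx(total, abs=1e-9)


class TestMBEEnergy:
    def test_order_one_is_sum_of_monomer_energies(self, cluster5):
        _atoms, scheme, potential = cluster5
        backend = ToyBackend(potential)
        store = EnergyStore()
        retained = [SubsystemKey((i,)) for i in range(scheme.N)]
        total, _, _ = mbe_energy(retained, scheme, backend, store)
        monos = sum(
            store_get_or_compute(store, SubsystemKey((i,)), "target", backend, scheme).energy
            for i in range(scheme.N)
        )
        assert total == pytest.approx(monos)

    def test_unscreened_full_order_equals_supersystem(self, cluster5):
        _atoms, scheme, potential = cluster5
        backend = ToyBackend(potential)
        store = EnergyStore()
        g = _unscreened_graph(scheme.N, scheme.N)
        total, _, _ = mbe_energy(g.all_retained(), scheme, backend, store)
        sup = store_get_or_compute(
            store, SubsystemKey(range(scheme.N)), "target", backend, scheme
        ).energy
        assert total == pytest.approx(sup, abs=1e-8)

    def test_pairwise_backend_mbe2_is_exact(self, cluster5):
        _atoms, scheme, potential = cluster5
        spec0 = ToyPotentialSpec(charges=potential.charges, lj=potential.lj, alpha=0.0)
        backend = ToyBackend(spec0)
        store = EnergyStore()
        g = _unscreened_graph(scheme.N, 2)
        total, _, _ = mbe_energy(g.all_retained(2), scheme, backend, store)
        sup = store_get_or_compute(
            store, SubsystemKey(range(scheme.N)), "target", backend, scheme
        ).energy
        assert total == pytest.approx(sup, abs=1e-10)


class TestInteractionEnergy:
    def test_requires_a_ligand(self, cluster5):
        _atoms, scheme, potential = cluster5
        g = _unscreened_graph(scheme.N, 2)
        with pytest.raises(InputError):
            interaction_energy(scheme, g, ToyBackend(potential))

    def test_decoupled_ligand_gives_zero(self):
        _atoms, scheme, potential = make_toy_complex(FixtureSpec(kind="toy_complex", N=5, seed=3))
        lig = scheme.ligand_id
        charges = dict(potential.charges)
        for atom in scheme.fragments[lig].member_atoms:
            charges[atom.serial] = 0.0
        lj = {el: (0.0, 0.0) for el in potential.lj}
        alpha = dict(potential.alpha)
        alpha[lig] = 0.0
        decoupled = ToyPotentialSpec(charges=charges, lj=lj, alpha=alpha)
        g = _unscreened_graph(scheme.N, 3)
        result = interaction_energy(scheme, g, ToyBackend(decoupled))
        assert result.delta_E_int == pytest.approx(0.0, abs=1e-9)

    def test_pairwise_mbe2_equals_direct_ligand_pair_sum(self):
        _atoms, scheme, potential = make_toy_complex(FixtureSpec(kind="toy_complex", N=6, seed=9))
        spec0 = ToyPotentialSpec(charges=potential.charges, lj=potential.lj, alpha=0.0)
        backend = ToyBackend(spec0)
        store = EnergyStore()
        g = _unscreened_graph(scheme.N, 2)
        result = interaction_energy(scheme, g, backend, store)
        lig = scheme.ligand_id
        direct = 0.0
        for a in range(scheme.N):
            if a == lig:
                continue
            e_al = store_get_or_compute(store, SubsystemKey((a, lig)), "target", backend, scheme).energy
            e_a = store_get_or_compute(store, SubsystemKey((a,)), "target", backend, scheme).energy
            e_l = store_get_or_compute(store, SubsystemKey((lig,)), "target", backend, scheme).energy
            direct += e_al - e_a - e_l
        assert result.delta_E_int == pytest.approx(direct, abs=1e-9)

    @pytest.mark.parametrize("n", [2, 3, 4, 6])
    def test_cancellation_shortcut_equals_explicit_difference(self, n):
        _atoms, scheme, potential = make_toy_complex(FixtureSpec(kind="toy_complex", N=6, seed=5))
        backend = ToyBackend(potential)
        store = EnergyStore()
        g = build_screened_graph(
            scheme, ScreeningConfig(tau_by_order={3: 0.05}, d_by_order={}), n, backend, store
        )
        shortcut = interaction_energy(scheme, g, backend, store, method="cancellation")
        explicit = interaction_energy(scheme, g, backend, store, method="explicit")
        assert shortcut.delta_E_int == pytest.approx(explicit.delta_E_int, abs=1e-8)

    def test_order_one_contribution_is_zero(self, complex6):
        _atoms, scheme, potential = complex6
        g = _unscreened_graph(scheme.N, 2)
        result = interaction_energy(scheme, g, ToyBackend(potential))
        assert result.per_order_contributions[1] == 0.0

    def test_subsumption_reported_via_ledger_support(self, complex6):
        # with aggressive screening, raising n can lower the number of
        # distinct evaluations as low-order terms are subsumed
        _atoms, scheme, potential = complex6
        result = {}
        for n in (2, 3):
            backend = ToyBackend(potential)
            store = EnergyStore()
            g = build_screened_graph(
                scheme, ScreeningConfig(tau_by_order={}, d_by_order={}), n, backend, store
            )
            result[n] = interaction_energy(scheme, g, backend, store).n_subsystems_evaluated
        assert result[3] > 0 and result[2] > 0  # counts reported per run


class TestTermDistribution:
    def test_bin_counts_conserve_terms(self, complex6):
        _atoms, scheme, potential = complex6
        backend = ToyBackend(potential)
        store = EnergyStore()
        g = _unscreened_graph(scheme.N, 3)
        result = interaction_energy(scheme, g, backend, store)
        dist = term_distribution(result.breakdown, bin_width=0.5)
        for order, (counts, _edges) in dist.histograms.items():
            n_terms = sum(1 for key, _ in result.breakdown.per_term_values if key.order == order)
            assert counts.sum() == n_terms

    def test_dominant_ligand_ion_pair_is_flagged(self, complex6):
        _atoms, scheme, potential = complex6
        backend = ToyBackend(potential)
        store = EnergyStore()
        g = _unscreened_graph(scheme.N, 2)
        result = interaction_energy(scheme, g, backend, store)
        dist = term_distribution(result.breakdown)
        assert dist.flagged, "the ligand-ion pair should exceed 20 kcal/mol"
        top_key, top_value = dist.flagged[0]
        ion = next(f.id for f in scheme.fragments if f.role == "ion_group")
        assert set(top_key) == {scheme.ligand_id, ion}

    def test_empty_breakdown_yields_empty_histograms(self):
        from mbescreen.assembly import NBodyBreakdown

        dist = term_distribution(NBodyBreakdown())
        assert dist.histograms == {} and dist.flagged == []
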