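"""Shared fixtures: a synthetic tripeptide structure, toy clusters and
complexes, and helpers for building randomly screened interaction graphs."""

from __future__ import annotations

import numpy as np
import pytest

from mbescreen.fixtures import FixtureSpec, make_cluster, make_toy_complex
from mbescreen.graph import InteractionGraph, NodeStatus, SubsystemKey, build_layer_propose_and_check
from mbescreen.structure import AtomRecord


def tripeptide_atoms() -> list[AtomRecord]:
    """Synthetic extended three-residue peptide (ALA-GLY-ALA-like backbone).

    Residues are spaced so each carbonyl C sits ~1.7 A from the next amide
    N (a peptide bond) while no other interresidue contact is bonded.
    """
    atoms = []
    serial = 1
    resnames = ["ALA", "GLY", "ALA"]
    for i, resname in enumerate(resnames):
        off = np.array([3.8 * i, 0.0, 0.0])
        backbone = [
            ("N", "N", np.array([0.0, 0.0, 0.0])),
            ("CA", "C", np.array([1.46, 0.0, 0.0])),
            ("C", "C", np.array([2.46, 1.06, 0.0])),
            ("O", "O", np.array([2.46, 2.26, 0.0])),
        ]
        if resname == "ALA":
            backbone.append(("CB", "C", np.array([1.46, -1.52, 0.0])))
        for name, element, pos in backbone:
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, element=element, position=pos + off,
                    residue_name=resname, residue_index=i + 1, chain_id="A",
                )
            )
            serial += 1
    return atoms


@pytest.fixture
def tripeptide():
    return tripeptide_atoms()


@pytest.fixture(scope="session")
def cluster5():
    return make_cluster(FixtureSpec(kind="cluster", N=5, seed=11))


@pytest.fixture(scope="session")
def cluster8():
    return make_cluster(FixtureSpec(kind="cluster", N=8, seed=7))


@pytest.fixture(scope="session")
def complex6():
    return make_toy_complex(FixtureSpec(kind="toy_complex", N=6, seed=5))


def point_scheme(fragment_atom_specs):
    """Build a scheme directly from [(element, xyz), ...] lists per fragment;
    serials are assigned 1, 2, ... in listing order."""
    from mbescreen.structure import Fragment, FragmentationScheme

    fragments = []
    serial = 1
    for fid, spec in enumerate(fragment_atom_specs):
        members = []
        for element, pos in spec:
            members.append(
                AtomRecord(
                    serial=serial, name=f"{element}{serial}", element=element,
                    position=np.asarray(pos, float), residue_name="FRG",
                    residue_index=fid + 1, chain_id="A",
                )
            )
            serial += 1
        fragments.append(Fragment(id=fid, role="residue", member_atoms=members))
    return FragmentationScheme(fragments)


def random_screened_graph(
    n_fragments: int,
    up_to: int,
    M: int,
    rng: np.random.Generator,
    keep_prob: float = 0.6,
) -> InteractionGraph:
    """Graph with layers 2..up_to built by the parental screen and random
    eliminations: each admitted candidate survives with ``keep_prob``."""
    graph = InteractionGraph(n_fragments, M=M, n_max=up_to + 1)
    for k in range(2, up_to + 1):
        candidates = sorted(build_layer_propose_and_check(graph, k))
        keep_mask = rng.random(len(candidates)) < keep_prob
        retained = [c for c, keep in zip(candidates, keep_mask) if keep]
        removed = [
            (c, NodeStatus.REMOVED_ENERGY)
            for c, keep in zip(candidates, keep_mask)
            if not keep
        ]
        graph.add_layer(k, retained, removed)
    return graph
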