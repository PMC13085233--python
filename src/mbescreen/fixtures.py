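"""Reproducible synthetic inputs for the expansion machinery.

Two families of fixtures cover the structural regimes the method is built
for:

``make_cluster``
    N rigid water-like triatomic fragments packed by rejection sampling at a
    condensed-phase density (30 A^3 per fragment, 2.6 A minimum separation).
    This emulates the geometry of hydrogen-bonded molecular clusters -- the
    regime where distance screening produces a sparse interaction graph --
    without pretending to model water physics.

``make_toy_complex``
    A protein-ligand-like arrangement: one central multi-atom ligand with
    net charge -1, a divalent (+2) single-atom ion within 3 A of the ligand
    (close enough to dominate the two-body spectrum, and deliberately *not*
    mergeable with the ligand), one -1 "acidic residue" adjacent, and
    neutral triatomic residues shell-packed out to a configurable radius.
    All fragments are polarizable so corrections are nonzero at every order.

Both generators are exactly reproducible from the seed, and their output
round-trips through :func:`mbescreen.structure.fragment_structure`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TextIO

import numpy as np

from .backends import ToyPotentialSpec
from .errors import GenerationError
from .structure import (
    AtomRecord,
    FragmentationConfig,
    FragmentationScheme,
    fragment_structure,
)

#: water-like per-fragment volume (A^3) used to size cluster boxes
FRAGMENT_VOLUME = 30.0
#: default TIP3P-like charges and geometry for neutral triatomics
O_CHARGE, H_CHARGE = -0.834, 0.417
OH_LENGTH, HOH_ANGLE = 0.9572, np.deg2rad(104.52)

DEFAULT_LJ = {
    "O": (0.152, 3.151),
    "C": (0.10, 3.40),
    "N": (0.17, 3.25),
    "Zn": (0.0125, 1.96),
    "H": (0.0, 0.0),
}

_MAX_ATTEMPTS = 100_000


@dataclass
class FixtureSpec:
    kind: str  # "cluster" | "toy_complex"
    N: int
    min_separation: float = 2.6
    box_or_radius: float | None = None
    seed: int = 0
    charge_pattern: dict[str, int] = field(
        default_factory=lambda: {"ligand": -1, "ion": 2, "acid": -1}
    )
    alpha: float = 1.2
    ligand_alpha: float = 2.5


def make_fixture(spec: FixtureSpec):
    if spec.kind == "cluster":
        return make_cluster(spec)
    if spec.kind == "toy_complex":
        return make_toy_complex(spec)
    raise GenerationError(f"unknown fixture kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# Cluster
# ---------------------------------------------------------------------------


def make_cluster(spec: FixtureSpec) -> tuple[list[AtomRecord], FragmentationScheme, ToyPotentialSpec]:
    """Pack N rigid triatomics into a cube with a minimum center separation."""
    if spec.N < 2:
        raise GenerationError("cluster fixtures need N >= 2 fragments")
    rng = np.random.default_rng(spec.seed)
    edge = spec.box_or_radius or (FRAGMENT_VOLUME * spec.N) ** (1.0 / 3.0)
    centers = _pack_box(rng, spec.N, edge, spec.min_separation)

    atoms: list[AtomRecord] = []
    charges: dict[int, float] = {}
    serial = 1
    for i, center in enumerate(centers):
        for name, element, q, pos in _triatomic(rng, center):
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, element=element, position=pos,
                    residue_name="FRG", residue_index=i + 1, chain_id="A",
                )
            )
            charges[serial] = q
            serial += 1
    scheme = fragment_structure(atoms, FragmentationConfig())
    potential = ToyPotentialSpec(
        charges=charges,
        lj=dict(DEFAULT_LJ),
        alpha={f.id: spec.alpha for f in scheme.fragments},
    )
    return atoms, scheme, potential


def _pack_box(rng: np.random.Generator, n: int, edge: float, min_sep: float) -> np.ndarray:
    centers: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(_MAX_ATTEMPTS):
            p = rng.uniform(0.0, edge, 3)
            if all(np.linalg.norm(p - c) >= min_sep for c in centers):
                centers.append(p)
                break
        else:
            raise GenerationError(
                f"could not place fragment {len(centers) + 1}/{n} in a {edge:.1f} A box; "
                "increase box_or_radius or reduce min_separation"
            )
    return np.array(centers)


def _triatomic(rng: np.random.Generator, center: np.ndarray):
    """Water-like rigid fragment: charged center, two positive satellites."""
    axis = _random_unit(rng)
    ortho = _random_unit(rng)
    ortho -= axis * (ortho @ axis)
    norm = np.linalg.norm(ortho)
    if norm < 1e-8:  # pathological draw; derandomised retry is overkill
        ortho = np.cross(axis, [1.0, 0.0, 0.0])
        norm = np.linalg.norm(ortho)
    ortho /= norm
    half = HOH_ANGLE / 2.0
    h1 = center + OH_LENGTH * (np.cos(half) * axis + np.sin(half) * ortho)
    h2 = center + OH_LENGTH * (np.cos(half) * axis - np.sin(half) * ortho)
    return [
        ("O", "O", O_CHARGE, center),
        ("H1", "H", H_CHARGE, h1),
        ("H2", "H", H_CHARGE, h2),
    ]


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# Toy protein-ligand complex
# ---------------------------------------------------------------------------


def make_toy_complex(spec: FixtureSpec) -> tuple[list[AtomRecord], FragmentationScheme, ToyPotentialSpec]:
    """Ligand + divalent ion + acidic residue + neutral shell residues."""
    if spec.N < 3:
        raise GenerationError("toy complex needs N >= 3 fragments")
    rng = np.random.default_rng(spec.seed)
    q_ligand = spec.charge_pattern.get("ligand", -1)
    q_ion = spec.charge_pattern.get("ion", 2)
    q_acid = spec.charge_pattern.get("acid", -1)

    atoms: list[AtomRecord] = []
    charges: dict[int, float] = {}
    serial = 1

    # ligand: central atom plus four satellites in the xy plane, net q_ligand
    lig_atoms = [
        ("C1", "C", q_ligand - 4 * 0.1, np.zeros(3)),
        ("O1", "O", 0.1, np.array([1.4, 0.0, 0.0])),
        ("N1", "N", 0.1, np.array([-1.4, 0.0, 0.0])),
        ("C2", "C", 0.1, np.array([0.0, 1.4, 0.0])),
        ("C3", "C", 0.1, np.array([0.0, -1.4, 0.0])),
    ]
    for name, element, q, pos in lig_atoms:
        atoms.append(
            AtomRecord(serial=serial, name=name, element=element, position=pos,
                       residue_name="LIG", residue_index=900, chain_id="L", is_ligand=True)
        )
        charges[serial] = q
        serial += 1

    # divalent ion on the z axis, inside 3 A of the ligand but outside the
    # 2.5 A merge cutoff of every residue
    ion_pos = np.array([0.0, 0.0, 2.9])
    atoms.append(
        AtomRecord(serial=serial, name="ZN", element="Zn", position=ion_pos,
                   residue_name="ZN", residue_index=901, chain_id="L", is_ion=True)
    )
    charges[serial] = float(q_ion)
    serial += 1

    # acidic residue adjacent to the ligand
    acid_center = np.array([0.0, 4.6, 0.0])
    for (name, element, q, pos), dq in zip(_triatomic(rng, acid_center), (q_acid, 0.0, 0.0)):
        atoms.append(
            AtomRecord(serial=serial, name=name, element=element, position=pos,
                       residue_name="ACD", residue_index=1, chain_id="A")
        )
        charges[serial] = q + dq
        serial += 1

    # neutral residues shell-packed between r_inner and r_outer
    n_shell = spec.N - 3
    r_inner = 5.0
    r_outer = spec.box_or_radius or max(
        8.0, (r_inner**3 + FRAGMENT_VOLUME * 2.0 * max(n_shell, 1) * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    )
    placed = [np.zeros(3), ion_pos, acid_center]
    for i in range(n_shell):
        for _attempt in range(_MAX_ATTEMPTS):
            direction = _random_unit(rng)
            u = rng.uniform(r_inner**3, r_outer**3)
            center = direction * u ** (1.0 / 3.0)
            if np.linalg.norm(center - ion_pos) < 4.0:
                continue
            if all(np.linalg.norm(center - c) >= spec.min_separation for c in placed):
                placed.append(center)
                break
        else:
            raise GenerationError(
                f"could not place shell residue {i + 1}/{n_shell}; increase box_or_radius"
            )
        for name, element, q, pos in _triatomic(rng, center):
            atoms.append(
                AtomRecord(serial=serial, name=name, element=element, position=pos,
                           residue_name="FRG", residue_index=i + 2, chain_id="A")
            )
            charges[serial] = q
            serial += 1

    config = FragmentationConfig(
        ligand_resnames=frozenset({"LIG"}),
        residue_charges={"ACD": q_acid},
        ion_charges={"ZN": q_ion},
        ligand_charge=q_ligand,
    )
    scheme = fragment_structure(atoms, config)
    alpha = {f.id: spec.alpha for f in scheme.fragments}
    lig_id = scheme.ligand_id
    assert lig_id is not None
    alpha[lig_id] = spec.ligand_alpha
    potential = ToyPotentialSpec(charges=charges, lj=dict(DEFAULT_LJ), alpha=alpha)
    return atoms, scheme, potential


# ---------------------------------------------------------------------------
# Plain-text emission
# ---------------------------------------------------------------------------


def write_fixture_pdb(atoms: list[AtomRecord], stream: TextIO) -> None:
    """Minimal fixed-column PDB emission (ATOM for residues, HETATM for
    ligand/ion records) so fixtures round-trip through the PDB reader."""
    for a in atoms:
        record = "HETATM" if (a.is_ligand or a.is_ion) else "ATOM  "
        x, y, z = a.position
        stream.write(
            f"{record}{a.serial:>5} {a.name:<4}{a.residue_name:>4} {a.chain_id}"
            f"{a.residue_index:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2}\n"
        )
    stream.write("END\n")


def write_potential_table(potential: ToyPotentialSpec, stream: TextIO) -> None:
    stream.write("# section\tkey\tvalues\n")
    for serial in sorted(potential.charges):
        stream.write(f"charge\t{serial}\t{potential.charges[serial]:.6f}\n")
    for element in sorted(potential.lj):
        eps, sigma = potential.lj[element]
        stream.write(f"lj\t{element}\t{eps:.6f}\t{sigma:.6f}\n")
    if isinstance(potential.alpha, dict):
        for fid in sorted(potential.alpha):
            stream.write(f"alpha\t{fid}\t{potential.alpha[fid]:.6f}\n")
    else:
        stream.write(f"alpha\t*\t{float(potential.alpha):.6f}\n")


def read_potential_table(stream: TextIO) -> ToyPotentialSpec:
    charges: dict[int, float] = {}
    lj: dict[str, tuple[float, float]] = {}
    alpha: dict[int, float] | float = {}
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "charge":
            charges[int(parts[1])] = float(parts[2])
        elif parts[0] == "lj":
            lj[parts[1]] = (float(parts[2]), float(parts[3]))
        elif parts[0] == "alpha":
            if parts[1] == "*":
                alpha = float(parts[2])
            else:
                assert isinstance(alpha, dict)
                alpha[int(parts[1])] = float(parts[2])
    return ToyPotentialSpec(charges=charges, lj=lj, alpha=alpha)
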