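"""Structure input and residue-level fragmentation.

Protein-ligand structures are fragmented into single amino-acid residues by
cutting each Calpha-C(O) backbone bond and capping both severed valences with
hydrogen atoms; the carbonyl group travels with the following residue, so a
fragment is the chemically sensible unit N-Calpha-sidechain plus the
preceding peptide carbonyl.  Ionic cofactors are merged into one monomer with
every residue that has an atom strictly within the merge cutoff (2.5 A by
default) -- except the ligand, which must stay a separate fragment so that a
protein-ligand interaction energy can be defined at all.  The ligand is never
fragmented.

Subsystem geometries are unions of fragment member atoms; a cap hydrogen is
emitted only when the bond it replaces leads *outside* the subsystem.  When
both bond partners are inside, the caps are dropped and the original bond is
restored, so the all-fragment subsystem reproduces the input structure
exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import numpy as np

from .errors import FormatError, FragmentationError, InputError
from .graph import SubsystemKey

logger = logging.getLogger(__name__)

#: strict upper bound (A) for recognising a C-N peptide bond between residues
PEPTIDE_BOND_CUTOFF = 1.8

DEFAULT_RESIDUE_CHARGES = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}
DEFAULT_ION_CHARGES = {
    "ZN": 2, "MG": 2, "CA": 2, "MN": 2, "FE": 2, "CU": 2, "NI": 2,
    "NA": 1, "K": 1, "LI": 1, "CL": -1, "BR": -1, "DIV": 2,
}
WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP", "TIP3"})


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    residue_name: str
    residue_index: int
    chain_id: str
    is_ligand: bool = False
    is_ion: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise InputError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not re.fullmatch(r"[A-Z][a-z]?", self.element):
            raise InputError(f"atom {self.serial}: invalid element symbol {self.element!r}")


@dataclass(frozen=True)
class CapAtom:
    """Synthetic hydrogen replacing a cut covalent bond.

    ``host_fragment`` owns the cap; the cap is emitted in a subsystem geometry
    only if ``partner_fragment`` is absent from the subsystem.
    """

    serial: int  # negative, unique within a scheme
    position: np.ndarray
    host_fragment: int
    partner_fragment: int
    element: str = "H"


@dataclass
class Fragment:
    id: int
    role: str  # residue | ion_group | ligand
    member_atoms: list[AtomRecord]
    cap_atoms: list[CapAtom] = field(default_factory=list)
    formal_charge: int = 0
    spin_multiplicity: int = 1
    label: str = ""

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.member_atoms])


@dataclass
class FragmentationScheme:
    fragments: list[Fragment]

    @property
    def N(self) -> int:
        return len(self.fragments)

    @property
    def ligand_id(self) -> int | None:
        for frag in self.fragments:
            if frag.role == "ligand":
                return frag.id
        return None

    @property
    def total_charge(self) -> int:
        return sum(f.formal_charge for f in self.fragments)

    def __getitem__(self, fragment_id: int) -> Fragment:
        return self.fragments[fragment_id]

    def validate(self) -> None:
        for i, frag in enumerate(self.fragments):
            if frag.id != i:
                raise InputError("fragment ids must be 0..N-1 in order")
        serials = [a.serial for f in self.fragments for a in f.member_atoms]
        if len(serials) != len(set(serials)):
            raise InputError("an atom belongs to more than one fragment")


@dataclass
class FragmentMapEntry:
    fragment_id: int
    role: str
    charge: int
    members: str  # "A:12,A:13" residue tokens or "atoms:0-2,7" index spec


@dataclass
class FragmentationConfig:
    ligand_resnames: frozenset[str] = frozenset({"LIG"})
    ion_resnames: frozenset[str] = frozenset(DEFAULT_ION_CHARGES)
    ion_merge_cutoff: float = 2.5
    keep_waters: bool = False
    residue_charges: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_RESIDUE_CHARGES))
    charge_overrides: dict[tuple[str, int], int] = field(default_factory=dict)
    ion_charges: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ION_CHARGES))
    ligand_charge: int = 0
    cap_bond_length: float = 1.09
    default_multiplicity: int = 1
    fragment_map: list[FragmentMapEntry] | None = None


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_structure(
    path: str,
    format: str | None = None,
    config: FragmentationConfig | None = None,
) -> list[AtomRecord]:
    """Read a PDB or XYZ file into atom records.

    PDB: residue indices and chain ids are preserved as written (1-based);
    ligand and ion flags are set from HETATM records using the resname sets
    in ``config``.  XYZ carries no residue metadata, so a fragment map must
    be supplied in ``config``; atoms are then tagged with their mapped
    fragment as a pseudo-residue.
    """
    config = config or FragmentationConfig()
    if format is None:
        format = "xyz" if path.lower().endswith(".xyz") else "pdb"
    if format == "pdb":
        atoms = _read_pdb(path, config)
    elif format == "xyz":
        atoms = _read_xyz_structure(path, config)
    else:
        raise InputError(f"unknown structure format {format!r}")
    if not atoms:
        raise InputError(f"{path}: structure contains no atoms")
    return atoms


def _read_pdb(path: str, config: FragmentationConfig) -> list[AtomRecord]:
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(path)
        arr = pdb_file.get_structure(model=1, extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises a mix of error types
        raise FormatError(f"{path}: could not parse as PDB ({exc})") from exc
    atoms: list[AtomRecord] = []
    for i in range(arr.array_length()):
        res_name = str(arr.res_name[i]).strip().upper()
        hetero = bool(arr.hetero[i])
        element = str(arr.element[i]).strip().capitalize()
        atoms.append(
            AtomRecord(
                serial=int(arr.atom_id[i]),
                name=str(arr.atom_name[i]).strip(),
                element=element,
                position=arr.coord[i].astype(float),
                residue_name=res_name,
                residue_index=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]).strip() or "A",
                is_ligand=hetero and res_name in config.ligand_resnames,
                is_ion=hetero and res_name in config.ion_resnames,
            )
        )
    return atoms


def _read_xyz_structure(path: str, config: FragmentationConfig) -> list[AtomRecord]:
    if not config.fragment_map:
        raise InputError(
            "XYZ input carries no residue metadata; a fragment map is required in the config"
        )
    elements, coords, _charge, _mult = read_xyz(path)
    owner: dict[int, FragmentMapEntry] = {}
    for entry in config.fragment_map:
        for idx in _parse_atom_spec(entry.members):
            owner[idx] = entry
    atoms = []
    for i, (el, xyz) in enumerate(zip(elements, coords)):
        try:
            entry = owner[i]
        except KeyError:
            raise InputError(f"atom index {i} not covered by the fragment map") from None
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=f"{el}{i}",
                element=el.capitalize(),
                position=xyz,
                residue_name={"ligand": "LIG", "ion_group": "ION"}.get(entry.role, "FRG"),
                residue_index=entry.fragment_id + 1,
                chain_id="A",
                is_ligand=entry.role == "ligand",
                is_ion=entry.role == "ion_group",
            )
        )
    return atoms


def _parse_atom_spec(spec: str) -> list[int]:
    if not spec.startswith("atoms:"):
        raise InputError(f"XYZ fragment map members must use 'atoms:' specs, got {spec!r}")
    out: list[int] = []
    for token in spec[len("atoms:"):].split(","):
        if "-" in token:
            lo, hi = token.split("-")
            out.extend(range(int(lo), int(hi) + 1))
        else:
            out.append(int(token))
    return out


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def fragment_structure(
    atoms: Sequence[AtomRecord], config: FragmentationConfig | None = None
) -> FragmentationScheme:
    """Apply the residue fragmentation protocol to a structure.

    One fragment per residue (backbone cut at Calpha-C(O), both severed
    valences hydrogen-capped), ions merged with every non-ligand residue
    strictly within ``config.ion_merge_cutoff``, ligand kept whole.
    """
    config = config or FragmentationConfig()
    if not atoms:
        raise InputError("cannot fragment an empty structure")
    atoms = [
        a for a in atoms
        if config.keep_waters or a.residue_name not in WATER_RESNAMES or a.is_ligand
    ]
    if not atoms:
        raise InputError("structure is empty after water removal")

    ligand_atoms = [a for a in atoms if a.is_ligand]
    ion_atoms = [a for a in atoms if a.is_ion and not a.is_ligand]
    residue_atoms = [a for a in atoms if not a.is_ligand and not a.is_ion]

    # group residue and ion atoms into units by (chain, residue index)
    units: dict[tuple[str, int, bool], list[AtomRecord]] = {}
    unit_order: list[tuple[str, int, bool]] = []
    for a in residue_atoms + ion_atoms:
        uid = (a.chain_id, a.residue_index, a.is_ion)
        if uid not in units:
            units[uid] = []
            unit_order.append(uid)
        units[uid].append(a)

    # -- peptide cuts ------------------------------------------------------
    # a cut is demanded between residues r1 -> r2 whenever the carbonyl C of
    # r1 is covalently bonded to the amide N of r2
    cuts: list[dict] = []
    residue_uids = [u for u in unit_order if not u[2]]
    for u1 in residue_uids:
        group1 = units[u1]
        c_atom = _atom_by_name(group1, "C")
        if c_atom is None:
            continue
        for u2 in residue_uids:
            if u2 == u1 or u2[0] != u1[0]:
                continue
            n_atom = _atom_by_name(units[u2], "N")
            if n_atom is None:
                continue
            if np.linalg.norm(c_atom.position - n_atom.position) < PEPTIDE_BOND_CUTOFF:
                ca_atom = _atom_by_name(group1, "CA")
                if ca_atom is None:
                    raise FragmentationError(
                        f"residue {u1[0]}:{u1[1]} is peptide-bonded but has no CA atom; "
                        "cannot place the Calpha-C(O) cut"
                    )
                o_atom = _atom_by_name(group1, "O")
                cuts.append({"donor": u1, "acceptor": u2, "C": c_atom, "O": o_atom, "CA": ca_atom})

    # move carbonyl groups across each cut: C(O) belongs with the acceptor
    members: dict[tuple, list[AtomRecord]] = {u: list(g) for u, g in units.items()}
    for cut in cuts:
        moved = [cut["C"]] + ([cut["O"]] if cut["O"] is not None else [])
        members[cut["donor"]] = [a for a in members[cut["donor"]] if a not in moved]
        members[cut["acceptor"]] = members[cut["acceptor"]] + moved

    # -- ion merging (union-find, hence transitive and idempotent) ---------
    uf = _UnionFind(len(unit_order))
    index_of = {u: i for i, u in enumerate(unit_order)}
    ion_uids = [u for u in unit_order if u[2]]
    for iu in ion_uids:
        ion_pos = np.array([a.position for a in members[iu]])
        merged_with = []
        for ru in residue_uids:
            res_pos = np.array([a.position for a in members[ru]])
            if res_pos.size == 0:
                continue
            dmin = _min_distance(ion_pos, res_pos)
            if dmin < config.ion_merge_cutoff:  # strict inequality
                uf.union(index_of[iu], index_of[ru])
                merged_with.append(ru)
        if len(merged_with) > 1:
            logger.info(
                "ion %s:%s bridges %d residues; merged transitively into one fragment",
                iu[0], iu[1], len(merged_with),
            )

    # -- assemble fragments -------------------------------------------------
    components: dict[int, list[tuple]] = {}
    for u in unit_order:
        components.setdefault(uf.find(index_of[u]), []).append(u)

    draft: list[dict] = []
    for root in components:
        uids = components[root]
        frag_atoms = [a for u in uids for a in members[u]]
        if not frag_atoms:
            continue
        has_ion = any(u[2] for u in uids)
        charge = 0
        labels = []
        for u in uids:
            chain, resid, is_ion = u
            resname = units[u][0].residue_name
            labels.append(f"{chain}:{resid}:{resname}")
            if is_ion:
                charge += config.ion_charges.get(resname, 0)
            else:
                charge += config.charge_overrides.get(
                    (chain, resid), config.residue_charges.get(resname, 0)
                )
        draft.append(
            {
                "role": "ion_group" if has_ion else "residue",
                "atoms": frag_atoms,
                "charge": charge,
                "label": "+".join(sorted(labels)),
                "uids": uids,
                "first_serial": min(a.serial for a in frag_atoms),
            }
        )
    if ligand_atoms:
        draft.append(
            {
                "role": "ligand",
                "atoms": list(ligand_atoms),
                "charge": config.ligand_charge,
                "label": "ligand",
                "uids": [],
                "first_serial": min(a.serial for a in ligand_atoms),
            }
        )

    # fragment-map charges/roles win when one was supplied (XYZ route)
    if config.fragment_map:
        by_id = {e.fragment_id: e for e in config.fragment_map}
        for d in draft:
            resindex = d["atoms"][0].residue_index - 1
            if resindex in by_id and d["role"] != "ligand":
                d["charge"] = by_id[resindex].charge
        for d in draft:
            if d["role"] == "ligand":
                lig_entries = [e for e in config.fragment_map if e.role == "ligand"]
                if lig_entries:
                    d["charge"] = lig_entries[0].charge

    draft.sort(key=lambda d: d["first_serial"])
    fragments = [
        Fragment(
            id=i,
            role=d["role"],
            member_atoms=d["atoms"],
            formal_charge=d["charge"],
            spin_multiplicity=config.default_multiplicity,
            label=d["label"],
        )
        for i, d in enumerate(draft)
    ]

    # -- caps ---------------------------------------------------------------
    frag_of_uid = {}
    for i, d in enumerate(draft):
        for u in d["uids"]:
            frag_of_uid[u] = i
    cap_serial = -1
    for cut in cuts:
        donor_frag = frag_of_uid[cut["donor"]]
        acceptor_frag = frag_of_uid[cut["acceptor"]]
        if donor_frag == acceptor_frag:
            continue  # cut interior to a merged fragment: bond never severed
        ca, c = cut["CA"].position, cut["C"].position
        for host, anchor, toward in (
            (donor_frag, ca, c),
            (acceptor_frag, c, ca),
        ):
            vec = toward - anchor
            norm = np.linalg.norm(vec)
            if norm == 0:
                raise FragmentationError("coincident CA and C atoms at a cut bond")
            pos = anchor + config.cap_bond_length * vec / norm
            partner = acceptor_frag if host == donor_frag else donor_frag
            fragments[host].cap_atoms.append(
                CapAtom(serial=cap_serial, position=pos, host_fragment=host, partner_fragment=partner)
            )
            cap_serial -= 1

    scheme = FragmentationScheme(fragments)
    scheme.validate()
    return scheme


def _atom_by_name(group: Iterable[AtomRecord], name: str) -> AtomRecord | None:
    for a in group:
        if a.name == name:
            return a
    return None


def _min_distance(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial.distance import cdist

    return float(cdist(a, b).min())


# ---------------------------------------------------------------------------
# Subsystem geometry
# ---------------------------------------------------------------------------


@dataclass
class GeometryBlock:
    """Atoms of one subsystem, ready for an energy backend.

    Cap hydrogens carry the (negative) serial of the cap record and a zero
    partial charge in the toy backends.
    """

    key: SubsystemKey
    serials: np.ndarray  # (n,) int
    elements: list[str]
    coords: np.ndarray  # (n, 3) float, Angstrom
    fragment_of: np.ndarray  # (n,) int fragment id
    is_cap: np.ndarray  # (n,) bool
    charge: int
    multiplicity: int

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def to_xyz(self) -> str:
        lines = [str(self.n_atoms), f"charge={self.charge} multiplicity={self.multiplicity}"]
        for el, (x, y, z) in zip(self.elements, self.coords):
            lines.append(f"{el} {x:.8f} {y:.8f} {z:.8f}")
        return "\n".join(lines) + "\n"


def emit_subsystem_geometry(
    scheme: FragmentationScheme, key: Iterable[int]
) -> GeometryBlock:
    """Union of the member and cap atoms of the fragments named by ``key``.

    A cap is included only when its partner fragment lies outside the
    subsystem; for a cut interior to the subsystem both caps are omitted and
    the original bond is restored by the presence of both real atoms.
    """
    ids = list(key)
    if not ids:
        raise InputError("empty subsystem key")
    skey = key if isinstance(key, SubsystemKey) else SubsystemKey(ids)
    inside = set(skey)
    if max(inside) >= scheme.N or min(inside) < 0:
        raise InputError(f"key {tuple(skey)} refers to fragments outside the scheme")

    serials, elements, coords, frag_of, caps = [], [], [], [], []
    multiplicity_excess = 0
    charge = 0
    for fid in skey:
        frag = scheme[fid]
        charge += frag.formal_charge
        multiplicity_excess += frag.spin_multiplicity - 1
        for a in frag.member_atoms:
            serials.append(a.serial)
            elements.append(a.element)
            coords.append(a.position)
            frag_of.append(fid)
            caps.append(False)
        for cap in frag.cap_atoms:
            if cap.partner_fragment not in inside:
                serials.append(cap.serial)
                elements.append(cap.element)
                coords.append(cap.position)
                frag_of.append(fid)
                caps.append(True)
    return GeometryBlock(
        key=skey,
        serials=np.array(serials, dtype=int),
        elements=elements,
        coords=np.array(coords, dtype=float),
        fragment_of=np.array(frag_of, dtype=int),
        is_cap=np.array(caps, dtype=bool),
        charge=charge,
        multiplicity=1 + multiplicity_excess,
    )


# ---------------------------------------------------------------------------
# Plain-text interchange: XYZ and fragment map
# ---------------------------------------------------------------------------


def read_xyz(path: str) -> tuple[list[str], np.ndarray, int, int]:
    """XYZ reader; recognises ``charge=Q multiplicity=S`` comment tags."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: first line of an XYZ file must be the atom count") from exc
    comment = lines[1] if len(lines) > 1 else ""
    charge, mult = 0, 1
    m = re.search(r"charge=(-?\d+)", comment)
    if m:
        charge = int(m.group(1))
    m = re.search(r"multiplicity=(\d+)", comment)
    if m:
        mult = int(m.group(1))
    elements, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: malformed XYZ atom line {line!r}")
        elements.append(parts[0])
        coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
    if len(elements) != n:
        raise FormatError(f"{path}: expected {n} atoms, found {len(elements)}")
    return elements, np.array(coords), charge, mult


def write_fragment_map(scheme: FragmentationScheme, stream: TextIO) -> None:
    stream.write("# fragment_id\trole\tcharge\tmembers\n")
    for frag in scheme.fragments:
        if frag.role == "ligand":
            members = frag.label or "ligand"
        else:
            tokens = sorted({f"{a.chain_id}:{a.residue_index}" for a in frag.member_atoms})
            members = ",".join(tokens)
        stream.write(f"{frag.id}\t{frag.role}\t{frag.formal_charge}\t{members}\n")


def read_fragment_map(stream: TextIO) -> list[FragmentMapEntry]:
    entries = []
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fid, role, charge, members = line.split("\t")
        entries.append(FragmentMapEntry(int(fid), role, int(charge), members))
    return entries
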