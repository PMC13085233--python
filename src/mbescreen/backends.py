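"""Energy backends and the deduplicating energy store.

The package never bundles a quantum-chemistry engine.  Instead it provides a
deterministic *toy* potential with a tunable degree of many-body character,
which is what lets every stage of the expansion machinery be exercised and
verified:

* permanent-charge Coulomb and Lennard-Jones terms between atoms of
  different fragments (with fragment polarizabilities set to zero the total
  energy is an exact sum of isolated pair energies, so every n-body
  correction of order >= 3 vanishes identically);
* self-consistent induced point dipoles, one per fragment at its centroid,
  responding linearly to the permanent charges of all other fragments and to
  each other.  The mutual-induction equations are solved exactly as a dense
  3f x 3f linear system, so the model is analytic, deterministic, and
  genuinely many-body at every order.

Energies are cached in a content-addressed store: the digest is a SHA-256
hash of the canonical fragment-id tuple, the level tag, and the backend
descriptor, so permuted keys deduplicate and a given subsystem is evaluated
at most once per store lifetime.
"""

from __future__ import annotations

import hashlib
import json
import shlex
import sqlite3
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol

import numpy as np

from .errors import BackendError
from .graph import SubsystemKey
from .structure import FragmentationScheme, GeometryBlock, emit_subsystem_geometry

#: Coulomb constant, kcal*A/(mol*e^2)
COULOMB_CONSTANT = 332.0637
#: 1 hartree in kcal/mol
HARTREE_TO_KCAL = 627.5095


@dataclass(frozen=True)
class EnergyRecord:
    key: tuple[int, ...]
    level: str
    energy: float
    converged: bool


class Backend(Protocol):
    descriptor: str

    def evaluate(self, block: GeometryBlock) -> tuple[float, bool]: ...


@dataclass
class ToyPotentialSpec:
    """Parameters of the toy potential.

    charges
        partial charge (e) per atom serial; cap atoms (negative serials)
        default to zero.
    lj
        per-element Lennard-Jones (epsilon kcal/mol, sigma A); absent
        elements have no LJ term.
    alpha
        isotropic polarizability (A^3) per fragment id, or one scalar for
        all fragments; zero switches induction off entirely.
    """

    charges: Mapping[int, float]
    lj: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    alpha: Mapping[int, float] | float = 0.0

    def alpha_of(self, fragment_id: int) -> float:
        if isinstance(self.alpha, Mapping):
            return float(self.alpha.get(fragment_id, 0.0))
        return float(self.alpha)

    def digest(self) -> str:
        payload = {
            "charges": sorted(self.charges.items()),
            "lj": sorted((el, list(p)) for el, p in self.lj.items()),
            "alpha": sorted(self.alpha.items()) if isinstance(self.alpha, Mapping) else self.alpha,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class ToyBackend:
    """Deterministic polarizable point-charge potential."""

    def __init__(self, spec: ToyPotentialSpec, name: str = "toy"):
        self.spec = spec
        self.name = name
        self.descriptor = f"{name}:{spec.digest()}"
        self.n_evaluations = 0

    def evaluate(self, block: GeometryBlock) -> tuple[float, bool]:
        self.n_evaluations += 1
        try:
            return toy_energy(self.spec, block), True
        except np.linalg.LinAlgError:
            return float("nan"), False


def toy_energy(spec: ToyPotentialSpec, block: GeometryBlock) -> float:
    """Evaluate the toy potential on one subsystem geometry (kcal/mol)."""
    coords = block.coords
    n = len(coords)
    q = np.array([spec.charges.get(int(s), 0.0) for s in block.serials])
    frag = block.fragment_of

    # pairwise permanent-charge + LJ terms between different fragments
    energy = 0.0
    eps = np.empty(n)
    sig = np.empty(n)
    for i, el in enumerate(block.elements):
        e, s = spec.lj.get(el, (0.0, 0.0))
        eps[i] = e
        sig[i] = s
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff**2).sum(-1))
    iu, ju = np.triu_indices(n, k=1)
    inter = frag[iu] != frag[ju]
    iu, ju = iu[inter], ju[inter]
    rij = r[iu, ju]
    if np.any(rij < 1e-8):
        raise BackendError("coincident atoms in subsystem geometry")
    energy += float(np.sum(COULOMB_CONSTANT * q[iu] * q[ju] / rij))
    epsij = np.sqrt(eps[iu] * eps[ju])
    sigij = 0.5 * (sig[iu] + sig[ju])
    mask = epsij > 0
    if np.any(mask):
        sr6 = (sigij[mask] / rij[mask]) ** 6
        energy += float(np.sum(4.0 * epsij[mask] * (sr6**2 - sr6)))

    energy += _induction_energy(spec, block, q)
    return energy


def _induction_energy(spec: ToyPotentialSpec, block: GeometryBlock, q: np.ndarray) -> float:
    """Mutual-induction energy of fragment point dipoles, solved exactly.

    Each polarizable fragment carries one isotropic dipole at the centroid of
    its non-cap atoms.  Dipoles respond to the permanent field of all *other*
    fragments' charges and to each other; U = -1/2 C sum_f mu_f . F_f with mu
    from the exact solve of (alpha^-1 - T) mu = F.
    """
    frag_ids = sorted(set(int(f) for f in block.fragment_of))
    polarizable = [f for f in frag_ids if spec.alpha_of(f) > 0.0]
    if not polarizable or len(frag_ids) < 2:
        return 0.0

    centroids = {}
    for f in frag_ids:
        sel = (block.fragment_of == f) & (~block.is_cap)
        if not np.any(sel):
            sel = block.fragment_of == f
        centroids[f] = block.coords[sel].mean(axis=0)

    # permanent field (e/A^2) at each polarizable centroid from other fragments
    p = len(polarizable)
    F = np.zeros((p, 3))
    for a, f in enumerate(polarizable):
        c = centroids[f]
        sel = block.fragment_of != f
        dr = c - block.coords[sel]
        d = np.linalg.norm(dr, axis=1)
        if np.any(d < 1e-8):
            raise BackendError("atom coincides with a fragment centroid")
        F[a] = np.sum(q[sel, None] * dr / d[:, None] ** 3, axis=0)

    # interaction matrix A = alpha^-1 - T (dimension 3p)
    A = np.zeros((3 * p, 3 * p))
    for a, f in enumerate(polarizable):
        A[3 * a : 3 * a + 3, 3 * a : 3 * a + 3] = np.eye(3) / spec.alpha_of(f)
        for b, g in enumerate(polarizable):
            if b <= a:
                continue
            dr = centroids[f] - centroids[g]
            d = np.linalg.norm(dr)
            T = (3.0 * np.outer(dr, dr) / d**2 - np.eye(3)) / d**3
            A[3 * a : 3 * a + 3, 3 * b : 3 * b + 3] = -T
            A[3 * b : 3 * b + 3, 3 * a : 3 * a + 3] = -T
    mu = np.linalg.solve(A, F.ravel()).reshape(p, 3)
    return float(-0.5 * COULOMB_CONSTANT * np.sum(mu * F))


# ---------------------------------------------------------------------------
# Energy store
# ---------------------------------------------------------------------------


class EnergyStore:
    """Insert-once energy database keyed by a cryptographic digest of the
    canonical subsystem key, the level tag, and the backend descriptor.

    Backed by a single-file sqlite database (or an in-memory one when no
    path is given), so a store reopened from disk never re-evaluates."""

    def __init__(self, path: str | Path | None = None):
        self.path = str(path) if path is not None else ":memory:"
        self._conn = sqlite3.connect(self.path)
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS records ("
            " digest TEXT PRIMARY KEY, key TEXT, level TEXT,"
            " energy REAL, converged INTEGER)"
        )
        self._conn.commit()
        self.n_evaluations = 0  # evaluations performed through this handle

    @staticmethod
    def digest(key: Iterable[int], level: str, descriptor: str) -> str:
        canonical = ",".join(map(str, sorted(key)))
        return hashlib.sha256(f"{canonical}|{level}|{descriptor}".encode()).hexdigest()

    def get(self, key: Iterable[int], level: str, descriptor: str) -> EnergyRecord | None:
        d = self.digest(key, level, descriptor)
        row = self._conn.execute(
            "SELECT key, level, energy, converged FROM records WHERE digest=?", (d,)
        ).fetchone()
        if row is None:
            return None
        return EnergyRecord(tuple(int(t) for t in row[0].split(",")), row[1], row[2], bool(row[3]))

    def put(self, key: Iterable[int], level: str, descriptor: str, energy: float, converged: bool) -> EnergyRecord:
        d = self.digest(key, level, descriptor)
        canonical = ",".join(map(str, sorted(key)))
        self._conn.execute(
            "INSERT OR IGNORE INTO records VALUES (?,?,?,?,?)",
            (d, canonical, level, energy, int(converged)),
        )
        self._conn.commit()
        return self.get(key, level, descriptor)  # type: ignore[return-value]

    def close(self) -> None:
        self._conn.close()


def store_get_or_compute(
    store: EnergyStore,
    key: Iterable[int],
    level: str,
    backend: Backend,
    scheme: FragmentationScheme,
) -> EnergyRecord:
    """Cached backend evaluation: at most one computation per (key, level,
    backend) for the lifetime of the store file."""
    skey = key if isinstance(key, SubsystemKey) else SubsystemKey(key)
    cached = store.get(skey, level, backend.descriptor)
    if cached is not None:
        return cached
    block = emit_subsystem_geometry(scheme, skey)
    try:
        energy, converged = backend.evaluate(block)
    except BackendError:
        energy, converged = float("nan"), False
    store.n_evaluations += 1
    return store.put(skey, level, backend.descriptor, energy, converged)


# ---------------------------------------------------------------------------
# External backend stub
# ---------------------------------------------------------------------------


class ExternalBackend:
    """Interface to a user-supplied command that reads an XYZ geometry file
    (charge/multiplicity on the comment line) and prints one energy value.

    The command template must contain an ``{input}`` placeholder.  The last
    floating-point token printed to stdout is taken as the energy; hartree
    output is converted to kcal/mol.  Any failure (nonzero exit, unparseable
    output, timeout) yields an unconverged result instead of an exception.
    """

    def __init__(self, command_template: str, unit: str = "kcal/mol", timeout: float = 300.0):
        if "{input}" not in command_template:
            raise ValueError("command template must contain an {input} placeholder")
        if unit not in ("kcal/mol", "hartree"):
            raise ValueError(f"unknown energy unit {unit!r}")
        self.command_template = command_template
        self.unit = unit
        self.timeout = timeout
        self.descriptor = f"external:{hashlib.sha256((command_template + unit).encode()).hexdigest()[:16]}"

    def evaluate(self, block: GeometryBlock) -> tuple[float, bool]:
        with tempfile.NamedTemporaryFile("w", suffix=".xyz", delete=False) as fh:
            fh.write(block.to_xyz())
            path = fh.name
        try:
            cmd = [tok.format(input=path) for tok in shlex.split(self.command_template)]
            proc = subprocess.run(
                cmd, capture_output=True, text=True, timeout=self.timeout
            )
            if proc.returncode != 0:
                return float("nan"), False
            value = _last_float(proc.stdout)
            if value is None:
                return float("nan"), False
            if self.unit == "hartree":
                value *= HARTREE_TO_KCAL
            return value, True
        except (subprocess.TimeoutExpired, OSError):
            return float("nan"), False
        finally:
            Path(path).unlink(missing_ok=True)


def _last_float(text: str) -> float | None:
    value = None
    for token in text.split():
        try:
            value = float(token)
        except ValueError:
            continue
    return value
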