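"""End-to-end orchestration: configuration, screened graph construction,
energy assembly, and the run report.

A run proceeds fragmentation -> layer-by-layer graph construction (parental
screen via the selected algorithm, then distance, then energy screening;
cheap filters before expensive ones) -> resummation -> target-level
evaluation -> assembly.  The report echoes the full configuration and the
per-order audit counts, so a report suffices to reproduce its run.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field
from typing import Iterable

import pandas as pd
import yaml

from .assembly import (
    InteractionEnergyResult,
    NBodyBreakdown,
    interaction_energy,
    mbe_energy,
)
from .backends import Backend, EnergyStore, ExternalBackend, ToyBackend, ToyPotentialSpec, store_get_or_compute
from .errors import InputError, MBEScreenError
from .fixtures import FixtureSpec, make_fixture, read_potential_table
from .graph import InteractionGraph, NodeStatus, build_layer, subsystem_count
from .screening import DistanceCalculator, ScreeningConfig, distance_screen, energy_screen
from .graph import SubsystemKey
from .structure import (
    FragmentationConfig,
    FragmentationScheme,
    fragment_structure,
    read_fragment_map,
    read_structure,
)


@dataclass
class RunConfig:
    """Everything a run needs; fully echoed into the report."""

    # input: either a fixture spec or a structure file
    fixture: FixtureSpec | None = None
    structure_path: str | None = None
    structure_format: str | None = None
    fragment_map_path: str | None = None
    potential_path: str | None = None  # toy-potential table for file input

    fragmentation: FragmentationConfig = field(default_factory=FragmentationConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    n_max: int = 4
    algorithm: str | None = None  # parental-screen override; default auto
    mode: str = "interaction"  # or "total"
    low_backend: str = "toy"
    target_backend: str = "toy"
    external_command: str | None = None
    external_unit: str = "kcal/mol"
    store_path: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_max < 1:
            raise InputError("n_max must be >= 1")
        if self.mode not in ("interaction", "total"):
            raise InputError("mode must be 'interaction' or 'total'")
        if self.fixture is None and self.structure_path is None:
            raise InputError("either a fixture spec or a structure path is required")
        for name in (self.low_backend, self.target_backend):
            if name not in ("toy", "external"):
                raise InputError(f"unknown backend {name!r}")
            if name == "external" and not self.external_command:
                raise InputError("external backend requires external_command")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fragmentation"]["ligand_resnames"] = sorted(self.fragmentation.ligand_resnames)
        d["fragmentation"]["ion_resnames"] = sorted(self.fragmentation.ion_resnames)
        d["fragmentation"]["charge_overrides"] = {
            f"{chain}:{resid}": q
            for (chain, resid), q in self.fragmentation.charge_overrides.items()
        }
        return d


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    kwargs = dict(raw)
    if "fixture" in kwargs and kwargs["fixture"] is not None:
        kwargs["fixture"] = FixtureSpec(**kwargs["fixture"])
    if "fragmentation" in kwargs and kwargs["fragmentation"] is not None:
        frag = dict(kwargs["fragmentation"])
        for key in ("ligand_resnames", "ion_resnames"):
            if key in frag:
                frag[key] = frozenset(frag[key])
        if "charge_overrides" in frag:
            frag["charge_overrides"] = {
                (k.split(":")[0], int(k.split(":")[1])): int(v)
                for k, v in frag["charge_overrides"].items()
            }
        kwargs["fragmentation"] = FragmentationConfig(**frag)
    if "screening" in kwargs and kwargs["screening"] is not None:
        scr = dict(kwargs["screening"])
        for key in ("tau_by_order", "d_by_order"):
            if key in scr:
                scr[key] = {int(k): float(v) for k, v in scr[key].items()}
        kwargs["screening"] = ScreeningConfig(**scr)
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# System loading
# ---------------------------------------------------------------------------


@dataclass
class System:
    scheme: FragmentationScheme
    potential: ToyPotentialSpec | None


def load_system(config: RunConfig) -> System:
    if config.fixture is not None:
        _atoms, scheme, potential = make_fixture(config.fixture)
        return System(scheme, potential)
    frag_config = config.fragmentation
    if config.fragment_map_path:
        with open(config.fragment_map_path) as fh:
            frag_config.fragment_map = read_fragment_map(fh)
    atoms = read_structure(config.structure_path, config.structure_format, frag_config)
    scheme = fragment_structure(atoms, frag_config)
    potential = None
    if config.potential_path:
        with open(config.potential_path) as fh:
            potential = read_potential_table(fh)
    return System(scheme, potential)


def make_backend(config: RunConfig, system: System, which: str) -> Backend:
    name = config.low_backend if which == "low" else config.target_backend
    if name == "toy":
        if system.potential is None:
            raise InputError(
                "toy backend requires a potential table (or a fixture input)"
            )
        return ToyBackend(system.potential, name=f"toy-{which}")
    return ExternalBackend(config.external_command, config.external_unit)


# ---------------------------------------------------------------------------
# Graph construction with screening
# ---------------------------------------------------------------------------


def build_screened_graph(
    scheme: FragmentationScheme,
    screening: ScreeningConfig,
    n_max: int,
    low_backend: Backend | None = None,
    store: EnergyStore | None = None,
    algorithm: str | None = None,
) -> InteractionGraph:
    """Layered bottom-up construction with the full screening cascade:
    missing parents, then distance, then energy (cheap before expensive)."""
    graph = InteractionGraph(scheme.N, M=screening.M, n_max=n_max)
    calc = DistanceCalculator(scheme)
    store = store if store is not None else EnergyStore()
    for k in range(2, n_max + 1):
        candidates = build_layer(graph, k, algorithm)
        parent_rejected = subsystem_count(scheme.N, k) - len(candidates)
        kept_d, removed_d = distance_screen(candidates, scheme, screening, calc)
        if screening.tau_by_order.get(k) is not None and low_backend is not None:
            kept, removed_e = energy_screen(kept_d, scheme, low_backend, screening, store)
        else:
            kept, removed_e = kept_d, set()
        removed = [(key, NodeStatus.REMOVED_DISTANCE) for key in removed_d]
        removed += [(key, NodeStatus.REMOVED_ENERGY) for key in removed_e]
        graph.add_layer(k, kept, removed, parent_rejected)
    return graph


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    config: dict
    n_fragments: int
    ligand_id: int | None
    mode: str
    energy: float  # dE_int (interaction) or MBE(n) total
    per_order: dict[int, float]
    n_subsystems_evaluated: int
    audit: dict[int, dict[str, int]]
    breakdown: NBodyBreakdown
    graph: InteractionGraph

    def per_order_table(self) -> pd.DataFrame:
        rows = []
        for order in sorted(self.audit):
            rows.append(
                {
                    "order": order,
                    "dE_kcal": round(self.per_order.get(order, 0.0), 8),
                    **self.audit[order],
                }
            )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write("# mbescreen run report\n")
        label = "delta_E_int" if self.mode == "interaction" else "E_total"
        buf.write(f"{label} = {self.energy:.8f} kcal/mol\n")
        buf.write(f"n_fragments = {self.n_fragments}\n")
        buf.write(f"ligand_id = {self.ligand_id}\n")
        buf.write(f"n_subsystems_evaluated = {self.n_subsystems_evaluated}\n")
        buf.write("\n## per-order contributions and subsystem counts\n")
        buf.write(self.per_order_table().to_csv(sep="\t", index=False))
        buf.write("\n## configuration echo\n")
        buf.write(yaml.safe_dump(self.config, sort_keys=True))
        return buf.getvalue()


def run_pipeline(config: RunConfig) -> RunReport:
    config.validate()
    try:
        system = load_system(config)
    except MBEScreenError as exc:
        raise type(exc)(f"[stage: input] {exc}") from exc
    scheme = system.scheme
    store = EnergyStore(config.store_path)
    low = make_backend(config, system, "low")
    target = make_backend(config, system, "target")

    graph = build_screened_graph(
        scheme, config.screening, config.n_max, low, store, config.algorithm
    )

    if config.mode == "interaction":
        if scheme.ligand_id is None:
            raise InputError("[stage: assembly] interaction mode requires a ligand fragment")
        result = interaction_energy(scheme, graph, target, store)
        return RunReport(
            config=config.to_dict(),
            n_fragments=scheme.N,
            ligand_id=scheme.ligand_id,
            mode="interaction",
            energy=result.delta_E_int,
            per_order=result.per_order_contributions,
            n_subsystems_evaluated=result.n_subsystems_evaluated,
            audit=result.audit,
            breakdown=result.breakdown,
            graph=graph,
        )

    total, breakdown, ledger = mbe_energy(graph.all_retained(), scheme, target, store)
    return RunReport(
        config=config.to_dict(),
        n_fragments=scheme.N,
        ligand_id=scheme.ligand_id,
        mode="total",
        energy=total,
        per_order=dict(breakdown.per_order_sums),
        n_subsystems_evaluated=len(ledger.support()),
        audit=graph.status_counts(),
        breakdown=breakdown,
        graph=graph,
    )


def supersystem_benchmark(
    scheme: FragmentationScheme, backend: Backend, store: EnergyStore, mode: str
) -> float:
    """Unfragmented reference: E of the whole system, or for interaction
    mode the supramolecular dE_int from three unfragmented evaluations."""
    all_key = SubsystemKey(range(scheme.N))

    def energy(key: SubsystemKey) -> float:
        rec = store_get_or_compute(store, key, "target", backend, scheme)
        if not rec.converged:
            raise InputError(f"supersystem evaluation failed for {tuple(key)}")
        return rec.energy

    if mode == "total":
        return energy(all_key)
    ligand = scheme.ligand_id
    if ligand is None:
        raise InputError("interaction benchmark requires a ligand")
    protein_ids = [i for i in range(scheme.N) if i != ligand]
    e_pl = energy(all_key)
    e_p = energy(SubsystemKey(protein_ids))
    e_l = energy(SubsystemKey((ligand,)))
    return e_pl - e_p - e_l


def convergence_scan(config: RunConfig, orders: Iterable[int]) -> pd.DataFrame:
    """One pipeline run per truncation order, reusing the energy store.

    With a toy backend the unfragmented supersystem is cheap, so the scan
    also reports the absolute error against that benchmark.
    """
    orders = sorted(orders)
    if any(o < 1 for o in orders):
        raise InputError("orders must be >= 1")
    config.validate()
    system = load_system(config)
    store = EnergyStore(config.store_path)
    low = make_backend(config, system, "low")
    target = make_backend(config, system, "target")
    scheme = system.scheme

    benchmark = None
    if config.target_backend == "toy":
        benchmark = supersystem_benchmark(scheme, target, store, config.mode)

    rows = []
    for n in orders:
        graph = build_screened_graph(
            scheme, config.screening, n, low, store, config.algorithm
        )
        if config.mode == "interaction":
            result = interaction_energy(scheme, graph, target, store)
            value, count = result.delta_E_int, result.n_subsystems_evaluated
        else:
            value, breakdown, ledger = mbe_energy(graph.all_retained(), scheme, target, store)
            count = len(ledger.support())
        row = {"n": n, "energy_kcal": value, "n_subsystems": count}
        if benchmark is not None:
            row["abs_error_kcal"] = abs(value - benchmark)
            row["benchmark_kcal"] = benchmark
        rows.append(row)
    return pd.DataFrame(rows)
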