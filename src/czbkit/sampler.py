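"""Replica-exchange Metropolis Monte Carlo over restraint + tether potentials.

This is a desk-scale conformational sampler for a flexible chain bound to a
tethered core: the experimental-restraint and tether potentials are exactly
the two-well and harmonic forms used for analysis, and a soft-sphere
excluded-volume term stands in for a molecular force field.  Replicas run a
temperature ladder (default: the 16-value reduced-unit ladder
0.480…0.767 ε) with nearest-neighbour configuration swaps.

Moves are torsion pivots about φ/ψ of the mobile chain (exact rigid
rotations, no geometry distortion), local crankshaft rotations about a
Cα–Cα axis, and single-atom jiggles.  Reduced temperature is used directly
as the Metropolis temperature in surrogate energy units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, ContractError
from .residues import SASA_RADII
from .restraints import (
    HarmonicTether,
    RestraintSet,
    TwoWellPotential,
)
from .structio import Ensemble, Structure

# the 16-temperature reduced-unit replica ladder
DEFAULT_TEMPERATURES: tuple[float, ...] = (
    0.480, 0.495, 0.512, 0.528, 0.546, 0.563, 0.581, 0.600,
    0.619, 0.638, 0.658, 0.679, 0.700, 0.722, 0.744, 0.767,
)

# recorded for provenance only; the MC sampler has no physical clock
DMD_TIME_UNIT_FS = 50.0
DMD_TOTAL_SAMPLING_US = 8.0


@dataclass
class SamplerConfig:
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    steps_per_replica: int = 2000
    snapshot_interval: int = 200
    swap_interval: int = 100
    move_weights: dict = field(
        default_factory=lambda: {"pivot": 0.8, "crankshaft": 0.1, "jiggle": 0.1}
    )
    max_rotation_deg: float = 20.0
    max_translation: float = 0.3
    mobile_chains: tuple[str, ...] = ("C",)
    seed: int = 0

    def __post_init__(self):
        temps = tuple(float(t) for t in self.temperatures)
        if any(t2 <= t1 for t1, t2 in zip(temps, temps[1:])):
            raise ConfigError("temperatures must be strictly increasing")
        if any(t <= 0 for t in temps):
            raise ConfigError("temperatures must be positive")
        self.temperatures = temps
        if self.steps_per_replica < 1 or self.snapshot_interval < 1 or self.swap_interval < 1:
            raise ConfigError("steps and intervals must be >= 1")
        total = sum(self.move_weights.values())
        if total <= 0:
            raise ConfigError("move weights must not all be zero")
        unknown = set(self.move_weights) - {"pivot", "crankshaft", "jiggle"}
        if unknown:
            raise ConfigError(f"unknown move types {sorted(unknown)}")
        self.move_weights = {k: v / total for k, v in self.move_weights.items()}


@dataclass
class EnergyDecomposition:
    restraint: float = 0.0
    tether: float = 0.0
    excluded_volume: float = 0.0

    @property
    def total(self) -> float:
        return self.restraint + self.tether + self.excluded_volume


class EnergyModel:
    """Restraint + tether + soft-sphere excluded-volume energy of a topology.

    The excluded-volume term is Σ (σ_ij − r)² over heavy-atom pairs with
    r < σ_ij = r_i + r_j (element radii), restricted to pairs on different
    chains or separated by more than ``min_seq_sep`` residues in the same
    chain, so covalent neighbourhoods and local secondary structure are not
    penalised (no bonded-geometry terms exist to balance them).
    """

    def __init__(
        self,
        topology: Structure,
        restraint_set: RestraintSet | None = None,
        potential: TwoWellPotential | None = None,
        tethers: Sequence[HarmonicTether] = (),
        radii: dict[str, float] | None = None,
        min_seq_sep: int = 5,
        ev_enabled: bool = True,
    ):
        self.topology = topology
        self.restraint_set = restraint_set
        self.potential = potential or TwoWellPotential()
        self.tethers = list(tethers)
        self.min_seq_sep = min_seq_sep
        self.ev_enabled = ev_enabled
        radii = radii or SASA_RADII
        n = len(topology)

        if restraint_set is not None:
            self._r_ia = np.array(
                [topology.index_of(r.atom_a) for r in restraint_set], dtype=int
            )
            self._r_ib = np.array(
                [topology.index_of(r.atom_b) for r in restraint_set], dtype=int
            )
            self._r_bounds = np.array([r.upper_bound for r in restraint_set])
        else:
            self._r_ia = np.empty(0, dtype=int)
            self._r_ib = np.empty(0, dtype=int)
            self._r_bounds = np.empty(0)

        self._t_idx: list[np.ndarray] = []
        self._t_ref: list[np.ndarray] = []
        self._t_k: list[float] = []
        for t in self.tethers:
            self._t_idx.append(
                np.array([topology.index_of(k) for k in t.keys], dtype=int)
            )
            self._t_ref.append(np.asarray(t.reference, float))
            self._t_k.append(t.spring_constant)

        self._heavy = np.array([a.is_heavy for a in topology.atoms])
        self._radius = np.array(
            [radii.get(a.element, 1.7) if a.is_heavy else 0.0 for a in topology.atoms]
        )
        chain_index = {c: i for i, c in enumerate(topology.chain_ids)}
        self._chain = np.array([chain_index[a.chain_id] for a in topology.atoms])
        self._resseq = np.array([a.res_seq for a in topology.atoms])

    # -- pair admissibility for excluded volume
    def _ev_allowed(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        both_heavy = self._heavy[i] & self._heavy[j]
        diff_chain = self._chain[i] != self._chain[j]
        far_seq = np.abs(self._resseq[i] - self._resseq[j]) > self.min_seq_sep
        return both_heavy & (diff_chain | far_seq)

    def _ev_group(self, coords: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
        """EV energy over the pair block idx_a × idx_b (cross only)."""
        if not self.ev_enabled or len(idx_a) == 0 or len(idx_b) == 0:
            return 0.0
        d = coords[idx_a][:, None, :] - coords[idx_b][None, :, :]
        dist = np.sqrt((d * d).sum(axis=2))
        sigma = self._radius[idx_a][:, None] + self._radius[idx_b][None, :]
        ii, jj = np.meshgrid(idx_a, idx_b, indexing="ij")
        mask = self._ev_allowed(ii.ravel(), jj.ravel()).reshape(dist.shape)
        overlap = np.where(mask & (dist < sigma), sigma - dist, 0.0)
        return float((overlap**2).sum())

    def _ev_within(self, coords: np.ndarray, idx: np.ndarray) -> float:
        if not self.ev_enabled or len(idx) < 2:
            return 0.0
        d = coords[idx][:, None, :] - coords[idx][None, :, :]
        dist = np.sqrt((d * d).sum(axis=2))
        sigma = self._radius[idx][:, None] + self._radius[idx][None, :]
        ii, jj = np.meshgrid(idx, idx, indexing="ij")
        mask = self._ev_allowed(ii.ravel(), jj.ravel()).reshape(dist.shape)
        mask &= np.triu(np.ones_like(dist, dtype=bool), k=1)
        overlap = np.where(mask & (dist < sigma), sigma - dist, 0.0)
        return float((overlap**2).sum())

    def restraint_energy(self, coords: np.ndarray, which: np.ndarray | None = None) -> float:
        if len(self._r_ia) == 0:
            return 0.0
        ia, ib, bounds = self._r_ia, self._r_ib, self._r_bounds
        if which is not None:
            ia, ib, bounds = ia[which], ib[which], bounds[which]
        d = coords[ia] - coords[ib]
        r = np.sqrt((d * d).sum(axis=1))
        return float(self.potential.energy(r, bounds).sum())

    def tether_energy(self, coords: np.ndarray, moved: np.ndarray | None = None) -> float:
        total = 0.0
        for idx, ref, k in zip(self._t_idx, self._t_ref, self._t_k):
            if moved is not None:
                sel = np.isin(idx, moved)
                if not sel.any():
                    continue
                d = coords[idx[sel]] - ref[sel]
            else:
                d = coords[idx] - ref
            total += k * float((d * d).sum())
        return total

    def decompose(self, coords: np.ndarray) -> EnergyDecomposition:
        all_idx = np.arange(len(coords))
        return EnergyDecomposition(
            restraint=self.restraint_energy(coords),
            tether=self.tether_energy(coords),
            excluded_volume=self._ev_within(coords, all_idx),
        )

    def delta(
        self, coords_old: np.ndarray, coords_new: np.ndarray, moved: np.ndarray
    ) -> EnergyDecomposition:
        """Energy change restricted to terms touching the moved atoms."""
        if self.ev_enabled:
            static = np.setdiff1d(
                np.arange(len(coords_old)), moved, assume_unique=False
            )
        else:
            static = np.empty(0, dtype=int)
        touch = (
            np.isin(self._r_ia, moved) | np.isin(self._r_ib, moved)
            if len(self._r_ia)
            else None
        )
        d_restraint = (
            self.restraint_energy(coords_new, touch)
            - self.restraint_energy(coords_old, touch)
            if touch is not None and touch.any()
            else 0.0
        )
        d_tether = self.tether_energy(coords_new, moved) - self.tether_energy(
            coords_old, moved
        )
        d_ev = (
            self._ev_group(coords_new, moved, static)
            + self._ev_within(coords_new, moved)
            - self._ev_group(coords_old, moved, static)
            - self._ev_within(coords_old, moved)
        )
        return EnergyDecomposition(d_restraint, d_tether, d_ev)


def total_energy(structure: Structure, model: EnergyModel) -> EnergyDecomposition:
    """Energy decomposition of one structure under a configured model."""
    return model.decompose(structure.coords)


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(−ΔE/T))."""
    if temperature <= 0:
        raise ContractError("temperature must be positive")
    if delta_e <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_e / temperature))


def swap_probability(e_i: float, e_j: float, t_i: float, t_j: float) -> float:
    """Parallel-tempering exchange probability for two replicas."""
    return float(min(1.0, np.exp((1.0 / t_i - 1.0 / t_j) * (e_i - e_j))))


@dataclass
class ReplicaState:
    """Mutable per-replica state used by the sampler loop."""

    coords: np.ndarray
    temperature: float
    temperature_index: int
    energy: EnergyDecomposition
    rng: np.random.Generator


def attempt_swap(
    state_i: ReplicaState, state_j: ReplicaState, rng: np.random.Generator
) -> bool:
    """Attempt a nearest-neighbour temperature swap between two replicas."""
    if abs(state_i.temperature_index - state_j.temperature_index) != 1:
        raise ContractError("swap attempted between non-adjacent temperatures")
    p = swap_probability(
        state_i.energy.total,
        state_j.energy.total,
        state_i.temperature,
        state_j.temperature,
    )
    if rng.random() < p:
        state_i.temperature, state_j.temperature = (
            state_j.temperature,
            state_i.temperature,
        )
        state_i.temperature_index, state_j.temperature_index = (
            state_j.temperature_index,
            state_i.temperature_index,
        )
        return True
    return False


class _MoveSet:
    """Precomputed move machinery for a topology's mobile chains."""

    def __init__(self, topology: Structure, config: SamplerConfig):
        self.config = config
        self.jiggle_atoms = np.array(
            [
                i
                for i, a in enumerate(topology.atoms)
                if a.chain_id in config.mobile_chains
            ],
            dtype=int,
        )
        if len(self.jiggle_atoms) == 0:
            raise ConfigError(
                f"no atoms on mobile chains {config.mobile_chains}"
            )
        # per-residue pivot definitions on mobile chains
        self.pivots: list[tuple[int, int, np.ndarray]] = []
        self.crankshafts: list[tuple[int, int, np.ndarray]] = []
        for chain in config.mobile_chains:
            res_atoms: dict[int, list[int]] = {}
            for i, a in enumerate(topology.atoms):
                if a.chain_id == chain:
                    res_atoms.setdefault(a.res_seq, []).append(i)
            res_list = sorted(res_atoms)
            for pos, res in enumerate(res_list):
                names = {
                    topology.atoms[i].atom_name: i for i in res_atoms[res]
                }
                if not {"N", "CA", "C"} <= set(names):
                    continue
                downstream = [
                    i
                    for r in res_list[pos + 1:]
                    for i in res_atoms[r]
                ]
                # φ pivot: about N–CA, moves C/O/side chain + downstream
                phi_moved = [
                    i
                    for i in res_atoms[res]
                    if topology.atoms[i].atom_name not in ("N", "CA")
                ] + downstream
                if phi_moved:
                    self.pivots.append(
                        (names["N"], names["CA"], np.array(phi_moved, dtype=int))
                    )
                # ψ pivot: about CA–C, moves O + downstream
                psi_moved = ([names["O"]] if "O" in names else []) + downstream
                if psi_moved:
                    self.pivots.append(
                        (names["CA"], names["C"], np.array(psi_moved, dtype=int))
                    )
            # crankshaft: rotate residues strictly between two Cα 2–4 apart
            for pos, res in enumerate(res_list):
                for gap in (2, 3, 4):
                    if pos + gap >= len(res_list):
                        continue
                    res_j = res_list[pos + gap]
                    ni = {topology.atoms[i].atom_name: i for i in res_atoms[res]}
                    nj = {topology.atoms[i].atom_name: i for i in res_atoms[res_j]}
                    if "CA" not in ni or "CA" not in nj:
                        continue
                    moved = [
                        i
                        for r in res_list[pos + 1 : pos + gap]
                        for i in res_atoms[r]
                    ]
                    moved += [
                        i for i in res_atoms[res]
                        if topology.atoms[i].atom_name in ("C", "O")
                    ]
                    moved += [
                        i for i in res_atoms[res_j]
                        if topology.atoms[i].atom_name == "N"
                    ]
                    if moved:
                        self.crankshafts.append(
                            (ni["CA"], nj["CA"], np.array(moved, dtype=int))
                        )
        weights = config.move_weights
        kinds, probs = [], []
        for kind in ("pivot", "crankshaft", "jiggle"):
            w = weights.get(kind, 0.0)
            if w > 0:
                if kind == "pivot" and not self.pivots:
                    raise ConfigError("pivot weight > 0 but no pivotable residues")
                if kind == "crankshaft" and not self.crankshafts:
                    raise ConfigError("crankshaft weight > 0 but no crankshaft axes")
                kinds.append(kind)
                probs.append(w)
        self.kinds = kinds
        self.probs = np.array(probs) / sum(probs)

    def propose(
        self, coords: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (new coords, moved atom indices)."""
        kind = self.kinds[int(rng.choice(len(self.kinds), p=self.probs))]
        cfg = self.config
        if kind == "jiggle":
            atom = int(self.jiggle_atoms[rng.integers(len(self.jiggle_atoms))])
            new = coords.copy()
            new[atom] += rng.uniform(-cfg.max_translation, cfg.max_translation, 3)
            return new, np.array([atom])
        pool = self.pivots if kind == "pivot" else self.crankshafts
        i0, i1, moved = pool[int(rng.integers(len(pool)))]
        angle = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
        origin = coords[i0]
        axis = coords[i1] - coords[i0]
        norm = np.linalg.norm(axis)
        if norm < 1e-8:
            return coords.copy(), np.empty(0, dtype=int)
        from .geometry import rotation_about_axis

        rot = rotation_about_axis(axis / norm, angle)
        new = coords.copy()
        new[moved] = (coords[moved] - origin) @ rot.T + origin
        return new, moved


@dataclass
class SwapLogEntry:
    step: int
    pair: tuple[int, int]
    accepted: bool


def run_sampling(
    initial: Structure,
    restraint_set: RestraintSet | None,
    tethers: Sequence[HarmonicTether],
    config: SamplerConfig,
    potential: TwoWellPotential | None = None,
    ev_enabled: bool = True,
) -> tuple[Ensemble, list[SwapLogEntry]]:
    """Run replica-exchange MC from ``initial``; return snapshots + swap log.

    Snapshots are taken from every replica each ``snapshot_interval`` steps
    and annotated with replica (temperature) index, temperature, step and
    the energy decomposition.  Identical seed + config reproduce the
    trajectory bit-for-bit.
    """
    model = EnergyModel(
        initial,
        restraint_set=restraint_set,
        potential=potential,
        tethers=tethers,
        ev_enabled=ev_enabled,
    )
    moves = _MoveSet(initial, config)
    n_rep = len(config.temperatures)
    states = [
        ReplicaState(
            coords=initial.coords,
            temperature=config.temperatures[r],
            temperature_index=r,
            energy=model.decompose(initial.coords),
            rng=np.random.default_rng(config.seed + r),
        )
        for r in range(n_rep)
    ]
    swap_rng = np.random.default_rng(config.seed + 86243)
    snapshots: list[Structure] = []
    ann: dict[str, list[float]] = {
        k: [] for k in ("replica", "temperature", "step", "energy",
                        "restraint_energy", "tether_energy", "excluded_volume")
    }
    swap_log: list[SwapLogEntry] = []
    swap_parity = 0

    for step in range(1, config.steps_per_replica + 1):
        for state in states:
            new, moved = moves.propose(state.coords, state.rng)
            if len(moved) == 0:
                continue
            d = model.delta(state.coords, new, moved)
            if metropolis_accept(d.total, state.temperature, state.rng):
                state.coords = new
                state.energy = EnergyDecomposition(
                    state.energy.restraint + d.restraint,
                    state.energy.tether + d.tether,
                    state.energy.excluded_volume + d.excluded_volume,
                )
        if step % config.swap_interval == 0 and n_rep > 1:
            # refresh decompositions to keep incremental sums audit-exact
            for state in states:
                state.energy = model.decompose(state.coords)
            by_temp = sorted(states, key=lambda s: s.temperature_index)
            for lo in range(swap_parity, n_rep - 1, 2):
                accepted = attempt_swap(by_temp[lo], by_temp[lo + 1], swap_rng)
                swap_log.append(SwapLogEntry(step, (lo, lo + 1), accepted))
            swap_parity = 1 - swap_parity
        if step % config.snapshot_interval == 0:
            for state in states:
                state.energy = model.decompose(state.coords)
                snapshots.append(
                    initial.with_coords(
                        state.coords,
                        label=f"step{step}-T{state.temperature_index}",
                    )
                )
                ann["replica"].append(state.temperature_index)
                ann["temperature"].append(state.temperature)
                ann["step"].append(step)
                ann["energy"].append(state.energy.total)
                ann["restraint_energy"].append(state.energy.restraint)
                ann["tether_energy"].append(state.energy.tether)
                ann["excluded_volume"].append(state.energy.excluded_volume)
    ensemble = Ensemble(snapshots, annotations=ann)
    return ensemble, swap_log
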