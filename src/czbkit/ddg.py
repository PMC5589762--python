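"""In-silico point-mutation screen of the binding interface.

For each candidate substitution on the histone side, side chains around the
site are repacked by simulated-annealing rotamer Monte Carlo under a
surrogate energy (soft-sphere van der Waals + distance-dependent Coulomb on
charged groups + rotamer prior), in four arms: mutant/wild-type × bound
complex/histone dimer alone.  The change in binding free energy is

    ΔΔG = (ΔG_complex,mut − ΔG_dimer,mut) − (ΔG_complex,wt − ΔG_dimer,wt)

with positive ΔΔG meaning the mutation destabilises binding.  Runs are
paired by seed across the four arms, repeated over runs and centroid
structures, and reported as mean ± SEM.  The surrogate energy is documented
and reproducible, but its scale is arbitrary: rankings and signs are the
meaningful output, not kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .build import build_side_chain
from .errors import ContractError
from .residues import (
    BACKBONE_ATOMS,
    N_CHI,
    PARTIAL_CHARGES,
    ROTAMERS,
    SASA_RADII,
    STANDARD_AA,
    element_of,
)
from .structio import AtomRecord, Ensemble, Structure

EXCLUDED_TARGETS = ("PRO", "CYS")


@dataclass(frozen=True)
class Mutation:
    chain_id: str
    res_seq: int
    from_res: str
    to_res: str

    def __post_init__(self):
        for r in (self.from_res, self.to_res):
            if r not in STANDARD_AA:
                raise ValueError(f"non-standard residue {r!r}")
        if self.to_res in EXCLUDED_TARGETS or self.to_res == self.from_res:
            raise ValueError(
                f"disallowed target {self.to_res} at {self.chain_id}{self.res_seq}"
            )

    @property
    def label(self) -> str:
        return f"{self.from_res}{self.res_seq}{self.to_res}"


def enumerate_mutations(
    sites: Sequence[tuple[str, int, str]],
) -> list[Mutation]:
    """All substitutions per site except proline, cysteine and the native.

    17 per site for a non-CYS native; a CYS native yields 18 (only PRO and
    the native excluded, applying the rule literally).  Output order:
    site order, then alphabetical by target three-letter code.
    """
    out: list[Mutation] = []
    for chain, res_seq, native in sites:
        if native not in STANDARD_AA:
            raise ValueError(f"non-standard native residue {native!r}")
        for target in sorted(STANDARD_AA):
            if target == native or target in EXCLUDED_TARGETS:
                continue
            out.append(Mutation(chain, res_seq, native, target))
    return out


@dataclass
class AnnealSchedule:
    """Geometric temperature ladder for the rotamer annealing."""

    t_start: float = 5.0
    t_end: float = 0.1
    sweeps: int = 200

    def temperatures(self) -> np.ndarray:
        return np.geomspace(self.t_start, self.t_end, self.sweeps)


@dataclass
class RepackParams:
    """Surrogate-energy and search parameters (documented placeholders)."""

    shell_radius: float = 8.0  # Å around the site Cα
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    vdw_weight: float = 20.0
    sigma_scale: float = 0.9  # forgiveness factor on vdW contact distances
    elec_weight: float = 83.0  # ~332/(4r²): distance-dependent dielectric
    prior_weight: float = 0.5
    chi_jitter_deg: float = 8.0  # per-run sub-rotamer relaxation width


class _Candidate:
    __slots__ = ("names", "coords", "weight", "radii", "charges")

    def __init__(self, names, coords, weight, res_name):
        self.names = list(names)
        self.coords = np.asarray(coords, float).reshape(-1, 3)
        self.weight = weight
        self.radii = np.array(
            [SASA_RADII.get(element_of(n), 1.7) for n in self.names]
        )
        self.charges = np.array(
            [PARTIAL_CHARGES.get((res_name, n), 0.0) for n in self.names]
        )


def _side_chain_names(structure: Structure, chain: str, res_seq: int) -> list[str]:
    return [
        a.atom_name
        for a in structure.atoms
        if a.chain_id == chain and a.res_seq == res_seq
        and a.atom_name not in BACKBONE_ATOMS and a.is_heavy
    ]


class _RepackProblem:
    """Discrete rotamer-state optimisation around one site."""

    def __init__(
        self,
        structure: Structure,
        site: tuple[str, int],
        to_res: str | None,
        params: RepackParams,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.structure = structure
        self.params = params
        chain, res_seq = site
        residues = structure.residues()
        res_types = {(c, r): n for c, r, n in residues}
        if (chain, res_seq) not in res_types:
            raise ContractError(f"site {site} not in structure")
        self.native = res_types[(chain, res_seq)]
        self.target = to_res or self.native

        coords = structure.coords
        ca_site = coords[structure.index_of((chain, res_seq, "CA"))]

        # shell: residues with any heavy atom within shell_radius of site Cα
        res_atoms: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(structure.atoms):
            res_atoms.setdefault((a.chain_id, a.res_seq), []).append(i)
        shell: list[tuple[str, int]] = []
        for key, idx in res_atoms.items():
            if key == (chain, res_seq):
                continue
            d = np.linalg.norm(coords[idx] - ca_site, axis=1).min()
            if d <= params.shell_radius and N_CHI[res_types[key]] >= 1:
                shell.append(key)
        shell.sort()
        self.repack_keys = [(chain, res_seq)] + shell

        # candidate rotamer coordinate sets per repackable residue
        self.candidates: list[list[_Candidate]] = []
        movable_atoms: set[int] = set()
        for key in self.repack_keys:
            c, r = key
            res_name = self.target if key == (chain, res_seq) else res_types[key]
            bb = {
                n: coords[structure.index_of((c, r, n))]
                for n in ("N", "CA", "C")
            }
            cands: list[_Candidate] = []
            max_w = max(w for w, _ in ROTAMERS[res_name])
            for w, chis in ROTAMERS[res_name]:
                if params.chi_jitter_deg > 0 and chis:
                    chis = tuple(
                        c + rng.normal(0.0, params.chi_jitter_deg) for c in chis
                    )
                side = build_side_chain(res_name, bb["N"], bb["CA"], bb["C"], chis)
                names = list(side)
                cands.append(
                    _Candidate(names, [side[n] for n in names], w, res_name)
                )
            if key != (chain, res_seq):
                # current (input) side chain as an extra zero-penalty state
                names = _side_chain_names(structure, c, r)
                if names:
                    native_coords = [
                        coords[structure.index_of((c, r, n))] for n in names
                    ]
                    cands.append(
                        _Candidate(names, native_coords, max_w, res_name)
                    )
            self.candidates.append(cands)
            for i in res_atoms[key]:
                if structure.atoms[i].atom_name not in BACKBONE_ATOMS:
                    movable_atoms.add(i)

        # environment: every heavy atom that is not a movable side chain,
        # excluding each residue's own + sequence-adjacent backbones from
        # its interaction list (bonded context)
        self.env_idx = np.array(
            [
                i
                for i, a in enumerate(structure.atoms)
                if a.is_heavy and i not in movable_atoms
            ],
            dtype=int,
        )
        self.env_coords = coords[self.env_idx]
        self.env_radii = np.array(
            [SASA_RADII.get(structure.atoms[i].element, 1.7) for i in self.env_idx]
        )
        self.env_charge = np.array(
            [
                PARTIAL_CHARGES.get(
                    (structure.atoms[i].res_name, structure.atoms[i].atom_name), 0.0
                )
                for i in self.env_idx
            ]
        )
        env_res = [
            (structure.atoms[i].chain_id, structure.atoms[i].res_seq)
            for i in self.env_idx
        ]

        # precompute E_env per (residue, candidate) and pair tables
        self.e_env: list[np.ndarray] = []
        for key, cands in zip(self.repack_keys, self.candidates):
            c, r = key
            own = np.array(
                [
                    (ec == c and abs(er - r) <= 1)
                    for ec, er in env_res
                ]
            )
            vals = np.empty(len(cands))
            for ci, cand in enumerate(cands):
                vals[ci] = self._interaction(
                    cand,
                    self.env_coords[~own],
                    self.env_radii[~own],
                    self.env_charge[~own],
                ) - params.prior_weight * math.log(max(cand.weight, 1e-9))
            self.e_env.append(vals)

        n = len(self.repack_keys)
        self.pair_tables: dict[tuple[int, int], np.ndarray] = {}
        for i in range(n):
            for j in range(i + 1, n):
                tab = np.zeros((len(self.candidates[i]), len(self.candidates[j])))
                nonzero = False
                for ci, cand_i in enumerate(self.candidates[i]):
                    for cj, cand_j in enumerate(self.candidates[j]):
                        e = self._interaction(
                            cand_i, cand_j.coords, cand_j.radii, cand_j.charges
                        )
                        tab[ci, cj] = e
                        nonzero = nonzero or e != 0.0
                if nonzero:
                    self.pair_tables[(i, j)] = tab

    # -- energy pieces -----------------------------------------------------
    def _interaction(self, cand, other_coords, other_radii, other_charge) -> float:
        if len(cand.coords) == 0 or len(other_coords) == 0:
            return 0.0
        p = self.params
        d = np.linalg.norm(
            cand.coords[:, None, :] - other_coords[None, :, :], axis=2
        )
        d = np.maximum(d, 0.5)
        sigma = p.sigma_scale * (cand.radii[:, None] + other_radii[None, :])
        overlap = np.where(d < sigma, sigma - d, 0.0)
        e_vdw = p.vdw_weight * float((overlap**2).sum())
        if np.any(cand.charges) and np.any(other_charge):
            e_elec = p.elec_weight * float(
                ((cand.charges[:, None] * other_charge[None, :]) / d**2).sum()
            )
        else:
            e_elec = 0.0
        return e_vdw + e_elec

    # -- annealing ---------------------------------------------------------
    def total_energy(self, state: np.ndarray) -> float:
        e = sum(self.e_env[i][state[i]] for i in range(len(state)))
        for (i, j), tab in self.pair_tables.items():
            e += tab[state[i], state[j]]
        return float(e)

    def anneal(self, rng: np.random.Generator) -> tuple[np.ndarray, float]:
        n = len(self.repack_keys)
        state = np.array([int(np.argmin(self.e_env[i])) for i in range(n)])
        energy = self.total_energy(state)
        best_state, best_e = state.copy(), energy
        for t in self.params.schedule.temperatures():
            for i in rng.permutation(n):
                k = len(self.candidates[i])
                if k < 2:
                    continue
                proposal = int(rng.integers(k))
                if proposal == state[i]:
                    continue
                delta = self.e_env[i][proposal] - self.e_env[i][state[i]]
                for (a, b), tab in self.pair_tables.items():
                    if a == i:
                        delta += tab[proposal, state[b]] - tab[state[i], state[b]]
                    elif b == i:
                        delta += tab[state[a], proposal] - tab[state[a], state[i]]
                if delta <= 0 or rng.random() < math.exp(-delta / t):
                    state[i] = proposal
                    energy += delta
                    if energy < best_e - 1e-12:
                        best_e, best_state = energy, state.copy()
        return best_state, float(best_e)

    def apply(self, state: np.ndarray) -> Structure:
        """Rebuild the structure with the chosen rotamer state.

        Backbone atoms are reused bitwise; the site residue's atom names
        switch to the target residue type.
        """
        chain, res_seq = self.repack_keys[0]
        replacement: dict[tuple[str, int], tuple[str, dict[str, np.ndarray]]] = {}
        for pos, key in enumerate(self.repack_keys):
            cand = self.candidates[pos][state[pos]]
            res_name = self.target if pos == 0 else None
            replacement[key] = (
                res_name,
                dict(zip(cand.names, cand.coords)),
            )
        new_atoms: list[AtomRecord] = []
        for a in self.structure.atoms:
            key = (a.chain_id, a.res_seq)
            if key not in replacement:
                new_atoms.append(a)
                continue
            res_name, side = replacement[key]
            if a.atom_name in BACKBONE_ATOMS:
                if res_name is not None and res_name != a.res_name:
                    a = AtomRecord(
                        a.chain_id, a.res_seq, res_name, a.atom_name,
                        a.element, a.coord, a.bfactor,
                    )
                new_atoms.append(a)
                if a.atom_name == "O":
                    # side chain inserted after the backbone block
                    final_res = res_name or a.res_name
                    for n, xyz in side.items():
                        new_atoms.append(
                            AtomRecord(
                                a.chain_id, a.res_seq, final_res, n,
                                element_of(n),
                                tuple(float(v) for v in xyz),
                            )
                        )
        return Structure(new_atoms, label=self.structure.label)


def mutate_and_repack(
    structure: Structure,
    mutation: Mutation | None,
    params: RepackParams | None = None,
    seed: int = 0,
    site: tuple[str, int] | None = None,
) -> tuple[Structure, float]:
    """Repack around a site, optionally substituting the residue type.

    With ``mutation=None`` and an explicit ``site``, performs a wild-type
    repack-only pass (used for the reference arms of the ΔΔG protocol).
    Backbone coordinates are never touched.
    """
    params = params or RepackParams()
    if mutation is not None:
        key = (mutation.chain_id, mutation.res_seq)
        to_res = mutation.to_res
        res_types = {(c, r): n for c, r, n in structure.residues()}
        if res_types.get(key) != mutation.from_res:
            raise ContractError(
                f"site {key} is {res_types.get(key)}, not {mutation.from_res}"
            )
    elif site is not None:
        key, to_res = site, None
    else:
        raise ContractError("need a mutation or an explicit site")
    rng = np.random.default_rng(seed)
    problem = _RepackProblem(structure, key, to_res, params, rng)
    state, energy = problem.anneal(rng)
    return problem.apply(state), energy


@dataclass
class DdgRecord:
    mutation: Mutation
    values: np.ndarray  # (n_centroids, n_runs) per-run ΔΔG
    n_runs: int

    @property
    def ddg_mean(self) -> float:
        return float(self.values.mean())

    @property
    def ddg_sem(self) -> float:
        """SEM over all pooled runs × centroids."""
        flat = self.values.ravel()
        if len(flat) < 2:
            return 0.0
        return float(flat.std(ddof=1) / math.sqrt(len(flat)))

    @property
    def sem_over_runs(self) -> float:
        per_run = self.values.mean(axis=0)
        if len(per_run) < 2:
            return 0.0
        return float(per_run.std(ddof=1) / math.sqrt(len(per_run)))

    @property
    def sem_over_centroids(self) -> float:
        per_c = self.values.mean(axis=1)
        if len(per_c) < 2:
            return 0.0
        return float(per_c.std(ddof=1) / math.sqrt(len(per_c)))


def _arm_energies(
    complex_structure: Structure,
    dimer_structure: Structure,
    mutation: Mutation | None,
    site: tuple[str, int],
    params: RepackParams,
    seed: int,
) -> tuple[float, float]:
    _, e_complex = mutate_and_repack(
        complex_structure, mutation, params=params, seed=seed, site=site
    )
    _, e_dimer = mutate_and_repack(
        dimer_structure, mutation, params=params, seed=seed, site=site
    )
    return e_complex, e_dimer


def ddg_of_mutation(
    centroids: Ensemble | Sequence[Structure],
    mutation: Mutation,
    chaperone_chain: str = "C",
    n_runs: int = 50,
    seed: int = 0,
    params: RepackParams | None = None,
) -> DdgRecord:
    """ΔΔG of one substitution over centroid structures.

    Each run repacks mutant and wild type in the complex and in the
    histone dimer (chaperone chain removed) with a shared per-run seed, so
    the annealing noise cancels pairwise.  The screen mutates the histone
    side only; a chaperone-chain site is a contract error.
    """
    if mutation.chain_id == chaperone_chain:
        raise ContractError("mutation screen operates on the histone side only")
    params = params or RepackParams()
    members = list(centroids)
    site = (mutation.chain_id, mutation.res_seq)
    values = np.zeros((len(members), n_runs))
    for ci, member in enumerate(members):
        dimer = member.drop_chains([chaperone_chain])
        for run in range(n_runs):
            run_seed = (seed * 1000003 + ci * 10007 + run * 101) % (2**31)
            mc, md = _arm_energies(member, dimer, mutation, site, params, run_seed)
            wc, wd = _arm_energies(member, dimer, None, site, params, run_seed)
            values[ci, run] = (mc - md) - (wc - wd)
    return DdgRecord(mutation, values, n_runs)


def wt_noise_floor(
    centroids: Ensemble | Sequence[Structure],
    site: tuple[str, int],
    chaperone_chain: str = "C",
    n_runs: int = 50,
    seed: int = 0,
    params: RepackParams | None = None,
    paired: bool = True,
) -> np.ndarray:
    """WT-vs-WT ΔΔG replicates: the screen's intrinsic noise at a site.

    With ``paired=True`` both arms share seeds and the result is exactly
    zero (algebraic cancellation); with ``paired=False`` the arms draw
    independent seeds, giving the annealing-noise floor.
    """
    params = params or RepackParams()
    members = list(centroids)
    values = np.zeros((len(members), n_runs))
    for ci, member in enumerate(members):
        dimer = member.drop_chains([chaperone_chain])
        for run in range(n_runs):
            s1 = (seed * 1000003 + ci * 10007 + run * 101) % (2**31)
            s2 = s1 if paired else (s1 + 7919) % (2**31)
            mc, md = _arm_energies(member, dimer, None, site, params, s1)
            wc, wd = _arm_energies(member, dimer, None, site, params, s2)
            values[ci, run] = (mc - md) - (wc - wd)
    return values


def screen_interface(
    centroids: Ensemble | Sequence[Structure],
    interface_residues: Sequence[tuple[str, int, str]],
    chaperone_chain: str = "C",
    n_runs: int = 50,
    seed: int = 0,
    params: RepackParams | None = None,
) -> tuple[pd.DataFrame, list[DdgRecord]]:
    """Full screen: every allowed substitution at every interface residue.

    Returns a table (mutation, site, ddg_mean, ddg_sem, n_runs) sorted by
    descending mean ΔΔG, plus the underlying records.  Deterministic for a
    given seed; the mutation set, not its input order, defines the result.
    """
    if not interface_residues:
        raise ContractError("no interface residues supplied")
    mutations = enumerate_mutations(sorted(interface_residues))
    records = [
        ddg_of_mutation(
            centroids, m, chaperone_chain=chaperone_chain,
            n_runs=n_runs, seed=seed, params=params,
        )
        for m in mutations
    ]
    rows = [
        {
            "mutation": r.mutation.label,
            "chain": r.mutation.chain_id,
            "res_seq": r.mutation.res_seq,
            "ddg_mean": r.ddg_mean,
            "ddg_sem": r.ddg_sem,
            "n_runs": r.n_runs * r.values.shape[0],
        }
        for r in records
    ]
    table = pd.DataFrame(rows).sort_values(
        ["ddg_mean", "mutation"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    order = {row["mutation"]: i for i, row in table.iterrows()}
    records.sort(key=lambda r: order[r.mutation.label])
    return table, records
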