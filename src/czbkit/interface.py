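"""Interface analysis: heavy-atom contacts, solvent-accessible surface area
and buried-surface statistics, plus a B-factor heat-map export.

A contact is a heavy-atom pair — one atom per group — within 6 Å
(inclusive).  SASA uses the Shrake–Rupley sphere-point method with
golden-spiral points (default 960) and a 1.4 Å water probe; buried SASA of
a two-group partition is SASA(A) + SASA(B) − SASA(AB).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ContractError, RadiusError
from .geometry import golden_spiral_points
from .residues import SASA_RADII
from .structio import AtomKey, AtomSelector, Ensemble, Structure, write_structure_models

ResidueKey = tuple[str, int]

DEFAULT_CONTACT_CUTOFF = 6.0
DEFAULT_PROBE = 1.4
DEFAULT_SPHERE_POINTS = 960


@dataclass
class ContactCounts:
    """Contacts of one structure across a two-group partition."""

    per_residue_a: dict[ResidueKey, int]
    per_residue_b: dict[ResidueKey, int]
    total: int


@dataclass
class InterfaceProfile:
    """Ensemble-averaged per-residue contact counts."""

    per_residue: dict[ResidueKey, float]
    totals: list[int]  # total contacts per member
    group_a: AtomSelector = None
    group_b: AtomSelector = None

    @property
    def mean_total(self) -> float:
        return float(np.mean(self.totals))


def _heavy_indices(structure: Structure, selector: AtomSelector) -> np.ndarray:
    idx = selector.indices(structure)
    return np.array(
        [i for i in idx if structure.atoms[i].is_heavy], dtype=int
    )


def count_contacts(
    structure: Structure,
    group_a: AtomSelector,
    group_b: AtomSelector,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactCounts:
    """Heavy-atom pairs across two disjoint groups within ``cutoff`` Å.

    The cutoff is inclusive (a pair at exactly 6.00 Å counts).  Each
    qualifying pair increments the count of its residue on both sides, so
    the per-side sums and the total all agree.
    """
    ia = _heavy_indices(structure, group_a)
    ib = _heavy_indices(structure, group_b)
    if np.intersect1d(ia, ib).size:
        raise ContractError("contact groups overlap")
    coords = structure.coords
    per_a: dict[ResidueKey, int] = {}
    per_b: dict[ResidueKey, int] = {}
    total = 0
    if len(ia) and len(ib):
        d = np.linalg.norm(
            coords[ia][:, None, :] - coords[ib][None, :, :], axis=2
        )
        pairs = np.argwhere(d <= cutoff)
        total = len(pairs)
        for pi, pj in pairs:
            aa = structure.atoms[ia[pi]]
            ab = structure.atoms[ib[pj]]
            per_a[(aa.chain_id, aa.res_seq)] = per_a.get((aa.chain_id, aa.res_seq), 0) + 1
            per_b[(ab.chain_id, ab.res_seq)] = per_b.get((ab.chain_id, ab.res_seq), 0) + 1
    return ContactCounts(per_a, per_b, int(total))


def average_contacts(
    ensemble: Ensemble,
    group_a: AtomSelector,
    group_b: AtomSelector,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> InterfaceProfile:
    """Per-residue contact counts averaged over ensemble members."""
    sums: dict[ResidueKey, float] = {}
    totals: list[int] = []
    for member in ensemble:
        cc = count_contacts(member, group_a, group_b, cutoff)
        totals.append(cc.total)
        for side in (cc.per_residue_a, cc.per_residue_b):
            for key, n in side.items():
                sums[key] = sums.get(key, 0.0) + n
    n_members = len(ensemble)
    per_residue = {k: v / n_members for k, v in sums.items()}
    return InterfaceProfile(per_residue, totals, group_a, group_b)


@dataclass
class SasaResult:
    atom_sasa: np.ndarray  # Å² per atom, structure order
    per_chain: dict[str, float]
    probe: float
    points: int

    @property
    def total(self) -> float:
        return float(self.atom_sasa.sum())


def compute_sasa(
    structure: Structure,
    radii: dict[str, float] | None = None,
    probe: float = DEFAULT_PROBE,
    points: int = DEFAULT_SPHERE_POINTS,
) -> SasaResult:
    """Shrake–Rupley SASA with golden-spiral sphere points.

    Hydrogens are ignored (zero area and not occluders), matching the
    heavy-atom view used throughout the interface analysis.
    """
    radii = radii or SASA_RADII
    heavy = [i for i, a in enumerate(structure.atoms) if a.is_heavy]
    for i in heavy:
        el = structure.atoms[i].element
        if el not in radii:
            raise RadiusError(f"no radius for element {el!r}")
    coords = structure.coords[heavy]
    rad = np.array([radii[structure.atoms[i].element] for i in heavy])
    sphere = golden_spiral_points(points)
    expanded = rad + probe
    tree = cKDTree(coords)
    atom_sasa = np.zeros(len(structure))
    max_reach = 2 * (rad.max() + probe)
    for n, i in enumerate(heavy):
        center = coords[n]
        ri = expanded[n]
        neigh = [
            m for m in tree.query_ball_point(center, ri + rad.max() + probe)
            if m != n
        ]
        pts = center + ri * sphere
        if neigh:
            nb = np.array(neigh, dtype=int)
            d = np.linalg.norm(
                pts[:, None, :] - coords[nb][None, :, :], axis=2
            )
            accessible = np.all(d >= expanded[nb][None, :], axis=1)
        else:
            accessible = np.ones(points, dtype=bool)
        atom_sasa[i] = 4.0 * np.pi * ri**2 * accessible.mean()
    per_chain: dict[str, float] = {}
    for i, a in enumerate(structure.atoms):
        per_chain[a.chain_id] = per_chain.get(a.chain_id, 0.0) + atom_sasa[i]
    return SasaResult(atom_sasa, per_chain, probe, points)


def buried_sasa(
    complex_structure: Structure,
    partition: tuple[tuple[str, ...], tuple[str, ...]],
    radii: dict[str, float] | None = None,
    probe: float = DEFAULT_PROBE,
    points: int = DEFAULT_SPHERE_POINTS,
) -> float:
    """Buried surface SASA(A) + SASA(B) − SASA(AB) for a chain partition."""
    group_a, group_b = (tuple(partition[0]), tuple(partition[1]))
    chains = set(complex_structure.chain_ids)
    if set(group_a) & set(group_b):
        raise ContractError("partition groups overlap")
    if set(group_a) | set(group_b) != chains:
        missing = chains - (set(group_a) | set(group_b))
        raise ContractError(f"partition does not cover chains {sorted(missing)}")
    sub_a = complex_structure.drop_chains(group_b)
    sub_b = complex_structure.drop_chains(group_a)
    kwargs = dict(radii=radii, probe=probe, points=points)
    return (
        compute_sasa(sub_a, **kwargs).total
        + compute_sasa(sub_b, **kwargs).total
        - compute_sasa(complex_structure, **kwargs).total
    )


def buried_sasa_ensemble(
    ensemble: Ensemble,
    partition: tuple[tuple[str, ...], tuple[str, ...]],
    **kwargs,
) -> tuple[float, float, np.ndarray]:
    """Mean, SD (over members) and per-member buried SASA of an ensemble.

    The spread statistic reported is the standard deviation across members,
    labelled as such.
    """
    values = np.array(
        [buried_sasa(m, partition, **kwargs) for m in ensemble]
    )
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return float(values.mean()), sd, values


def export_heatmap(
    structure: Structure,
    profile: InterfaceProfile,
    path: str | Path,
    tsv_path: str | Path | None = None,
) -> tuple[Path, Path]:
    """Write a PDB whose B-factors carry per-residue average contact counts.

    Atoms of residues absent from the profile get B = 0.  A companion TSV
    (chain, resseq, resname, avg_contacts) covers the residues of the two
    analysed groups.
    """
    path = Path(path)
    tsv_path = Path(tsv_path) if tsv_path is not None else path.with_suffix(".tsv")
    for (chain, res_seq) in profile.per_residue:
        if not any(
            a.chain_id == chain and a.res_seq == res_seq for a in structure.atoms
        ):
            raise ContractError(f"profile residue {(chain, res_seq)} not in structure")
    bfactors = {
        atom.key: float(profile.per_residue.get((atom.chain_id, atom.res_seq), 0.0))
        for atom in structure.atoms
    }
    write_structure_models(structure, path, bfactor_source=bfactors)

    rows = []
    group_selectors = [s for s in (profile.group_a, profile.group_b) if s is not None]
    group_residues: set[ResidueKey] | None = None
    if group_selectors:
        group_residues = set()
        for sel in group_selectors:
            for i in sel.indices(structure):
                a = structure.atoms[i]
                group_residues.add((a.chain_id, a.res_seq))
    for chain, res_seq, res_name in structure.residues():
        if group_residues is not None and (chain, res_seq) not in group_residues:
            continue
        rows.append(
            {
                "chain": chain,
                "resseq": res_seq,
                "resname": res_name,
                "avg_contacts": profile.per_residue.get((chain, res_seq), 0.0),
            }
        )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    return path, tsv_path
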