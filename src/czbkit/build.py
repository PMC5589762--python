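"""Idealised peptide construction: backbones from torsions, side chains from
rotamer chi angles, and chains threaded along an arbitrary Cα path.

These builders produce toy all-atom models with standard local geometry; they
make no claim of force-field-level realism and are used by the synthetic-data
generator and by the side-chain repacking screen (which rebuilds side chains
on fixed backbones).
"""

from __future__ import annotations

import numpy as np

from .geometry import place_atom
from .residues import (
    BB_GEOMETRY,
    CB_ROW,
    N_CHI,
    ROTAMERS,
    SIDE_CHAIN_ZMAT,
    element_of,
)
from .structio import AtomRecord, Structure


def build_side_chain(
    res_name: str,
    n: np.ndarray,
    ca: np.ndarray,
    c: np.ndarray,
    chis: tuple[float, ...] | None = None,
) -> dict[str, np.ndarray]:
    """Heavy side-chain atom positions (CB outward) on a given backbone.

    ``chis`` defaults to the highest-weight rotamer of the residue type.
    """
    if res_name == "GLY":
        return {}
    if chis is None:
        chis = max(ROTAMERS[res_name], key=lambda wc: wc[0])[1]
    if len(chis) < N_CHI[res_name]:
        raise ValueError(
            f"{res_name} needs {N_CHI[res_name]} chi angles, got {len(chis)}"
        )
    placed: dict[str, np.ndarray] = {"N": np.asarray(n, float),
                                     "CA": np.asarray(ca, float),
                                     "C": np.asarray(c, float)}
    name, a, b, cref, bond, angle, torsion = CB_ROW
    placed["CB"] = place_atom(placed[a], placed[b], placed[cref], bond, angle, torsion)
    for row in SIDE_CHAIN_ZMAT[res_name]:
        name, a, b, cref, bond, angle, torsion = row
        if isinstance(torsion, tuple):
            _, k, offset = torsion
            tors = chis[k - 1] + offset
        else:
            tors = torsion
        placed[name] = place_atom(placed[a], placed[b], placed[cref], bond, angle, tors)
    return {k: v for k, v in placed.items() if k not in ("N", "CA", "C")}


def build_backbone(
    n_res: int,
    phi: float | list[float],
    psi: float | list[float],
    omega: float = 180.0,
) -> list[dict[str, np.ndarray]]:
    """Backbone (N, CA, C, O) of an ``n_res`` peptide from torsions (NeRF)."""
    phis = [phi] * n_res if np.isscalar(phi) else list(phi)
    psis = [psi] * n_res if np.isscalar(psi) else list(psi)
    g = BB_GEOMETRY
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([g["N-CA"], 0.0, 0.0])
    ang = np.radians(g["N-CA-C"])
    c0 = ca0 + g["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[-1]
        n_next = place_atom(
            prev["N"], prev["CA"], prev["C"], g["C-N"], g["CA-C-N"], psis[i - 1]
        )
        ca_next = place_atom(
            prev["CA"], prev["C"], n_next, g["N-CA"], g["C-N-CA"], omega
        )
        c_next = place_atom(
            prev["C"], n_next, ca_next, g["CA-C"], g["N-CA-C"], phis[i]
        )
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    # carbonyl oxygens: anti to the next N (trans peptide plane)
    for i, r in enumerate(res):
        if i + 1 < n_res:
            o_tors = (
                _dihedral4(res[i + 1]["N"], r["N"], r["CA"], r["C"]) + 180.0
            )
        else:
            o_tors = psis[i] + 180.0
        r["O"] = place_atom(r["N"], r["CA"], r["C"], g["C-O"], g["CA-C-O"], o_tors)
    return res


def _dihedral4(ref, a, b, c) -> float:
    from .geometry import dihedral

    return dihedral(ref, a, b, c)


def backbone_from_ca_path(
    ca_path: np.ndarray, up_hints: np.ndarray
) -> list[dict[str, np.ndarray]]:
    """Backbone atoms threaded along an explicit Cα path.

    ``up_hints`` (one unit-ish vector per residue) orients the local peptide
    frame; N and C are tilted off the chain tangent so that angle(N, CA, C)
    is near ideal and successive C–N distances land near the peptide bond
    length when consecutive Cα are ~3.8 Å apart.  Local geometry is standard;
    inter-residue closure is approximate (toy construction).
    """
    ca_path = np.asarray(ca_path, float)
    n_res = len(ca_path)
    g = BB_GEOMETRY
    tilt = np.radians(34.5)
    out: list[dict[str, np.ndarray]] = []
    for i in range(n_res):
        if i == 0:
            t = ca_path[1] - ca_path[0]
        elif i == n_res - 1:
            t = ca_path[-1] - ca_path[-2]
        else:
            t = ca_path[i + 1] - ca_path[i - 1]
        t = t / np.linalg.norm(t)
        u = np.asarray(up_hints[i], float)
        w = u - np.dot(u, t) * t
        nw = np.linalg.norm(w)
        if nw < 1e-8:
            w = np.cross(t, [0.0, 0.0, 1.0])
            nw = np.linalg.norm(w)
        w = w / nw
        ca = ca_path[i]
        n_at = ca + g["N-CA"] * (-t * np.cos(tilt) - w * np.sin(tilt))
        c_at = ca + g["CA-C"] * (t * np.cos(tilt) - w * np.sin(tilt))
        o_at = place_atom(n_at, ca, c_at, g["C-O"], g["CA-C-O"], 140.0)
        out.append({"N": n_at, "CA": ca.copy(), "C": c_at, "O": o_at})
    return out


def assemble_chain(
    chain_id: str,
    sequence: list[str],
    backbones: list[dict[str, np.ndarray]],
    chi_choices: list[tuple[float, ...] | None] | None = None,
    start_res_seq: int = 1,
    avoid_coords: np.ndarray | None = None,
) -> list[AtomRecord]:
    """AtomRecords for one chain: backbone + side chains, residues in order.

    When ``avoid_coords`` is given (an (m, 3) array of context atoms), each
    residue's rotamer is chosen greedily as the library entry whose side
    chain keeps the largest minimum distance to the context plus the chain's
    own backbone and previously placed side chains — a deterministic
    clash-avoidance pass for generator use.
    """
    avoid: np.ndarray | None = None
    bb_per_res: list[np.ndarray] = []
    placed_sides: list[np.ndarray] = []
    if avoid_coords is not None:
        avoid = np.asarray(avoid_coords, float).reshape(-1, 3)
        # CB is backbone-determined, so include it in the fixed context
        bb_per_res = []
        for res_name, bb in zip(sequence, backbones):
            pts = [bb[n] for n in ("N", "CA", "C", "O")]
            if res_name != "GLY":
                name, a, b, cref, bond, angle, torsion = CB_ROW
                pts.append(place_atom(bb[a], bb[b], bb[cref], bond, angle, torsion))
            bb_per_res.append(np.array(pts))
    records: list[AtomRecord] = []
    for i, (res_name, bb) in enumerate(zip(sequence, backbones)):
        res_seq = start_res_seq + i
        chis = None if chi_choices is None else chi_choices[i]
        if chis is None and avoid is not None and res_name not in ("GLY", "ALA"):
            # other residues' backbones + context + side chains placed so far
            ctx = np.vstack(
                [avoid]
                + [b for j, b in enumerate(bb_per_res) if j != i]
                + placed_sides
            )
            best, best_clear = None, -np.inf
            for w, cand in ROTAMERS[res_name]:
                side_try = build_side_chain(res_name, bb["N"], bb["CA"], bb["C"], cand)
                pts = np.array([side_try[n] for n in side_try if n != "CB"])
                if len(pts) == 0:
                    best = cand
                    break
                clear = float(
                    np.min(np.linalg.norm(ctx[None, :, :] - pts[:, None, :], axis=2))
                )
                if clear > best_clear + 1e-9:
                    best_clear, best = clear, cand
            chis = best
        side = build_side_chain(res_name, bb["N"], bb["CA"], bb["C"], chis)
        if avoid is not None and side:
            placed_sides.append(np.array(list(side.values())))
        for name in ("N", "CA", "C", "O"):
            records.append(
                AtomRecord(chain_id, res_seq, res_name, name, element_of(name),
                           tuple(float(v) for v in bb[name]))
            )
        for name, pos in side.items():
            records.append(
                AtomRecord(chain_id, res_seq, res_name, name, element_of(name),
                           tuple(float(v) for v in pos))
            )
    return records


def clash_pairs(
    structure: Structure, threshold: float = 2.4
) -> list[tuple[int, int, float]]:
    """Non-bonded heavy-atom pairs closer than ``threshold`` Å.

    Pairs within one residue, and backbone–backbone pairs of sequence
    neighbours in the same chain, are treated as bonded context and skipped.
    """
    from scipy.spatial import cKDTree

    heavy = [i for i, a in enumerate(structure.atoms) if a.is_heavy]
    coords = structure.coords[heavy]
    tree = cKDTree(coords)
    bb = {"N", "CA", "C", "O"}
    out = []
    for ii, jj in tree.query_pairs(threshold):
        i, j = heavy[ii], heavy[jj]
        ai, aj = structure.atoms[i], structure.atoms[j]
        if ai.chain_id == aj.chain_id:
            if ai.res_seq == aj.res_seq:
                continue
            if (
                abs(ai.res_seq - aj.res_seq) == 1
                and ai.atom_name in bb
                and aj.atom_name in bb
            ):
                continue
            # CB of a residue sits ~2.4 Å from its neighbours' backbone
            if abs(ai.res_seq - aj.res_seq) == 1 and {
                ai.atom_name, aj.atom_name
            } & bb and {ai.atom_name, aj.atom_name} & {"CB"}:
                continue
        d = float(np.linalg.norm(np.array(ai.coord) - np.array(aj.coord)))
        out.append((i, j, d))
    return out
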