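"""Synthetic fixtures: a toy chaperone–histone complex, ground-truth NOE
restraints, graded decoy ensembles and a planted ΔΔG benchmark.

The toy geometry mimics the arrangement of an intrinsically disordered
chaperone bound to a compact histone dimer: two short α-helices (chains A, B)
form the "histone core" and an extended chain C wraps around a configurable
fraction of the core's circumference at a controlled contact spacing.
Everything is deterministic under a seed and emitted in standard formats so
every other module can be tested without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .build import (
    assemble_chain,
    backbone_from_ca_path,
    build_backbone,
    clash_pairs,
)
from .errors import GenerationError
from .restraints import NOERestraint, RestraintSet
from .structio import AtomRecord, Ensemble, Structure

CA_SPACING = 3.8  # Å between consecutive Cα along the wrapped chain

# fixed core sequences (pattern repeated/truncated to the requested length):
# small residues keep the idealised helix pair compact and clash-free, and
# keep the core's convex outline close to its backbone so the wrapped chain
# stays in contact along the whole arc.
_CORE_PATTERN_A = ["ALA", "SER", "ALA", "THR", "ALA", "SER"]
_CORE_PATTERN_B = ["SER", "ALA", "THR", "ALA", "SER", "ALA"]
_CHAPERONE_PATTERN = ["SER", "ALA", "GLY", "THR", "ALA", "SER"]


@dataclass
class ToySpec:
    """Geometry of the synthetic complex.

    ``wrap_fraction`` is the fraction of the core circumference covered by
    the chaperone chain (default two thirds, the lasso-like arrangement);
    ``contact_spacing`` is the gap between the chaperone backbone and the
    outermost core atoms.  ``chaperone_len=None`` sizes chain C to just
    cover the wrap (plus a two-residue tail).
    """

    core_len: int = 18
    chaperone_len: int | None = None
    wrap_fraction: float = 2.0 / 3.0
    contact_spacing: float = 4.0
    helix_separation: float = 10.5
    seed: int = 0

    def __post_init__(self):
        if self.core_len < 3:
            raise ValueError("core chains need at least 3 residues")
        if self.chaperone_len is not None and self.chaperone_len < 3:
            raise ValueError("chaperone needs at least 3 residues")
        if not (0.0 < self.wrap_fraction <= 1.0):
            raise ValueError("wrap fraction must be in (0, 1]")


@dataclass
class DecoySpec:
    """Decoy ensemble: Gaussian chaperone perturbation at graded σ levels."""

    sigma_levels: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)
    members_per_level: int = 10
    seed: int = 0

    def __post_init__(self):
        if any(s < 0 for s in self.sigma_levels):
            raise ValueError("sigma levels must be non-negative")
        if self.members_per_level < 1:
            raise ValueError("members_per_level must be >= 1")


def _repeat_pattern(pattern: list[str], n: int) -> list[str]:
    return [pattern[i % len(pattern)] for i in range(n)]


def _axis_align_z(coords: np.ndarray) -> np.ndarray:
    """Rotation+centering matrix pair aligning the principal axis with z."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s < 1e-10:
        return centered
    c = float(np.dot(axis, z))
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return centered @ rot.T


def _helix_backbones(n_res: int, flip: bool, x_shift: float):
    """Ideal α-helix backbone dicts, axis on z, optionally flipped, shifted."""
    bbs = build_backbone(n_res, phi=-57.0, psi=-47.0)
    names = ("N", "CA", "C", "O")
    flat = np.array([bb[n] for bb in bbs for n in names])
    flat = _axis_align_z(flat)
    if flip:
        flat = flat @ np.diag([-1.0, 1.0, -1.0])
    flat[:, 0] += x_shift
    out = []
    for i in range(n_res):
        out.append({n: flat[4 * i + j] for j, n in enumerate(names)})
    return out


def _radius_for_clearance(core_coords: np.ndarray, angle: float, spacing: float) -> float:
    """Radius r so that (r·cosθ, r·sinθ, 0) sits ``spacing`` Å from the core.

    The nearest-core-atom distance grows monotonically with r outside the
    core, so a bisection on r is exact enough at 10⁻³ Å.
    """
    direction = np.array([np.cos(angle), np.sin(angle), 0.0])

    def clearance(r: float) -> float:
        p = r * direction
        return float(np.linalg.norm(core_coords - p, axis=1).min()) - spacing

    lo, hi = 0.0, 60.0
    if clearance(hi) < 0:
        raise GenerationError("core too large for wrap construction")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if clearance(mid) < 0:
            lo = mid
        else:
            hi = mid
    return hi


def make_toy_complex(spec: ToySpec | None = None) -> Structure:
    """Build the two-helix core (chains A, B) with wrapped chain C."""
    spec = spec or ToySpec()
    seq_a = _repeat_pattern(_CORE_PATTERN_A, spec.core_len)
    seq_b = _repeat_pattern(_CORE_PATTERN_B, spec.core_len)

    half = spec.helix_separation / 2.0
    bbs_a = _helix_backbones(spec.core_len, flip=False, x_shift=-half)
    bbs_b = _helix_backbones(spec.core_len, flip=True, x_shift=half)

    # side chains placed with cross-chain clash avoidance
    rec_a = assemble_chain("A", seq_a, bbs_a, avoid_coords=np.empty((0, 3)))
    coords_a = np.array([r.coord for r in rec_a])
    rec_b = assemble_chain("B", seq_b, bbs_b, avoid_coords=coords_a)
    core_records = rec_a + rec_b
    core_heavy = np.array(
        [r.coord for r in core_records if r.element != "H"]
    )

    # Path radius from the support function of the core's xy footprint:
    # the wrap follows the convex outline of the core at ``contact_spacing``
    # clearance, so it can neither dive into the inter-helix groove nor
    # clash with protruding side chains.
    xy = core_heavy[:, :2]

    def radius_at(angle: float) -> float:
        u = np.array([np.cos(angle), np.sin(angle)])
        return float((xy @ u).max()) + spec.contact_spacing

    def point_at(angle: float) -> np.ndarray:
        r = radius_at(angle)
        return np.array([r * np.cos(angle), r * np.sin(angle), 0.0])

    # march chain C Cα positions around the core at z = 0 (core mid-height)
    span = spec.wrap_fraction * 2.0 * np.pi
    theta = 0.0
    ca_path = [point_at(0.0)]
    wrapped = 1
    while True:
        dtheta = CA_SPACING / radius_at(theta)
        for _ in range(2):
            step = float(np.linalg.norm(point_at(theta + dtheta) - ca_path[-1]))
            dtheta *= CA_SPACING / step
        if theta + dtheta > span:
            break
        theta += dtheta
        ca_path.append(point_at(theta))
        wrapped += 1

    n_chap = spec.chaperone_len if spec.chaperone_len is not None else wrapped + 2
    if n_chap < 3:
        n_chap = 3
    # tail: continue along the exit tangent, drifting outward
    while len(ca_path) < n_chap:
        if len(ca_path) >= 2:
            t = ca_path[-1] - ca_path[-2]
            t = t / np.linalg.norm(t)
        else:
            t = np.array([0.0, 1.0, 0.0])
        outward = ca_path[-1] / np.linalg.norm(ca_path[-1])
        step_dir = t + 0.35 * outward
        step_dir /= np.linalg.norm(step_dir)
        ca_path.append(ca_path[-1] + CA_SPACING * step_dir)
    ca_path = np.array(ca_path[:n_chap])

    # local frames: tilt backbone toward the core, side chains point outward
    up_hints = ca_path / np.linalg.norm(ca_path, axis=1, keepdims=True)
    bbs = backbone_from_ca_path(ca_path, up_hints)
    seq_c = _repeat_pattern(_CHAPERONE_PATTERN, n_chap)
    core_coords_all = np.array([r.coord for r in core_records])
    rec_c = assemble_chain("C", seq_c, bbs, avoid_coords=core_coords_all)

    structure = Structure(core_records + rec_c, label=f"toy-seed{spec.seed}")
    clashes = clash_pairs(structure, threshold=2.4)
    if clashes:
        i, j, d = clashes[0]
        raise GenerationError(
            f"reference clash: {structure.atoms[i].key} vs "
            f"{structure.atoms[j].key} at {d:.2f} Å "
            f"({len(clashes)} pairs total) — infeasible spec"
        )
    return structure


def derive_true_restraints(
    structure: Structure,
    n_per_residue: int = 2,
    slack: float = 0.5,
    chaperone_chain: str = "C",
    max_reference_distance: float = 5.0,
) -> RestraintSet:
    """Cross-chain heavy-atom restraints consistent with the reference.

    For every chaperone residue, up to ``n_per_residue`` of its shortest
    heavy-atom contacts (≤ ``max_reference_distance`` Å) with the core are
    turned into upper bounds ``r + slack``, so the reference itself has zero
    violation by construction.
    """
    if slack < 0:
        raise ValueError("slack must be non-negative")
    chap_idx = [
        i for i, a in enumerate(structure.atoms)
        if a.chain_id == chaperone_chain and a.is_heavy
    ]
    core_idx = [
        i for i, a in enumerate(structure.atoms)
        if a.chain_id != chaperone_chain and a.is_heavy
    ]
    if not chap_idx or not core_idx:
        raise GenerationError("no interface: need chaperone and core chains")
    coords = structure.coords
    core_coords = coords[core_idx]
    by_residue: dict[int, list[tuple[float, int, int]]] = {}
    for i in chap_idx:
        d = np.linalg.norm(core_coords - coords[i], axis=1)
        for jj in np.flatnonzero(d <= max_reference_distance):
            j = core_idx[jj]
            res = structure.atoms[i].res_seq
            by_residue.setdefault(res, []).append((float(d[jj]), i, j))
    restraints: list[NOERestraint] = []
    for res in sorted(by_residue):
        picks = sorted(by_residue[res], key=lambda t: (t[0], t[1], t[2]))
        for dist, i, j in picks[:n_per_residue]:
            restraints.append(
                NOERestraint(
                    structure.atoms[i].key,
                    structure.atoms[j].key,
                    upper_bound=dist + slack,
                    interface=True,
                )
            )
    if not restraints:
        raise GenerationError(
            f"no heavy-atom pairs within {max_reference_distance} Å across the interface"
        )
    return RestraintSet(restraints, provenance="synthetic-truth")


def write_restraint_table(rset: RestraintSet, path: str | Path) -> Path:
    """Serialise a restraint set in the package's table dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# chain resseq atomname chain resseq atomname upper_A\n")
        for r in rset:
            fh.write(
                f"{r.atom_a[0]} {r.atom_a[1]} {r.atom_a[2]} "
                f"{r.atom_b[0]} {r.atom_b[1]} {r.atom_b[2]} "
                f"{r.upper_bound:.3f}\n"
            )
    return path


def make_decoy_ensemble(
    structure: Structure,
    spec: DecoySpec | None = None,
    chaperone_chain: str = "C",
) -> tuple[Ensemble, np.ndarray]:
    """Decoys with the chaperone perturbed by zero-mean Gaussian noise.

    Returns the ensemble plus the per-member ground-truth σ labels (also
    attached as the ``sigma`` annotation).
    """
    spec = spec or DecoySpec()
    rng = np.random.default_rng(spec.seed)
    chap_mask = np.array(
        [a.chain_id == chaperone_chain for a in structure.atoms]
    )
    members: list[Structure] = []
    labels: list[float] = []
    base = structure.coords
    for sigma in spec.sigma_levels:
        for m in range(spec.members_per_level):
            coords = base.copy()
            if sigma > 0:
                coords[chap_mask] += rng.normal(
                    0.0, sigma, size=(int(chap_mask.sum()), 3)
                )
            members.append(
                structure.with_coords(coords, label=f"decoy-s{sigma:g}-{m}")
            )
            labels.append(sigma)
    ens = Ensemble(members)
    ens.set_annotation("sigma", labels)
    return ens, np.array(labels)


@dataclass(frozen=True)
class PlantedSite:
    """A benchmark site with its expected mutational effect."""

    chain_id: str
    res_seq: int
    res_name: str
    to_res: str
    expected_sign: int  # +1 destabilising, 0 null


def make_ddg_benchmark(
    seed: int = 0,
) -> tuple[Ensemble, list[PlantedSite]]:
    """Toy centroids plus planted mutation sites of known-sign effect.

    Site 1: a small (ALA) core residue whose Cβ direction points at the
    chaperone — enlarging it must clash (expected ΔΔG > 0).  Site 2: a
    solvent-exposed residue with no chaperone atom within 12 Å (expected
    |ΔΔG| ≈ 0).  Three lightly jittered copies of the reference stand in
    for refined-ensemble centroids.
    """
    from .build import build_side_chain
    from .residues import ROTAMERS

    structure = make_toy_complex(ToySpec(seed=seed))
    coords = structure.coords
    chap_heavy = np.array(
        [a.is_heavy and a.chain_id == "C" for a in structure.atoms]
    )
    chap_coords = coords[chap_heavy]
    # atoms the repacker can never move: chaperone backbone + CB
    chap_fixed = coords[
        np.array(
            [
                a.is_heavy
                and a.chain_id == "C"
                and a.atom_name in ("N", "CA", "C", "O", "CB")
                for a in structure.atoms
            ]
        )
    ]

    clash_site = None
    best_probe_dist = np.inf
    worst_rotamer_best = np.inf
    distal_site = None
    best_distal = -np.inf
    for chain, res_seq, res_name in structure.residues():
        if chain == "C" or res_name != "ALA":
            continue
        try:
            bb = {
                n: coords[structure.index_of((chain, res_seq, n))]
                for n in ("N", "CA", "C")
            }
            cb = coords[structure.index_of((chain, res_seq, "CB"))]
        except KeyError:
            continue
        ca = bb["CA"]
        direction = cb - ca
        direction /= np.linalg.norm(direction)
        # probe just beyond CB, where the first atom of a larger side chain sits
        probe = ca + 2.9 * direction
        d_probe = float(np.linalg.norm(chap_coords - probe, axis=1).min())
        # clash must be unavoidable: every rotamer of the enlarged residue
        # has to overlap immovable chaperone atoms
        worst = -np.inf
        for _, chis in ROTAMERS["TRP"]:
            side = build_side_chain("TRP", bb["N"], bb["CA"], bb["C"], chis)
            pts = np.array(list(side.values()))
            d = float(
                np.linalg.norm(pts[:, None, :] - chap_fixed[None, :, :], axis=2).min()
            )
            worst = max(worst, d)
        res_atoms = [
            i for i, a in enumerate(structure.atoms)
            if a.chain_id == chain and a.res_seq == res_seq
        ]
        d_res = float(
            min(
                np.linalg.norm(chap_coords - coords[i], axis=1).min()
                for i in res_atoms
            )
        )
        if worst < worst_rotamer_best and d_probe < 4.0:
            worst_rotamer_best = worst
            best_probe_dist = d_probe
            clash_site = (chain, res_seq, res_name)
        if d_res > best_distal:
            best_distal = d_res
            distal_site = (chain, res_seq, res_name)
    if clash_site is None or worst_rotamer_best >= 2.9:
        raise GenerationError(
            f"no ALA site forces a chaperone clash (best evasion "
            f"{worst_rotamer_best:.2f} Å, probe {best_probe_dist:.2f} Å)"
        )
    if distal_site is None or best_distal <= 12.0:
        raise GenerationError(
            f"no ALA site is distal to the chaperone (farthest {best_distal:.2f} Å)"
        )

    rng = np.random.default_rng(seed + 101)
    members = [structure.with_coords(coords, label="centroid-0")]
    for m in (1, 2):
        jitter = rng.normal(0.0, 0.05, size=coords.shape)
        members.append(
            structure.with_coords(coords + jitter, label=f"centroid-{m}")
        )
    sites = [
        PlantedSite(*clash_site, to_res="TRP", expected_sign=1),
        PlantedSite(*distal_site, to_res="TRP", expected_sign=0),
    ]
    return Ensemble(members), sites
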