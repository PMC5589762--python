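"""NOE distance restraints: parsing, modification rules, violations, energies.

NOE cross-peaks yield *upper bounds* on interproton distances.  Because the
NOE signal scales as r⁻⁶, the distance an ensemble effectively presents to
the experiment is the inverse sixth root of the mean of r⁻⁶ over members —
short-distance conformers dominate.  Violations are one-sided:
``max(0, r − upper_bound)``.

Two standard preprocessing rules are implemented for force fields without
aliphatic hydrogens:

1. an aliphatic-hydrogen endpoint is remapped to its bonded carbon and the
   bound grows by 1 Å per remapped endpoint (extra bond length);
2. all bounds are padded by 1 Å for the NOE signal's standard deviation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import RestraintResolutionError, SelectionError
from .residues import element_of, is_aliphatic_hydrogen, parent_heavy_atom
from .structio import AtomKey, Ensemble, Structure

DEFAULT_CHAPERONE_CHAIN = "C"


@dataclass(frozen=True)
class NOERestraint:
    """One atom-pair upper-bound restraint (Å)."""

    atom_a: AtomKey
    atom_b: AtomKey
    upper_bound: float
    remapped_aliphatic_a: bool = False
    remapped_aliphatic_b: bool = False
    padded: bool = False
    interface: bool = False

    def __post_init__(self):
        if self.upper_bound <= 0:
            raise ValueError("upper_bound must be positive")
        if self.atom_a == self.atom_b:
            raise ValueError("restraint endpoints must differ")

    @property
    def pair(self) -> tuple[AtomKey, AtomKey]:
        return (self.atom_a, self.atom_b)


@dataclass
class RestraintSet:
    """Ordered collection of restraints with a provenance note."""

    restraints: list[NOERestraint]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def __getitem__(self, i):
        return self.restraints[i]

    def subset(self, which: str = "all") -> "RestraintSet":
        """``all`` or ``interface`` (chaperone-histone spanning) restraints."""
        if which == "all":
            chosen = list(self.restraints)
        elif which == "interface":
            chosen = [r for r in self.restraints if r.interface]
        else:
            raise ValueError(f"unknown subset {which!r}")
        if not chosen:
            raise SelectionError(f"no restraints in subset {which!r}")
        return RestraintSet(chosen, provenance=f"{self.provenance}[{which}]")


@dataclass(frozen=True)
class TwoWellPotential:
    """Stepwise distance potential with a flat favourable well.

    Zero for ``lower_edge ≤ r ≤ upper_edge`` (the upper edge being the
    restraint bound), ``inner_step`` below the lower edge, and a step plus
    linear ramp ``outer_step · (1 + (r − upper_edge))`` beyond the bound so
    Monte-Carlo moves feel a restoring signal.
    """

    lower_edge: float = 1.8
    outer_step: float = 1.0
    inner_step: float | None = None

    def energy(self, r: np.ndarray, upper_edge: np.ndarray) -> np.ndarray:
        r = np.asarray(r, float)
        upper = np.asarray(upper_edge, float)
        inner = self.outer_step if self.inner_step is None else self.inner_step
        out = np.zeros(np.broadcast(r, upper).shape)
        below = r < self.lower_edge
        above = r > upper
        out = np.where(below, inner, out)
        out = np.where(above, self.outer_step * (1.0 + (r - upper)), out)
        return out


@dataclass
class HarmonicTether:
    """Per-atom harmonic restraint to reference coordinates, E = k·|Δx|²."""

    keys: list[AtomKey]
    reference: np.ndarray  # (n, 3)
    spring_constant: float = 0.4  # kcal·mol⁻¹·atom⁻¹ at 1 Å displacement

    def __post_init__(self):
        self.reference = np.asarray(self.reference, float)
        if self.spring_constant < 0:
            raise ValueError("spring constant must be non-negative")
        if self.reference.shape != (len(self.keys), 3):
            raise ValueError("reference coordinate shape mismatch")

    @classmethod
    def from_structure(
        cls, structure: Structure, selector, spring_constant: float = 0.4
    ) -> "HarmonicTether":
        idx = selector.indices(structure)
        if len(idx) == 0:
            raise SelectionError("tether selection is empty")
        keys = [structure.atoms[i].key for i in idx]
        return cls(keys, structure.coords[idx], spring_constant)


# --------------------------------------------------------------------------
# Parsing


def _is_interface_pair(a: AtomKey, b: AtomKey, chaperone_chain: str) -> bool:
    chains = {a[0], b[0]}
    return chaperone_chain in chains and len(chains) == 2


def _resolve(topology: Structure, key: AtomKey, lineno: int | None = None) -> None:
    if not topology.has_atom(key):
        where = f" (line {lineno})" if lineno is not None else ""
        raise RestraintResolutionError(
            f"restraint atom {key} not found on topology{where}"
        )


def parse_restraints(
    path: str | Path,
    topology: Structure,
    chaperone_chain: str = DEFAULT_CHAPERONE_CHAIN,
) -> RestraintSet:
    """Parse the whitespace table dialect.

    Lines are ``chain resseq atomname chain resseq atomname upper_Å``;
    ``#`` starts a comment.  Every atom must resolve on ``topology``.
    """
    path = Path(path)
    restraints: list[NOERestraint] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 7:
                raise RestraintResolutionError(
                    f"expected 7 fields at line {lineno} of {path.name}, "
                    f"got {len(fields)}"
                )
            a = (fields[0], int(fields[1]), fields[2])
            b = (fields[3], int(fields[4]), fields[5])
            upper = float(fields[6])
            _resolve(topology, a, lineno)
            _resolve(topology, b, lineno)
            restraints.append(
                NOERestraint(
                    a, b, upper,
                    interface=_is_interface_pair(a, b, chaperone_chain),
                )
            )
    return RestraintSet(restraints, provenance=str(path))


_XPLOR_ASSIGN = re.compile(
    r"assign\s*"
    r"\(\s*segid\s+(\S+)\s+and\s+resid\s+(\d+)\s+and\s+name\s+(\S+)\s*\)\s*"
    r"\(\s*segid\s+(\S+)\s+and\s+resid\s+(\d+)\s+and\s+name\s+(\S+)\s*\)\s*"
    r"([\d.]+)\s+([\d.]+)\s+([\d.]+)",
    re.IGNORECASE,
)


def parse_xplor_restraints(
    path: str | Path,
    topology: Structure,
    chaperone_chain: str = DEFAULT_CHAPERONE_CHAIN,
) -> RestraintSet:
    """Secondary reader for X-PLOR ``assign`` statements.

    Upper bound is taken as ``d + dplus`` per the X-PLOR convention
    ``assign (sel) (sel) d dminus dplus``.
    """
    path = Path(path)
    text = path.read_text()
    restraints: list[NOERestraint] = []
    for m in _XPLOR_ASSIGN.finditer(text):
        a = (m.group(1), int(m.group(2)), m.group(3).upper())
        b = (m.group(4), int(m.group(5)), m.group(6).upper())
        upper = float(m.group(7)) + float(m.group(9))
        _resolve(topology, a)
        _resolve(topology, b)
        restraints.append(
            NOERestraint(a, b, upper, interface=_is_interface_pair(a, b, chaperone_chain))
        )
    if not restraints:
        raise RestraintResolutionError(f"no assign statements found in {path}")
    return RestraintSet(restraints, provenance=str(path))


# --------------------------------------------------------------------------
# Modification rules


def _remap_endpoint(
    key: AtomKey, topology: Structure
) -> tuple[AtomKey, bool]:
    """Return (possibly remapped key, was_remapped)."""
    chain, res_seq, name = key
    if element_of(name) != "H":
        return key, False
    # residue type looked up from any atom of that residue on the topology
    res_name = None
    for a in topology.atoms:
        if a.chain_id == chain and a.res_seq == res_seq:
            res_name = a.res_name
            break
    if res_name is None:
        raise RestraintResolutionError(f"residue of atom {key} not on topology")
    if not is_aliphatic_hydrogen(res_name, name):
        return key, False  # polar hydrogen: untouched
    parent = parent_heavy_atom(res_name, name)
    new_key = (chain, res_seq, parent)
    _resolve(topology, new_key)
    return new_key, True


def remap_aliphatic(restraint: NOERestraint, topology: Structure) -> NOERestraint:
    """Replace aliphatic-H endpoints by their bonded carbons, +1 Å each."""
    a, remapped_a = _remap_endpoint(restraint.atom_a, topology)
    b, remapped_b = _remap_endpoint(restraint.atom_b, topology)
    bound = restraint.upper_bound + 1.0 * (remapped_a + remapped_b)
    return replace(
        restraint,
        atom_a=a,
        atom_b=b,
        upper_bound=bound,
        remapped_aliphatic_a=restraint.remapped_aliphatic_a or remapped_a,
        remapped_aliphatic_b=restraint.remapped_aliphatic_b or remapped_b,
    )


def remap_set(rset: RestraintSet, topology: Structure) -> RestraintSet:
    """Apply :func:`remap_aliphatic` to every restraint.

    Methyl/methylene hydrogens collapse onto the same carbon; the resulting
    duplicate pairs are merged keeping the loosest bound (conservative NOE
    convention), preserving first-occurrence order.
    """
    merged: dict[frozenset, NOERestraint] = {}
    order: list[frozenset] = []
    for r in rset:
        rr = remap_aliphatic(r, topology)
        sig = frozenset((rr.atom_a, rr.atom_b))
        if sig in merged:
            if rr.upper_bound > merged[sig].upper_bound:
                merged[sig] = rr
        else:
            merged[sig] = rr
            order.append(sig)
    return RestraintSet(
        [merged[s] for s in order], provenance=f"{rset.provenance}+remap"
    )


def pad_restraints(rset: RestraintSet, pad: float = 1.0) -> RestraintSet:
    """Add ``pad`` Å to every upper bound (NOE standard-deviation allowance)."""
    if pad < 0:
        raise ValueError("pad must be non-negative")
    out = [
        replace(r, upper_bound=r.upper_bound + pad, padded=r.padded or pad > 0)
        for r in rset
    ]
    return RestraintSet(out, provenance=f"{rset.provenance}+pad{pad:g}")


# --------------------------------------------------------------------------
# Distances, violations, energies


def _pair_indices(structure: Structure, rset: RestraintSet) -> tuple[np.ndarray, np.ndarray]:
    ia = np.empty(len(rset), dtype=int)
    ib = np.empty(len(rset), dtype=int)
    for i, r in enumerate(rset):
        _resolve(structure, r.atom_a)
        _resolve(structure, r.atom_b)
        ia[i] = structure.index_of(r.atom_a)
        ib[i] = structure.index_of(r.atom_b)
    return ia, ib


def restraint_distances(structure: Structure, rset: RestraintSet) -> np.ndarray:
    """Observed distance (Å) per restraint on one structure."""
    ia, ib = _pair_indices(structure, rset)
    d = structure._coords[ia] - structure._coords[ib]
    return np.sqrt((d * d).sum(axis=1))


def structure_violation(structure: Structure, restraint: NOERestraint) -> float:
    """One-sided violation ``max(0, r − upper_bound)`` for a single restraint."""
    rs = RestraintSet([restraint])
    r = float(restraint_distances(structure, rs)[0])
    return max(0.0, r - restraint.upper_bound)


def structure_mean_violation(
    structure: Structure, rset: RestraintSet, subset: str = "all"
) -> float:
    """Mean one-sided violation over a restraint subset for one snapshot."""
    sel = rset.subset(subset)
    r = restraint_distances(structure, sel)
    bounds = np.array([x.upper_bound for x in sel])
    return float(np.maximum(0.0, r - bounds).mean())


def ensemble_distances(ensemble: Ensemble, rset: RestraintSet) -> np.ndarray:
    """(n_members, n_restraints) distance matrix."""
    ia, ib = _pair_indices(ensemble.members[0], rset)
    coords = ensemble.coords_array()
    d = coords[:, ia, :] - coords[:, ib, :]
    return np.sqrt((d * d).sum(axis=2))


def ensemble_effective_distance(
    ensemble: Ensemble, restraint: NOERestraint
) -> float:
    """r⁻⁶ ensemble-averaged effective distance for one restraint."""
    r = ensemble_distances(ensemble, RestraintSet([restraint]))[:, 0]
    if np.any(r <= 0):
        raise ZeroDivisionError("coincident restraint atoms (r = 0) in ensemble")
    return float(np.mean(r ** -6.0) ** (-1.0 / 6.0))


def mean_ensemble_violation(
    ensemble: Ensemble, rset: RestraintSet, subset: str = "all"
) -> float:
    """Mean violation of r⁻⁶-averaged distances over a restraint subset."""
    sel = rset.subset(subset)
    r = ensemble_distances(ensemble, sel)
    if np.any(r <= 0):
        raise ZeroDivisionError("coincident restraint atoms (r = 0) in ensemble")
    eff = np.mean(r ** -6.0, axis=0) ** (-1.0 / 6.0)
    bounds = np.array([x.upper_bound for x in sel])
    return float(np.maximum(0.0, eff - bounds).mean())


def restraint_energy(
    structure: Structure,
    rset: RestraintSet,
    potential: TwoWellPotential | None = None,
) -> float:
    """Total two-well restraint energy of one structure."""
    potential = potential or TwoWellPotential()
    r = restraint_distances(structure, rset)
    bounds = np.array([x.upper_bound for x in rset])
    return float(potential.energy(r, bounds).sum())


def tether_energy(structure: Structure, tether: HarmonicTether) -> float:
    """Σ k·|x − x_ref|² over tethered atoms."""
    idx = np.array([structure.index_of(k) for k in tether.keys], dtype=int)
    d = structure._coords[idx] - tether.reference
    return float(tether.spring_constant * (d * d).sum())
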