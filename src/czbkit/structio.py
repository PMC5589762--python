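"""Multi-model PDB I/O, atom selection, superposition and RMSD.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`AtomRecord` plus a cached coordinate array, and an
:class:`Ensemble` is an ordered list of structures sharing one topology with
per-member scalar annotations (energies, violations, replica ids ...).
Residue numbering follows the author numbering of the input file; nothing is
renumbered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from .errors import AlignmentError, PDBParseError, SelectionError, TopologyError
from .residues import element_of

AtomKey = tuple[str, int, str]  # (chain_id, res_seq, atom_name)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus coordinates (Å) and a B-factor slot."""

    chain_id: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    coord: tuple[float, float, float]
    bfactor: float = 0.0

    @property
    def key(self) -> AtomKey:
        return (self.chain_id, self.res_seq, self.atom_name)

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


class Structure:
    """One conformation: ordered atoms with unique (chain, resseq, name) keys."""

    def __init__(self, atoms: Sequence[AtomRecord], label: str = ""):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("a Structure needs at least one atom")
        keys = [a.key for a in atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom key {dup} in structure {label!r}")
        self.atoms: list[AtomRecord] = atoms
        self.label = label
        self._index: dict[AtomKey, int] = {k: i for i, k in enumerate(keys)}
        self._coords = np.array([a.coord for a in atoms], dtype=float)
        if not np.all(np.isfinite(self._coords)):
            raise ValueError(f"non-finite coordinates in structure {label!r}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float64 array; a defensive copy."""
        return self._coords.copy()

    @property
    def keys(self) -> list[AtomKey]:
        return [a.key for a in self.atoms]

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def index_of(self, key: AtomKey) -> int:
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"atom {key} not in structure {self.label!r}") from None

    def has_atom(self, key: AtomKey) -> bool:
        return key in self._index

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        coords = np.asarray(coords, float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            replace(a, coord=(float(x), float(y), float(z)))
            for a, (x, y, z) in zip(self.atoms, coords)
        ]
        return Structure(atoms, label if label is not None else self.label)

    def drop_chains(self, chains: Iterable[str], label: str | None = None) -> "Structure":
        drop = set(chains)
        kept = [a for a in self.atoms if a.chain_id not in drop]
        if not kept:
            raise ValueError("dropping these chains would leave no atoms")
        return Structure(kept, label if label is not None else self.label)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, res_seq, res_name) triples."""
        out: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if (a.chain_id, a.res_seq) not in seen:
                seen.add((a.chain_id, a.res_seq))
                out.append((a.chain_id, a.res_seq, a.res_name))
        return out


@dataclass
class AtomSelector:
    """Deterministic, file-ordered atom subset of a Structure.

    ``None`` filters are pass-through.  ``res_range`` is inclusive on both
    ends.  ``heavy_only`` drops hydrogens/deuteriums.
    """

    chains: tuple[str, ...] | None = None
    res_range: tuple[int, int] | None = None
    atom_names: tuple[str, ...] | None = None
    heavy_only: bool = False

    @classmethod
    def backbone(
        cls,
        chains: Iterable[str] | None = None,
        res_range: tuple[int, int] | None = None,
    ) -> "AtomSelector":
        return cls(
            chains=tuple(chains) if chains is not None else None,
            res_range=res_range,
            atom_names=("N", "CA", "C", "O"),
        )

    def indices(self, structure: Structure) -> np.ndarray:
        out = []
        for i, a in enumerate(structure.atoms):
            if self.chains is not None and a.chain_id not in self.chains:
                continue
            if self.res_range is not None and not (
                self.res_range[0] <= a.res_seq <= self.res_range[1]
            ):
                continue
            if self.atom_names is not None and a.atom_name not in self.atom_names:
                continue
            if self.heavy_only and not a.is_heavy:
                continue
            out.append(i)
        return np.array(out, dtype=int)


class Ensemble:
    """Ordered structures of identical topology with per-member annotations."""

    def __init__(
        self,
        members: Sequence[Structure],
        annotations: Mapping[str, Sequence[float]] | None = None,
    ):
        members = list(members)
        if not members:
            raise ValueError("an Ensemble needs at least one member")
        ref_keys = members[0].keys
        for m in members[1:]:
            if m.keys != ref_keys:
                raise TopologyError(
                    f"member {m.label!r} does not share the topology of "
                    f"{members[0].label!r}"
                )
        self.members: list[Structure] = members
        self.annotations: dict[str, np.ndarray] = {}
        for name, values in (annotations or {}).items():
            self.set_annotation(name, values)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def set_annotation(self, name: str, values: Sequence[float]) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(self.members),):
            raise ValueError(
                f"annotation {name!r} has {arr.shape} values for "
                f"{len(self.members)} members"
            )
        self.annotations[name] = arr

    def subset(self, indices: Sequence[int]) -> "Ensemble":
        idx = list(indices)
        sub = Ensemble([self.members[i] for i in idx])
        for name, values in self.annotations.items():
            sub.set_annotation(name, values[idx])
        return sub

    def coords_array(self) -> np.ndarray:
        """(n_members, n_atoms, 3) stacked coordinates."""
        return np.stack([m._coords for m in self.members])


# --------------------------------------------------------------------------
# PDB reading / writing


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, str, float]:
    try:
        name = line[12:16].strip()
        altloc = line[16].strip() if len(line) > 16 else ""
        res_name = line[17:20].strip()
        chain = line[21].strip() or " "
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        bfac_field = line[60:66].strip()
        bfactor = float(bfac_field) if bfac_field else 0.0
        element = line[76:78].strip() if len(line) >= 77 else ""
        if not element:
            element = element_of(name)
        if not name or not res_name:
            raise ValueError("empty atom or residue name")
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    record = AtomRecord(
        chain_id=chain,
        res_seq=res_seq,
        res_name=res_name,
        atom_name=name,
        element=element,
        coord=(x, y, z),
        bfactor=bfactor,
    )
    return record, altloc, occupancy


def read_structure_models(path: str | Path, dialect: str = "pdb") -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    One member per MODEL block; a file without MODEL records yields a
    single-member ensemble.  Alternate locations are collapsed to the
    highest-occupancy conformer (ties prefer blank/'A').
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    models: list[list[AtomRecord]] = []
    model_labels: list[str] = []
    current: list[AtomRecord] | None = None
    # altloc bookkeeping: key -> (position in current, occupancy, altloc)
    alt_seen: dict[AtomKey, tuple[int, float, str]] = {}
    in_model_blocks = False

    def close_model(label: str) -> None:
        nonlocal current, alt_seen
        if current:
            models.append(current)
            model_labels.append(label)
        current = None
        alt_seen = {}

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if current is not None:
                    close_model(f"{path.stem}:{len(models) + 1}")
                in_model_blocks = True
                current = []
                alt_seen = {}
            elif rec == "ENDMDL":
                close_model(f"{path.stem}:{len(models) + 1}")
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    if in_model_blocks:
                        raise PDBParseError(
                            f"coordinates outside MODEL/ENDMDL at line {lineno}"
                        )
                    current = []
                    alt_seen = {}
                atom, altloc, occ = _parse_atom_line(line, lineno)
                key = atom.key
                if key in alt_seen:
                    pos, old_occ, old_alt = alt_seen[key]
                    if not altloc and not old_alt:
                        raise PDBParseError(
                            f"duplicate atom {key} at line {lineno}"
                        )
                    better = occ > old_occ or (
                        occ == old_occ and altloc in ("", "A") and old_alt not in ("", "A")
                    )
                    if better:
                        current[pos] = atom
                        alt_seen[key] = (pos, occ, altloc)
                else:
                    alt_seen[key] = (len(current), occ, altloc)
                    current.append(atom)
    if current is not None:
        close_model(f"{path.stem}:{len(models) + 1}")
    if not models:
        raise PDBParseError(f"no coordinates found in {path}")
    structures = [
        Structure(atoms, label)
        for atoms, label in zip(models, model_labels)
    ]
    return Ensemble(structures)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and not name[:1].isdigit():
        return f" {name:<3}"
    return f"{name:<4}"


def write_structure_models(
    ensemble: Ensemble | Structure,
    path: str | Path,
    bfactor_source: Mapping[AtomKey, float] | None = None,
) -> Path:
    """Write an ensemble as a MODEL/ENDMDL multi-model PDB file.

    ``bfactor_source`` maps atom keys to values for the B-factor column;
    a key absent from the structure raises ``KeyError``.
    """
    if isinstance(ensemble, Structure):
        ensemble = Ensemble([ensemble])
    path = Path(path)
    if bfactor_source is not None:
        for key in bfactor_source:
            ensemble.members[0].index_of(key)  # KeyError if unmappable
    with path.open("w") as fh:
        multi = len(ensemble) > 1
        for i, member in enumerate(ensemble, start=1):
            if multi:
                fh.write(f"MODEL     {i:>4}\n")
            for serial, atom in enumerate(member.atoms, start=1):
                bf = atom.bfactor
                if bfactor_source is not None:
                    bf = bfactor_source.get(atom.key, bf)
                x, y, z = atom.coord
                fh.write(
                    "ATOM  {serial:>5} {name} {res:<3} {chain}{resseq:>4}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}          "
                    "{elem:>2}\n".format(
                        serial=serial % 100000,
                        name=_format_atom_name(atom.atom_name, atom.element),
                        res=atom.res_name,
                        chain=atom.chain_id[:1] or " ",
                        resseq=atom.res_seq,
                        x=x, y=y, z=z,
                        occ=1.0,
                        bf=bf,
                        elem=atom.element[:2],
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


# --------------------------------------------------------------------------
# Superposition

def superpose(
    mobile: Structure,
    reference: Structure,
    selector: AtomSelector | None = None,
) -> tuple[Structure, float]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    The optimal rotation/translation is found on the selected atoms
    (Kabsch via SVD) and applied to *all* atoms of ``mobile``.  Returns the
    transformed structure and the RMSD over the selection.
    """
    selector = selector or AtomSelector()
    idx_m = selector.indices(mobile)
    idx_r = selector.indices(reference)
    if len(idx_m) != len(idx_r):
        raise AlignmentError(
            f"selection sizes differ: {len(idx_m)} mobile vs {len(idx_r)} reference"
        )
    if len(idx_m) < 3:
        raise AlignmentError("superposition needs at least 3 selected atoms")
    x = mobile._coords[idx_m]
    y = reference._coords[idx_r]
    # degenerate (collinear) geometry leaves a free rotation
    for pts in (x, y):
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise AlignmentError("selected atoms are collinear; fit is degenerate")
    sup = SVDSuperimposer()
    sup.set(y, x)  # reference first per Biopython convention
    sup.run()
    rot, tran = sup.get_rotran()
    moved = mobile._coords @ rot + tran
    return mobile.with_coords(moved), float(sup.get_rms())


def rmsd(
    a: Structure,
    b: Structure,
    selector: AtomSelector | None = None,
    superposed: bool = True,
) -> float:
    """RMSD between two structures over a selection, with optional fitting."""
    if superposed:
        return superpose(a, b, selector)[1]
    selector = selector or AtomSelector()
    ia, ib = selector.indices(a), selector.indices(b)
    if len(ia) != len(ib) or len(ia) == 0:
        raise SelectionError("selection mismatch or empty selection")
    d = a._coords[ia] - b._coords[ib]
    return float(np.sqrt((d * d).sum(axis=1).mean()))
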