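"""Minimal PDB coordinate I/O and atom selection.

Only fixed-width ATOM records are parsed (HETATM is ignored, except
oxidized/modified cysteine variants which are mapped back to CYS so mined
cystines are not lost). Hydrogens are dropped on read: every geometric
criterion downstream is heavy-atom based. Altloc policy: keep the highest
occupancy, ties broken by 'A' then alphabetically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

log = logging.getLogger(__name__)

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# HETATM residue names that carry a cysteine backbone + SG (oxidized /
# modified cysteines); mapped to CYS on read so interchain bridges survive.
_CYS_VARIANTS = {"CYS", "CYX", "CSO", "CSS", "OCS", "CSX", "CME", "CSD"}

# Bondi van der Waals radii (Angstrom), heavy atoms only.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}

ATOMIC_MASSES = {
    "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974,
    "SE": 78.971, "H": 1.008,
}


class PDBFormatError(ValueError):
    """Malformed PDB record; message carries the 1-based line number."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    serial: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.element not in VDW_RADII and self.element != "H":
            raise ValueError(f"element {self.element!r} has no vdW radius entry")

    @property
    def vdw_radius(self) -> float:
        return VDW_RADII[self.element]

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES[self.element]

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(), self.serial)


@dataclass
class Residue:
    res_name: str
    res_seq: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""  # insertion code, part of the composite residue key

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate atom names in {self.res_name} {self.chain_id}{self.res_seq}"
            )

    @property
    def key(self) -> tuple[int, str]:
        return (self.res_seq, self.icode)

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_AA

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(
            f"atom {name!r} not found in {self.res_name} {self.chain_id}{self.res_seq}"
        )

    def has_atoms(self, names: Iterable[str]) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)

    def copy(self) -> "Residue":
        return Residue(self.res_name, self.res_seq, self.chain_id,
                       [a.copy() for a in self.atoms], self.icode)


@dataclass
class StructureModel:
    """An ordered set of chains, each an ordered list of residues."""

    chains: dict[str, list[Residue]]
    model_id: str = "1"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("structure must have at least one chain")
        for cid, residues in self.chains.items():
            for r in residues:
                if r.chain_id != cid:
                    raise ValueError(
                        f"residue {r.res_name}{r.res_seq} filed under chain {cid!r} "
                        f"but labelled {r.chain_id!r}"
                    )

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues():
            for a in r.atoms:
                yield r, a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def residue(self, chain_id: str, res_seq: int, icode: str = "") -> Residue:
        for r in self.chains[chain_id]:
            if r.key == (res_seq, icode):
                return r
        raise KeyError(f"no residue {res_seq}{icode} in chain {chain_id}")

    def coords(self) -> np.ndarray:
        return np.array([a.coords for _, a in self.atoms()], dtype=float)

    def copy(self) -> "StructureModel":
        return StructureModel(
            {cid: [r.copy() for r in residues] for cid, residues in self.chains.items()},
            self.model_id, self.source,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigidly moved copy: x -> R @ x + t."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for _, a in out.atoms():
            a.coords = R @ a.coords + t
        return out


def _guess_element(atom_name: str, element_field: str) -> str:
    el = element_field.strip().upper()
    if el:
        return el
    # Fall back to the atom-name convention: columns 13-14 hold the element,
    # digits and remoteness letters follow.
    stripped = atom_name.strip()
    if stripped[:2] in ("SE",):
        return "SE"
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def read_pdb(path: str | Path, model_index: int = 1) -> StructureModel:
    """Read one model's ATOM records from a PDB file.

    ``model_index`` is 1-based over MODEL blocks; files without MODEL
    records count as a single implicit model. Hydrogens are dropped;
    altlocs resolved to the highest-occupancy copy.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if model_index < 1:
        raise IndexError(f"model_index must be >= 1, got {model_index}")

    current_model = 1
    seen_model_record = False
    in_wanted = model_index == 1
    # (chain, resseq, icode, atomname) -> (occupancy, altloc, Atom, resname)
    picked: dict[tuple, tuple] = {}
    order: list[tuple] = []
    res_names: dict[tuple, str] = {}
    n_models_seen = 1

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if seen_model_record:
                    current_model += 1
                seen_model_record = True
                n_models_seen = current_model
                in_wanted = current_model == model_index
                continue
            if rec == "ENDMDL":
                continue
            if not in_wanted:
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(f"line {lineno}: truncated ATOM record")
            res_name = line[17:20].strip()
            if rec == "HETATM" and res_name not in _CYS_VARIANTS:
                continue
            try:
                serial = int(line[6:11])
            except ValueError:
                serial = 0
            atom_name = line[12:16]
            altloc = line[16]
            chain_id = line[21]
            try:
                res_seq = int(line[22:26])
            except ValueError as exc:
                raise PDBFormatError(f"line {lineno}: bad residue number") from exc
            icode = line[26].strip()
            try:
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError as exc:
                raise PDBFormatError(f"line {lineno}: bad coordinate field") from exc
            try:
                occ = float(line[54:60])
            except (ValueError, IndexError):
                occ = 1.0
            element = _guess_element(atom_name, line[76:78] if len(line) >= 78 else "")
            if element == "H":
                continue
            if res_name in _CYS_VARIANTS:
                res_name = "CYS"
            name = atom_name.strip()
            key = (chain_id, res_seq, icode, name)
            atom = Atom(name, element, np.array(xyz), serial)
            if key in picked:
                old_occ, old_alt, _, _ = picked[key]
                better = occ > old_occ or (occ == old_occ and altloc < old_alt)
                if better:
                    log.debug("altloc %s replaces %s for %s", altloc, old_alt, key)
                    picked[key] = (occ, altloc, atom, res_name)
                else:
                    log.debug("altloc %s discarded for %s", altloc, key)
                continue
            picked[key] = (occ, altloc, atom, res_name)
            order.append(key)
            res_names.setdefault((chain_id, res_seq, icode), res_name)

    if seen_model_record and model_index > n_models_seen:
        raise IndexError(
            f"model_index {model_index} out of range: file has {n_models_seen} model(s)"
        )
    if not order:
        raise PDBFormatError(f"{path}: no ATOM records in model {model_index}")

    chains: dict[str, list[Residue]] = {}
    current: Residue | None = None
    for key in order:
        chain_id, res_seq, icode, _ = key
        _, _, atom, _ = picked[key]
        if (current is None or current.chain_id != chain_id
                or current.key != (res_seq, icode)):
            current = Residue(res_names[(chain_id, res_seq, icode)],
                              res_seq, chain_id, [], icode)
            chains.setdefault(chain_id, []).append(current)
        current.atoms.append(atom)
    return StructureModel(chains, model_id=str(model_index), source=str(path))


def write_pdb(structure: StructureModel, path: str | Path) -> Path:
    """Write fixed-width ATOM records; coordinates at 3 decimals.

    Serial numbers are reassigned sequentially and wrap at 99999 so the
    file stays re-readable for arbitrarily large structures.
    """
    path = Path(path)
    if structure.n_atoms == 0:
        raise ValueError("refusing to write a structure with no atoms")
    lines = []
    serial = 0
    for res in structure.residues():
        for a in res.atoms:
            serial = serial % 99999 + 1
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            x, y, z = a.coords
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{res.res_name:>3s} "
                f"{res.chain_id}{res.res_seq:4d}{res.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
        # chain break marker after each chain's last residue
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


_CANONICAL_ATOM_ORDER = {n: i for i, n in enumerate(
    ["N", "CA", "C", "O", "CB", "CG", "CG1", "CG2", "OG", "OG1", "SG",
     "CD", "CD1", "CD2", "ND1", "ND2", "OD1", "OD2", "SD",
     "CE", "CE1", "CE2", "CE3", "NE", "NE1", "NE2", "OE1", "OE2",
     "CZ", "CZ2", "CZ3", "NZ", "CH2", "NH1", "NH2", "OH", "OXT"]
)}


def select_atoms(
    structure: StructureModel,
    chain_id: str | None = None,
    atom_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[tuple[Residue, Atom]]]:
    """Select coordinates with back-references.

    Order is deterministic regardless of file record order: (chain id,
    residue number, insertion code, canonical atom-name order). ``None``
    selects everything; an empty selection is valid.
    """
    wanted = set(atom_names) if atom_names is not None else None
    hits: list[tuple[Residue, Atom]] = []
    for res in structure.residues():
        if chain_id is not None and res.chain_id != chain_id:
            continue
        for a in res.atoms:
            if wanted is None or a.name in wanted:
                hits.append((res, a))
    hits.sort(key=lambda ra: (
        ra[0].chain_id, ra[0].res_seq, ra[0].icode,
        _CANONICAL_ATOM_ORDER.get(ra[1].name, 999), ra[1].name,
    ))
    if not hits:
        return np.empty((0, 3)), []
    coords = np.array([a.coords for _, a in hits], dtype=float)
    return coords, hits
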