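"""Mining interchain cystine rotamers and their dihedral statistics.

A "rotamer" here is the ten-atom geometry of a disulfide-bridged cysteine
pair taken from a real (or synthetic) multi-chain structure: N, CA, C, CB,
SG of each half-cystine, plus the derived chi1 torsions of each chain and
the bridge torsion chi3 = CB-SG-SG'-CB'. Interchain bridges are what
templates a covalent homodimer; intra-chain disulfides are excluded.
Low-strain disulfides cluster near chi3 = +-90 deg, which is why the mined
distribution is reported as a histogram over (-180, 180].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import dihedral
from .structio import Residue, StructureModel

log = logging.getLogger(__name__)

ROTAMER_ATOMS = ("N", "CA", "C", "CB", "SG")

#: default SG-SG cutoff: covalent S-S bond ~2.05 A plus coordinate error.
MAX_SS_DEFAULT = 2.3

_LIBRARY_VERSION = 1


@dataclass
class DisulfideRotamer:
    """Paired oxidized-cysteine coordinates with cystine dihedrals."""

    rotamer_id: str
    cys_a: dict[str, np.ndarray]  # atom name -> 3-vector (A)
    cys_b: dict[str, np.ndarray]
    chi3: float
    chi1_a: float
    chi1_b: float
    ss_distance: float
    source: str = ""

    def __post_init__(self) -> None:
        for label, block in (("a", self.cys_a), ("b", self.cys_b)):
            for name in ROTAMER_ATOMS:
                if name not in block:
                    raise ValueError(f"rotamer {self.rotamer_id}: cys_{label} missing {name}")
                block[name] = np.asarray(block[name], float)
                if block[name].shape != (3,) or not np.all(np.isfinite(block[name])):
                    raise ValueError(
                        f"rotamer {self.rotamer_id}: cys_{label}.{name} not a finite 3-vector"
                    )
        if not (self.ss_distance <= MAX_SS_DEFAULT):
            raise ValueError(
                f"rotamer {self.rotamer_id}: SG-SG {self.ss_distance:.2f} A is not covalent"
            )
        if not (-180.0 < self.chi3 <= 180.0):
            raise ValueError(f"rotamer {self.rotamer_id}: chi3 {self.chi3} out of (-180, 180]")


@dataclass
class RotamerLibrary:
    rotamers: list[DisulfideRotamer]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.rotamer_id for r in self.rotamers]
        if len(ids) != len(set(ids)):
            raise ValueError("rotamer_ids are not unique")

    def __len__(self) -> int:
        return len(self.rotamers)

    def __iter__(self):
        return iter(self.rotamers)


def find_interchain_disulfides(
    structure: StructureModel, max_ss: float = MAX_SS_DEFAULT
) -> list[tuple[Residue, Residue]]:
    """All CYS pairs on different chains with SG-SG <= max_ss.

    Order is deterministic: sorted by (chain, residue number) of each
    partner with the lexicographically smaller partner first. CYS residues
    lacking an SG atom are skipped with a warning.
    """
    if len(structure.chains) < 2:
        raise ValueError("need at least two chains to find interchain disulfides")
    cys: list[tuple[Residue, np.ndarray]] = []
    for res in structure.residues():
        if res.res_name != "CYS":
            continue
        try:
            sg = res.atom("SG").coords
        except KeyError:
            log.warning("CYS %s%s lacks SG; skipped", res.chain_id, res.res_seq)
            continue
        cys.append((res, sg))
    pairs = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            ra, sa = cys[i]
            rb, sb = cys[j]
            if ra.chain_id == rb.chain_id:
                continue
            if np.linalg.norm(sa - sb) <= max_ss:
                a, b = sorted((ra, rb), key=lambda r: (r.chain_id, r.res_seq, r.icode))
                pairs.append((a, b))
    pairs.sort(key=lambda p: (p[0].chain_id, p[0].res_seq, p[1].chain_id, p[1].res_seq))
    return pairs


def extract_rotamer(
    structure: StructureModel, pair: tuple[Residue, Residue], source: str = ""
) -> DisulfideRotamer:
    """Lift a bridged cysteine pair into a reusable rotamer.

    chi3 = CB(a)-SG(a)-SG(b)-CB(b); chi1 = N-CA-CB-SG per chain. The id
    follows the ``<pos_a><chain_a>_<pos_b><chain_b>_<source>`` scheme used
    to trace each dimer model back to the structure its bridge came from.
    """
    res_a, res_b = pair
    blocks = []
    for res in (res_a, res_b):
        block = {}
        for name in ROTAMER_ATOMS:
            try:
                block[name] = res.atom(name).coords.copy()
            except KeyError as exc:
                raise ValueError(
                    f"residue {res.res_name} {res.chain_id}{res.res_seq} missing atom {name}"
                ) from exc
        blocks.append(block)
    a, b = blocks
    chi3 = dihedral(a["CB"], a["SG"], b["SG"], b["CB"])
    chi1_a = dihedral(a["N"], a["CA"], a["CB"], a["SG"])
    chi1_b = dihedral(b["N"], b["CA"], b["CB"], b["SG"])
    ss = float(np.linalg.norm(a["SG"] - b["SG"]))
    src = source or Path(structure.source).stem or structure.model_id
    rid = (f"{res_a.res_seq}{res_a.chain_id.lower()}_"
           f"{res_b.res_seq}{res_b.chain_id.lower()}_{src}")
    return DisulfideRotamer(rid, a, b, chi3, chi1_a, chi1_b, ss, src)


def mine_corpus(
    paths: list[str | Path], max_ss: float = MAX_SS_DEFAULT
) -> RotamerLibrary:
    """Mine every interchain cystine from a list of PDB files."""
    from .structio import read_pdb

    rotamers: list[DisulfideRotamer] = []
    seen: set[str] = set()
    n_files = 0
    for p in paths:
        p = Path(p)
        try:
            structure = read_pdb(p)
        except Exception as exc:  # skip unreadable corpus members, keep mining
            log.warning("skipping %s: %s", p, exc)
            continue
        n_files += 1
        if len(structure.chains) < 2:
            continue
        for pair in find_interchain_disulfides(structure, max_ss):
            try:
                rot = extract_rotamer(structure, pair, source=p.stem)
            except ValueError as exc:
                log.warning("%s: %s", p, exc)
                continue
            if rot.rotamer_id in seen:  # same bridge found twice (symmetry copies)
                continue
            seen.add(rot.rotamer_id)
            rotamers.append(rot)
    if not rotamers:
        log.warning("mining produced an empty library (%d files read)", n_files)
    return RotamerLibrary(rotamers, provenance={
        "n_files": n_files, "max_ss": max_ss,
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    })


def chi3_distribution(library: RotamerLibrary, bin_width: float = 10.0) -> pd.DataFrame:
    """Histogram of chi3 over (-180, 180]; counts sum to the library size."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(library) == 0:
        raise ValueError("empty library has no chi3 distribution")
    nbins = int(np.ceil(360.0 / bin_width))
    edges = -180.0 + bin_width * np.arange(nbins + 1)
    edges[-1] = max(edges[-1], 180.0)
    chi = np.array([r.chi3 for r in library])
    # right-closed bins so +180 lands in the last bin and -180 is excluded
    idx = np.clip(np.searchsorted(edges, chi, side="left") - 1, 0, nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"bin_center": centers, "count": counts})


_COORD_COLS = [f"{half}_{name}_{ax}"
               for half in ("a", "b") for name in ROTAMER_ATOMS for ax in "xyz"]
_META_COLS = ["rotamer_id", "chi3", "chi1_a", "chi1_b", "ss_distance", "source"]


def save_library(library: RotamerLibrary, path: str | Path) -> Path:
    """Serialize to TSV (one rotamer per row, full-precision coordinates)."""
    if len(library) == 0:
        raise ValueError("refusing to save an empty library")
    path = Path(path)
    rows = []
    for r in library:
        row: dict = {"rotamer_id": r.rotamer_id, "chi3": r.chi3, "chi1_a": r.chi1_a,
                     "chi1_b": r.chi1_b, "ss_distance": r.ss_distance, "source": r.source}
        for half, block in (("a", r.cys_a), ("b", r.cys_b)):
            for name in ROTAMER_ATOMS:
                for k, ax in enumerate("xyz"):
                    row[f"{half}_{name}_{ax}"] = repr(float(block[name][k]))
        rows.append(row)
    df = pd.DataFrame(rows, columns=_META_COLS + _COORD_COLS)
    prov = ";".join(f"{k}={v}" for k, v in library.provenance.items())
    with path.open("w") as fh:
        fh.write(f"# cysdimer rotamer library v{_LIBRARY_VERSION}; {prov}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def load_library(path: str | Path) -> RotamerLibrary:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith(f"# cysdimer rotamer library v{_LIBRARY_VERSION}"):
            raise ValueError(f"{path}: not a v{_LIBRARY_VERSION} rotamer library file")
        df = pd.read_csv(fh, sep="\t")
    missing = [c for c in _META_COLS + _COORD_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    rotamers = []
    for _, row in df.iterrows():
        blocks = {}
        for half in ("a", "b"):
            blocks[half] = {
                name: np.array([row[f"{half}_{name}_{ax}"] for ax in "xyz"], float)
                for name in ROTAMER_ATOMS
            }
        rotamers.append(DisulfideRotamer(
            row["rotamer_id"], blocks["a"], blocks["b"],
            float(row["chi3"]), float(row["chi1_a"]), float(row["chi1_b"]),
            float(row["ss_distance"]), str(row["source"]),
        ))
    prov = {}
    for kv in header.split(";")[1:]:
        if "=" in kv:
            k, v = kv.strip().split("=", 1)
            prov[k] = v
    return RotamerLibrary(rotamers, provenance=prov)
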