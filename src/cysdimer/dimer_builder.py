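"""Rigid-body construction of disulfide-bridged homodimers.

For each mined cystine rotamer, two copies of a single-Cys monomer are
least-squares fitted — via the backbone + CB of the mutated cysteine — onto
the rotamer's two half-cystines, the cysteine coordinates are replaced by
the rotamer's own (so the bridge geometry is exactly the experimental one),
and the resulting two-chain model is kept only if the protomers do not
sterically overlap. This mirrors how covalent-template modelling is done
when no energy function is trusted: geometry is grafted, never relaxed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import RigidTransform, dihedral, place_atom, superpose
from .rotamer_library import DisulfideRotamer, RotamerLibrary
from .structio import Atom, Residue, StructureModel

log = logging.getLogger(__name__)

FIT_ATOMS = ("N", "CA", "C", "CB")

#: fraction of summed vdW radii below which two atoms count as clashing.
OVERLAP_FACTOR_DEFAULT = 0.6

# idealized cysteine side-chain internal coordinates
_CB_SG_BOND = 1.81     # A
_CA_CB_SG_ANGLE = 114.0  # deg
_CHI1_DEFAULT = -60.0    # deg, used when the parent residue has no gamma atom

_GAMMA_ATOMS = ("CG", "CG1", "OG", "OG1", "SG", "CG2")


@dataclass
class DimerModel:
    """Two protomer copies joined through a library rotamer."""

    structure: StructureModel
    rotamer_id: str
    cys_position: int
    model_id: str
    fit_rmsd_a: float
    fit_rmsd_b: float
    chi3: float

    def __post_init__(self) -> None:
        if len(self.structure.chains) != 2:
            raise ValueError("DimerModel requires exactly two chains")
        lens = [len(r) for r in self.structure.chains.values()]
        if lens[0] != lens[1]:
            raise ValueError("protomer copies differ in residue count")

    @property
    def ss_distance(self) -> float:
        a, b = self.structure.chain_ids
        sg_a = self.structure.residue(a, self.cys_position).atom("SG").coords
        sg_b = self.structure.residue(b, self.cys_position).atom("SG").coords
        return float(np.linalg.norm(sg_a - sg_b))


def mutate_to_cys(structure: StructureModel, chain_id: str, res_seq: int) -> StructureModel:
    """Replace a residue's side chain with a cysteine SG.

    The side chain beyond CB is removed; SG is placed at 1.81 A from CB
    with angle CA-CB-SG = 114 deg and torsion N-CA-CB-SG equal to the
    parent's chi1 (direction of its gamma atom) when one exists, else
    -60 deg (the most common chi1 rotamer). The backbone is untouched.
    """
    out = structure.copy()
    res = out.residue(chain_id, res_seq)
    if res.res_name == "GLY" or not res.has_atoms(("N", "CA", "C", "CB")):
        raise ValueError(
            f"cannot mutate {res.res_name} {chain_id}{res_seq}: requires N, CA, C, CB"
        )
    n, ca, cb = (res.atom(x).coords for x in ("N", "CA", "CB"))
    chi1 = _CHI1_DEFAULT
    for g in _GAMMA_ATOMS:
        try:
            chi1 = dihedral(n, ca, cb, res.atom(g).coords)
            break
        except KeyError:
            continue
    sg = place_atom(n, ca, cb, _CB_SG_BOND, _CA_CB_SG_ANGLE, chi1)
    keep = [a for a in res.atoms if a.name in ("N", "CA", "C", "O", "CB")]
    keep.append(Atom("SG", "S", sg))
    res.atoms = keep
    res.res_name = "CYS"
    return out


def _cys_block_coords(res: Residue, names=FIT_ATOMS) -> np.ndarray:
    return np.array([res.atom(n).coords for n in names], float)


def _rotamer_block_coords(block: dict[str, np.ndarray], names=FIT_ATOMS) -> np.ndarray:
    return np.array([block[n] for n in names], float)


def build_dimer(
    monomer: StructureModel, cys_position: int, rotamer: DisulfideRotamer,
    model_id: str = "",
) -> DimerModel:
    """Graft two monomer copies onto a cystine rotamer.

    Each copy is fitted on its half-cystine over {N, CA, C, CB}; after the
    whole-copy rigid motion, the cysteine's N, CA, C, CB, SG are overwritten
    with the rotamer's coordinates and the carbonyl O is rebuilt from the
    local backbone frame, so the bridge geometry equals the template's
    exactly while everything else moves rigidly.
    """
    chain_in = monomer.chain_ids[0]
    cys = monomer.residue(chain_in, cys_position)
    if cys.res_name != "CYS" or not cys.has_atoms(FIT_ATOMS):
        raise ValueError(
            f"monomer residue {cys_position} must be CYS with {FIT_ATOMS} "
            "(run mutate_to_cys first)"
        )
    mobile = _cys_block_coords(cys)
    copies = []
    fits = []
    for new_chain, block in (("A", rotamer.cys_a), ("B", rotamer.cys_b)):
        tf = superpose(mobile, _rotamer_block_coords(block))
        moved = monomer.transformed(tf.rotation, tf.translation)
        residues = []
        for r in moved.chains[chain_in]:
            r.chain_id = new_chain
            residues.append(r)
        copy = StructureModel({new_chain: residues}, model_id=new_chain)
        _substitute_cys(copy, new_chain, cys_position, block)
        copies.append(copy)
        fits.append(tf.fit_rmsd)
    structure = StructureModel(
        {"A": copies[0].chains["A"], "B": copies[1].chains["B"]},
        model_id=model_id or rotamer.rotamer_id,
        source=f"rotamer:{rotamer.rotamer_id}",
    )
    return DimerModel(structure, rotamer.rotamer_id, cys_position,
                      model_id or rotamer.rotamer_id, fits[0], fits[1], rotamer.chi3)


def _substitute_cys(copy: StructureModel, chain_id: str, res_seq: int,
                    block: dict[str, np.ndarray]) -> None:
    res = copy.residue(chain_id, res_seq)
    had_o = res.has_atoms(("O",))
    if had_o:
        # rebuild carbonyl O in the rotamer backbone's local frame so the
        # peptide plane follows the grafted backbone
        n, ca, c, o = (res.atom(x).coords for x in ("N", "CA", "C", "O"))
        tf = superpose(np.array([n, ca, c]),
                       np.array([block["N"], block["CA"], block["C"]]))
        new_o = tf.apply(o[None, :])[0]
    for name in ("N", "CA", "C", "CB", "SG"):
        res.atom(name).coords = np.asarray(block[name], float).copy()
    if had_o:
        res.atom("O").coords = new_o


def clash_check(
    dimer: DimerModel, overlap_factor: float = OVERLAP_FACTOR_DEFAULT
) -> tuple[int, list[tuple]]:
    """Count interchain heavy-atom pairs closer than overlap_factor x vdW sum.

    The bridging cysteines' SG and CB atoms are exempt (they are covalently
    bonded across the interface by construction). Strict inequality: a pair
    at exactly the threshold is not a clash.
    """
    s = dimer.structure
    cid_a, cid_b = s.chain_ids
    entries = {cid: [] for cid in (cid_a, cid_b)}
    for res in s.residues():
        bridging = res.res_seq == dimer.cys_position and res.res_name == "CYS"
        for a in res.atoms:
            if bridging and a.name in ("SG", "CB"):
                continue
            entries[res.chain_id].append((res.res_seq, a.name, a.coords, a.vdw_radius))
    pairs: list[tuple] = []
    count = 0
    for ra, na, ca, va in entries[cid_a]:
        for rb, nb, cb, vb in entries[cid_b]:
            limit = overlap_factor * (va + vb)
            if np.sum((ca - cb) ** 2) < limit * limit:
                count += 1
                pairs.append(((cid_a, ra, na), (cid_b, rb, nb)))
    pairs.sort()
    return count, pairs


def build_ensemble(
    monomer: StructureModel, cys_position: int, library: RotamerLibrary,
    overlap_factor: float = OVERLAP_FACTOR_DEFAULT,
) -> tuple[list[DimerModel], list[tuple[str, int]]]:
    """One build attempt per rotamer; clashing models are rejected.

    Returns (accepted, rejected) where rejected rows are (rotamer_id,
    clash_count); build errors are logged per rotamer and counted as
    rejections with clash_count -1, never aborting the batch. Accepted
    models get sequential ids ``model_<k> (<rotamer_id>)``.
    """
    accepted: list[DimerModel] = []
    rejected: list[tuple[str, int]] = []
    if len(library) == 0:
        log.warning("build_ensemble called with an empty library")
        return accepted, rejected
    k = 0
    for rot in library:
        try:
            dimer = build_dimer(monomer, cys_position, rot)
        except Exception as exc:
            log.warning("rotamer %s: build failed: %s", rot.rotamer_id, exc)
            rejected.append((rot.rotamer_id, -1))
            continue
        n_clash, _ = clash_check(dimer, overlap_factor)
        if n_clash > 0:
            rejected.append((rot.rotamer_id, n_clash))
            continue
        k += 1
        dimer.model_id = f"model_{k} ({rot.rotamer_id})"
        accepted.append(dimer)
    log.info("ensemble: %d accepted, %d rejected of %d rotamers",
             len(accepted), len(rejected), len(library))
    return accepted, rejected
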