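"""Cys mutation, rigid grafting, clash filtering and batch construction."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist

from cysdimer.dimer_builder import (DimerModel, build_dimer, build_ensemble,
                                    clash_check, mutate_to_cys)
from cysdimer.ensemble_analysis import rmsd_between
from cysdimer.rotamer_library import (RotamerLibrary, extract_rotamer,
                                      find_interchain_disulfides)
from cysdimer.structio import Atom, Residue, StructureModel, VDW_RADII
from cysdimer.synthetic_data import make_disulfide_dimer, make_protomer


def test_mutate_to_cys_contract(protomer):
    trp = make_protomer(12, 4, seed=1, aromatics={6: "TRP"})
    mutated = mutate_to_cys(trp, "A", 6)
    res = mutated.residue("A", 6)
    assert res.res_name == "CYS"
    assert sorted(a.name for a in res.atoms) == ["C", "CA", "CB", "N", "O", "SG"]
    cb_sg = np.linalg.norm(res.atom("CB").coords - res.atom("SG").coords)
    assert cb_sg == pytest.approx(1.81, abs=0.01)
    # backbone untouched
    for name in ("N", "CA", "C", "O", "CB"):
        assert np.allclose(res.atom(name).coords,
                           trp.residue("A", 6).atom(name).coords, atol=1e-6)


def test_mutate_ala_uses_default_chi1(protomer):
    from cysdimer.geometry import dihedral

    mutated = mutate_to_cys(protomer, "A", 3)  # an Ala: no gamma atom to copy
    res = mutated.residue("A", 3)
    chi1 = dihedral(res.atom("N").coords, res.atom("CA").coords,
                    res.atom("CB").coords, res.atom("SG").coords)
    assert chi1 == pytest.approx(-60.0, abs=1e-6)


def test_mutate_errors(protomer):
    with pytest.raises(KeyError):
        mutate_to_cys(protomer, "A", 99)
    gly = protomer.copy()
    gly.chains["A"][0].res_name = "GLY"
    gly.chains["A"][0].atoms = [a for a in gly.chains["A"][0].atoms if a.name != "CB"]
    with pytest.raises(ValueError):
        mutate_to_cys(gly, "A", 1)


def _rotamer_from(protomer, chi3, seed):
    d = make_disulfide_dimer(protomer, chi3, seed=seed)
    return extract_rotamer(d, find_interchain_disulfides(d)[0], f"s{seed}"), d


def test_build_dimer_bridge_and_rigidity(protomer):
    rot, _ = _rotamer_from(protomer, 85.0, 2)
    dimer = build_dimer(protomer, 6, rot)
    assert dimer.ss_distance == pytest.approx(rot.ss_distance, abs=1e-3)
    # intra-chain geometry preserved exactly away from the grafted Cys
    mono_coords = np.array([a.coords for r in protomer.chains["A"] for a in r.atoms
                            if r.res_seq != 6])
    for cid in "AB":
        chain_coords = np.array([a.coords for r in dimer.structure.chains[cid]
                                 for a in r.atoms if r.res_seq != 6])
        assert np.allclose(pdist(chain_coords), pdist(mono_coords), atol=1e-6)


def test_build_dimer_reconstruction_oracle(protomer):
    """Rebuilding from a mined rotamer reproduces the source dimer."""
    rot, original = _rotamer_from(protomer, -95.0, 8)
    rebuilt = build_dimer(protomer, 6, rot)
    wrapper = DimerModel(original, rot.rotamer_id, 6, "orig", 0.0, 0.0, -95.0)
    assert rmsd_between(rebuilt, wrapper) < 0.8


def test_build_dimer_invariant_to_monomer_pretransform(protomer):
    from scipy.spatial.transform import Rotation

    rot, _ = _rotamer_from(protomer, 85.0, 2)
    rng = np.random.default_rng(3)
    moved = protomer.transformed(Rotation.random(rng=rng).as_matrix(),
                                 rng.normal(size=3) * 30)
    d1 = build_dimer(protomer, 6, rot)
    d2 = build_dimer(moved, 6, rot)
    assert np.allclose(d1.structure.coords(), d2.structure.coords(), atol=1e-6)


def _two_atom_dimer(gap: float) -> DimerModel:
    def chain(cid, x):
        atoms = [Atom("N", "N", [x, 0, 0]), Atom("CA", "C", [x, 1.2, 0]),
                 Atom("C", "C", [x, 2.4, 0]), Atom("CB", "C", [x, 3.6, 0])]
        return [Residue("ALA", 1, cid, atoms)]

    s = StructureModel({"A": chain("A", 0.0), "B": chain("B", gap)})
    return DimerModel(s, "r", 99, "m", 0.0, 0.0, 90.0)


def test_clash_check_trivial_and_boundary():
    far = _two_atom_dimer(100.0)
    assert clash_check(far)[0] == 0
    overlapped = _two_atom_dimer(0.0)
    assert clash_check(overlapped)[0] > 0
    # carbon pairs exactly at the C-C threshold: strict inequality means no
    # clash (all other cross-chain pairs are farther or have smaller radii)
    cc = 0.6 * (VDW_RADII["C"] + VDW_RADII["C"])
    assert clash_check(_two_atom_dimer(cc))[0] == 0
    assert clash_check(_two_atom_dimer(cc - 1e-6))[0] > 0


def test_clash_check_equals_exhaustive_enumeration(dimer85):
    wrapper = DimerModel(dimer85, "r", 6, "m", 0.0, 0.0, 85.0)
    count, pairs = clash_check(wrapper, overlap_factor=0.9)
    # independent oracle: brute-force pair enumeration
    rows = []
    for cid in dimer85.chain_ids:
        for r in dimer85.chains[cid]:
            for a in r.atoms:
                if r.res_seq == 6 and a.name in ("SG", "CB"):
                    continue
                rows.append((cid, a.coords, a.vdw_radius))
    expect = 0
    for ca, xa, va in rows:
        for cb, xb, vb in rows:
            if ca == "A" and cb == "B":
                if np.linalg.norm(xa - xb) < 0.9 * (va + vb):
                    expect += 1
    assert count == expect == len(pairs)


def test_clash_monotone_along_approach(protomer):
    """Shrinking the inter-protomer distance never decreases the count."""
    base = _two_atom_dimer(10.0)
    counts = []
    for gap in np.linspace(10.0, 0.5, 12):
        counts.append(clash_check(_two_atom_dimer(gap))[0])
    assert all(b >= a for a, b in zip(counts, counts[1:]))


def test_build_ensemble_partition_and_designed_split(protomer):
    rots = []
    for i, chi in enumerate((85.0, -95.0, 170.0)):
        rot, _ = _rotamer_from(protomer, chi, 20 + i)
        rot.rotamer_id += f"_{i}"
        rots.append(rot)
    # two rotamers designed to force overlap: cys_b equals cys_a, so the
    # grafted copy B superimposes exactly onto copy A
    for j in (3, 4):
        rot, _ = _rotamer_from(protomer, 85.0, 2)
        rot.cys_b = {k: v.copy() for k, v in rot.cys_a.items()}
        rot.ss_distance = 0.0
        rot.rotamer_id += f"_clash{j}"
        rots.append(rot)
    lib = RotamerLibrary(rots)
    accepted, rejected = build_ensemble(protomer, 6, lib)
    assert len(accepted) == 3 and len(rejected) == 2
    assert {r.rotamer_id for r in accepted} | {r[0] for r in rejected} \
        == {r.rotamer_id for r in lib}
    assert [m.model_id.startswith(f"model_{k+1} ") for k, m in enumerate(accepted)]


def test_build_ensemble_empty_library(protomer):
    accepted, rejected = build_ensemble(protomer, 6, RotamerLibrary([]))
    assert accepted == [] and rejected == []
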