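"""Clustering, geometric descriptors, SASA/interface and selection."""

import numpy as np
import pytest

from cysdimer.dimer_builder import DimerModel, build_dimer
from cysdimer.ensemble_analysis import (SelectionCriteria, apply_selection,
                                        cluster, hbond_persistence,
                                        interface_report, max_diameter,
                                        pairwise_rmsd, radius_of_gyration,
                                        rmsd_between, sasa_per_atom)
from cysdimer.rotamer_library import extract_rotamer, find_interchain_disulfides
from cysdimer.structio import Atom, Residue, StructureModel
from cysdimer.synthetic_data import make_disulfide_dimer, make_protomer


@pytest.fixture(scope="module")
def ensemble(protomer):
    """Five dimers from distinct chi3 templates, rebuilt via the library."""
    models = []
    for k, chi in enumerate((-170.0, -95.0, 30.0, 85.0, 170.0)):
        d = make_disulfide_dimer(protomer, chi, seed=30 + k)
        rot = extract_rotamer(d, find_interchain_disulfides(d)[0], f"c{k}")
        m = build_dimer(protomer, 6, rot, model_id=f"model_{k+1} (c{k})")
        models.append(m)
    return models


def _wrap(structure, chi3=85.0):
    return DimerModel(structure, "r", 6, structure.model_id or "m", 0.0, 0.0, chi3)


def test_rmsd_identity_rigid_copy_and_chain_swap(dimer85):
    m = _wrap(dimer85)
    assert rmsd_between(m, m) == pytest.approx(0, abs=1e-9)

    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(9)
    moved = dimer85.transformed(Rotation.random(rng=rng).as_matrix(),
                                rng.normal(size=3) * 15)
    moved.model_id = "moved"
    assert rmsd_between(m, _wrap(moved)) == pytest.approx(0, abs=1e-6)

    res_a = [r.copy() for r in dimer85.chains["B"]]
    res_b = [r.copy() for r in dimer85.chains["A"]]
    for r in res_a:
        r.chain_id = "A"
    for r in res_b:
        r.chain_id = "B"
    swapped = StructureModel({"A": res_a, "B": res_b}, model_id="swap")
    assert rmsd_between(m, _wrap(swapped)) == pytest.approx(0, abs=1e-6)


def test_pairwise_matrix_axioms(ensemble):
    D, ids = pairwise_rmsd(ensemble)
    assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)
    assert ids == sorted(ids)
    assert (D[~np.eye(len(ids), dtype=bool)] > 0).all()


def test_cluster_trivial_and_extreme_cutoffs(ensemble):
    identical = [ensemble[0]] * 3
    # distinct ids required for labelling
    import copy

    models = []
    for i in range(3):
        m = copy.deepcopy(ensemble[0])
        m.model_id = f"model_{i+1} (same)"
        models.append(m)
    assert cluster(models, cutoff=8.0).n_clusters == 1

    res_tiny = cluster(ensemble, cutoff=1e-6)
    assert res_tiny.n_clusters == len(ensemble)
    res_huge = cluster(ensemble, cutoff=1e6)
    assert res_huge.n_clusters == 1
    with pytest.raises(ValueError):
        cluster(ensemble, cutoff=0.0)


def test_cluster_labels_invariant_under_input_permutation(ensemble):
    ref = cluster(ensemble, cutoff=8.0)
    rng = np.random.default_rng(2)
    perm = list(ensemble)
    rng.shuffle(perm)
    again = cluster(perm, cutoff=8.0)
    assert ref.labels == again.labels
    assert ref.medoids == again.medoids


def test_two_far_models_split_at_cutoff(ensemble):
    far = [ensemble[0], ensemble[1]]
    D, _ = pairwise_rmsd(far)
    if D[0, 1] > 8.0:
        assert cluster(far, cutoff=8.0).n_clusters == 2
    assert cluster(far, cutoff=D[0, 1] + 0.1).n_clusters == 1


def test_max_diameter_and_interior_atom():
    a = Residue("ALA", 1, "A", [Atom("CA", "C", [0, 0, 0])])
    b = Residue("ALA", 2, "A", [Atom("CA", "C", [10, 0, 0])])
    s = StructureModel({"A": [a, b]})
    assert max_diameter(s) == pytest.approx(1.0)
    s.chains["A"].append(Residue("ALA", 3, "A", [Atom("CA", "C", [5, 1, 0])]))
    assert max_diameter(s) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        max_diameter(StructureModel({"A": [a]}))


def test_radius_of_gyration_closed_forms():
    a = Residue("ALA", 1, "A", [Atom("CA", "C", [0, 0, 0])])
    assert radius_of_gyration(StructureModel({"A": [a]})) == 0.0
    # two equal masses 2 A apart -> Rg = 1 A = 0.1 nm
    two = StructureModel({"A": [
        Residue("ALA", 1, "A", [Atom("CA", "C", [0, 0, 0])]),
        Residue("ALA", 2, "A", [Atom("CA", "C", [2, 0, 0])]),
    ]})
    assert radius_of_gyration(two) == pytest.approx(0.1, abs=1e-12)
    # uniform shell of radius 10 A -> Rg -> 1.0 nm
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(400, 3))
    pts = 10.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
    shell = StructureModel({"A": [
        Residue("ALA", i + 1, "A", [Atom("CA", "C", p)]) for i, p in enumerate(pts)
    ]})
    assert radius_of_gyration(shell) == pytest.approx(1.0, rel=0.01)


def test_single_atom_sasa_matches_analytic_sphere():
    for r in (1.52, 1.7, 1.8):
        area = sasa_per_atom(np.zeros((1, 3)), np.array([r]), probe=1.4,
                             n_points=960)[0]
        assert area == pytest.approx(4 * np.pi * (r + 1.4) ** 2, rel=0.02)


def test_sasa_quadrature_converges_and_buried_atom_is_zero():
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    radii = np.array([1.7, 1.7])
    a1 = sasa_per_atom(coords, radii, n_points=480).sum()
    a2 = sasa_per_atom(coords, radii, n_points=960).sum()
    assert abs(a1 - a2) / a2 < 0.01
    # a small atom fully inside a big one has zero SASA
    buried = sasa_per_atom(np.zeros((2, 3)), np.array([0.1, 3.0]), probe=1.4)
    assert buried[0] == 0.0


def test_sasa_cross_checked_against_biotite(dimer85):
    struc = pytest.importorskip("biotite.structure")
    coords, refs = [], []
    from cysdimer.structio import select_atoms

    xyz, hits = select_atoms(dimer85)
    radii = np.array([a.vdw_radius for _, a in hits])
    ours = sasa_per_atom(xyz, radii, probe=1.4, n_points=960).sum()
    arr = struc.AtomArray(len(hits))
    arr.coord = np.asarray(xyz, np.float32)
    arr.chain_id = np.array([r.chain_id for r, _ in hits])
    arr.res_id = np.array([r.res_seq for r, _ in hits])
    arr.res_name = np.array([r.res_name for r, _ in hits])
    arr.atom_name = np.array([a.name for _, a in hits])
    arr.element = np.array([a.element for _, a in hits])
    theirs = struc.sasa(arr, probe_radius=1.4, point_number=960,
                        vdw_radii=radii).sum()
    assert ours == pytest.approx(theirs, rel=0.02)


def test_interface_separated_protomers_and_symmetry(protomer, dimer85):
    m = _wrap(dimer85)
    rep = interface_report(m, n_points=240)
    assert rep.interface_area > 0

    far = dimer85.copy()
    for r in far.chains["B"]:
        for a in r.atoms:
            a.coords = a.coords + np.array([100.0, 0, 0])
    rep_far = interface_report(_wrap(far), n_points=240)
    assert rep_far.interface_area == pytest.approx(0, abs=1.0)
    assert rep_far.interface_residues == {"A": [], "B": []}
    assert rep_far.hydrogen_bonds == [] and rep_far.trp_contacts == []

    swapped = StructureModel(
        {"B": [r.copy() for r in dimer85.chains["B"]],
         "A": [r.copy() for r in dimer85.chains["A"]]})
    rep_sw = interface_report(_wrap(swapped), n_points=240)
    assert rep_sw.interface_area == pytest.approx(rep.interface_area, rel=1e-6)


def test_hbond_persistence_threshold(ensemble):
    df = hbond_persistence(ensemble, min_fraction=0.0)
    if len(df):
        assert (df["fraction"] > 0).all() and (df["fraction"] <= 1).all()
    high = hbond_persistence(ensemble, min_fraction=0.99)
    assert set(high.columns) == {"donor", "acceptor", "fraction"}
    with pytest.raises(ValueError):
        hbond_persistence([], 0.3)


def test_apply_selection_diameter_flag_matches_construction(ensemble):
    diams = [max_diameter(m.structure) for m in ensemble]
    lo = float(np.percentile(diams, 30))
    hi = float(np.percentile(diams, 80))
    crit = SelectionCriteria(diameter_range=(lo, hi))
    reports = apply_selection(ensemble, crit, sasa_points=120)
    for rep, d in zip(reports, diams):
        assert rep.diameter_ok == (lo <= d <= hi)
        assert rep.max_diameter >= rep.rg
        assert rep.selected == (rep.diameter_ok and rep.trp_interface_ok
                                and rep.quality_ok)


def test_trp_quencher_criterion(protomer):
    """A model with an interface Trp but no quencher nearby fails the flag."""
    trp_only = make_protomer(12, 6, seed=5, aromatics={5: "TRP"})
    d = make_disulfide_dimer(trp_only, 85.0, seed=6)
    reports = apply_selection([_wrap(d)], SelectionCriteria(
        diameter_range=(0.1, 50.0), quencher_residues=frozenset({"HIS"})),
        sasa_points=120)
    assert reports[0].trp_interface_ok is False
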