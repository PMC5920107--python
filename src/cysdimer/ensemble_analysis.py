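"""Ensemble clustering, geometric descriptors and model selection.

Dimer models are compared by Calpha RMSD after optimal superposition
(minimized over the two chain pairings of a homodimer), clustered
agglomeratively at a distance cutoff (default 8 A), and screened with
three criteria drawn from solution measurements:

1. maximum molecular diameter inside the hydrodynamic size window
   measured by DLS (default 5.5-6.5 nm);
2. at least one interface Trp with a potential quencher side chain
   (Cys, His, Tyr, Phe) from the partner protomer nearby — the static
   structural reading of the dimer's damped Trp fluorescence;
3. structural quality, here: no steric clashes.

Interface geometry (buried area, interface residues, hydrogen bonds) is
computed from rolling-probe solvent-accessible surface area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .dimer_builder import DimerModel, clash_check
from .geometry import rmsd, superpose
from .structio import StructureModel, select_atoms

log = logging.getLogger(__name__)

CLUSTER_CUTOFF_DEFAULT = 8.0  # A
DIAMETER_RANGE_DEFAULT = (5.5, 6.5)  # nm
QUENCHER_RESIDUES_DEFAULT = frozenset({"CYS", "HIS", "TYR", "PHE"})
QUENCHER_CUTOFF_DEFAULT = 7.0  # A, ring-centroid to ring-centroid/SG
SASA_PROBE_DEFAULT = 1.4  # A
DSASA_THRESHOLD_DEFAULT = 0.1  # A^2
HBOND_DISTANCE_DEFAULT = 3.5  # A heavy-atom donor-acceptor
SASA_POINTS_DEFAULT = 960

_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    # Trp six-membered (benzene) ring of the indole
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

# heavy-atom H-bond chemistry: which N/O atoms can donate / accept
_DONORS = {
    ("*", "N"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("LYS", "NZ"),
    ("TRP", "NE1"), ("HIS", "ND1"), ("HIS", "NE2"), ("ASN", "ND2"),
    ("GLN", "NE2"), ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
}
_ACCEPTORS = {
    ("*", "O"), ("*", "OXT"), ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"),
    ("GLU", "OE2"), ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"),
    ("THR", "OG1"), ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("MET", "SD"),
}


def _is_donor(res_name: str, atom_name: str) -> bool:
    if ("*", atom_name) in _DONORS and res_name != "PRO":
        return True
    return (res_name, atom_name) in _DONORS


def _is_acceptor(res_name: str, atom_name: str) -> bool:
    return ("*", atom_name) in _ACCEPTORS or (res_name, atom_name) in _ACCEPTORS


# ---------------------------------------------------------------- clustering

@dataclass
class ClusterResult:
    labels: dict[str, int]
    n_clusters: int
    cutoff: float
    linkage: str
    distance_matrix: np.ndarray
    model_ids: list[str]
    medoids: dict[int, str] = field(default_factory=dict)


def _ca_coords(model: DimerModel) -> tuple[np.ndarray, np.ndarray]:
    s = model.structure
    a, b = s.chain_ids
    ca_a, _ = select_atoms(s, a, ("CA",))
    ca_b, _ = select_atoms(s, b, ("CA",))
    return ca_a, ca_b


def _fit_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    tf = superpose(x, y)
    return rmsd(tf.apply(x), y)


def rmsd_between(m1: DimerModel, m2: DimerModel) -> float:
    """Calpha RMSD after optimal superposition, minimized over the two
    chain pairings (A->A/B->B vs A->B/B->A)."""
    a1, b1 = _ca_coords(m1)
    a2, b2 = _ca_coords(m2)
    if len(a1) != len(a2) or len(b1) != len(b2):
        raise ValueError(
            f"chain length mismatch between {m1.model_id} and {m2.model_id}"
        )
    direct = _fit_rmsd(np.vstack([a1, b1]), np.vstack([a2, b2]))
    swapped = _fit_rmsd(np.vstack([b1, a1]), np.vstack([a2, b2]))
    return min(direct, swapped)


def pairwise_rmsd(models: list[DimerModel]) -> tuple[np.ndarray, list[str]]:
    """Symmetric Calpha-RMSD matrix in model_id lexicographic order."""
    ordered = sorted(models, key=lambda m: m.model_id)
    ids = [m.model_id for m in ordered]
    n = len(ordered)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = rmsd_between(ordered[i], ordered[j])
    return D, ids


def cluster(
    models: list[DimerModel], cutoff: float = CLUSTER_CUTOFF_DEFAULT,
    linkage_method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of the ensemble cut at ``cutoff`` (A).

    Deterministic under input reordering: models are sorted by model_id
    before the distance matrix is built, and cluster indices are relabelled
    1..k in order of first appearance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not models:
        raise ValueError("cannot cluster an empty ensemble")
    D, ids = pairwise_rmsd(models)
    if len(ids) == 1:
        return ClusterResult({ids[0]: 1}, 1, cutoff, linkage_method, D, ids,
                             {1: ids[0]})
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    raw = fcluster(Z, t=cutoff, criterion="distance")
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for mid, lab in zip(ids, raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[mid] = remap[lab]
    medoids: dict[int, str] = {}
    for c in sorted(set(labels.values())):
        members = [i for i, mid in enumerate(ids) if labels[mid] == c]
        sums = D[np.ix_(members, members)].sum(axis=1)
        medoids[c] = ids[members[int(np.argmin(sums))]]
    return ClusterResult(labels, len(remap), cutoff, linkage_method, D, ids, medoids)


# ------------------------------------------------------------- descriptors

def max_diameter(structure: StructureModel) -> float:
    """Maximum heavy-atom pairwise distance, in nm."""
    coords = structure.coords()
    if len(coords) < 2:
        raise ValueError("need at least two atoms for a diameter")
    return float(pdist(coords).max()) / 10.0


def radius_of_gyration(structure: StructureModel) -> float:
    """Mass-weighted radius of gyration, in nm."""
    coords = structure.coords()
    masses = np.array([a.mass for _, a in structure.atoms()])
    com = np.average(coords, axis=0, weights=masses)
    rg2 = np.average(np.sum((coords - com) ** 2, axis=1), weights=masses)
    return float(np.sqrt(rg2)) / 10.0


def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ])


def sasa_per_atom(
    coords: np.ndarray, radii: np.ndarray,
    probe: float = SASA_PROBE_DEFAULT, n_points: int = SASA_POINTS_DEFAULT,
) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area per atom (A^2).

    Each atom's solvent sphere (radius r_i + probe) is sampled on a
    golden-spiral lattice; a point is accessible when outside every
    neighbour's solvent sphere. Exact for an isolated atom up to the
    quadrature (converges as n_points grows).
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float) + probe
    n = len(coords)
    unit = _sphere_points(n_points)
    out = np.empty(n)
    # neighbour lists via one distance matrix; ensembles here are small
    d2 = squareform(pdist(coords) ** 2, checks=False) if n > 1 else np.zeros((1, 1))
    for i in range(n):
        if n > 1:
            reach = (radii[i] + radii) ** 2
            nbr = np.where((d2[i] < reach) & (np.arange(n) != i))[0]
        else:
            nbr = np.array([], int)
        pts = coords[i] + radii[i] * unit
        if len(nbr):
            diff = pts[:, None, :] - coords[nbr][None, :, :]
            buried = np.any(
                np.einsum("ijk,ijk->ij", diff, diff) < radii[nbr][None, :] ** 2,
                axis=1,
            )
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    return out


@dataclass
class InterfaceReport:
    interface_residues: dict[str, list[tuple[int, str, float]]]  # chain -> (seq, name, dSASA)
    interface_area: float
    hydrogen_bonds: list[tuple]
    trp_contacts: list[tuple]

    def __post_init__(self) -> None:
        if self.interface_area < -1e-6:
            raise ValueError("interface_area must be non-negative")


def _chain_sasa(structure: StructureModel, chain_id: str | None,
                probe: float, n_points: int) -> dict[tuple, float]:
    """Per-residue SASA for one chain context (or the whole complex)."""
    coords, refs = select_atoms(structure, chain_id)
    if len(refs) == 0:
        return {}
    radii = np.array([a.vdw_radius for _, a in refs])
    areas = sasa_per_atom(coords, radii, probe, n_points)
    per_res: dict[tuple, float] = {}
    for (res, _), area in zip(refs, areas):
        key = (res.chain_id, res.res_seq, res.icode)
        per_res[key] = per_res.get(key, 0.0) + float(area)
    return per_res


def interface_report(
    dimer: DimerModel, probe: float = SASA_PROBE_DEFAULT,
    dsasa_threshold: float = DSASA_THRESHOLD_DEFAULT,
    hbond_distance: float = HBOND_DISTANCE_DEFAULT,
    quencher_residues: frozenset[str] = QUENCHER_RESIDUES_DEFAULT,
    quencher_cutoff: float = QUENCHER_CUTOFF_DEFAULT,
    n_points: int = SASA_POINTS_DEFAULT,
) -> InterfaceReport:
    """Geometric protein-protein interface characterization.

    interface_area = (SASA_A + SASA_B - SASA_AB) / 2; interface residues
    are those burying more than ``dsasa_threshold`` A^2 upon complexation.
    Hydrogen bonds use a heavy-atom donor-acceptor distance criterion
    (the models carry no hydrogens). Trp contacts measure the indole
    benzene-ring centroid against partner aromatic-ring centroids or SG.
    """
    s = dimer.structure
    if len(s.chains) != 2:
        raise ValueError("interface_report requires a two-chain structure")
    cid_a, cid_b = s.chain_ids

    iso_a = StructureModel({cid_a: [r.copy() for r in s.chains[cid_a]]})
    iso_b = StructureModel({cid_b: [r.copy() for r in s.chains[cid_b]]})
    sasa_a = _chain_sasa(iso_a, None, probe, n_points)
    sasa_b = _chain_sasa(iso_b, None, probe, n_points)
    sasa_ab = _chain_sasa(s, None, probe, n_points)

    total_free = sum(sasa_a.values()) + sum(sasa_b.values())
    area = max(0.0, (total_free - sum(sasa_ab.values())) / 2.0)

    interface_res: dict[str, list[tuple[int, str, float]]] = {cid_a: [], cid_b: []}
    for cid, iso in ((cid_a, sasa_a), (cid_b, sasa_b)):
        for key, free in iso.items():
            dsasa = free - sasa_ab.get(key, 0.0)
            if dsasa > dsasa_threshold:
                res = s.residue(key[0], key[1], key[2])
                interface_res[cid].append((key[1], res.res_name, round(dsasa, 3)))
        interface_res[cid].sort()

    hbonds = _interchain_hbonds(s, cid_a, cid_b, hbond_distance)
    trp = _trp_contacts(s, cid_a, cid_b, quencher_residues, quencher_cutoff)
    return InterfaceReport(interface_res, float(area), hbonds, trp)


def _interchain_hbonds(s: StructureModel, cid_a: str, cid_b: str,
                       max_d: float) -> list[tuple]:
    def polar(cid):
        out = []
        for res in s.chains[cid]:
            for a in res.atoms:
                if a.element in ("N", "O", "S"):
                    out.append((res, a))
        return out

    bonds = []
    for ra, aa in polar(cid_a):
        for rb, ab in polar(cid_b):
            d = float(np.linalg.norm(aa.coords - ab.coords))
            if d > max_d:
                continue
            ab_ok = _is_donor(ra.res_name, aa.name) and _is_acceptor(rb.res_name, ab.name)
            ba_ok = _is_donor(rb.res_name, ab.name) and _is_acceptor(ra.res_name, aa.name)
            if ab_ok:
                bonds.append(((cid_a, ra.res_seq, aa.name), (cid_b, rb.res_seq, ab.name),
                              round(d, 3)))
            elif ba_ok:
                bonds.append(((cid_b, rb.res_seq, ab.name), (cid_a, ra.res_seq, aa.name),
                              round(d, 3)))
    bonds.sort()
    return bonds


def _ring_centroid(res) -> np.ndarray | None:
    names = _RING_ATOMS.get(res.res_name)
    if names is None:
        return None
    try:
        return np.mean([res.atom(n).coords for n in names], axis=0)
    except KeyError:
        return None


def _trp_contacts(s: StructureModel, cid_a: str, cid_b: str,
                  quenchers: frozenset[str], cutoff: float) -> list[tuple]:
    contacts = []
    for cid, other in ((cid_a, cid_b), (cid_b, cid_a)):
        for res in s.chains[cid]:
            if res.res_name != "TRP":
                continue
            cen = _ring_centroid(res)
            if cen is None:
                continue
            for partner in s.chains[other]:
                point = None
                if partner.res_name == "CYS":
                    try:
                        point = partner.atom("SG").coords
                    except KeyError:
                        point = None
                else:
                    point = _ring_centroid(partner)
                if point is None:
                    continue
                d = float(np.linalg.norm(cen - point))
                if d <= cutoff:
                    contacts.append((
                        (cid, res.res_seq), (other, partner.res_seq, partner.res_name),
                        round(d, 3), partner.res_name in quenchers,
                    ))
    contacts.sort()
    return contacts


def hbond_persistence(
    ensemble: list[DimerModel], min_fraction: float = 0.30,
    hbond_distance: float = HBOND_DISTANCE_DEFAULT,
) -> pd.DataFrame:
    """Bonds present in at least ``min_fraction`` of the ensemble's models.

    The static-ensemble counterpart of trajectory H-bond persistence: bond
    identity is the (chain, residue, atom) donor/acceptor pair; the
    reported fraction is the share of models in which it occurs.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    counts: dict[tuple, int] = {}
    for m in ensemble:
        cid_a, cid_b = m.structure.chain_ids
        seen = {(d, a) for d, a, _ in
                _interchain_hbonds(m.structure, cid_a, cid_b, hbond_distance)}
        for bond in seen:
            counts[bond] = counts.get(bond, 0) + 1
    rows = [
        {"donor": d, "acceptor": a, "fraction": c / len(ensemble)}
        for (d, a), c in counts.items() if c / len(ensemble) >= min_fraction
    ]
    rows.sort(key=lambda r: (-r["fraction"], str(r["donor"])))
    return pd.DataFrame(rows, columns=["donor", "acceptor", "fraction"])


# --------------------------------------------------------------- selection

@dataclass
class SelectionCriteria:
    diameter_range: tuple[float, float] = DIAMETER_RANGE_DEFAULT
    quencher_residues: frozenset[str] = QUENCHER_RESIDUES_DEFAULT
    quencher_cutoff: float = QUENCHER_CUTOFF_DEFAULT
    require_clash_free: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.diameter_range
        if not lo < hi:
            raise ValueError("diameter_range must satisfy min < max")
        if self.quencher_cutoff <= 0:
            raise ValueError("quencher_cutoff must be positive")


@dataclass
class ModelReport:
    model_id: str
    max_diameter: float  # nm
    rg: float            # nm
    clash_count: int
    interface: InterfaceReport
    chi3: float
    diameter_ok: bool
    trp_interface_ok: bool
    quality_ok: bool

    @property
    def selected(self) -> bool:
        return self.diameter_ok and self.trp_interface_ok and self.quality_ok

    def __post_init__(self) -> None:
        if self.max_diameter < self.rg:
            raise ValueError("max_diameter cannot be smaller than Rg")


def apply_selection(
    models: list[DimerModel], criteria: SelectionCriteria = SelectionCriteria(),
    sasa_points: int = SASA_POINTS_DEFAULT,
) -> list[ModelReport]:
    """Score every model against the three selection criteria."""
    reports = []
    lo, hi = criteria.diameter_range
    for m in models:
        diam = max_diameter(m.structure)
        rg = radius_of_gyration(m.structure)
        n_clash, _ = clash_check(m)
        iface = interface_report(
            m, quencher_residues=criteria.quencher_residues,
            quencher_cutoff=criteria.quencher_cutoff, n_points=sasa_points,
        )
        interface_trp = {
            (cid, seq) for cid, rows in iface.interface_residues.items()
            for seq, name, _ in rows if name == "TRP"
        }
        trp_ok = any(
            contact[0] in interface_trp and contact[3]
            for contact in iface.trp_contacts
        )
        reports.append(ModelReport(
            model_id=m.model_id, max_diameter=diam, rg=rg, clash_count=n_clash,
            interface=iface, chi3=m.chi3,
            diameter_ok=lo <= diam <= hi,
            trp_interface_ok=trp_ok,
            quality_ok=(n_clash == 0) or not criteria.require_clash_free,
        ))
    n_sel = sum(r.selected for r in reports)
    log.info("selection: %d/%d models pass all three criteria", n_sel, len(reports))
    return reports
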