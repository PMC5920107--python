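"""Synthetic inputs with known ground truth for every pipeline stage.

Structures: idealized alpha-helical protomers (poly-Ala with one surface
cysteine and optional aromatic residues) and two-chain dimers carrying a
bridging cystine whose chi3 torsion is imposed analytically, so mining and
rebuilding can be checked against exact truth. Curves: hemolysis kinetics,
dose-response, thermal melts, quenching series, absorbance ladders, MALDI
peak sets and SEC calibrations generated from their fitters' own model
with seeded noise; defaults sit at the measured values for the sticholysin
W111C system (HC50 0.31/62.4 nM, Vmax 1.05/0.69 min^-1, Tm 57.2/64.9 and
69.9/74 degC, K_SV 4.56/3.03 M^-1, eps 1.78 mL mg^-1 cm^-1, dimer mass
38 618.35 Da, DLS diameters 4.2/5.9 nm).

Every generator is deterministic per (parameters, seed) and, when it
writes files, emits a JSON truth sidecar; recovery tests read truth only
from the returned/emitted metadata.

The protomer is an idealized helix, not a real actinoporin fold: the
geometric pipeline is fold-agnostic and the real NMR template stays an
optional external input.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .biophysics import (AbsorbancePair, KineticCurve, MassPeakSet,
                         MeltingCurve, PROTON_MASS_DEFAULT, QuenchSeries,
                         SECCalibration)
from .geometry import dihedral, place_atom, superpose
from .structio import Atom, Residue, StructureModel, write_pdb

# measured reference values for the W111C system, used as generator defaults
REFERENCE_PARAMS = {
    "hc50_monomer_nM": 0.31, "hc50_dimer_nM": 62.4,
    "vmax_monomer_per_min": 1.05, "vmax_dimer_per_min": 0.69,
    "tm_cd_dimer_C": 57.2, "tm_cd_rstl_C": 64.9, "tm_cd_monomer_C": 64.0,
    "tm_fluor_dimer_C": 69.9, "tm_fluor_monomer_C": 74.0,
    "ksv_monomer_per_M": 4.56, "ksv_dimer_per_M": 3.03,
    "epsilon_corrected": 1.78, "epsilon_uncorrected": 2.00,
    "monomer_mass_Da": 19272.96, "dimer_maldi_mass_Da": 38618.35,
    "diameter_monomer_nm": 4.2, "diameter_dimer_nm": 5.9,
}

_SS_BOND = 2.05       # A
_CB_S_S_ANGLE = 104.0  # deg
_CB_SG_BOND = 1.81
_CA_CB_SG_ANGLE = 114.0
_CA_CB_BOND = 1.53


@dataclass
class SyntheticConfig:
    """Bundle of generator parameters; echoed into every truth sidecar."""

    seed: int
    noise_sd: float = 0.02
    params: dict = field(default_factory=lambda: dict(REFERENCE_PARAMS))


# ------------------------------------------------------------ structures

def _ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Idealized CB from backbone: tetrahedral take-off at 1.53 A."""
    b1 = ca - n
    b2 = ca - c
    bisector = b1 / np.linalg.norm(b1) + b2 / np.linalg.norm(b2)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(b1, b2)
    perp /= np.linalg.norm(perp)
    direction = np.sqrt(1.0 / 3.0) * bisector + np.sqrt(2.0 / 3.0) * perp
    return ca + _CA_CB_BOND * direction


def make_protomer(
    n_res: int, cys_at: int, seed: int = 0,
    aromatics: dict[int, str] | None = None, chain_id: str = "A",
) -> StructureModel:
    """Idealized alpha-helical protomer: poly-Ala + one Cys.

    Backbone: CA on a helix of rise 1.5 A, 100 deg/residue, radius 2.3 A
    (consecutive CA-CA ~3.8 A); N/C interpolated along the trace, CB at
    tetrahedral geometry, SG on the cysteine. ``aromatics`` optionally
    places TRP/TYR/PHE/HIS side chains (planar rings at idealized
    geometry) at given residue numbers for interface tests. Deterministic
    per seed (the seed only orients ring torsions).
    """
    if n_res < 5:
        raise ValueError("n_res must be >= 5")
    if not 1 <= cys_at <= n_res:
        raise ValueError(f"cys_at {cys_at} out of range 1..{n_res}")
    aromatics = aromatics or {}
    rng = np.random.default_rng(seed)
    rise, twist, radius = 1.5, np.radians(100.0), 2.3
    ca = np.array([
        [radius * np.cos(i * twist), radius * np.sin(i * twist), rise * i]
        for i in range(n_res)
    ])
    residues = []
    for i in range(n_res):
        prev_dir = (ca[i - 1] - ca[i]) if i > 0 else (2 * ca[0] - ca[1] - ca[0])
        next_dir = (ca[i + 1] - ca[i]) if i < n_res - 1 else (2 * ca[-1] - ca[-2] - ca[-1])
        n_at = ca[i] + 1.45 * prev_dir / np.linalg.norm(prev_dir)
        c_at = ca[i] + 1.52 * next_dir / np.linalg.norm(next_dir)
        o_at = place_atom(n_at, ca[i], c_at, 1.23, 120.5, 135.0)
        cb = _ideal_cb(n_at, ca[i], c_at)
        seq = i + 1
        name = "ALA"
        atoms = [Atom("N", "N", n_at), Atom("CA", "C", ca[i]),
                 Atom("C", "C", c_at), Atom("O", "O", o_at), Atom("CB", "C", cb)]
        if seq == cys_at:
            name = "CYS"
            sg = place_atom(n_at, ca[i], cb, _CB_SG_BOND, _CA_CB_SG_ANGLE, -60.0)
            atoms.append(Atom("SG", "S", sg))
        elif seq in aromatics:
            name = aromatics[seq]
            atoms.extend(_aromatic_side_chain(name, n_at, ca[i], cb, rng))
        residues.append(Residue(name, seq, chain_id, atoms))
    return StructureModel({chain_id: residues}, model_id="protomer",
                          source=f"synthetic:helix_{n_res}_{cys_at}_{seed}")


# ring adjacency orders; the first atom is the ring's attachment vertex
_RING_TEMPLATES = {
    "PHE": ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"],
    "TYR": ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"],
    "HIS": ["CG", "ND1", "CE1", "NE2", "CD2"],
    "TRP": ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"],
}


def _regular_ring(names: list[str], attach: np.ndarray, axis: np.ndarray,
                  ref: np.ndarray) -> list[Atom]:
    """Regular planar polygon with vertex 0 at ``attach``, opening along axis."""
    k = len(names)
    r_ring = 1.39 / (2.0 * np.sin(np.pi / k))
    center = attach + r_ring * axis
    v = np.cross(axis, ref)
    v /= np.linalg.norm(v)
    u = -axis  # vertex 0 direction: from center back to the attachment point
    atoms = []
    for j, nm in enumerate(names):
        ang = 2.0 * np.pi * j / k
        pos = center + r_ring * (np.cos(ang) * u + np.sin(ang) * v)
        atoms.append(Atom(nm, "N" if nm.startswith("N") else "C", pos))
    return atoms


def _aromatic_side_chain(res_name: str, n, ca, cb, rng) -> list[Atom]:
    """Planar idealized ring beyond CB (schematic geometry: centroids and
    distances are what downstream criteria use, not covalent detail)."""
    chi1 = float(rng.uniform(-180.0, 180.0))
    cg = place_atom(n, ca, cb, 1.50, 114.0, chi1)
    axis = cg - cb
    axis /= np.linalg.norm(axis)
    ref = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(ref) < 1e-6:
        ref = np.cross(axis, [0.0, 1.0, 0.0])
    ref /= np.linalg.norm(ref)
    if res_name in ("PHE", "TYR", "HIS"):
        atoms = _regular_ring(_RING_TEMPLATES[res_name], cg, axis, ref)
        if res_name == "TYR":
            center = cg + (1.39 / (2.0 * np.sin(np.pi / 6))) * axis
            cz = next(a.coords for a in atoms if a.name == "CZ")
            oh = cz + 1.38 * (cz - center) / np.linalg.norm(cz - center)
            atoms.append(Atom("OH", "O", oh))
        return atoms
    # TRP: benzene six-ring attached one bond beyond CG, plus minimal
    # five-ring atoms (CD1, NE1) so the residue looks indole-like
    cd2 = cg + 1.43 * axis
    atoms = [Atom("CG", "C", cg)]
    atoms += _regular_ring(_RING_TEMPLATES["TRP"], cd2, axis, ref)
    cd1 = place_atom(ca, cb, cg, 1.37, 127.0, 60.0)
    ne1 = place_atom(cb, cg, cd1, 1.37, 109.0, 180.0)
    atoms += [Atom("CD1", "C", cd1), Atom("NE1", "N", ne1)]
    return atoms


def make_disulfide_dimer(
    protomer: StructureModel, chi3: float, seed: int = 0,
    chain_ids: tuple[str, str] = ("A", "B"),
    max_attempts: int = 144,
) -> StructureModel:
    """Join two protomer copies through an analytically built cystine.

    The partner half-cystine is constructed from internal coordinates:
    SG-SG = 2.05 A, CB-S-S angles 104 deg, and CB-S-S'-CB' torsion exactly
    ``chi3``. Two torsions not constrained by the bridge (the chi2-like
    rotations about each CB-SG bond) are free: they are scanned on a
    deterministic grid until the placement is clash-free. Rotating copy B
    about its own CB-SG bond leaves the bridge atoms fixed, so chi3 is
    preserved exactly during the search.
    """
    cid = protomer.chain_ids[0]
    cys = [r for r in protomer.chains[cid] if r.res_name == "CYS"]
    if len(cys) != 1:
        raise ValueError("protomer must have exactly one CYS")
    cys_a = cys[0]
    ca_a, cb_a, sg_a = (cys_a.atom(x).coords for x in ("CA", "CB", "SG"))

    from .dimer_builder import DimerModel, clash_check

    rng = np.random.default_rng(seed)
    n_grid = int(np.sqrt(max_attempts)) or 1
    offsets = rng.uniform(0, 360.0 / n_grid, 2)  # seeded grid phase
    grid = [(offsets[0] + i * 360.0 / n_grid, offsets[1] + j * 360.0 / n_grid)
            for i in range(n_grid) for j in range(n_grid)]
    best = None
    for chi2_a, chi2_b in grid:
        sg_b = place_atom(ca_a, cb_a, sg_a, _SS_BOND, _CB_S_S_ANGLE, chi2_a)
        cb_b = place_atom(cb_a, sg_a, sg_b, _CB_SG_BOND, _CB_S_S_ANGLE, chi3)
        ca_b = place_atom(sg_a, sg_b, cb_b, _CA_CB_BOND, _CA_CB_SG_ANGLE, chi2_b)
        mobile = np.array([cys_a.atom(x).coords for x in ("CA", "CB", "SG")])
        target = np.array([ca_b, cb_b, sg_b])
        tf = superpose(mobile, target)
        copy_b = protomer.transformed(tf.rotation, tf.translation)

        res_a = [r.copy() for r in protomer.chains[cid]]
        res_b = copy_b.chains[cid]
        for r in res_a:
            r.chain_id = chain_ids[0]
        for r in res_b:
            r.chain_id = chain_ids[1]
        dimer_struct = StructureModel(
            {chain_ids[0]: res_a, chain_ids[1]: res_b},
            model_id=f"synthetic_dimer_chi3_{chi3:+.0f}",
            source=f"synthetic:dimer_chi3={chi3}_seed={seed}",
        )
        wrapper = DimerModel(dimer_struct, "synthetic", cys_a.res_seq,
                             dimer_struct.model_id, tf.fit_rmsd, tf.fit_rmsd, chi3)
        n_clash, _ = clash_check(wrapper)
        achieved = dihedral(
            dimer_struct.residue(chain_ids[0], cys_a.res_seq).atom("CB").coords,
            dimer_struct.residue(chain_ids[0], cys_a.res_seq).atom("SG").coords,
            dimer_struct.residue(chain_ids[1], cys_a.res_seq).atom("SG").coords,
            dimer_struct.residue(chain_ids[1], cys_a.res_seq).atom("CB").coords,
        )
        if best is None or n_clash < best[0]:
            best = (n_clash, dimer_struct, achieved)
        if n_clash == 0:
            break
    n_clash, structure, achieved = best
    if n_clash > 0:
        raise RuntimeError(
            f"no clash-free placement for chi3={chi3} (best attempt: {n_clash} clashes)"
        )
    if abs(achieved - chi3) > 0.5 and abs(abs(achieved - chi3) - 360.0) > 0.5:
        raise RuntimeError(
            f"bridge construction drifted: requested chi3 {chi3}, achieved {achieved:.2f}"
        )
    return structure


def make_library_corpus(
    n_structures: int, chi3_sampler, seed: int, out_dir: str | Path,
    n_res: int = 12, cys_at: int = 6,
) -> tuple[list[Path], Path]:
    """Write a corpus of two-chain cystine dimers plus a truth table.

    ``chi3_sampler`` is either a sequence of chi3 values (cycled), the
    string "bimodal" (mixture of Gaussians at +-90, sd 10), or a callable
    rng -> chi3. Returns (pdb paths, truth sidecar path). An ``n=0``
    request writes only an empty truth file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    def draw(i: int) -> float:
        if callable(chi3_sampler):
            return float(chi3_sampler(rng))
        if chi3_sampler == "bimodal":
            mode = 90.0 if rng.random() < 0.5 else -90.0
            v = rng.normal(mode, 10.0)
            return float((v + 180.0) % 360.0 - 180.0)
        seq = list(chi3_sampler)
        return float(seq[i % len(seq)])

    protomer = make_protomer(n_res, cys_at, seed=seed)
    paths = []
    truth = []
    for i in range(n_structures):
        chi3 = draw(i)
        dimer = make_disulfide_dimer(protomer, chi3, seed=seed + i + 1)
        p = out_dir / f"synthetic_{i:03d}.pdb"
        write_pdb(dimer, p)
        paths.append(p)
        truth.append({"file": p.name, "chi3": chi3, "cys_at": cys_at})
    sidecar = out_dir / "truth.json"
    sidecar.write_text(json.dumps({
        "generator": "make_library_corpus",
        "n_structures": n_structures, "seed": seed, "n_res": n_res,
        "cys_at": cys_at, "structures": truth,
    }, indent=1))
    return paths, sidecar


# ---------------------------------------------------------------- curves

def make_hemolysis_curves(
    hc50: float = REFERENCE_PARAMS["hc50_dimer_nM"],
    vmax: float = REFERENCE_PARAMS["vmax_dimer_per_min"],
    c0: float = 150.0,
    concentrations=None,
    hill_slope: float = 1.5,
    a0: float = 1.0, a_tx100: float = 0.1,
    t_end: float = 15.0, n_times: int = 61,
    noise_sd: float = 0.02, seed: int = 0,
) -> tuple[list[KineticCurve], dict]:
    """Turbidity time courses + endpoint dose-response with known truth.

    Each curve is a logistic plateau-to-floor decay whose steepness follows
    the saturating rate law vmax*(1-exp(-c/c0)) and whose lag shortens
    monotonically with concentration; the endpoint hemolysis follows a
    Hill sigmoid in concentration. Truth carries the closed-form half-time
    of every noiseless curve.
    """
    if concentrations is None:
        concentrations = np.geomspace(hc50 / 4, hc50 * 16, 8)
    concentrations = np.asarray(concentrations, float)
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_end, n_times)
    curves = []
    truth_rows = []
    for c in concentrations:
        rate = vmax * (1.0 - np.exp(-c / c0))
        frac = (c ** hill_slope) / (hc50 ** hill_slope + c ** hill_slope)
        end = a0 - frac * (a0 - a_tx100)
        lag = 1.0 + 4.0 * hc50 / (hc50 + c)  # monotone decreasing in c
        tau = 1.0 / max(4.0 * rate, 1e-9)
        mid = lag + 2.0 * tau
        clean = end + (a0 - end) / (1.0 + np.exp((times - mid) / tau))
        # closed-form first crossing of a0/2 for the noiseless curve
        if end < a0 / 2.0 < clean[0]:
            t_half = mid + tau * np.log((a0 - end) / (a0 / 2.0 - end) - 1.0)
        else:
            t_half = None
        noisy = clean * (1.0 + noise_sd * rng.standard_normal(times.shape))
        curves.append(KineticCurve(times, noisy, concentration=float(c)))
        truth_rows.append({"concentration_nM": float(c), "rate_per_min": float(rate),
                           "t_half_min": t_half,
                           "hemolysis_pct": float(frac * 100.0)})
    truth = {
        "generator": "make_hemolysis_curves", "seed": seed, "noise_sd": noise_sd,
        "hc50_nM": hc50, "vmax_per_min": vmax, "c0_nM": c0,
        "hill_slope": hill_slope, "a0": a0, "a_tx100": a_tx100,
        "curves": truth_rows,
    }
    return curves, truth


def make_dose_response(
    hc50: float = REFERENCE_PARAMS["hc50_dimer_nM"],
    hill_slope: float = 1.5, plateau: float = 100.0,
    concentrations=None, noise_sd: float = 0.03, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Hill-sigmoid endpoint hemolysis with multiplicative noise."""
    if concentrations is None:
        concentrations = np.geomspace(20.0, 1000.0, 10)
    c = np.asarray(concentrations, float)
    rng = np.random.default_rng(seed)
    clean = plateau * c ** hill_slope / (hc50 ** hill_slope + c ** hill_slope)
    noisy = clean * (1.0 + noise_sd * rng.standard_normal(c.shape))
    truth = {"generator": "make_dose_response", "seed": seed, "noise_sd": noise_sd,
             "hc50_nM": hc50, "hill_slope": hill_slope, "plateau": plateau}
    return c, noisy, truth


def make_melting_curve(
    tm: float = REFERENCE_PARAMS["tm_cd_dimer_C"],
    cooperativity: float = 2.0,
    baselines: tuple[float, float] = (-20.0, -2.0),
    grid=None, noise_sd: float = 0.02, seed: int = 0,
    signal_type: str = "CD",
) -> tuple[MeltingCurve, dict]:
    """Two-state Boltzmann melt on [20, 90] degC with flat baselines.

    ``cooperativity`` is the transition width parameter (degC): the
    unfolded fraction is 1 / (1 + exp((tm - T)/width)).
    """
    if grid is None:
        grid = np.arange(20.0, 90.5, 1.0)
    t = np.asarray(grid, float)
    if t.min() < 20.0 - 1e-9 or t.max() > 90.0 + 1e-9:
        raise ValueError("temperature grid must lie within [20, 90] degC")
    rng = np.random.default_rng(seed)
    frac_unfolded = 1.0 / (1.0 + np.exp((tm - t) / cooperativity))
    folded_s, unfolded_s = baselines
    clean = folded_s + (unfolded_s - folded_s) * frac_unfolded
    span = abs(unfolded_s - folded_s)
    noisy = clean + noise_sd * span * rng.standard_normal(t.shape)
    curve = MeltingCurve(t, noisy, signal_type=signal_type,
                         s20=float(clean[0]), s90=float(clean[-1]))
    truth = {"generator": "make_melting_curve", "seed": seed, "noise_sd": noise_sd,
             "tm_C": tm, "cooperativity_C": cooperativity,
             "baselines": list(baselines), "signal_type": signal_type}
    return curve, truth


def make_quench_series(
    ksv: float = REFERENCE_PARAMS["ksv_monomer_per_M"],
    concentrations=None, noise_sd: float = 0.02, seed: int = 0,
) -> tuple[QuenchSeries, dict]:
    """Linear Stern-Volmer series F0/F = 1 + ksv * [Q], noisy except [Q]=0."""
    if concentrations is None:
        concentrations = np.linspace(0.0, 0.3, 7)
    q = np.asarray(concentrations, float)
    rng = np.random.default_rng(seed)
    clean = 1.0 + ksv * q
    noise = 1.0 + noise_sd * rng.standard_normal(q.shape)
    noise[q == 0] = 1.0  # the unquenched reference defines F0
    series = QuenchSeries(q, clean * noise)
    truth = {"generator": "make_quench_series", "seed": seed,
             "noise_sd": noise_sd, "ksv_per_M": ksv}
    return series, truth


def make_absorbance_set(
    epsilon: float = REFERENCE_PARAMS["epsilon_corrected"],
    concentrations=None, scatter_amp: float = 0.22,
    noise_sd: float = 0.02, seed: int = 0,
) -> tuple[list[AbsorbancePair], dict]:
    """A280/A350 ladders: true absorption eps*c plus a scattering tail.

    The scattering contribution scatter_amp*c appears identically at 280
    and 350 nm, so the corrected fit recovers eps while the uncorrected
    one overestimates it by scatter_amp.
    """
    if concentrations is None:
        concentrations = np.linspace(0.1, 1.0, 10)
    c = np.asarray(concentrations, float)
    rng = np.random.default_rng(seed)
    scatter = scatter_amp * c
    a280 = (epsilon * c + scatter) * (1.0 + noise_sd * rng.standard_normal(c.shape))
    a350 = scatter * (1.0 + noise_sd * rng.standard_normal(c.shape))
    pairs = [AbsorbancePair(float(a), float(max(s, 0.0)), float(cc))
             for a, s, cc in zip(a280, a350, c)]
    truth = {"generator": "make_absorbance_set", "seed": seed, "noise_sd": noise_sd,
             "epsilon": epsilon, "scatter_amp": scatter_amp}
    return pairs, truth


def make_maldi_peaks(
    mw: float = REFERENCE_PARAMS["dimer_maldi_mass_Da"],
    charges=(1, 2, 3, 4), mz_jitter: float = 0.0, seed: int = 0,
    proton_mass: float = PROTON_MASS_DEFAULT,
) -> tuple[MassPeakSet, dict]:
    """[M + zH]^z+ peak list for a single neutral mass, optional m/z jitter."""
    rng = np.random.default_rng(seed)
    peaks = []
    for z in charges:
        mz = (mw + z * proton_mass) / z + mz_jitter * rng.standard_normal()
        peaks.append((float(mz), int(z)))
    truth = {"generator": "make_maldi_peaks", "seed": seed,
             "mw_Da": mw, "charges": list(charges), "mz_jitter": mz_jitter,
             "proton_mass": proton_mass}
    return MassPeakSet(peaks, proton_mass), truth


def make_sec_standards(
    a: float = 7.5, b: float = -0.2, volumes=None,
) -> tuple[SECCalibration, dict]:
    """Calibration standards lying exactly on log10(MW) = a + b * Ve."""
    if volumes is None:
        volumes = np.linspace(8.0, 20.0, 6)
    ve = np.asarray(volumes, float)
    standards = [(float(v), float(10.0 ** (a + b * v))) for v in ve]
    truth = {"generator": "make_sec_standards", "a": a, "b": b,
             "volumes": list(map(float, ve))}
    return SECCalibration(standards), truth


def make_emission_pair(
    trp_center: float = 339.0, trp_width: float = 28.0, trp_amp: float = 2.0,
    tyr_center: float = 319.0, tyr_width: float = 16.0, tyr_amp: float = 1.0,
    grid=None,
) -> tuple:
    """A 275 nm-excited total spectrum (Trp + Tyr) and its pure-Trp part.

    The Tyr Gaussian is truncated to zero beyond 360 nm so the 380 nm
    anchor sees only Trp, making the decomposition exactly recoverable.
    """
    from .biophysics import EmissionSpectrum

    if grid is None:
        grid = np.arange(300.0, 420.0, 1.0)
    wl = np.asarray(grid, float)
    trp = np.exp(-0.5 * ((wl - trp_center) / trp_width) ** 2)
    tyr = tyr_amp * np.exp(-0.5 * ((wl - tyr_center) / tyr_width) ** 2)
    tyr[wl > 360.0] = 0.0
    total = trp_amp * trp + tyr
    truth = {"generator": "make_emission_pair", "scale": trp_amp,
             "tyr_truth": tyr}
    return (EmissionSpectrum(wl, total, 275.0),
            EmissionSpectrum(wl, trp, 295.0), truth)
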