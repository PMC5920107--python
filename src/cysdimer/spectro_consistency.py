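"""Disulfide chi3 chirality and near-UV CD consistency scoring.

A cystine's chi3 torsion makes the S-S chromophore inherently dissymmetric:
0 < chi3 < 180 deg is the right-handed P screw sense, -180 < chi3 < 0 the
left-handed M sense, and the cis/trans boundaries (0, +-180 deg) are not
dissymmetric at all. Empirical rules relate the sign and position of the
near-UV CD difference band (dimer minus monomer) to candidate chi3 values;
because both an na-sigma* and an nb-sigma* band of either sign can occur
for a given handedness, the rule's candidate angles are taken as input
here (default {85, -95} deg) and never derived from the band sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_CANDIDATES = (85.0, -95.0)
DEFAULT_TOLERANCE = 10.0
DEFAULT_WINDOW = (270.0, 300.0)


@dataclass
class ChiralityCall:
    chi3: float
    chirality: str  # "P" | "M" | "achiral-boundary"
    note: str = ""


@dataclass
class NearUVDifference:
    wavelengths: np.ndarray
    delta_ellipticity: np.ndarray
    band_sign: int
    band_lambda_max: float


@dataclass
class ConsistencyVerdict:
    chi3: float
    candidates: tuple[float, ...]
    tolerance: float
    consistent: bool
    matched_candidate: float | None
    distances: dict[float, float]


def chirality(chi3: float) -> ChiralityCall:
    """P/M handedness of a disulfide torsion; boundaries flagged achiral."""
    if not (-180.0 < chi3 <= 180.0):
        raise ValueError(f"chi3 {chi3} outside (-180, 180]")
    if chi3 == 0.0:
        return ChiralityCall(chi3, "achiral-boundary", "cis conformer (chi3 = 0)")
    if chi3 == 180.0:
        return ChiralityCall(chi3, "achiral-boundary", "trans conformer (chi3 = 180)")
    if chi3 > 0:
        return ChiralityCall(chi3, "P", "right-handed screw; na-sigma*/nb-sigma* bands possible")
    return ChiralityCall(chi3, "M", "left-handed screw; na-sigma*/nb-sigma* bands possible")


def near_uv_difference(
    dimer_spectrum: tuple[np.ndarray, np.ndarray],
    monomer_spectrum: tuple[np.ndarray, np.ndarray],
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> NearUVDifference:
    """Pointwise dimer-minus-monomer CD difference and its in-window band.

    band_sign is the sign of the difference at the in-window extremum of
    |delta|; antisymmetric under swapping the two inputs.
    """
    wl_d, y_d = (np.asarray(v, float) for v in dimer_spectrum)
    wl_m, y_m = (np.asarray(v, float) for v in monomer_spectrum)
    if wl_d.shape != wl_m.shape or not np.allclose(wl_d, wl_m):
        raise ValueError("dimer and monomer spectra are on different wavelength grids")
    delta = y_d - y_m
    lo, hi = window
    mask = (wl_d >= lo) & (wl_d <= hi)
    if not mask.any():
        raise ValueError(f"wavelength grid does not cover the window {window}")
    sub = delta[mask]
    idx = int(np.argmax(np.abs(sub)))
    peak = sub[idx]
    sign = 0 if peak == 0 else (1 if peak > 0 else -1)
    return NearUVDifference(wl_d, delta, sign, float(wl_d[mask][idx]))


def circular_distance(a: float, b: float) -> float:
    """Distance on the torsion circle: min(|a-b|, 360-|a-b|)."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def consistency_check(
    chi3_model: float,
    candidates: tuple[float, ...] = DEFAULT_CANDIDATES,
    tolerance: float = DEFAULT_TOLERANCE,
) -> ConsistencyVerdict:
    """Is a model's chi3 within tolerance of any spectroscopic candidate?

    Distances are circular, so 179 vs -179 deg counts as 2 deg apart.
    """
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    dists = {float(c): circular_distance(chi3_model, c) for c in candidates}
    best = min(dists, key=dists.get)
    ok = dists[best] <= tolerance
    return ConsistencyVerdict(
        chi3=chi3_model, candidates=tuple(float(c) for c in candidates),
        tolerance=tolerance, consistent=ok,
        matched_candidate=best if ok else None, distances=dists,
    )
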