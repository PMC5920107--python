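"""Analysis formulas for the solution measurements around the dimer model.

Covers: scattering-corrected absorbance and extinction-coefficient fitting;
hemolysis percentage, lysis half-times, the saturating rate-vs-concentration
law and its Vmax; Hill dose-response fitting (HC50); mean residue
ellipticity; two-state thermal-denaturation normalization and Tm from the
derivative maximum; Stern-Volmer quenching; Trp/Tyr emission decomposition;
MALDI charge-state consensus mass; and SEC molecular-weight calibration.

All fitters are deterministic: linear fits are closed form, nonlinear fits
use least squares from data-driven starts (10 jittered restarts with a
fixed seed when the first fit is poor).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter
from scipy.stats import linregress

log = logging.getLogger(__name__)

PROTON_MASS_DEFAULT = 1.007276  # Da
_N_RESTARTS = 10
_RESTART_SEED = 20180426


@dataclass
class FitResult:
    """A fitted scalar of interest plus the full parameter set."""

    value: float
    stderr: float
    params: dict[str, float]
    param_errors: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


# ------------------------------------------------------------- absorbance

@dataclass
class AbsorbancePair:
    a280: float
    a350: float
    concentration: float | None = None  # mg/mL

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a280) and np.isfinite(self.a350)):
            raise ValueError("absorbances must be finite")
        if self.a350 < 0:
            raise ValueError("scattering reading A350 cannot be negative")


def corrected_absorbance(pair: AbsorbancePair) -> float:
    """Scattering-corrected A280: Acorr = A280 - A350."""
    return pair.a280 - pair.a350


def extinction_fit(pairs: list[AbsorbancePair], corrected: bool = True) -> FitResult:
    """Extinction coefficient (mL mg^-1 cm^-1) from A vs concentration.

    Least-squares line with a free intercept (reported); the slope is the
    extinction coefficient. ``corrected=True`` subtracts the A350
    scattering tail from each reading first.
    """
    pts = [(p.concentration, corrected_absorbance(p) if corrected else p.a280)
           for p in pairs if p.concentration is not None]
    if len(pts) < 3:
        raise ValueError("need at least 3 points with concentrations")
    c = np.array([p[0] for p in pts])
    a = np.array([p[1] for p in pts])
    if np.unique(c).size < 2:
        raise ValueError("singular design: concentrations are not distinct")
    fit = linregress(c, a)
    return FitResult(
        value=float(fit.slope), stderr=float(fit.stderr),
        params={"slope": float(fit.slope), "intercept": float(fit.intercept)},
        param_errors={"slope": float(fit.stderr),
                      "intercept": float(fit.intercept_stderr)},
        diagnostics={"r_squared": float(fit.rvalue ** 2), "corrected": corrected},
    )


# -------------------------------------------------------------- hemolysis

@dataclass
class HemolysisAssay:
    a0: float
    a_end: float
    a_tx100: float

    def __post_init__(self) -> None:
        if not self.a0 > self.a_tx100:
            raise ValueError(
                "invalid assay: initial turbidity must exceed the fully-lysed reference"
            )


def hemolysis_percent(assay: HemolysisAssay) -> float:
    """Hemolysis (%) = (A0 - Aend) / (A0 - ATX100) * 100.

    Not clamped; values above 100% are flagged as a warning (they indicate
    turbidity below the fully-lysed reference).
    """
    denom = assay.a0 - assay.a_tx100
    pct = (assay.a0 - assay.a_end) / denom * 100.0
    if pct > 100.0:
        log.warning("hemolysis %.1f%% exceeds 100%% (turbidity below TX-100 reference)", pct)
    return pct


@dataclass
class KineticCurve:
    times: np.ndarray       # min
    turbidity: np.ndarray   # OD units
    concentration: float = np.nan  # nM

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.turbidity = np.asarray(self.turbidity, float)
        if self.times.shape != self.turbidity.shape or self.times.size < 4:
            raise ValueError("need matching time/turbidity arrays of >= 4 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def half_time(curve: KineticCurve) -> float | None:
    """First time the turbidity crosses below half its initial value.

    Linear interpolation between the bracketing points; None when the
    half level is never crossed. First-crossing semantics make the result
    robust to non-monotone noise after lysis.
    """
    y = curve.turbidity
    t = curve.times
    half = y[0] / 2.0
    below = np.where(y < half)[0]
    if below.size == 0:
        return None
    j = below[0]
    if j == 0:
        return float(t[0])
    t0, t1 = t[j - 1], t[j]
    y0, y1 = y[j - 1], y[j]
    return float(t0 + (half - y0) * (t1 - t0) / (y1 - y0))


def _fit_with_restarts(model, x, y, p0, bounds) -> tuple[np.ndarray, np.ndarray]:
    """curve_fit with a handful of seeded jittered restarts; best SSR wins."""
    rng = np.random.default_rng(_RESTART_SEED)
    best = None
    starts = [np.asarray(p0, float)]
    starts += [np.asarray(p0, float) * rng.uniform(0.5, 2.0, len(p0))
               for _ in range(_N_RESTARTS)]
    last_err = None
    for start in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(model, x, y, p0=start, bounds=bounds,
                                       maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        ssr = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise RuntimeError(f"nonlinear fit failed to converge: {last_err}")
    return best[1], best[2]


def rate_saturation_fit(concentrations, rates) -> FitResult:
    """Fit rate(c) = Vmax * (1 - exp(-c / c0)); value is Vmax (min^-1).

    The hemolysis rate (reciprocal half-time) rises with toxin
    concentration and saturates at the maximal lytic velocity Vmax.
    """
    c = np.asarray(concentrations, float)
    r = np.asarray(rates, float)
    if c.size < 4:
        raise ValueError("need at least 4 concentrations")

    def model(x, vmax, c0):
        return vmax * (1.0 - np.exp(-x / c0))

    p0 = [float(r.max()), float(np.median(c))]
    popt, pcov = _fit_with_restarts(model, c, r, p0,
                                    bounds=([0, 1e-12], [np.inf, np.inf]))
    perr = np.sqrt(np.diag(pcov))
    return FitResult(
        value=float(popt[0]), stderr=float(perr[0]),
        params={"vmax": float(popt[0]), "c0": float(popt[1])},
        param_errors={"vmax": float(perr[0]), "c0": float(perr[1])},
    )


@dataclass
class DoseResponse:
    concentrations: np.ndarray   # nM, > 0
    hemolysis_percent: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, float)
        self.hemolysis_percent = np.asarray(self.hemolysis_percent, float)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if not np.all(np.isfinite(self.hemolysis_percent)):
            raise ValueError("hemolysis percentages must be finite")


def hill_fit(dose: DoseResponse) -> FitResult:
    """Hill sigmoid fit; the k parameter is the HC50 (nM).

    y(c) = plateau * c^h / (k^h + c^h). Initialization: k at the
    concentration nearest 50% response, slope 1, plateau at the maximum.
    """
    c = dose.concentrations
    y = dose.hemolysis_percent
    if c.size < 5:
        raise ValueError("need at least 5 doses spanning the transition")
    if y.max() < 40.0 or y.min() > 60.0:
        raise ValueError("no transition through 50% in the dose range")

    def model(x, k, h, plateau):
        return plateau * x ** h / (k ** h + x ** h)

    k0 = float(c[np.argmin(np.abs(y - 50.0))])
    p0 = [k0, 1.0, float(y.max())]
    popt, pcov = _fit_with_restarts(model, c, y, p0,
                                    bounds=([1e-12, 0.05, 1.0], [np.inf, 50.0, 200.0]))
    perr = np.sqrt(np.diag(pcov))
    return FitResult(
        value=float(popt[0]), stderr=float(perr[0]),
        params={"hc50": float(popt[0]), "slope": float(popt[1]),
                "plateau": float(popt[2])},
        param_errors={"hc50": float(perr[0]), "slope": float(perr[1]),
                      "plateau": float(perr[2])},
    )


# ------------------------------------------------------------------- CD

@dataclass
class CDSpectrum:
    wavelengths: np.ndarray
    ellipticity: np.ndarray  # measured theta, degrees
    concentration: float     # mM
    n_residues: int
    path_length: float       # cm

    def __post_init__(self) -> None:
        if self.concentration <= 0 or self.path_length <= 0 or self.n_residues < 1:
            raise ValueError("concentration, path length and residue count must be positive")


def mean_residue_ellipticity(spectrum: CDSpectrum) -> np.ndarray:
    """[theta]_lambda = 100 * theta / (c * n * L), deg cm^2 / dmol."""
    denom = spectrum.concentration * spectrum.n_residues * spectrum.path_length
    return 100.0 * np.asarray(spectrum.ellipticity, float) / denom


# -------------------------------------------------------------- melting

@dataclass
class MeltingCurve:
    temperatures: np.ndarray  # deg C
    signal: np.ndarray        # ellipticity at 220 nm or fluorescence at 334 nm
    signal_type: str = "CD"   # "CD" | "fluorescence"
    s20: float | None = None  # folded endpoint reference
    s90: float | None = None  # unfolded endpoint reference

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, float)
        self.signal = np.asarray(self.signal, float)
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be increasing")
        if self.s20 is None:
            self.s20 = float(self.signal[0])
        if self.s90 is None:
            self.s90 = float(self.signal[-1])


def denaturation_percent(curve: MeltingCurve) -> np.ndarray:
    """%denaturation = (S20 - S(T)) / (S20 - S90) * 100 for either signal.

    0% at the folded endpoint, 100% at the unfolded endpoint by
    construction.
    """
    if curve.s20 == curve.s90:
        raise ValueError("endpoint signals are equal; normalization undefined")
    return (curve.s20 - curve.signal) / (curve.s20 - curve.s90) * 100.0


def melting_temperature(curve: MeltingCurve, smoothing: int = 9) -> FitResult:
    """Tm as the maximum of d(%denaturation)/dT.

    The derivative is estimated with a Savitzky-Golay first-derivative
    filter (window ``smoothing`` grid points, cubic), whose window should
    be comparable to the transition width; the maximum is refined by
    quadratic interpolation around the discrete peak. The 50% crossing of
    the smoothed curve is reported as a cross-check; a discrepancy above
    2 degC logs a warning.
    """
    t = curve.temperatures
    if t.size < 8:
        raise ValueError("need at least 8 temperatures spanning the transition")
    pct = denaturation_percent(curve)
    if pct.max() < 50.0:
        raise ValueError("no transition detected (denaturation never reaches 50%)")
    win = max(5, smoothing if smoothing % 2 == 1 else smoothing + 1)
    win = min(win, t.size if t.size % 2 == 1 else t.size - 1)
    step = float(np.mean(np.diff(t)))
    deriv = savgol_filter(pct, win, 3, deriv=1, delta=step)
    pct_s = savgol_filter(pct, win, 3)
    j = int(np.argmax(deriv))
    tm = float(t[j])
    if 0 < j < len(deriv) - 1:  # quadratic refinement between grid points
        y0, y1, y2 = deriv[j - 1], deriv[j], deriv[j + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            shift = float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))
            tm = float(t[j] + shift * step)
    # 50% crossing cross-check
    above = np.where(pct_s >= 50.0)[0]
    t50 = np.nan
    if above.size and above[0] > 0:
        k = above[0]
        t50 = float(np.interp(50.0, [pct_s[k - 1], pct_s[k]], [t[k - 1], t[k]]))
    if np.isfinite(t50) and abs(t50 - tm) > 2.0:
        log.warning("Tm cross-check: derivative max %.1f vs 50%% crossing %.1f degC", tm, t50)
    return FitResult(value=tm, stderr=step / 2.0,
                     params={"tm": tm, "t50": t50},
                     diagnostics={"signal_type": curve.signal_type, "window": win})


# ------------------------------------------------------------- quenching

@dataclass
class QuenchSeries:
    quencher_conc: np.ndarray  # M
    f0_over_f: np.ndarray

    def __post_init__(self) -> None:
        self.quencher_conc = np.asarray(self.quencher_conc, float)
        self.f0_over_f = np.asarray(self.f0_over_f, float)
        if self.quencher_conc.size < 3 or 0.0 not in self.quencher_conc:
            raise ValueError("need >= 3 quencher concentrations including 0")
        if np.any(self.f0_over_f < 1.0 - 1e-9):
            log.warning("F0/F below 1 observed; check the series")


def stern_volmer_fit(series: QuenchSeries) -> FitResult:
    """K_SV (M^-1) from F0/F = 1 + K_SV [Q] with the intercept fixed at 1.

    The free-intercept line is reported as a diagnostic; a large deviation
    of its intercept from 1 signals static quenching or curvature.
    """
    q = series.quencher_conc
    y = series.f0_over_f - 1.0
    denom = float(q @ q)
    if denom == 0:
        raise ValueError("singular design: all quencher concentrations are zero")
    ksv = float(q @ y) / denom
    resid = y - ksv * q
    dof = max(q.size - 1, 1)
    stderr = float(np.sqrt(resid @ resid / dof / denom))
    diag = {}
    if np.unique(q).size >= 3:
        free = linregress(q, series.f0_over_f)
        diag = {"free_slope": float(free.slope), "free_intercept": float(free.intercept)}
    return FitResult(value=ksv, stderr=stderr, params={"ksv": ksv},
                     param_errors={"ksv": stderr}, diagnostics=diag)


# ----------------------------------------------------------------- MALDI

@dataclass
class MassPeakSet:
    peaks: list[tuple[float, int]]  # (m/z, charge)
    proton_mass: float = PROTON_MASS_DEFAULT

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("need at least one peak")
        for mz, z in self.peaks:
            if mz <= 0:
                raise ValueError("m/z must be positive")
            if int(z) != z or z < 1:
                raise ValueError("charge must be a positive integer")


def maldi_consensus_mw(peaks: MassPeakSet) -> tuple[float, float, list[float]]:
    """Consensus neutral mass from multiply charged [M + zH]^z+ ions.

    Each peak deconvolves to M = z * (m/z) - z * m_proton; the consensus
    is the arithmetic mean over peaks and the spread the sample sd.
    """
    masses = [z * mz - z * peaks.proton_mass for mz, z in peaks.peaks]
    mean = float(np.mean(masses))
    sd = float(np.std(masses, ddof=1)) if len(masses) > 1 else 0.0
    return mean, sd, masses


def dimer_theoretical_mass(monomer_mass: float, convention: str = "paper") -> float:
    """Covalent-dimer mass bookkeeping.

    ``paper`` convention: exactly 2 x monomer. ``chemical``: 2 x monomer
    minus two hydrogens lost on disulfide formation (2 x 1.008 Da).
    """
    if convention == "paper":
        return 2.0 * monomer_mass
    if convention == "chemical":
        return 2.0 * monomer_mass - 2.016
    raise ValueError(f"unknown convention {convention!r}")


# ------------------------------------------------------------------- SEC

@dataclass
class SECCalibration:
    standards: list[tuple[float, float]]  # (elution volume mL, MW Da)
    slope: float = field(init=False)
    intercept: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.standards) < 2:
            raise ValueError("need at least 2 calibration standards")
        ve = np.array([s[0] for s in self.standards], float)
        mw = np.array([s[1] for s in self.standards], float)
        if np.any(ve <= 0) or np.any(mw <= 0):
            raise ValueError("volumes and masses must be positive")
        fit = np.polyfit(ve, np.log10(mw), 1)
        self.slope, self.intercept = float(fit[0]), float(fit[1])

    @property
    def volume_range(self) -> tuple[float, float]:
        ve = [s[0] for s in self.standards]
        return min(ve), max(ve)


def sec_mw_estimate(calibration: SECCalibration, elution_volume: float) -> float:
    """MW (Da) = 10^(a + b * Ve) from the log-linear calibration."""
    lo, hi = calibration.volume_range
    if not lo <= elution_volume <= hi:
        log.warning("elution volume %.2f mL outside calibrated range [%.2f, %.2f]: "
                    "extrapolating", elution_volume, lo, hi)
    return float(10.0 ** (calibration.intercept + calibration.slope * elution_volume))


# ------------------------------------------------- fluorescence spectra

@dataclass
class EmissionSpectrum:
    wavelengths: np.ndarray
    intensity: np.ndarray
    excitation: float  # nm (275 = Trp + Tyr; 295 = Trp only)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.intensity = np.asarray(self.intensity, float)
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


def trp_tyr_decomposition(
    total_275: EmissionSpectrum, trp_295: EmissionSpectrum, anchor: float = 380.0,
) -> dict:
    """Split a 275 nm-excited spectrum into Trp and Tyr components.

    Beyond ~380 nm Tyr no longer emits, so the 295 nm-excited (pure Trp)
    spectrum can be scaled to match the total there: scale =
    total(anchor)/trp(anchor); Trp_norm = scale * trp; Tyr = total -
    Trp_norm (reported raw and clipped at zero), with trapezoid areas.
    """
    if (total_275.wavelengths.shape != trp_295.wavelengths.shape
            or not np.allclose(total_275.wavelengths, trp_295.wavelengths)):
        raise ValueError("spectra are on different wavelength grids")
    wl = total_275.wavelengths
    if not wl[0] <= anchor <= wl[-1]:
        raise ValueError(f"grid does not cover the anchor {anchor} nm")
    trp_at = float(np.interp(anchor, wl, trp_295.intensity))
    if trp_at <= 0:
        raise ValueError("Trp spectrum vanishes at the anchor wavelength")
    total_at = float(np.interp(anchor, wl, total_275.intensity))
    scale = total_at / trp_at
    trp_norm = scale * trp_295.intensity
    tyr_raw = total_275.intensity - trp_norm
    tyr = np.clip(tyr_raw, 0.0, None)
    return {
        "scale": scale,
        "trp": trp_norm,
        "tyr": tyr,
        "tyr_raw": tyr_raw,
        "area_trp": float(np.trapezoid(trp_norm, wl)),
        "area_tyr": float(np.trapezoid(tyr, wl)),
        "area_total": float(np.trapezoid(total_275.intensity, wl)),
    }
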