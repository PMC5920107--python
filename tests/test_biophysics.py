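"""Measurement-analysis formulas: arithmetic contracts and exact recovery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cysdimer.biophysics as bp
import cysdimer.synthetic_data as syn


# ----------------------------------------------------------- absorbance

@pytest.mark.parametrize("a280, a350, expected", [
    (0.5, 0.0, 0.5), (0.5, 0.1, 0.4), (0.3, 0.3, 0.0),
])
def test_corrected_absorbance(a280, a350, expected):
    assert bp.corrected_absorbance(bp.AbsorbancePair(a280, a350)) == pytest.approx(expected)


def test_extinction_exact_on_noiseless_data():
    pairs, _ = syn.make_absorbance_set(epsilon=1.78, scatter_amp=0.22, noise_sd=0.0)
    fit = bp.extinction_fit(pairs, corrected=True)
    assert fit.value == pytest.approx(1.78, abs=1e-9)
    # the uncorrected fit absorbs the scattering tail into the slope
    raw = bp.extinction_fit(pairs, corrected=False)
    assert raw.value == pytest.approx(2.00, abs=1e-9)


def test_extinction_requires_enough_distinct_points():
    pairs = [bp.AbsorbancePair(0.1, 0.0, 0.1)] * 3
    with pytest.raises(ValueError):
        bp.extinction_fit(pairs)


# ------------------------------------------------------------ hemolysis

@pytest.mark.parametrize("a_end, expected", [(1.0, 0.0), (0.1, 100.0), (0.55, 50.0)])
def test_hemolysis_percent_arithmetic(a_end, expected):
    pct = bp.hemolysis_percent(bp.HemolysisAssay(1.0, a_end, 0.1))
    assert pct == pytest.approx(expected)


@given(st.floats(-5, 5))
def test_hemolysis_affine_invariance(shift):
    base = bp.hemolysis_percent(bp.HemolysisAssay(1.0, 0.7, 0.1))
    shifted = bp.hemolysis_percent(
        bp.HemolysisAssay(1.0 + shift, 0.7 + shift, 0.1 + shift))
    assert shifted == pytest.approx(base, rel=1e-9)


def test_hemolysis_invalid_assay():
    with pytest.raises(ValueError):
        bp.HemolysisAssay(0.1, 0.1, 0.5)


def test_half_time_linear_decay_and_never_crossing():
    t = np.linspace(0, 10, 11)
    curve = bp.KineticCurve(t, 1.0 - 0.1 * t)
    assert bp.half_time(curve) == pytest.approx(5.0)
    flat = bp.KineticCurve(t, np.full_like(t, 1.0))
    assert bp.half_time(flat) is None


@given(st.floats(0.1, 100))
def test_half_time_scale_invariance(scale):
    t = np.linspace(0, 10, 21)
    y = 1.0 / (1.0 + np.exp((t - 3.7) * 2))
    ref = bp.half_time(bp.KineticCurve(t, y))
    assert bp.half_time(bp.KineticCurve(t, scale * y)) == pytest.approx(ref, rel=1e-9)


def test_half_time_matches_generator_closed_form():
    curves, truth = syn.make_hemolysis_curves(
        hc50=62.4, vmax=0.69, concentrations=np.array([250.0, 500.0, 1000.0, 2000.0]),
        noise_sd=0.0, seed=0)
    step = curves[0].times[1] - curves[0].times[0]
    for cv, row in zip(curves, truth["curves"]):
        measured = bp.half_time(cv)
        if row["t_half_min"] is None:
            assert measured is None
        else:
            assert measured == pytest.approx(row["t_half_min"], abs=step / 2)


# ----------------------------------------------------------------- fits

def test_rate_saturation_exact_recovery():
    c = np.linspace(50, 3000, 8)
    r = 1.05 * (1 - np.exp(-c / 400.0))
    fit = bp.rate_saturation_fit(c, r)
    assert fit.value == pytest.approx(1.05, rel=1e-6)
    assert fit.params["c0"] == pytest.approx(400.0, rel=1e-6)


def test_hill_exact_recovery_and_no_transition_error():
    c, y, _ = syn.make_dose_response(hc50=62.4, noise_sd=0.0)
    fit = bp.hill_fit(bp.DoseResponse(c, y))
    assert fit.value == pytest.approx(62.4, rel=1e-6)
    with pytest.raises(ValueError):
        bp.hill_fit(bp.DoseResponse(np.array([1, 2, 3, 4, 5.0]),
                                    np.array([1, 2, 3, 2, 3.0])))


# ------------------------------------------------------------------- CD

def test_mean_residue_ellipticity_scaling():
    spec = bp.CDSpectrum(np.array([220.0]), np.array([10.0]), 1.0, 10, 1.0)
    assert bp.mean_residue_ellipticity(spec)[0] == pytest.approx(100.0)
    spec0 = bp.CDSpectrum(np.array([220.0]), np.array([0.0]), 1.0, 10, 1.0)
    assert bp.mean_residue_ellipticity(spec0)[0] == 0.0
    double_l = bp.CDSpectrum(np.array([220.0]), np.array([10.0]), 1.0, 10, 2.0)
    assert bp.mean_residue_ellipticity(double_l)[0] == pytest.approx(50.0)


# -------------------------------------------------------------- melting

def test_denaturation_percent_endpoints_and_midpoint():
    t = np.linspace(20, 90, 8)
    s = np.linspace(-20, -2, 8)
    curve = bp.MeltingCurve(t, s)
    pct = bp.denaturation_percent(curve)
    assert pct[0] == pytest.approx(0.0) and pct[-1] == pytest.approx(100.0)
    mid = bp.MeltingCurve(np.array([20.0, 55.0, 90.0]), np.array([-20.0, -11.0, -2.0]))
    assert bp.denaturation_percent(mid)[1] == pytest.approx(50.0)
    with pytest.raises(ValueError):
        bp.denaturation_percent(bp.MeltingCurve(t, np.full(8, -5.0)))


def test_melting_temperature_noiseless_and_cross_check():
    curve, truth = syn.make_melting_curve(tm=60.0, noise_sd=0.0)
    fit = bp.melting_temperature(curve)
    assert fit.value == pytest.approx(60.0, abs=0.5)
    assert fit.params["t50"] == pytest.approx(60.0, abs=0.5)
    # flat signal against externally supplied endpoints: no transition
    with pytest.raises(ValueError):
        bp.melting_temperature(bp.MeltingCurve(
            np.linspace(20, 90, 30), np.full(30, -20.0) + np.linspace(0, 0.1, 30),
            s20=-20.0, s90=-2.0))


# ------------------------------------------------------------ quenching

@pytest.mark.parametrize("ksv", [4.56, 3.03])
def test_stern_volmer_exact_recovery(ksv):
    series, _ = syn.make_quench_series(ksv=ksv, noise_sd=0.0)
    fit = bp.stern_volmer_fit(series)
    assert fit.value == pytest.approx(ksv, rel=1e-9)
    assert fit.diagnostics["free_intercept"] == pytest.approx(1.0, abs=1e-9)


# ----------------------------------------------------------------- MALDI

def test_maldi_single_peak_and_zero_sd():
    mean, sd, masses = bp.maldi_consensus_mw(bp.MassPeakSet([(1000.0, 1)], 1.0))
    assert mean == pytest.approx(999.0) and sd == 0.0
    m = 12345.6
    peaks = bp.MassPeakSet([((m + 1.0) / 1, 1), ((m + 2.0) / 2, 2)], 1.0)
    mean, sd, _ = bp.maldi_consensus_mw(peaks)
    assert mean == pytest.approx(m, abs=1e-9) and sd == pytest.approx(0.0, abs=1e-9)


def test_maldi_matches_spreadsheet_oracle():
    """Independent recomputation of the deconvolution arithmetic."""
    rows = [(38595.144, 1), (19317.722, 2), (12876.662, 3), (9655.708, 4)]
    proton = 1.007276
    oracle = [z * mz - z * proton for mz, z in rows]
    mean, sd, masses = bp.maldi_consensus_mw(bp.MassPeakSet(rows, proton))
    assert masses == pytest.approx(oracle, abs=1e-9)
    assert mean == pytest.approx(float(np.mean(oracle)), abs=1e-9)
    assert sd == pytest.approx(float(np.std(oracle, ddof=1)), abs=1e-9)


def test_dimer_mass_conventions():
    assert bp.dimer_theoretical_mass(19272.96, "paper") == pytest.approx(38545.92)
    assert bp.dimer_theoretical_mass(19272.96, "chemical") == pytest.approx(38543.904)
    with pytest.raises(ValueError):
        bp.dimer_theoretical_mass(1.0, "other")


# ------------------------------------------------------------------- SEC

def test_sec_log_linear_midpoint_and_endpoints():
    cal = bp.SECCalibration([(10.0, 1e5), (20.0, 1e3)])
    assert bp.sec_mw_estimate(cal, 15.0) == pytest.approx(1e4, rel=1e-9)
    assert bp.sec_mw_estimate(cal, 10.0) == pytest.approx(1e5, rel=1e-9)
    assert bp.sec_mw_estimate(cal, 25.0) == pytest.approx(1e2, rel=1e-9)  # extrapolated
    with pytest.raises(ValueError):
        bp.SECCalibration([(10.0, 1e5)])


# ------------------------------------------- Trp/Tyr decomposition

def test_trp_tyr_decomposition_recovers_construction():
    total, trp, truth = syn.make_emission_pair(trp_amp=2.0)
    out = bp.trp_tyr_decomposition(total, trp)
    assert out["scale"] == pytest.approx(2.0, rel=1e-9)
    assert np.allclose(out["tyr"], truth["tyr_truth"], atol=1e-6)


def test_trp_tyr_total_equals_trp_gives_zero_tyr():
    _, trp, _ = syn.make_emission_pair()
    same = bp.EmissionSpectrum(trp.wavelengths, trp.intensity, 275.0)
    out = bp.trp_tyr_decomposition(same, trp)
    assert np.allclose(out["tyr"], 0.0, atol=1e-12)
    assert out["scale"] == pytest.approx(1.0)


def test_trp_tyr_anchor_sees_only_trp():
    # adding Tyr signal below the anchor leaves the normalization unchanged
    total, trp, _ = syn.make_emission_pair(tyr_amp=1.0)
    total_more, _, _ = syn.make_emission_pair(tyr_amp=3.0)
    s1 = bp.trp_tyr_decomposition(total, trp)["scale"]
    s2 = bp.trp_tyr_decomposition(total_more, trp)["scale"]
    assert s1 == pytest.approx(s2, rel=1e-9)
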