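import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from selenospec.chrom_io import IDAParameters, IsotopeChromatogram, default_windows
from selenospec.ida_quant import (
    RatioTrace,
    mass_bias_correct,
    mass_flow,
    quantify_chromatogram,
    ratio_trace,
)
from selenospec.peaks import integrate_windows
from selenospec.synthetic_data import (
    natural_mass_flow,
    simulate_chromatogram,
    spec_from_concentrations,
)


def closed_form_oracle(mf_sp, aw_nat, aw_sp, a_s74, a_s78, a_n74, a_n78, r_m):
    """Independent route: molar balance of the post-column mixing point."""
    n_spike = mf_sp / aw_sp
    n_sample = n_spike * (r_m * a_s74 - a_s78) / (a_n78 - r_m * a_n74)
    return n_sample * aw_nat


def make_trace(ratios):
    r = np.asarray(ratios, dtype=float)
    return RatioTrace(time_s=np.arange(len(r), dtype=float), ratio=r, valid=np.ones(len(r), bool))


def test_equal_channels_give_unit_ratio():
    t = np.arange(5) * 1.5
    chrom = IsotopeChromatogram(
        time_s=t, intensities={74: np.full(5, 100.0), 78: np.full(5, 100.0)}
    )
    trace = ratio_trace(chrom)
    np.testing.assert_allclose(trace.ratio, 1.0)


def test_smoothing_one_is_identity():
    rng = np.random.default_rng(0)
    t = np.arange(50) * 1.5
    i74 = 100 + rng.random(50)
    i78 = 10 + rng.random(50)
    chrom = IsotopeChromatogram(time_s=t, intensities={74: i74, 78: i78})
    raw = ratio_trace(chrom, smoothing_points=1)
    np.testing.assert_array_equal(raw.ratio, i78 / i74)


def test_all_points_below_threshold_fails():
    t = np.arange(5) * 1.5
    chrom = IsotopeChromatogram(
        time_s=t, intensities={74: np.full(5, 1.0), 78: np.full(5, 100.0)}
    )
    with pytest.raises(ValueError, match="no spike signal"):
        ratio_trace(chrom, count_threshold=10.0)


def test_baseline_ratio_equals_spike_ratio(ida):
    """Far from any peak only spike reaches the detector: R = a_sp78/a_sp74."""
    spec = spec_from_concentrations({"SELENOP": 59.2})
    chrom, _ = simulate_chromatogram(spec)
    trace = ratio_trace(chrom)
    blank = trace.time_min > 40
    np.testing.assert_allclose(trace.ratio[blank], ida.ratio_spike, atol=1e-6)


def test_mass_flow_zero_at_spike_ratio(ida):
    trace = make_trace([ida.ratio_spike] * 4)
    mf = mass_flow(trace, ida)
    np.testing.assert_array_equal(mf.mass_flow_ng_min, 0.0)


def test_natural_ratio_pole_is_masked_and_counted(ida):
    pole = 1.0 / ida.ratio_natural_inverse
    trace = make_trace([ida.ratio_spike, pole, 5.0])
    mf = mass_flow(trace, ida)
    assert mf.pole_points == 1
    assert not mf.valid[1]
    assert mf.valid[0] and mf.valid[2]


def test_matches_independent_closed_form_oracle():
    """100 random parameter draws agree with the molar-balance oracle to 1e-10."""
    rng = np.random.default_rng(20260930)
    for _ in range(100):
        a_s74 = rng.uniform(0.9, 0.9999)
        a_s78 = 1.0 - a_s74
        ida = IDAParameters(
            spike_concentration_ng_ml=rng.uniform(10, 1000),
            spike_flow_ml_min=rng.uniform(0.01, 1.0),
            spike_abundances={74: a_s74, 78: a_s78},
        )
        r_sp = ida.ratio_spike
        r_pole = 1.0 / ida.ratio_natural_inverse
        r_m = rng.uniform(r_sp * 1.01, r_pole * 0.99)
        mf = mass_flow(make_trace([r_m]), ida)
        expected = closed_form_oracle(
            ida.spike_mass_flow_ng_min,
            ida.atomic_weight_natural,
            ida.atomic_weight_spike,
            a_s74,
            a_s78,
            ida.natural_abundances[74],
            ida.natural_abundances[78],
            r_m,
        )
        assert mf.mass_flow_ng_min[0] == pytest.approx(expected, rel=1e-10)


def test_worked_point_against_oracle(ida):
    """R_m = 5 with the 99.9 % spike and 10 ng/min spike flow."""
    mf = mass_flow(make_trace([5.0]), ida)
    expected = closed_form_oracle(
        10.0, ida.atomic_weight_natural, ida.atomic_weight_spike,
        0.999, 0.001, ida.natural_abundances[74], ida.natural_abundances[78], 5.0,
    )
    assert mf.mass_flow_ng_min[0] == pytest.approx(expected, rel=1e-10)


def test_forward_inverse_consistency_pointwise(ida):
    """Simulator peak of 5.92 ng reappears in the mass-flow trace pointwise."""
    spec = spec_from_concentrations({"SELENOP": 59.2})
    chrom, _ = simulate_chromatogram(spec)
    mf = quantify_chromatogram(chrom, ida)
    truth = natural_mass_flow(spec, mf.time_min)
    sel = truth > truth.max() * 1e-3
    np.testing.assert_allclose(
        mf.mass_flow_ng_min[sel], truth[sel], rtol=1e-3
    )


def test_mass_bias_factor_zero_is_identity():
    trace = make_trace([0.5, 1.0, 2.0])
    out = mass_bias_correct(trace, 0.0)
    np.testing.assert_array_equal(out.ratio, trace.ratio)


def test_mass_bias_linear_action():
    trace = make_trace([0.5, 1.0, 2.0])
    factor = (1.0 / 0.99 - 1.0) / 4.0  # correction = x0.99
    out = mass_bias_correct(trace, factor)
    np.testing.assert_allclose(out.ratio, trace.ratio * 0.99)


def test_mass_bias_round_trip_recovers_masses(ida, windows):
    spec = spec_from_concentrations({"SELENOP": 59.2}, mass_bias_per_amu=0.005)
    chrom, truth = simulate_chromatogram(spec)
    mf = quantify_chromatogram(chrom, ida, mass_bias_per_amu=0.005)
    amounts = {a.species_name: a.se_mass_ng for a in integrate_windows(mf, windows)}
    assert amounts["SELENOP"] == pytest.approx(truth.se_mass_ng["SELENOP"], rel=5e-3)


@given(st.floats(min_value=0.002, max_value=25.0), st.floats(min_value=0.1, max_value=1000.0))
def test_invariant_under_common_channel_rescaling(r_m, scale):
    """Sensitivity cancels in the ratio, so mass flow ignores common scaling."""
    ida = IDAParameters(
        spike_concentration_ng_ml=100.0,
        spike_flow_ml_min=0.1,
        spike_abundances={74: 0.999, 78: 0.001},
    )
    t = np.array([0.0, 1.5])
    i74 = np.array([1000.0, 1000.0])
    i78 = i74 * r_m
    base = mass_flow(ratio_trace(IsotopeChromatogram(time_s=t, intensities={74: i74, 78: i78})), ida)
    scaled = mass_flow(
        ratio_trace(
            IsotopeChromatogram(time_s=t, intensities={74: i74 * scale, 78: i78 * scale})
        ),
        ida,
    )
    np.testing.assert_allclose(scaled.mass_flow_ng_min, base.mass_flow_ng_min, rtol=1e-12)


@given(st.lists(st.floats(min_value=0.0011, max_value=26.0), min_size=2, max_size=20))
def test_monotone_in_measured_ratio_on_physical_branch(ratios):
    ida = IDAParameters(
        spike_concentration_ng_ml=100.0,
        spike_flow_ml_min=0.1,
        spike_abundances={74: 0.999, 78: 0.001},
    )
    ordered = sorted(ratios)
    mf = mass_flow(make_trace(ordered), ida)
    vals = mf.mass_flow_ng_min[mf.valid]
    assert np.all(np.diff(vals) >= -1e-12)


@pytest.mark.parametrize("smoothing", [1, 3, 5])
def test_integrated_mass_invariant_to_smoothing(ida, windows, smoothing):
    spec = spec_from_concentrations({"SELENOP": 59.2})
    chrom, truth = simulate_chromatogram(spec)
    mf = quantify_chromatogram(chrom, ida, smoothing_points=smoothing)
    amounts = {a.species_name: a.se_mass_ng for a in integrate_windows(mf, windows)}
    assert amounts["SELENOP"] == pytest.approx(truth.se_mass_ng["SELENOP"], rel=2e-3)
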