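"""Deamination-kinetics unit and property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleocpd.kinetics import (
    BandMeasurement,
    DegenerateMeasurementError,
    InsufficientDataError,
    TimeCourse,
    cpd_remaining_fraction,
    deaminated_fraction,
    fit_deamination,
    fold_change,
    half_life_to_rate,
    photoproduct_yield,
)
from nucleocpd.synthetic import TimeCourseSpec, generate_time_course


@pytest.mark.parametrize(
    "mC,T,expected",
    [(100, 0, 0.0), (0, 50, 1.0), (75, 25, 0.25), (88, 12, 0.12), (78, 22, 0.22)],
)
def test_deaminated_fraction(mC, T, expected):
    assert deaminated_fraction(mC, T) == pytest.approx(expected, abs=1e-12)


def test_deaminated_fraction_degenerate():
    with pytest.raises(DegenerateMeasurementError):
        deaminated_fraction(0, 0)
    with pytest.raises(ValueError):
        deaminated_fraction(-1, 5)


@pytest.mark.parametrize(
    "f_t,f_inf,expected",
    [(0.0, 0.12, 1.0), (0.12, 0.12, 0.0), (0.06, 0.12, 0.5)],
)
def test_cpd_remaining_fraction(f_t, f_inf, expected):
    assert cpd_remaining_fraction(f_t, f_inf) == pytest.approx(expected, abs=1e-12)


def test_cpd_remaining_fraction_unusable_terminal():
    with pytest.raises(DegenerateMeasurementError):
        cpd_remaining_fraction(0.1, 0.0)


def test_cpd_remaining_fraction_noise_overshoot_allowed():
    # noisy aliquots can exceed the terminal fraction; the result is
    # nonpositive and the fit (not this op) excludes it
    assert cpd_remaining_fraction(0.15, 0.12) < 0


@pytest.mark.parametrize(
    "mC,T,expected",
    [(88, 12, 0.12), (78, 22, 0.22), (0, 1, 1.0)],
)
def test_photoproduct_yield(mC, T, expected):
    term = BandMeasurement(time_h=100.0, intensity_mC=mC, intensity_T=T)
    assert photoproduct_yield(term) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "half_life,expected",
    [(13.0, math.log(2) / 13), (41.0, math.log(2) / 41), (math.log(2), 1.0)],
)
def test_half_life_to_rate(half_life, expected):
    assert half_life_to_rate(half_life) == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        half_life_to_rate(0.0)


@pytest.mark.parametrize(
    "test,ref,expected", [(41, 13, 41 / 13), (22, 12, 22 / 12), (7.7, 7.7, 1.0)]
)
def test_fold_change(test, ref, expected):
    assert fold_change(test, ref) == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        fold_change(test, 0)


def test_noiseless_fit_is_exact_round_trip():
    # generator and fit are exact inverses when no noise is present
    spec = TimeCourseSpec(
        k_true=0.0533,
        yield_true=0.12,
        initial_deaminated_fraction=0.0,
        times_h=(0.0, 6.0, 12.0, 24.0, 48.0),
        noise_sigma=0.0,
    )
    fit = fit_deamination(generate_time_course(spec))
    assert fit.half_life_h == pytest.approx(math.log(2) / 0.0533, abs=1e-9)
    assert fit.k * fit.half_life_h == pytest.approx(math.log(2), rel=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_nonzero_initial_deamination_does_not_bias_slope():
    spec = TimeCourseSpec(
        k_true=0.2,
        yield_true=0.12,
        initial_deaminated_fraction=0.1,  # intercept ln(0.9)
        times_h=(0.0, 2.0, 4.0, 8.0, 12.0),
        noise_sigma=0.0,
    )
    fit = fit_deamination(generate_time_course(spec))
    assert fit.k == pytest.approx(0.2, rel=1e-9)
    assert fit.intercept == pytest.approx(math.log(0.9), abs=1e-9)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    k=st.floats(0.01, 0.5),
    f0=st.floats(0.0, 0.5),
    yld=st.floats(0.05, 1.0),
    t_step=st.floats(0.5, 10.0),
)
def test_exact_recovery_property(k, f0, yld, t_step):
    """Any noiseless exponential course is recovered to 1e-9 relative,
    independent of the intercept offset."""
    times = tuple(t_step * i for i in range(6))
    spec = TimeCourseSpec(
        k_true=k,
        yield_true=yld,
        initial_deaminated_fraction=f0,
        times_h=times,
        noise_sigma=0.0,
    )
    fit = fit_deamination(generate_time_course(spec))
    assert fit.k == pytest.approx(k, rel=1e-9)
    assert fit.half_life_h * fit.k == pytest.approx(math.log(2), rel=1e-12)


def test_scale_invariance_per_aliquot(rng):
    """Multiplying both bands of any aliquot by a positive factor leaves
    fractions and the fit unchanged."""
    spec = TimeCourseSpec(k_true=0.05, seed=3)
    tc = generate_time_course(spec)
    scales = rng.uniform(0.1, 10.0, size=len(tc.measurements) + 1)
    scaled = TimeCourse(
        site_id=tc.site_id,
        measurements=tuple(
            BandMeasurement(m.time_h, s * m.intensity_mC, s * m.intensity_T)
            for m, s in zip(tc.measurements, scales)
        ),
        terminal=BandMeasurement(
            tc.terminal.time_h,
            scales[-1] * tc.terminal.intensity_mC,
            scales[-1] * tc.terminal.intensity_T,
        ),
    )
    f1, f2 = fit_deamination(tc), fit_deamination(scaled)
    assert f1.k == pytest.approx(f2.k, rel=1e-12)
    assert f1.yield_ == pytest.approx(f2.yield_, rel=1e-12)
    assert f1.intercept == pytest.approx(f2.intercept, rel=1e-12)


def test_rate_rank_is_reverse_of_half_life_rank(table):
    """On the packaged site table, rate constants order exactly opposite
    to half-lives."""
    records = list(table.values())
    by_halflife = sorted(records, key=lambda r: r.half_life_h)
    by_rate = sorted(records, key=lambda r: half_life_to_rate(r.half_life_h), reverse=True)
    assert [r.site_id for r in by_halflife] == [r.site_id for r in by_rate]


def test_stochastic_recovery_ncp_ds6_regime():
    """Mean fitted half-life over 500 noisy courses at the fastest-site
    rate (k = 0.198/h) lands within 10% of the true 3.5 h."""
    k_true = 0.198
    t12 = []
    for i in range(500):
        tc = generate_time_course(
            TimeCourseSpec(k_true=k_true, yield_true=0.22, noise_sigma=0.05, seed=i + 1)
        )
        t12.append(fit_deamination(tc).half_life_h)
    assert np.mean(t12) == pytest.approx(math.log(2) / k_true, rel=0.10)


def test_too_few_points_refused():
    with pytest.raises(InsufficientDataError):
        TimeCourse(
            site_id="x",
            measurements=(
                BandMeasurement(0, 90, 10),
                BandMeasurement(1, 80, 20),
            ),
            terminal=BandMeasurement(99, 50, 50),
        )


def test_no_detectable_deamination_flagged():
    # constant deaminated fraction -> slope 0 -> invalid fit, not a crash
    ms = tuple(BandMeasurement(t, 90.0, 10.0) for t in (0.0, 4.0, 8.0, 16.0))
    tc = TimeCourse(site_id="flat", measurements=ms, terminal=BandMeasurement(99, 50, 50))
    fit = fit_deamination(tc)
    assert not fit.valid
    assert fit.k <= 0


def test_points_beyond_plateau_are_excluded_and_counted():
    spec = TimeCourseSpec(
        k_true=0.3,
        initial_deaminated_fraction=0.0,
        times_h=(0.0, 2.0, 4.0, 8.0, 16.0, 32.0),
        noise_sigma=0.0,
    )
    fit = fit_deamination(generate_time_course(spec))
    # remaining fraction at 16 h is ~0.008, far below the 0.1 floor
    assert fit.n_excluded >= 2
    assert fit.n_points + fit.n_excluded == 6
    assert fit.k == pytest.approx(0.3, rel=1e-9)
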