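"""Exponential fitting, rate conversion, fold changes."""

import numpy as np
import pytest

from memfield.errors import ConvergenceError, RateUnidentifiableError
from memfield.kinetics import (ExponentialFit, FretTrace, TransferRate,
                               fit_single_exponential, fold_change,
                               read_fret_trace, summarize_rates,
                               transfer_rate)
from memfield.synth import make_fret_trace

T_GRID = np.linspace(0.0, 10.0, 60)


def test_noiseless_recovery_exact():
    trace = make_fret_trace(1.0, 2.0, 0.6, T_GRID, noise_sd=0.0)
    fit = fit_single_exponential(trace)
    assert fit.converged
    assert fit.F0 == pytest.approx(1.0, rel=1e-9)
    assert fit.F_inf == pytest.approx(2.0, rel=1e-9)
    assert fit.k_per_min == pytest.approx(0.6, rel=1e-9)
    assert fit.residual_rms < 1e-10


def test_decaying_signal_also_recovered():
    trace = make_fret_trace(5.0, 1.0, 1.7, T_GRID, noise_sd=0.0)
    fit = fit_single_exponential(trace)
    assert fit.k_per_min == pytest.approx(1.7, rel=1e-9)


def test_constant_trace_rejected():
    trace = FretTrace(time_min=T_GRID, signal=np.full_like(T_GRID, 3.0))
    with pytest.raises(RateUnidentifiableError):
        fit_single_exponential(trace)


def test_too_few_points_rejected():
    with pytest.raises(ValueError, match="6 points"):
        fit_single_exponential(FretTrace(time_min=np.arange(5.0),
                                         signal=np.arange(5.0)))


@pytest.mark.parametrize("k_true", [0.1, 0.6, 3.0])
def test_ci_coverage(k_true):
    """95% CI covers the true k in >= 90 of 100 noisy replicates."""
    amp = 1.0
    hits = 0
    for rep in range(100):
        trace = make_fret_trace(1.0, 1.0 + amp, k_true, T_GRID,
                                noise_sd=0.01 * amp, seed=1000 + rep)
        fit = fit_single_exponential(trace)
        lo, hi = fit.ci95_k()
        if lo <= k_true <= hi:
            hits += 1
    assert hits >= 90


def test_transfer_rate_reproduces_reported_magnitude():
    fit = ExponentialFit(F0=1.0, F_inf=2.0, k_per_min=0.6087, se_F0=0.0,
                         se_F_inf=0.0, se_k=0.0, residual_rms=0.0,
                         converged=True)
    rate = transfer_rate(fit, dhe0_uM=23.0, stard4_uM=1.0, f_eq=0.5)
    assert rate.rate_per_min == pytest.approx(7.0, abs=0.01)


def test_transfer_rate_scalings():
    fit = ExponentialFit(F0=1.0, F_inf=2.0, k_per_min=0.5, se_F0=0.0,
                         se_F_inf=0.0, se_k=0.05, residual_rms=0.0,
                         converged=True)
    base = transfer_rate(fit, 20.0, 1.0, f_eq=0.5)
    # linear in f_eq; f_eq -> 0+ drives the rate to 0
    tiny = transfer_rate(fit, 20.0, 1.0, f_eq=1e-9)
    assert tiny.rate_per_min == pytest.approx(0.0, abs=1e-6)
    assert transfer_rate(fit, 20.0, 1.0, f_eq=1.0).rate_per_min == \
        pytest.approx(2 * base.rate_per_min)
    # doubling the carrier halves the rate
    assert transfer_rate(fit, 20.0, 2.0, f_eq=0.5).rate_per_min == \
        pytest.approx(base.rate_per_min / 2)
    # linear in k
    fit2 = ExponentialFit(F0=1.0, F_inf=2.0, k_per_min=1.0, se_F0=0.0,
                          se_F_inf=0.0, se_k=0.05, residual_rms=0.0,
                          converged=True)
    assert transfer_rate(fit2, 20.0, 1.0, 0.5).rate_per_min == \
        pytest.approx(2 * base.rate_per_min)


def test_unconverged_fit_rejected():
    fit = ExponentialFit(F0=1.0, F_inf=2.0, k_per_min=0.5, se_F0=np.nan,
                         se_F_inf=np.nan, se_k=np.nan, residual_rms=0.0,
                         converged=False)
    with pytest.raises(ConvergenceError):
        transfer_rate(fit, 20.0, 1.0)


def _rate(v, se=0.0):
    return TransferRate(rate_per_min=v, se=se, dhe0_uM=23.0, f_eq=0.5,
                        carrier_uM=1.0)


def test_fold_change_cases():
    assert fold_change(_rate(5.0), _rate(5.0))[0] == 1.0
    ratio, se = fold_change(_rate(45.5), _rate(7.0))
    assert ratio == pytest.approx(6.5)
    assert se == 0.0
    ratio, se = fold_change(_rate(10.0, 1.0), _rate(5.0, 0.5))
    assert ratio == pytest.approx(2.0)
    assert se == pytest.approx(2.0 * np.sqrt(0.01 + 0.01), abs=1e-9)
    assert se == pytest.approx(0.283, abs=0.001)
    with pytest.raises(ValueError):
        fold_change(_rate(1.0), _rate(0.0))


def test_fold_change_scale_invariant():
    a, b = _rate(12.0, 0.6), _rate(4.0, 0.8)
    r1 = fold_change(a, b)
    a2, b2 = _rate(120.0, 6.0), _rate(40.0, 8.0)
    r2 = fold_change(a2, b2)
    assert r1[0] == pytest.approx(r2[0])
    assert r1[1] == pytest.approx(r2[1])


def test_summarize_rates():
    rates = [_rate(6.0, 0.1), _rate(7.0, 0.1), _rate(8.0, 0.1)]
    mean, sem = summarize_rates(rates)
    assert mean == pytest.approx(7.0)
    assert sem == pytest.approx(np.std([6, 7, 8], ddof=1) / np.sqrt(3))


def test_read_trace_csv(tmp_path):
    path = tmp_path / "trace.csv"
    path.write_text("time,signal\n0,1.0\n60,1.5\n120,1.8\n")
    tr = read_fret_trace(path, time_in_seconds=True)
    assert np.allclose(tr.time_min, [0.0, 1.0, 2.0])
    with pytest.raises(ValueError, match="columns"):
        bad = tmp_path / "bad.csv"
        bad.write_text("a,b\n1,2\n")
        read_fret_trace(bad)


def test_weighted_fit_uses_sigma():
    trace = make_fret_trace(1.0, 2.0, 0.6, T_GRID, noise_sd=0.01, seed=5)
    trace.sigma = np.full_like(trace.signal, 0.01)
    fit = fit_single_exponential(trace)
    assert fit.k_per_min == pytest.approx(0.6, rel=0.1)
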