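"""Sterol-transfer kinetics: single-exponential FRET fitting and conversion
to molecules transferred per carrier protein per minute.

Times are minutes throughout; input CSVs recorded in seconds are converted
on read.  The rate conversion uses the initial-rate convention
``rate = k * f_eq * DHE0 / [carrier]`` with the equilibrium transferred
fraction ``f_eq`` defaulting to 0.5 (symmetric donor/acceptor pools).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConvergenceError, RateUnidentifiableError

__all__ = ["FretTrace", "ExponentialFit", "TransferRate", "read_fret_trace",
           "fit_single_exponential", "transfer_rate", "fold_change",
           "summarize_rates"]


@dataclass
class FretTrace:
    time_min: np.ndarray
    signal: np.ndarray
    sigma: Optional[np.ndarray] = None      # per-point noise for weighted fits
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_min.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.signal.shape:
                raise ValueError("sigma length mismatch")

    @property
    def n_points(self) -> int:
        return len(self.time_min)


@dataclass
class ExponentialFit:
    F0: float
    F_inf: float
    k_per_min: float
    se_F0: float
    se_F_inf: float
    se_k: float
    residual_rms: float
    converged: bool

    def ci95_k(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.se_k
        return self.k_per_min - half, self.k_per_min + half


@dataclass
class TransferRate:
    rate_per_min: float      # molecules per carrier molecule per minute
    se: float
    dhe0_uM: float
    f_eq: float
    carrier_uM: float


def read_fret_trace(path: str | Path, time_in_seconds: bool = False,
                    metadata: dict | None = None) -> FretTrace:
    """Read a time/value CSV trace (columns: time, signal[, sigma])."""
    df = pd.read_csv(path, comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "time" not in cols or "signal" not in cols:
        raise ValueError(
            f"{path}: trace CSV needs 'time' and 'signal' columns, "
            f"found {list(df.columns)}")
    t = df[cols["time"]].to_numpy(dtype=float)
    if time_in_seconds:
        t = t / 60.0
    sigma = (df[cols["sigma"]].to_numpy(dtype=float)
             if "sigma" in cols else None)
    return FretTrace(time_min=t, signal=df[cols["signal"]].to_numpy(float),
                     sigma=sigma, metadata=metadata or {})


def _model(t: np.ndarray, F0: float, F_inf: float, k: float) -> np.ndarray:
    return F_inf + (F0 - F_inf) * np.exp(-k * t)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    F0, F_inf = float(y[0]), float(y[-1])
    amp = F0 - F_inf
    # crude decay time from the first crossing of amplitude/e, refined by a
    # log-linear fit on the tail where the residual amplitude is resolvable
    resid = np.abs(y - F_inf)
    good = resid > abs(amp) * 0.05
    k = 1.0
    if np.count_nonzero(good[1:]) >= 2 and abs(amp) > 0:
        tt = t[good]
        with np.errstate(divide="ignore"):
            ll = np.log(resid[good] / abs(amp))
        finite = np.isfinite(ll)
        if np.count_nonzero(finite) >= 2:
            slope = np.polyfit(tt[finite], ll[finite], 1)[0]
            if slope < 0:
                k = -slope
    return F0, F_inf, max(k, 1e-9)


def fit_single_exponential(trace: FretTrace) -> ExponentialFit:
    """Least-squares fit of ``F(t) = F_inf + (F0 - F_inf) exp(-k t)``.

    Unweighted unless the trace carries per-point sigmas.  Raises
    :class:`RateUnidentifiableError` for flat traces and
    :class:`ConvergenceError` if the optimizer fails.
    """
    if trace.n_points < 6:
        raise ValueError("need at least 6 points to fit an exponential")
    t, y = trace.time_min, trace.signal
    span = float(np.ptp(y))
    scale = max(float(np.max(np.abs(y))), 1.0)
    if span <= 1e-12 * scale:
        raise RateUnidentifiableError(
            "trace is constant; the decay rate is unidentifiable")
    p0 = _initial_guess(t, y)
    try:
        popt, pcov = curve_fit(
            _model, t, y, p0=p0, sigma=trace.sigma,
            absolute_sigma=trace.sigma is not None,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except RuntimeError as exc:
        raise ConvergenceError(f"exponential fit failed: {exc}") from exc
    ses = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    resid = y - _model(t, *popt)
    converged = bool(np.all(np.isfinite(ses)))
    return ExponentialFit(
        F0=float(popt[0]), F_inf=float(popt[1]), k_per_min=float(popt[2]),
        se_F0=float(ses[0]), se_F_inf=float(ses[1]), se_k=float(ses[2]),
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        converged=converged)


def transfer_rate(fit: ExponentialFit, dhe0_uM: float, stard4_uM: float,
                  f_eq: float = 0.5) -> TransferRate:
    """Convert a fitted rate constant to molecules/carrier/minute.

    ``rate = k * f_eq * DHE0 / [carrier]``: the first-order rate applied to
    the equilibrium-transferred sterol pool per carrier molecule.
    """
    if not fit.converged:
        raise ConvergenceError("cannot convert an unconverged fit")
    if dhe0_uM <= 0 or stard4_uM <= 0:
        raise ValueError("concentrations must be > 0")
    if not (0.0 < f_eq <= 1.0):
        raise ValueError("f_eq must lie in (0, 1]")
    factor = f_eq * dhe0_uM / stard4_uM
    return TransferRate(rate_per_min=fit.k_per_min * factor,
                        se=fit.se_k * factor, dhe0_uM=dhe0_uM, f_eq=f_eq,
                        carrier_uM=stard4_uM)


def fold_change(rate_a: TransferRate, rate_b: TransferRate
                ) -> tuple[float, float]:
    """Ratio a/b with first-order propagated standard error."""
    if rate_b.rate_per_min == 0:
        raise ValueError("reference rate is zero; fold change undefined")
    ratio = rate_a.rate_per_min / rate_b.rate_per_min
    rel_a = rate_a.se / rate_a.rate_per_min if rate_a.rate_per_min else 0.0
    rel_b = rate_b.se / rate_b.rate_per_min
    return ratio, abs(ratio) * math.sqrt(rel_a ** 2 + rel_b ** 2)


def summarize_rates(rates: list[TransferRate]) -> tuple[float, float]:
    """Mean and standard error across independent replicate fits."""
    if not rates:
        raise ValueError("need at least one replicate")
    vals = np.array([r.rate_per_min for r in rates])
    sem = (float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
           if len(vals) > 1 else float(rates[0].se))
    return float(np.mean(vals)), sem
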