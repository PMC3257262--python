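"""Per-residue transverse relaxation rates from CPMG decays.

Each residue's peak intensity decays mono-exponentially with the CPMG delay,
I(t) = I0 * exp(-R2 * t). R2 is obtained by nonlinear least squares with a
log-linear initial guess; the standard error comes from the fit covariance.
Elevated R2 flags ms-us conformational exchange; contiguous stretches of
elevated R2 are called as exchange segments with a robust z-score rule
(median + k * 1.4826 * MAD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize

from .datamodel import Condition, RelaxationSeries, SegmentCall, contiguous_runs

#: the standard 10-point CPMG delay schedule, in seconds
DEFAULT_CPMG_DELAYS_S = tuple(d / 1000.0 for d in range(10, 200, 20))

DEFAULT_K_SIGMA = 1.0
DEFAULT_MIN_LEN = 3


class FitError(ValueError):
    """A single-residue decay could not be fitted."""


def _monoexp(t: np.ndarray, i0: float, r2: float) -> np.ndarray:
    return i0 * np.exp(-r2 * t)


def fit_r2(
    series: RelaxationSeries, position: int, sigma: np.ndarray | None = None
) -> tuple[float, float]:
    """Fit I(t) = I0 exp(-R2 t) for one residue; returns (R2, SE) in s^-1.

    The initial guess comes from a log-linear regression of ln(I) on t, the
    refinement from nonlinear least squares; the SE is the square root of the
    R2 diagonal of the covariance. Non-positive intensities or a non-decaying
    curve raise :class:`FitError` (batch callers record these as failures
    rather than aborting).
    """
    if position not in series.intensities:
        raise KeyError(f"no decay recorded for residue {position}")
    t = np.asarray(series.delays_s)
    y = np.asarray(series.intensities[position], dtype=float)
    if np.any(y <= 0):
        raise FitError(f"residue {position}: non-positive intensities")
    # log-linear initialisation
    slope, intercept = np.polyfit(t, np.log(y), 1)
    if slope >= 0:
        raise FitError(f"residue {position}: intensities do not decay")
    p0 = (math.exp(intercept), -slope)
    if sigma is None and series.intensity_errors is not None:
        errs = series.intensity_errors.get(position)
        if errs is not None:
            sigma = np.asarray(errs, dtype=float)
    try:
        popt, pcov = optimize.curve_fit(
            _monoexp, t, y, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"residue {position}: {exc}") from exc
    r2 = float(popt[1])
    r2_err = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    if r2 <= 0:
        raise FitError(f"residue {position}: fitted R2 not positive ({r2:.3g})")
    return r2, r2_err


@dataclass
class R2Profile:
    """Fitted R2 values for one condition, with errors and failure records."""

    condition: Condition
    r2: dict[int, float]
    r2_err: dict[int, float]
    fit_quality: dict[int, float] = field(default_factory=dict)  # RMS residual / I0
    failures: dict[int, str] = field(default_factory=dict)

    def summary(self) -> dict[str, float]:
        """min / max / mean of the fitted rates (s^-1)."""
        vals = np.array(sorted(self.r2.values()))
        if vals.size == 0:
            raise ValueError("no converged fits to summarise")
        return {"min": float(vals.min()), "max": float(vals.max()),
                "mean": float(vals.mean()), "n": int(vals.size)}


def fit_profile(series: RelaxationSeries) -> R2Profile:
    """Fit every residue in a series; failures are recorded, not raised."""
    r2: dict[int, float] = {}
    err: dict[int, float] = {}
    quality: dict[int, float] = {}
    failures: dict[int, str] = {}
    t = np.asarray(series.delays_s)
    for pos in sorted(series.intensities):
        try:
            rate, se = fit_r2(series, pos)
        except FitError as exc:
            failures[pos] = str(exc)
            continue
        y = np.asarray(series.intensities[pos])
        # I0 back out of the model at t=0 via the fitted rate
        i0 = float(np.exp(np.log(y).mean() + rate * t.mean()))
        resid = y - _monoexp(t, i0, rate)
        r2[pos] = rate
        err[pos] = se
        quality[pos] = float(np.sqrt(np.mean(resid**2)) / i0)
    return R2Profile(series.condition, r2, err, quality, failures)


def detect_exchange_segments(
    profile: R2Profile,
    k_sigma: float = DEFAULT_K_SIGMA,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[SegmentCall]:
    """Contiguous stretches of elevated R2, flagged by a robust z-score.

    A residue is flagged when ``R2 > median + k_sigma * 1.4826 * MAD`` (the
    scaled median absolute deviation is a robust stand-in for the SD, immune
    to the exchange residues themselves). Maximal contiguous flagged runs of
    at least ``min_len`` residues are returned, labelled ``exchange``. The
    result depends only on the profile contents, not on insertion order.
    """
    if len(profile.r2) < 5:
        raise ValueError("need at least 5 fitted residues for exchange statistics")
    vals = np.array([profile.r2[p] for p in sorted(profile.r2)])
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    cutoff = med + k_sigma * 1.4826 * mad
    flagged = [p for p in sorted(profile.r2) if profile.r2[p] > cutoff]
    calls = []
    for start, end in contiguous_runs(flagged):
        if end - start + 1 >= min_len:
            calls.append(SegmentCall(
                start, end, "exchange", profile.condition.label,
                evidence={
                    "r2": {p: profile.r2[p] for p in range(start, end + 1)
                           if p in profile.r2},
                    "cutoff": cutoff, "median": med,
                    "robust_sd": 1.4826 * mad,
                },
            ))
    return calls
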