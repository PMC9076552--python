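"""Rate extraction from plate-reader time courses.

Sign convention: consumption assays (NADH oxidation) and production assays
(TNB2-, resorufin) both report positive rates; the direction is a property
of the assay.  Concentrations follow Beer-Lambert with the embedded
extinction coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "AssayConstants",
    "KineticTrace",
    "RateEstimate",
    "ReactivationProfile",
    "nadh_concentration",
    "max_linear_rate",
    "rotenone_sensitive_rate",
    "reactivation_lag",
    "citrate_synthase_rate",
    "amplex_quantify",
    "h2o2_stock_concentration",
    "fit_gsh_labeling",
]


@dataclass(frozen=True)
class AssayConstants:
    """Extinction coefficients and default optical path.

    eps_nadh_340_380 is in mM^-1 cm^-1 (dual-wavelength NADH assay);
    eps_tnb_412 and eps_h2o2_240 are in M^-1 cm^-1.  The default path of
    0.55 cm corresponds to a 200 ul fill in a 96-well plate and is
    overridable everywhere.
    """

    eps_nadh_340_380: float = 4.81
    eps_tnb_412: float = 13600.0
    eps_h2o2_240: float = 43.5
    path_cm: float = 0.55

    def __post_init__(self):
        for f in ("eps_nadh_340_380", "eps_tnb_412", "eps_h2o2_240", "path_cm"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


DEFAULT_CONSTANTS = AssayConstants()


@dataclass(frozen=True)
class KineticTrace:
    """Time-resolved absorbance/fluorescence signal for one well."""

    time_s: np.ndarray
    signal: np.ndarray
    reference: np.ndarray | None = None  # e.g. A380 for the NADH assay
    condition: str = ""
    rotenone: bool = False
    path_cm: float | None = None
    replicate: str | int = 0

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.size < 5:
            raise ValueError("need >= 5 time points for rate fitting")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if s.shape != t.shape:
            raise ValueError("signal/time shape mismatch")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "signal", s)
        if self.reference is not None:
            r = np.asarray(self.reference, dtype=float)
            if r.shape != t.shape:
                raise ValueError("reference/time shape mismatch")
            object.__setattr__(self, "reference", r)


@dataclass(frozen=True)
class RateEstimate:
    """Maximal linear rate from a sliding-window OLS fit."""

    rate: float  # concentration per minute, positive in assay direction
    window: tuple[float, float]  # seconds
    r_squared: float
    background_rate: float = 0.0

    @property
    def background_subtracted(self) -> float:
        return self.rate - self.background_rate


@dataclass(frozen=True)
class ReactivationProfile:
    lag_min: float  # time to reach 50% of the maximal smoothed rate
    t_max_rate_min: float
    initial_rate: float
    max_rate: float

    def __post_init__(self):
        if self.lag_min < 0:
            raise ValueError("lag must be >= 0")


def nadh_concentration(
    trace: KineticTrace, constants: AssayConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """NADH concentration series (mM): (A340 - A380) / (eps * path)."""
    if trace.reference is None:
        raise ValueError("NADH assay requires the A380 reference signal")
    path = trace.path_cm if trace.path_cm is not None else constants.path_cm
    if path <= 0:
        raise ValueError("path length must be > 0")
    return (trace.signal - trace.reference) / (constants.eps_nadh_340_380 * path)


def _window_slopes(
    time_s: np.ndarray, series: np.ndarray, width: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slopes (per second), centers and R^2 of every sliding OLS window."""
    n = len(series)
    slopes, centers, r2 = [], [], []
    for i in range(n - width + 1):
        t = time_s[i : i + width]
        y = series[i : i + width]
        fit = stats.linregress(t, y)
        slopes.append(fit.slope)
        centers.append(t.mean())
        r2.append(fit.rvalue**2 if not math.isnan(fit.rvalue) else 1.0)
    return np.asarray(slopes), np.asarray(centers), np.asarray(r2)


def max_linear_rate(
    time_s: Sequence[float],
    concentration: Sequence[float],
    window_width: int = 10,
    direction: str = "consumption",
) -> RateEstimate:
    """Steepest sliding-window OLS slope, reported positive.

    ``direction`` selects the sign of interest ("consumption" seeks the
    most negative slope, "production" the most positive); ties are broken
    by the earliest window.
    """
    t = np.asarray(time_s, dtype=float)
    c = np.asarray(concentration, dtype=float)
    if window_width < 5:
        raise ValueError("window_width must be >= 5 samples")
    if len(t) < window_width:
        raise ValueError(
            f"trace has {len(t)} samples, fewer than window_width={window_width}"
        )
    if direction not in ("consumption", "production"):
        raise ValueError("direction must be 'consumption' or 'production'")
    slopes, _, r2 = _window_slopes(t, c, window_width)
    signed = -slopes if direction == "consumption" else slopes
    best = int(np.argmax(signed))  # argmax returns the earliest maximum
    rate_per_min = max(signed[best], 0.0) * 60.0
    window = (float(t[best]), float(t[best + window_width - 1]))
    return RateEstimate(rate=rate_per_min, window=window, r_squared=float(r2[best]))


def rotenone_sensitive_rate(
    rate_total: float, rate_rotenone: float
) -> tuple[float, float]:
    """(total - background, sensitive fraction of total)."""
    if rate_total < 0 or rate_rotenone < 0:
        raise ValueError("rates must be >= 0")
    sensitive = rate_total - rate_rotenone
    if rate_total == 0:
        return sensitive, float("nan")
    return sensitive, sensitive / rate_total


def reactivation_lag(
    time_s: Sequence[float],
    concentration: Sequence[float],
    window_width: int = 10,
    direction: str = "consumption",
) -> ReactivationProfile:
    """Lag to half-maximal rate from a locally regressed rate curve.

    The instantaneous rate is the sliding-window OLS slope evaluated at
    window centers; the lag is the first (interpolated) time the smoothed
    rate reaches 50% of its maximum.  Immediately linear traces yield a
    lag of ~0.
    """
    t = np.asarray(time_s, dtype=float)
    c = np.asarray(concentration, dtype=float)
    if len(t) < window_width:
        raise ValueError("trace shorter than the smoothing window")
    slopes, centers, _ = _window_slopes(t, c, window_width)
    rate = -slopes if direction == "consumption" else slopes
    rate = np.clip(rate, 0.0, None)
    max_rate = float(rate.max())
    if max_rate == 0:
        raise ValueError("maximal rate is 0: lag undefined")
    half = 0.5 * max_rate
    idx = int(np.argmax(rate >= half))
    if idx == 0:
        lag_s = centers[0] if rate[0] >= half else float(centers[-1])
    else:
        # linear interpolation between the bracketing window centers
        f = (half - rate[idx - 1]) / (rate[idx] - rate[idx - 1])
        lag_s = centers[idx - 1] + f * (centers[idx] - centers[idx - 1])
    # a trace already at speed from t=0 has its first window at half rate
    # only because of smoothing; report 0 when the first window is maximal
    if rate[0] >= half:
        lag_s = 0.0
    t_max = float(centers[int(np.argmax(rate))])
    return ReactivationProfile(
        lag_min=float(lag_s) / 60.0,
        t_max_rate_min=t_max / 60.0,
        initial_rate=float(rate[0]) * 60.0,
        max_rate=max_rate * 60.0,
    )


def citrate_synthase_rate(
    trace: KineticTrace,
    constants: AssayConstants = DEFAULT_CONSTANTS,
    window_width: int = 10,
) -> RateEstimate:
    """TNB2- production rate (uM/min) from the A412 trace."""
    path = trace.path_cm if trace.path_cm is not None else constants.path_cm
    conc_uM = trace.signal / (constants.eps_tnb_412 * path) * 1e6
    return max_linear_rate(
        trace.time_s, conc_uM, window_width=window_width, direction="production"
    )


def amplex_quantify(
    sample_traces: Sequence[KineticTrace],
    standard_concs: Sequence[float],
    standard_signals: Sequence[float],
    window_width: int = 10,
    protein_mg: float | None = None,
) -> list[dict]:
    """Convert resorufin fluorescence slopes to H2O2 production rates.

    The standards (known [H2O2] in uM vs fluorescence) are fit by OLS; a
    sample's maximal linear fluorescence slope is divided by the standard
    slope to give uM/min (nmol/ml/min), normalized per mg when
    ``protein_mg`` is given.  Samples whose signal leaves the standard
    range are flagged as extrapolated.
    """
    x = np.asarray(standard_concs, dtype=float)
    y = np.asarray(standard_signals, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 standard points")
    fit = stats.linregress(x, y)
    if fit.slope <= 0:
        raise ValueError("standard curve slope must be positive")
    lo, hi = y.min(), y.max()
    results = []
    for trace in sample_traces:
        est = max_linear_rate(
            trace.time_s, trace.signal, window_width=window_width,
            direction="production",
        )
        rate_uM_min = est.rate / fit.slope
        if protein_mg is not None:
            rate_uM_min /= protein_mg
        results.append(
            {
                "condition": trace.condition,
                "replicate": trace.replicate,
                "rate_uM_per_min": rate_uM_min,
                "r_squared": est.r_squared,
                "extrapolated": bool(
                    trace.signal.min() < lo or trace.signal.max() > hi
                ),
            }
        )
    return results


def h2o2_stock_concentration(
    a240: float,
    dilution: float = 1.0,
    constants: AssayConstants = DEFAULT_CONSTANTS,
    path_cm: float = 1.0,
) -> float:
    """Molar H2O2 stock concentration from A240: A/(eps*path) * dilution."""
    if a240 < 0:
        raise ValueError("absorbance must be >= 0")
    if dilution <= 0 or path_cm <= 0:
        raise ValueError("dilution and path must be > 0")
    return a240 / (constants.eps_h2o2_240 * path_cm) * dilution


def fit_gsh_labeling(
    time_s: Sequence[float],
    labeled_fractions: Sequence[float],
    iam_conc_M: float,
) -> dict:
    """Pseudo-first-order alkylation fit: f(t) = 1 - exp(-k*[IAM]*t).

    Returns the bimolecular rate constant k (M^-1 s^-1) and the half-time
    ln2/(k*[IAM]).  Grossly non-monotone data trigger a fit warning flag.
    """
    t = np.asarray(time_s, dtype=float)
    f = np.asarray(labeled_fractions, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if iam_conc_M <= 0:
        raise ValueError("alkylator concentration must be > 0")

    def model(tt, kobs):
        return 1.0 - np.exp(-kobs * tt)

    if np.allclose(f, 0.0):
        kobs = 0.0
    else:
        (kobs,), _ = optimize.curve_fit(
            model, t, f, p0=[1.0 / max(t.max(), 1e-9)], bounds=(0, np.inf)
        )
    k = kobs / iam_conc_M
    # the model is monotone: a drop of more than 5 percentage points
    # between consecutive samples is a gross violation, not scatter
    warning = bool(np.diff(f).min(initial=0.0) < -0.05)
    return {
        "k_M_s": float(k),
        "k_obs_s": float(kobs),
        "half_time_s": math.inf if kobs == 0 else math.log(2) / kobs,
        "fit_warning": warning,
    }
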