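"""Four-pool active/deactive/alkylation state model and activity-exposure
correlation analysis.

Pools: A (active), D (deactive), A_alk (alkylated while active; remains
electron-transfer-competent and can no longer be locked), D_locked
(alkylated while deactive; permanently inactive).  Transfers are first
order and condition-dependent:

* A -> D at k_d, only without substrate;
* D -> A at k_a, only with substrate;
* D -> D_locked at k_x * [alkylator];
* A -> A_alk at k_x * [alkylator] * p_exposed.

Within a constant-condition segment the system is linear, so trajectories
are propagated with the exact matrix exponential; pool conservation is
exact to machine precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import expm

__all__ = [
    "ADKineticParams",
    "ADKineticState",
    "ProtocolEvent",
    "simulate_ad",
    "activity_from_state",
    "regression_with_ci",
    "binary_model_deviation",
    "ActivityExposurePoint",
]

POOLS = ("A", "D", "A_alk", "D_locked")


@dataclass(frozen=True)
class ADKineticParams:
    """First-order rate constants of the state model.

    Rates are per minute; ``k_x`` is per minute per unit alkylator
    concentration.  ``p_exposed`` scales the alkylation rate of the active
    pool (a free parameter for the observed sub-complete A-state
    alkylation; not a mechanistic claim).
    """

    k_d: float = 0.1  # deactivation, no substrate
    k_a: float = 0.3  # reactivation, with substrate
    k_x: float = 0.0  # alkylation per unit alkylator
    p_exposed: float = 1.0

    def __post_init__(self):
        for f in ("k_d", "k_a", "k_x"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if not 0 <= self.p_exposed <= 1:
            raise ValueError("p_exposed must lie in [0, 1]")


@dataclass(frozen=True)
class ADKineticState:
    """Pool fractions at one time point; fractions sum to 1."""

    time_min: float
    fractions: dict

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pool fractions sum to {total}, expected 1")
        if any(v < -1e-12 for v in self.fractions.values()):
            raise ValueError("pool fractions must be >= 0")


@dataclass(frozen=True)
class ProtocolEvent:
    """Timed condition change: add/remove substrate, add/quench alkylator."""

    t_min: float
    event: str
    value: float = 0.0

    _EVENTS = ("add_substrate", "remove_substrate", "add_alkylator", "quench_alkylator")

    def __post_init__(self):
        if self.event not in self._EVENTS:
            raise ValueError(f"unknown event {self.event!r}; one of {self._EVENTS}")
        if self.t_min < 0:
            raise ValueError("event time must be >= 0")
        if self.event == "add_alkylator" and self.value < 0:
            raise ValueError("alkylator concentration must be >= 0")

    @staticmethod
    def from_json(path: str | Path) -> list["ProtocolEvent"]:
        events = json.loads(Path(path).read_text())
        return [ProtocolEvent(**e) for e in events]


def _rate_matrix(
    params: ADKineticParams, substrate: bool, alkylator: float
) -> np.ndarray:
    """dx/dt = M @ x over pools (A, D, A_alk, D_locked)."""
    kd = params.k_d if not substrate else 0.0
    ka = params.k_a if substrate else 0.0
    kx = params.k_x * alkylator
    kxa = kx * params.p_exposed
    M = np.zeros((4, 4))
    M[0, 0] = -(kd + kxa)
    M[1, 0] = kd
    M[2, 0] = kxa
    M[0, 1] = ka
    M[1, 1] = -(ka + kx)
    M[3, 1] = kx
    return M


def simulate_ad(
    params: ADKineticParams,
    protocol_events: Sequence[ProtocolEvent] = (),
    dt: float = 0.1,
    horizon: float = 60.0,
    initial: Sequence[float] = (1.0, 0.0, 0.0, 0.0),
    substrate: bool = False,
    alkylator: float = 0.0,
) -> pd.DataFrame:
    """Propagate the pool fractions over ``horizon`` minutes.

    ``initial`` is (A, D, A_alk, D_locked) at t=0; ``substrate`` and
    ``alkylator`` set the conditions before the first event.  Output
    columns: time_min, A, D, A_alk, D_locked, substrate, alkylator,
    activity.
    """
    if dt <= 0 or horizon <= 0:
        raise ValueError("dt and horizon must be > 0")
    x = np.asarray(initial, dtype=float)
    if x.shape != (4,) or np.any(x < 0) or abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("initial fractions must be 4 non-negative values summing to 1")
    events = sorted(protocol_events, key=lambda e: e.t_min)
    if any(e.t_min > horizon for e in events):
        raise ValueError("event beyond the simulation horizon")

    n_steps = int(round(horizon / dt))
    grid = [i * dt for i in range(n_steps + 1)]
    breakpoints = sorted({0.0, horizon, *grid, *(e.t_min for e in events)})
    event_at: dict[float, list[ProtocolEvent]] = {}
    for e in events:
        event_at.setdefault(e.t_min, []).append(e)

    grid_set = set(np.round(grid, 12))
    rows = []
    t_prev = 0.0

    def apply_events(t):
        nonlocal substrate, alkylator
        for e in event_at.get(t, []):
            if e.event == "add_substrate":
                substrate = True
            elif e.event == "remove_substrate":
                substrate = False
            elif e.event == "add_alkylator":
                alkylator = e.value
            elif e.event == "quench_alkylator":
                alkylator = 0.0

    apply_events(0.0)
    rows.append((0.0, *x, substrate, alkylator))
    for t in breakpoints:
        if t == 0.0:
            continue
        M = _rate_matrix(params, substrate, alkylator)
        x = expm(M * (t - t_prev)) @ x
        x = np.clip(x, 0.0, None)
        x /= x.sum()
        t_prev = t
        apply_events(t)
        if round(t, 12) in grid_set:
            rows.append((t, *x, substrate, alkylator))

    df = pd.DataFrame(
        rows,
        columns=["time_min", *POOLS, "substrate", "alkylator"],
    )
    df["activity"] = df["A"] + df["A_alk"]
    return df


def activity_from_state(state: ADKineticState | dict) -> float:
    """Fraction of enzyme in electron-transfer-competent pools (A + A_alk)."""
    fractions = state.fractions if isinstance(state, ADKineticState) else state
    return float(fractions.get("A", 0.0) + fractions.get("A_alk", 0.0))


def two_state_analytic(
    params: ADKineticParams,
    t: np.ndarray,
    substrate: bool,
    a0: float = 1.0,
) -> np.ndarray:
    """Closed-form A(t) for the k_x = 0 reversible two-state system.

    With only one of k_d (no substrate) or k_a (substrate) active the
    system is a simple exponential approach; kept as an independent oracle
    for the matrix-exponential propagator.
    """
    t = np.asarray(t, dtype=float)
    if substrate:
        return 1.0 - (1.0 - a0) * np.exp(-params.k_a * t)
    return a0 * np.exp(-params.k_d * t)


# ---------------------------------------------------------------------------
# activity-exposure correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityExposurePoint:
    """One condition: activity (% of matched active control) vs exposure (%)."""

    condition: str
    activity_pct: float
    exposure_pct: float
    activity_sem: float = float("nan")
    exposure_sem: float = float("nan")

    def __post_init__(self):
        for v in (self.activity_pct, self.exposure_pct):
            if not -10.0 <= v <= 110.0:  # allow noise overshoot
                raise ValueError(f"value {v} outside the plausible 0-110% range")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    r_squared: float
    df: int

    def confidence_band(self, x: np.ndarray, level: float = 0.95) -> np.ndarray:
        """Half-width of the t-based confidence band for the mean response."""
        x = np.asarray(x, dtype=float)
        xm = np.mean(self._x)
        sxx = np.sum((self._x - xm) ** 2)
        se = self._resid_se * np.sqrt(1.0 / len(self._x) + (x - xm) ** 2 / sxx)
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.df)
        return tcrit * se

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def regression_with_ci(
    points: Sequence[ActivityExposurePoint] | np.ndarray,
    level: float = 0.95,
) -> RegressionResult:
    """OLS of exposure (%) on activity (%) with a t-based confidence band.

    Accepts ActivityExposurePoint records or an (n, 2) array of
    (activity, exposure) pairs; requires >= 3 points.
    """
    if len(points) < 3:
        raise ValueError("need >= 3 points for regression with a confidence band")
    if isinstance(points[0], ActivityExposurePoint):
        x = np.array([p.activity_pct for p in points])
        y = np.array([p.exposure_pct for p in points])
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    fit = stats.linregress(x, y)
    df = len(x) - 2
    tcrit = stats.t.ppf(0.5 + level / 2.0, df)
    result = RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_ci=(
            float(fit.slope - tcrit * fit.stderr),
            float(fit.slope + tcrit * fit.stderr),
        ),
        r_squared=float(fit.rvalue**2) if not math.isnan(fit.rvalue) else 1.0,
        df=df,
    )
    resid = y - (fit.intercept + fit.slope * x)
    resid_se = math.sqrt(np.sum(resid**2) / df) if df > 0 else 0.0
    object.__setattr__(result, "_x", x)
    object.__setattr__(result, "_resid_se", resid_se)
    return result


def binary_model_deviation(point: ActivityExposurePoint) -> float:
    """Signed vertical distance from the binary-model reference line.

    The reference is the optimal inverse correlation implied by the binary
    (occluded-in-active / exposed-in-deactive) model: exposure% = 100 -
    activity%.  Sign convention: deviation = line - observed, so a point
    *below* the line (less exposure than the binary model predicts) is
    positive, and a point above it (e.g. high exposure at full activity)
    is negative.
    """
    line = 100.0 - point.activity_pct
    return line - point.exposure_pct
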