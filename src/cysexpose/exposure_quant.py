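"""Peak areas of differentially labeled peptides -> per-cysteine exposure.

The quantification principle: the channel applied to the *native* sample
(before denaturation/reduction) marks thiols that were exposed during the
first labeling step; the channel applied after denaturation + reduction
marks thiols that were occluded.  The exposed fraction is the native-step
share of total peak area, and is invariant to which isotope plays the
"first" role.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Chromatogram",
    "PeakMeasurement",
    "LabelStep",
    "LabelScheme",
    "SCHEMES",
    "ExposureResult",
    "StandardCurve",
    "integrate_xic",
    "exposure_fraction",
    "channel_proportions",
    "resolve_scheme",
    "fit_standard_curve",
    "quantify",
    "exposure_from_table",
]


@dataclass(frozen=True)
class Chromatogram:
    """Centroided (rt, m/z, intensity) triples with non-decreasing rt."""

    rt_min: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        rt = np.asarray(self.rt_min, dtype=float)
        mzv = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if rt.size == 0:
            raise ValueError("empty chromatogram")
        if not (len(rt) == len(mzv) == len(inten)):
            raise ValueError("rt/mz/intensity lengths differ")
        if np.any(np.diff(rt) < 0):
            raise ValueError("retention times must be non-decreasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "rt_min", rt)
        object.__setattr__(self, "mz", mzv)
        object.__setattr__(self, "intensity", inten)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Chromatogram":
        df = pd.read_csv(path)
        return cls(df["rt_min"].values, df["mz"].values, df["intensity"].values)


@dataclass(frozen=True)
class PeakMeasurement:
    species_id: str
    channel: str
    area: float
    retention_time: float | None = None
    replicate: str | int = 0

    def __post_init__(self):
        if self.area < 0:
            raise ValueError("peak area must be >= 0")


def integrate_xic(
    chromatogram: Chromatogram,
    target_mz: float,
    mz_tol_ppm: float = 10.0,
    rt_window: tuple[float, float] | None = None,
) -> float:
    """Trapezoidal XIC area at ``target_mz`` within a ppm tolerance.

    Points whose m/z is outside the tolerance contribute zero intensity;
    returns 0.0 when no point matches.
    """
    if mz_tol_ppm <= 0:
        raise ValueError("mz_tol_ppm must be > 0")
    rt, mzv, inten = (
        chromatogram.rt_min,
        chromatogram.mz,
        chromatogram.intensity,
    )
    if rt_window is not None:
        lo, hi = rt_window
        keep = (rt >= lo) & (rt <= hi)
        rt, mzv, inten = rt[keep], mzv[keep], inten[keep]
    if rt.size == 0:
        return 0.0
    tol = target_mz * mz_tol_ppm * 1e-6
    signal = np.where(np.abs(mzv - target_mz) <= tol, inten, 0.0)
    if not np.any(signal > 0):
        return 0.0
    if rt.size == 1:
        return 0.0
    return float(np.trapezoid(signal, rt))


def exposure_fraction(area_first_label: float, area_second_label: float) -> float:
    """first / (first + second); the first label marks native-exposed thiols."""
    if area_first_label < 0 or area_second_label < 0:
        raise ValueError("areas must be >= 0")
    total = area_first_label + area_second_label
    if total == 0:
        raise ValueError("both areas zero: exposure undefined (missing)")
    return area_first_label / total


def channel_proportions(areas: Mapping[str, float]) -> dict[str, float]:
    """Each channel's share of the summed area; proportions sum to 1."""
    if len(areas) < 2:
        raise ValueError("need at least 2 channels")
    if any(a < 0 for a in areas.values()):
        raise ValueError("areas must be >= 0")
    total = sum(areas.values())
    if total == 0:
        raise ValueError("total area zero: proportions undefined (missing)")
    return {ch: a / total for ch, a in areas.items()}


@dataclass(frozen=True)
class LabelStep:
    """One step of a labeling scheme.

    ``context`` is where the label is applied: ``native-exposed`` (intact
    complex), ``denatured-reduced`` (after denaturation + reduction) or
    ``post-electrophoresis`` (residual thiols after gel separation).
    """

    name: str
    label: str
    context: str
    reversible: bool = False
    displaced_by: str | None = None  # step name of the displacement label

    _CONTEXTS = ("native-exposed", "denatured-reduced", "post-electrophoresis")

    def __post_init__(self):
        if self.context not in self._CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")


@dataclass(frozen=True)
class LabelScheme:
    """Ordered labeling steps mapping channels to exposure classes."""

    name: str
    steps: tuple[LabelStep, ...]

    def __post_init__(self):
        steps = tuple(self.steps)
        object.__setattr__(self, "steps", steps)
        native = [s for s in steps if s.context == "native-exposed"]
        if len(native) != 1:
            raise ValueError("exactly one step must target native-exposed thiols")
        if steps[-1].context == "native-exposed":
            raise ValueError(
                "final step must follow denaturation+reduction or electrophoresis"
            )
        if native[0].reversible:
            if native[0].displaced_by is None:
                raise ValueError(
                    "a reversible (MMTS) first step must name its displacement step"
                )
            if native[0].displaced_by not in {s.name for s in steps}:
                raise ValueError(
                    f"displacement step {native[0].displaced_by!r} not in scheme"
                )

    @property
    def channel_classes(self) -> dict[str, str]:
        """Map observable channel (step name) -> exposure class.

        Classes: ``exposed-step1`` (reactive during the native step),
        ``occluded`` (labeled only after denaturation+reduction), and for
        three-step gel schemes ``exposed-on-deactivation`` (the
        intermediate channel, labeled only after deactivation).
        """
        native = next(s for s in self.steps if s.context == "native-exposed")
        native_channel = native.displaced_by if native.reversible else native.name
        observable = [
            s for s in self.steps if not s.reversible and s.name != native_channel
        ]
        classes = {native_channel: "exposed-step1"}
        if len(observable) == 1:
            classes[observable[0].name] = "occluded"
        elif len(observable) == 2:
            classes[observable[0].name] = "exposed-on-deactivation"
            classes[observable[1].name] = "occluded"
        else:
            raise ValueError("scheme must yield 2 or 3 observable channels")
        return classes

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelScheme":
        spec = json.loads(Path(path).read_text())
        steps = tuple(LabelStep(**s) for s in spec["steps"])
        return cls(spec["name"], steps)


def _two_label(name: str, first: str, second: str) -> LabelScheme:
    return LabelScheme(
        name,
        (
            LabelStep(first, first, "native-exposed"),
            LabelStep(second, second, "denatured-reduced"),
        ),
    )


#: Built-in schemes.
SCHEMES: dict[str, LabelScheme] = {
    "two-label": _two_label("two-label", "IAM-light", "IAM-heavy"),
    "two-label-swapped": _two_label("two-label-swapped", "IAM-heavy", "IAM-light"),
    "nem": _two_label("nem", "NEM", "d5-NEM"),
    "tpp": _two_label("tpp", "TPP-IAM", "d15-TPP-IAM"),
    "mmts": LabelScheme(
        "mmts",
        (
            LabelStep(
                "MMTS", "MMTS", "native-exposed",
                reversible=True, displaced_by="IAM-light",
            ),
            LabelStep("IAM-light", "IAM-light", "denatured-reduced"),
            LabelStep("IAM-heavy", "IAM-heavy", "denatured-reduced"),
        ),
    ),
    "three-label": LabelScheme(
        "three-label",
        (
            LabelStep("IAM-light", "IAM-light", "native-exposed"),
            LabelStep("IAM-heavy", "IAM-heavy", "denatured-reduced"),
            LabelStep("NEM", "NEM", "post-electrophoresis"),
        ),
    ),
}


@dataclass
class ExposureResult:
    """Per-species channel proportions and the derived exposed fraction."""

    species_id: str
    proportions: dict[str, float]
    class_proportions: dict[str, float]
    exposed_fraction: float
    replicate_count: int = 1
    standard_error: float = float("nan")

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"channel proportions sum to {total}, expected 1")
        if not 0.0 <= self.exposed_fraction <= 1.0:
            raise ValueError("exposed fraction outside [0, 1]")


def resolve_scheme(
    scheme: LabelScheme | str,
    proportions: Mapping[str, float],
    species_id: str = "",
) -> ExposureResult:
    """Map channel proportions to exposure classes under ``scheme``.

    Every channel in ``proportions`` must be produced by a scheme step.
    The exposed fraction is the ``exposed-step1`` class proportion.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    classes = scheme.channel_classes
    unknown = set(proportions) - set(classes)
    if unknown:
        raise ValueError(
            f"channels {sorted(unknown)} have no generating step in "
            f"scheme {scheme.name!r}"
        )
    class_props = {cls: 0.0 for cls in classes.values()}
    for ch, p in proportions.items():
        class_props[classes[ch]] += p
    return ExposureResult(
        species_id=species_id,
        proportions=dict(proportions),
        class_proportions=class_props,
        exposed_fraction=class_props["exposed-step1"],
    )


def exposure_from_table(
    table: pd.DataFrame,
    scheme: LabelScheme | str = "two-label",
) -> pd.DataFrame:
    """Per-species exposure from a peak-area table.

    ``table`` columns: species_id, channel, replicate, area.  Exposure is
    computed per replicate, then averaged; dispersion is the standard error
    across replicates.  Replicates with zero total area are dropped as
    missing.
    """
    required = {"species_id", "channel", "replicate", "area"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    rows = []
    for species, sdf in table.groupby("species_id", sort=True):
        fractions = []
        pooled: dict[str, float] = {}
        for _, rdf in sdf.groupby("replicate"):
            areas = rdf.groupby("channel")["area"].sum().to_dict()
            for ch, a in areas.items():
                pooled[ch] = pooled.get(ch, 0.0) + a
            if sum(areas.values()) == 0:
                continue  # missing replicate
            props = channel_proportions(areas)
            fractions.append(resolve_scheme(scheme, props, species).exposed_fraction)
        if not fractions:
            continue
        n = len(fractions)
        mean = float(np.mean(fractions))
        sem = float(np.std(fractions, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        result = resolve_scheme(scheme, channel_proportions(pooled), species)
        row = {
            "species_id": species,
            "exposed_fraction": mean,
            "standard_error": sem,
            "replicate_count": n,
        }
        for cls, p in result.class_proportions.items():
            row[f"pooled:{cls}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of response ratio (analyte/IS area) vs known amount."""

    amounts: tuple[float, ...]
    ratios: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if not math.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 outside [0, 1]")


def fit_standard_curve(
    known_amounts: Sequence[float], ratios: Sequence[float]
) -> StandardCurve:
    """Least-squares line through (amount, analyte/IS ratio) points."""
    x = np.asarray(known_amounts, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points to fit a standard curve")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate standards: all amounts equal")
    fit = stats.linregress(x, y)
    return StandardCurve(
        tuple(x), tuple(y), float(fit.slope), float(fit.intercept),
        float(fit.rvalue**2),
    )


def quantify(area: float, is_area: float, curve: StandardCurve) -> float:
    """Invert the standard curve: amount = (area/IS - intercept) / slope."""
    if is_area <= 0:
        raise ValueError("internal-standard area must be > 0")
    if curve.slope == 0:
        raise ValueError("standard curve has zero slope")
    return (area / is_area - curve.intercept) / curve.slope
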