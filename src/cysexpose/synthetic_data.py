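"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its arguments and seed (byte-identical
CSV/FASTA/PDB output for a fixed configuration) and returns its ground
truth alongside the data, so downstream stages can be scored
automatically.

Noise models: multiplicative log-normal for peak areas (MS-like),
additive Gaussian for absorbance/fluorescence traces.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ad_analysis, kinetics
from .kinetics import AssayConstants

__all__ = [
    "gen_peak_table",
    "gen_chromatograms",
    "gen_absorbance_traces",
    "gen_toy_complex",
    "gen_gsh_timecourse",
    "gen_amplex",
    "write_outputs",
]


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# peak-area tables
# ---------------------------------------------------------------------------

def gen_peak_table(
    true_fractions: Mapping[str, float],
    n_replicates: int = 6,
    cv: float = 0.05,
    seed: int = 0,
    mean_total_area: float = 1e6,
    total_cv: float = 0.3,
    first_channel: str = "IAM-light",
    second_channel: str = "IAM-heavy",
) -> tuple[pd.DataFrame, dict]:
    """Light/heavy peak areas with known ground-truth exposure fractions.

    Per replicate a total abundance is drawn (log-normal), split by the
    true fraction into first-/second-label channels, and each channel gets
    independent log-normal noise of coefficient of variation ``cv``.
    Swapping ``first_channel``/``second_channel`` emulates the interchanged
    isotope labeling order.
    """
    if any(not 0.0 <= f <= 1.0 for f in true_fractions.values()):
        raise ValueError("true fractions must lie in [0, 1]")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for condition in sorted(true_fractions):
        f = true_fractions[condition]
        totals = mean_total_area * _lognormal_factor(rng, total_cv, n_replicates)
        noise1 = _lognormal_factor(rng, cv, n_replicates)
        noise2 = _lognormal_factor(rng, cv, n_replicates)
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "species_id": condition,
                    "channel": first_channel,
                    "replicate": rep,
                    "area": totals[rep - 1] * f * noise1[rep - 1],
                }
            )
            rows.append(
                {
                    "species_id": condition,
                    "channel": second_channel,
                    "replicate": rep,
                    "area": totals[rep - 1] * (1.0 - f) * noise2[rep - 1],
                }
            )
    truth = {
        "true_fractions": dict(true_fractions),
        "cv": cv,
        "n_replicates": n_replicates,
        "first_channel": first_channel,
        "second_channel": second_channel,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# chromatograms
# ---------------------------------------------------------------------------

def gen_chromatograms(
    species: Sequence[Mapping],
    rt_span_min: tuple[float, float] = (0.0, 10.0),
    sampling_s: float = 1.0,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Centroided Gaussian elution peaks.

    ``species`` entries need keys mz, rt_min, sd_min, height (and
    optionally species_id).  Each species contributes one centroid per
    scan at its m/z; zero-height species are omitted entirely.  The
    programmed area of each peak is height * sd * sqrt(2*pi) (minutes
    basis).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(rt_span_min[0], rt_span_min[1] + 1e-9, sampling_s / 60.0)
    rows = []
    truth_areas = {}
    for i, sp in enumerate(species):
        height = float(sp["height"])
        if height == 0:
            continue
        name = str(sp.get("species_id", f"species{i}"))
        mu, sd = float(sp["rt_min"]), float(sp["sd_min"])
        signal = height * np.exp(-0.5 * ((t - mu) / sd) ** 2)
        signal = signal + baseline + rng.normal(0.0, noise_sd, t.size)
        signal = np.clip(signal, 0.0, None)
        for rt, inten in zip(t, signal):
            rows.append({"rt_min": rt, "mz": float(sp["mz"]), "intensity": inten})
        truth_areas[name] = height * sd * math.sqrt(2.0 * math.pi)
    df = pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"])
    df = df.sort_values(["rt_min", "mz"], kind="stable").reset_index(drop=True)
    return df, {"areas_min": truth_areas, "sampling_s": sampling_s}


# ---------------------------------------------------------------------------
# absorbance plates
# ---------------------------------------------------------------------------

def gen_absorbance_traces(
    ad_params: ad_analysis.ADKineticParams = ad_analysis.ADKineticParams(),
    rate_mM_min: float = 0.01,
    nadh0_mM: float = 0.5,
    background_rate: float = 0.0,
    noise_sd: float = 0.0,
    duration_min: float = 30.0,
    interval_s: float = 12.0,
    seed: int = 0,
    constants: AssayConstants = kinetics.DEFAULT_CONSTANTS,
    a380_offset: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """NADH-oxidation plate with active, deactive and rotenone wells.

    The active well starts all-A and the deactive well all-D, both with
    substrate present from t=0, so the deactive trace reactivates with the
    programmed lag ln(2)/k_a.  NADH consumption integrates
    rate * activity(t) + background; rotenone wells contain the background
    rate only.  Signals are A340 (with the A380 reference) under
    Beer-Lambert with the configured path.
    """
    rng = np.random.default_rng(seed)
    t_min = np.arange(0.0, duration_min + 1e-9, interval_s / 60.0)
    wells = {
        "active": (1.0, 0.0, rate_mM_min),
        "deactive": (0.0, 1.0, rate_mM_min),
        "rotenone": (1.0, 0.0, 0.0),
    }
    rows = []
    for condition, (a0, d0, rate) in wells.items():
        if rate > 0:
            traj = ad_analysis.simulate_ad(
                ad_params,
                dt=interval_s / 60.0,
                horizon=duration_min,
                initial=(a0, d0, 0.0, 0.0),
                substrate=True,
            )
            activity = np.interp(t_min, traj["time_min"], traj["activity"])
        else:
            activity = np.zeros_like(t_min)
        consumption = rate * activity + background_rate
        nadh = nadh0_mM - np.concatenate(
            [[0.0], np.cumsum((consumption[1:] + consumption[:-1]) / 2.0
                              * np.diff(t_min))]
        )
        nadh = np.clip(nadh, 0.0, None)
        a340 = (
            a380_offset
            + nadh * constants.eps_nadh_340_380 * constants.path_cm
            + rng.normal(0.0, noise_sd, t_min.size)
        )
        a380 = a380_offset + rng.normal(0.0, noise_sd, t_min.size)
        for ti, s340, s380 in zip(t_min, a340, a380):
            rows.append(
                {
                    "condition": condition,
                    "rotenone": condition == "rotenone",
                    "time_s": ti * 60.0,
                    "a340": s340,
                    "a380": s380,
                    "path_cm": constants.path_cm,
                    "replicate": 1,
                }
            )
    # programmed lag: time for the deactive well's rate (proportional to
    # activity = 1 - exp(-k_a t)) to reach half its horizon maximum
    if ad_params.k_a > 0:
        a_end = 1.0 - math.exp(-ad_params.k_a * duration_min)
        lag_min = -math.log(1.0 - 0.5 * a_end) / ad_params.k_a
    else:
        lag_min = None
    truth = {
        "rate_mM_min": rate_mM_min,
        "background_rate_mM_min": background_rate,
        "lag_min": lag_min,
        "interval_s": interval_s,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# toy complex: sequences, alignment, structures, annotations
# ---------------------------------------------------------------------------

_PHI = (1.0 + math.sqrt(5.0)) / 2.0
_ICOSAHEDRON = np.array(
    [
        [0, 1, _PHI], [0, -1, _PHI], [0, 1, -_PHI], [0, -1, -_PHI],
        [1, _PHI, 0], [-1, _PHI, 0], [1, -_PHI, 0], [-1, -_PHI, 0],
        [_PHI, 0, 1], [-_PHI, 0, 1], [_PHI, 0, -1], [-_PHI, 0, -1],
    ]
) / math.sqrt(1.0 + _PHI * _PHI)

# sequence filler residues: no C/K/R/P, so tryptic sites stay controlled
_FILLER = "ADEFGHILMNQSTVWY"


def _pdb_atom(serial, name, res_name, chain, res_id, xyz, element):
    # strict PDB columns: name 13-16, resName 18-20, chain 22, resSeq 23-26,
    # coordinates 31-54, element 77-78
    return (
        f"ATOM  {serial:5d} {name:<4s} {res_name:<3s} {chain}{res_id:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def _build_pdb(sites: Sequence[dict], buried_key: str) -> str:
    """One SG atom per engineered cysteine, caged at 2.5 A when buried."""
    lines = []
    serial = 1
    for i, site in enumerate(sites):
        center = np.array([20.0 * i, 0.0, 0.0])
        lines.append(
            _pdb_atom(serial, "SG", "CYS", site["subunit"], site["position"],
                      center, "S")
        )
        serial += 1
        if site[buried_key]:
            for vertex in _ICOSAHEDRON:
                lines.append(
                    _pdb_atom(serial, "C", "CAG", site["subunit"],
                              9000 + serial, center + 2.5 * vertex, "C")
                )
                serial += 1
    return "\n".join(lines) + "\nEND\n"


def gen_toy_complex(
    engineered_cys: Sequence[Mapping] | None = None,
    n_species: int = 3,
    subunit_length: int = 60,
    seed: int = 0,
) -> dict:
    """Toy multi-subunit complex with fully controlled ground truth.

    ``engineered_cys`` entries: subunit (single letter, also the PDB
    chain), position (1-based), conserved (bool), buried_active /
    buried_deactive (bool; a buried gamma-S is enclosed in an icosahedral
    atom cage at 2.5 A), annotation (survey annotation string), and
    optionally modeled_deactive=False to drop the site from the deactive
    structure (disordered-loop case).

    Returns a dict with sequences, per-subunit alignments, the two PDB
    strings, the annotation table and the ground truth.
    """
    if engineered_cys is None:
        engineered_cys = [
            {"subunit": "A", "position": 15, "conserved": True,
             "buried_active": True, "buried_deactive": False,
             "annotation": "none"},
            {"subunit": "A", "position": 39, "conserved": True,
             "buried_active": False, "buried_deactive": False,
             "annotation": "none"},
            {"subunit": "B", "position": 22, "conserved": False,
             "buried_active": True, "buried_deactive": True,
             "annotation": "none"},
            {"subunit": "B", "position": 47, "conserved": True,
             "buried_active": True, "buried_deactive": True,
             "annotation": "FeS-ligand"},
        ]
    rng = np.random.default_rng(seed)
    species = [f"sp{j}" for j in range(n_species)]
    reference = species[0]
    subunits = sorted({str(s["subunit"]) for s in engineered_cys})
    sequences: dict[str, str] = {}
    alignments: dict[str, dict[str, str]] = {}
    for su in subunits:
        sites = [s for s in engineered_cys if str(s["subunit"]) == su]
        base = list(rng.choice(list(_FILLER), size=subunit_length))
        # sprinkle tryptic sites away from the engineered positions
        blocked = {int(s["position"]) for s in sites}
        for pos in range(8, subunit_length, 9):
            if pos + 1 not in blocked and pos + 2 not in blocked:
                base[pos] = "K"
        per_species = {sp: list(base) for sp in species}
        for s in sites:
            pos = int(s["position"])
            if not 1 <= pos <= subunit_length:
                raise ValueError(f"engineered position {pos} outside subunit")
            for j, sp in enumerate(species):
                if sp == reference or s["conserved"]:
                    per_species[sp][pos - 1] = "C"
                else:
                    per_species[sp][pos - 1] = "S"
        alignments[su] = {sp: "".join(per_species[sp]) for sp in species}
        sequences[su] = alignments[su][reference]
    annotations = pd.DataFrame(
        [
            {
                "subunit": s["subunit"],
                "position": s["position"],
                "annotation": s.get("annotation", "none"),
            }
            for s in engineered_cys
        ]
    )
    modeled_deactive = [
        s for s in engineered_cys if s.get("modeled_deactive", True)
    ]
    truth = {
        "reference_species": reference,
        "species": species,
        "engineered": [dict(s) for s in engineered_cys],
    }
    return {
        "sequences": sequences,
        "alignments": alignments,
        "pdb_active": _build_pdb(list(engineered_cys), "buried_active"),
        "pdb_deactive": _build_pdb(modeled_deactive, "buried_deactive"),
        "annotations": annotations,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# GSH labeling and Amplex Red
# ---------------------------------------------------------------------------

def gen_gsh_timecourse(
    k_M_s: float = 0.25,
    iam_conc_M: float = 0.02,
    times_s: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Labeled GSH fraction following 1 - exp(-k*[IAM]*t) plus noise."""
    if times_s is None:
        times_s = np.arange(0.0, 901.0, 30.0)
    rng = np.random.default_rng(seed)
    t = np.asarray(times_s, dtype=float)
    f = 1.0 - np.exp(-k_M_s * iam_conc_M * t)
    f = np.clip(f + rng.normal(0.0, noise_sd, t.size), 0.0, 1.0)
    df = pd.DataFrame({"time_s": t, "labeled_fraction": f})
    return df, {"k_M_s": k_M_s, "iam_conc_M": iam_conc_M}


def gen_amplex(
    rates_uM_min: Mapping[str, float] | None = None,
    standard_concs_uM: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5),
    response_per_uM: float = 1000.0,
    duration_min: float = 20.0,
    interval_s: float = 12.0,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Amplex Red standards and fluorescence traces with programmed rates.

    Returns (standards, traces, truth); standards columns conc_uM/signal,
    traces columns condition/time_s/signal.
    """
    if rates_uM_min is None:
        rates_uM_min = {"active": 0.5, "deactive": 0.05}
    rng = np.random.default_rng(seed)
    concs = np.asarray(standard_concs_uM, dtype=float)
    std_signal = response_per_uM * concs * (
        1.0 + rng.normal(0.0, noise_frac, concs.size)
    )
    standards = pd.DataFrame({"conc_uM": concs, "signal": std_signal})
    t_min = np.arange(0.0, duration_min + 1e-9, interval_s / 60.0)
    rows = []
    for condition in sorted(rates_uM_min):
        rate = rates_uM_min[condition]
        signal = response_per_uM * rate * t_min
        signal = signal * (1.0 + rng.normal(0.0, noise_frac, t_min.size))
        for ti, si in zip(t_min, signal):
            rows.append(
                {"condition": condition, "time_s": ti * 60.0, "signal": si}
            )
    traces = pd.DataFrame(rows)
    truth = {
        "rates_uM_min": dict(rates_uM_min),
        "response_per_uM": response_per_uM,
    }
    return standards, traces, truth


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def _write_fasta(records: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def write_outputs(what: str, outdir: str | Path, seed: int = 0, **kwargs) -> list[Path]:
    """Generate one dataset family and write standard text formats.

    ``what`` is one of peaks, chromatograms, traces, complex, gsh, amplex.
    Every dataset gets a ``*_truth.json`` sidecar.  Output is
    byte-reproducible for a fixed seed and arguments.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_kw = {"index": False, "float_format": "%.10g"}
    written: list[Path] = []

    def emit_csv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, **csv_kw)
        written.append(path)

    def emit_truth(truth: dict, name: str) -> None:
        path = outdir / name
        path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
        written.append(path)

    if what == "peaks":
        df, truth = gen_peak_table(
            kwargs.pop("true_fractions", {"A-state": 0.65, "D-state": 0.93}),
            seed=seed, **kwargs,
        )
        emit_csv(df, "peak_areas.csv")
        emit_truth(truth, "peak_areas_truth.json")
    elif what == "chromatograms":
        df, truth = gen_chromatograms(
            kwargs.pop(
                "species",
                [
                    {"species_id": "light", "mz": 836.3570, "rt_min": 5.0,
                     "sd_min": 0.1, "height": 1000.0},
                    {"species_id": "heavy", "mz": 838.3667, "rt_min": 5.0,
                     "sd_min": 0.1, "height": 500.0},
                ],
            ),
            seed=seed, **kwargs,
        )
        emit_csv(df, "chromatogram.csv")
        emit_truth(truth, "chromatogram_truth.json")
    elif what == "traces":
        df, truth = gen_absorbance_traces(seed=seed, **kwargs)
        emit_csv(df, "nadh_traces.csv")
        emit_truth(truth, "nadh_traces_truth.json")
    elif what == "complex":
        out = gen_toy_complex(seed=seed, **kwargs)
        _write_fasta(out["sequences"], outdir / "reference.fasta")
        written.append(outdir / "reference.fasta")
        for su, aln in out["alignments"].items():
            _write_fasta(aln, outdir / f"alignment_{su}.fasta")
            written.append(outdir / f"alignment_{su}.fasta")
        (outdir / "active.pdb").write_text(out["pdb_active"])
        (outdir / "deactive.pdb").write_text(out["pdb_deactive"])
        written += [outdir / "active.pdb", outdir / "deactive.pdb"]
        emit_csv(out["annotations"], "annotations.csv")
        emit_truth(out["truth"], "complex_truth.json")
    elif what == "gsh":
        df, truth = gen_gsh_timecourse(seed=seed, **kwargs)
        emit_csv(df, "gsh_timecourse.csv")
        emit_truth(truth, "gsh_timecourse_truth.json")
    elif what == "amplex":
        standards, traces, truth = gen_amplex(seed=seed, **kwargs)
        emit_csv(standards, "amplex_standards.csv")
        emit_csv(traces, "amplex_traces.csv")
        emit_truth(truth, "amplex_truth.json")
    else:
        raise ValueError(
            "what must be one of peaks, chromatograms, traces, complex, gsh, amplex"
        )
    return written
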