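"""Comparative cysteine survey.

Combines four independent classifications of each cysteine in a protein
complex: cross-species conservation (from a consumed alignment), MS
detectability of its fully-tryptic peptide, solvent accessibility of the
gamma-sulfur atom in two structural states (Shrake-Rupley, 5 A^2 cutoff),
and functional annotation (FeS ligand, disulfide, targeting sequence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import peptide_chem as pc

__all__ = [
    "VDW_RADII",
    "SurveyParams",
    "CysteineRecord",
    "SurveySummary",
    "Structure",
    "map_conserved_cysteines",
    "classify_detectability",
    "sphere_points",
    "shrake_rupley_sasa",
    "gamma_s_sasa",
    "classify_exposure_states",
    "survey_summary",
    "run_survey",
]

#: Van der Waals radii (A); configurable via the ``radii`` arguments.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}


@dataclass(frozen=True)
class SurveyParams:
    """Thresholds of the survey classification rules."""

    sasa_cutoff: float = 5.0  # A^2, exposed means strictly greater
    probe_radius: float = 1.4  # A
    min_peptide_length: int = 7
    min_mh2: float = 400.0  # m/z of the doubly protonated peptide
    max_mass: float = 6000.0  # Da, monoisotopic
    max_cys_per_peptide: int = 3

    def __post_init__(self):
        for name in (
            "sasa_cutoff", "probe_radius", "min_peptide_length",
            "min_mh2", "max_mass", "max_cys_per_peptide",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CysteineRecord:
    """One cysteine of the survey, numbered in the precursor sequence."""

    subunit: str
    position: int  # 1-based, ungapped precursor coordinate
    conserved: bool | None = None
    annotation: str = "none"  # FeS-ligand|intramolecular-disulfide|targeting-sequence|none
    sasa_active: float | None = None
    sasa_deactive: float | None = None
    detectability: str = "detectable"  # or "undetectable:<reason>"
    exposed_fraction: float | None = None
    #: some MS evidence exists but exposure could not be quantified; such
    #: residues are unquantified candidates without belonging to the
    #: strict no-data pool
    has_partial_data: bool = False
    exposure_category: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("position must be >= 1")
        for s in (self.sasa_active, self.sasa_deactive):
            if s is not None and s < 0:
                raise ValueError("SASA must be >= 0")

    @property
    def quantified(self) -> bool:
        return self.exposed_fraction is not None


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

def map_conserved_cysteines(
    alignment: Mapping[str, str],
    reference_species: str,
    subject_species: Sequence[str] | None = None,
    subunit: str = "",
) -> list[CysteineRecord]:
    """Locate reference cysteines and test conservation per column.

    ``alignment`` maps species id -> gapped sequence (all equal length,
    ``-`` for gaps).  A cysteine is conserved iff every subject species has
    ``C`` in the homologous column.  Positions are reported in ungapped
    reference coordinates (1-based).
    """
    if reference_species not in alignment:
        raise ValueError(f"reference {reference_species!r} absent from alignment")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences have unequal lengths")
    if subject_species is None:
        subject_species = [s for s in alignment if s != reference_species]
    missing = set(subject_species) - set(alignment)
    if missing:
        raise ValueError(f"subject species absent from alignment: {sorted(missing)}")
    ref = alignment[reference_species].upper()
    records = []
    ungapped = 0
    for col, aa in enumerate(ref):
        if aa == "-":
            continue
        ungapped += 1
        if aa != "C":
            continue
        conserved = all(
            alignment[sp][col].upper() == "C" for sp in subject_species
        )
        records.append(
            CysteineRecord(subunit=subunit, position=ungapped, conserved=conserved)
        )
    return records


# ---------------------------------------------------------------------------
# detectability
# ---------------------------------------------------------------------------

def classify_detectability(
    protein_sequence: str,
    cys_position: int,
    params: SurveyParams = SurveyParams(),
) -> str:
    """Detectability of the fully-tryptic peptide containing the site.

    Rules, applied in order to the 0-missed-cleavage peptide: length < 7,
    MH2+ < 400 m/z (with carbamidomethyl on all cysteines), monoisotopic
    mass > 6000 Da, more than 3 cysteines.  Returns ``"detectable"`` or
    ``"undetectable:<reason>"``; a detectable peptide with 2-3 cysteines is
    flagged ``"detectable:multi-cys"`` (not site-resolvable by peak area).
    """
    if not 1 <= cys_position <= len(protein_sequence):
        raise ValueError("cys_position outside sequence")
    if protein_sequence[cys_position - 1] != "C":
        raise ValueError(
            f"position {cys_position} is {protein_sequence[cys_position - 1]!r}, not C"
        )
    peptide = next(
        p
        for p in pc.digest(protein_sequence, 0)
        if p.start <= cys_position <= p.end
    )
    n_cys = peptide.sequence.count("C")
    cam = {site: "IAM-light" for site in peptide.cysteine_sites}
    mass = pc.peptide_mass(peptide.sequence, cam)
    if len(peptide) < params.min_peptide_length:
        return "undetectable:length"
    if pc.mz(mass, 2) < params.min_mh2:
        return "undetectable:mz"
    if mass > params.max_mass:
        return "undetectable:mass"
    if n_cys > params.max_cys_per_peptide:
        return "undetectable:cys-count"
    return "detectable:multi-cys" if n_cys > 1 else "detectable"


# ---------------------------------------------------------------------------
# solvent accessibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Structure:
    """Minimal atomic structure: names, elements, residues, coordinates."""

    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    chains: tuple[str, ...]
    res_names: tuple[str, ...]
    res_ids: tuple[int, ...]
    coords: np.ndarray  # (n, 3)

    @classmethod
    def from_pdb(cls, path: str | Path) -> "Structure":
        """Parse ATOM/HETATM records; element from columns 77-78 with
        fallback to the first letter of the atom name."""
        names, elements, chains, res_names, res_ids, xyz = [], [], [], [], [], []
        for line in Path(path).read_text().splitlines():
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            name = line[12:16].strip()
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = name[:1]
            names.append(name)
            elements.append(element.upper())
            chains.append(line[21])
            res_names.append(line[17:20].strip())
            res_ids.append(int(line[22:26]))
            xyz.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        return cls(
            tuple(names), tuple(elements), tuple(chains), tuple(res_names),
            tuple(res_ids), np.asarray(xyz, dtype=float).reshape(-1, 3),
        )

    def __len__(self) -> int:
        return len(self.atom_names)


def sphere_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit-sphere points (golden-spiral lattice)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    atom_indices: Sequence[int] | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2).

    For each atom, test points are placed on a sphere of radius
    ``r_atom + probe``; SASA = 4*pi*(r+probe)^2 * (fraction of points not
    inside any neighbor's expanded sphere).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    atom_indices = (
        list(range(len(coords))) if atom_indices is None else list(atom_indices)
    )
    unit = sphere_points(n_points)
    expanded = radii + probe_radius
    out = np.zeros(len(atom_indices))
    for k, i in enumerate(atom_indices):
        r = expanded[i]
        pts = coords[i] + r * unit
        # candidate occluders: centers within r + neighbor radius
        d_centers = np.linalg.norm(coords - coords[i], axis=1)
        neighbor = (d_centers < r + expanded) & (d_centers > 0)
        accessible = np.ones(len(pts), dtype=bool)
        for j in np.flatnonzero(neighbor):
            d = np.linalg.norm(pts[accessible] - coords[j], axis=1)
            keep = d >= expanded[j]
            idx = np.flatnonzero(accessible)
            accessible[idx[~keep]] = False
            if not accessible.any():
                break
        out[k] = 4.0 * math.pi * r * r * accessible.mean()
    return out


def gamma_s_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: Mapping[str, float] | None = None,
) -> dict[tuple[str, int], float]:
    """SASA of every cysteine gamma-sulfur (SG) atom in ``structure``.

    Returns ``{(chain, residue id): area}``; empty when the structure
    contains no cysteine sulfur.  Unknown elements default to carbon.
    """
    table = dict(VDW_RADII)
    if radii:
        table.update(radii)
    atom_radii = np.array(
        [table.get(el, table["C"]) for el in structure.elements]
    )
    targets = [
        i
        for i in range(len(structure))
        if structure.res_names[i] == "CYS"
        and structure.atom_names[i] == "SG"
        and structure.elements[i] == "S"
    ]
    if not targets:
        return {}
    areas = shrake_rupley_sasa(
        structure.coords, atom_radii, targets, probe_radius, n_sphere_points
    )
    return {
        (structure.chains[i], structure.res_ids[i]): float(a)
        for i, a in zip(targets, areas)
    }


def classify_exposure_states(
    sasa_active: float | None,
    sasa_deactive: float | None,
    cutoff: float = 5.0,
) -> dict:
    """Label each structural state exposed/occluded at ``cutoff``.

    Exposed means SASA strictly greater than the cutoff.  An unmodeled
    (``None``) residue in the deactive structure counts as exposed
    (disordered-loop convention); the candidate pattern is occluded in the
    active state AND exposed in the deactive state.
    """
    def state(sasa: float | None, unmodeled_exposed: bool) -> str:
        if sasa is None:
            return "exposed" if unmodeled_exposed else "unmodeled"
        return "exposed" if sasa > cutoff else "occluded"

    active = state(sasa_active, unmodeled_exposed=False)
    deactive = state(sasa_deactive, unmodeled_exposed=True)
    candidate = active == "occluded" and deactive == "exposed"
    return {"active": active, "deactive": deactive, "candidate_pattern": candidate}


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def _pct(num: int, den: int) -> float | None:
    """One-decimal percentage, or None for an empty denominator."""
    if den == 0:
        return None
    return round(100.0 * num / den, 1)


@dataclass(frozen=True)
class SurveySummary:
    """Count cascade and one-decimal percentages of the survey."""

    total: int
    conserved: int
    quantified: int
    no_data: int
    fes_no_data: int
    disulfide_no_data: int
    undetectable_no_data: int
    candidates: int
    fes_or_disulfide_candidates: int

    @property
    def pct_quantified(self) -> float | None:
        """Quantified share of conserved residues."""
        return _pct(self.quantified, self.conserved)

    @property
    def pct_fes_no_data(self) -> float | None:
        return _pct(self.fes_no_data, self.no_data)

    @property
    def pct_disulfide_no_data(self) -> float | None:
        return _pct(self.disulfide_no_data, self.no_data)

    @property
    def pct_undetectable_no_data(self) -> float | None:
        return _pct(self.undetectable_no_data, self.no_data)

    @property
    def pct_candidates(self) -> float | None:
        """Unquantified candidate share of conserved residues."""
        return _pct(self.candidates, self.conserved)

    @property
    def pct_fes_or_disulfide_candidates(self) -> float | None:
        return _pct(self.fes_or_disulfide_candidates, self.candidates)

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in self.__dataclass_fields__.values()  # type: ignore[attr-defined]
        }
        for name in dir(self):
            if name.startswith("pct_"):
                d[name] = getattr(self, name)
        return d


def survey_summary(records: Sequence[CysteineRecord]) -> SurveySummary:
    """Aggregate records into the survey count cascade.

    ``candidates`` are conserved residues left unquantified; ``no_data``
    is the stricter subset of candidates without even partial MS evidence
    (``has_partial_data`` distinguishes the two).  Percentages use the
    denominators of the cascade: quantified and candidates against
    conserved, the no-data breakdowns against no-data, and the
    FeS-or-disulfide share against candidates.
    """
    total = len(records)
    conserved = [r for r in records if r.conserved]
    quantified = [r for r in conserved if r.quantified]
    candidates = [r for r in conserved if not r.quantified]
    no_data = [r for r in candidates if not r.has_partial_data]
    fes = [r for r in no_data if r.annotation == "FeS-ligand"]
    ss = [r for r in no_data if r.annotation == "intramolecular-disulfide"]
    undet = [r for r in no_data if r.detectability.startswith("undetectable")]
    fes_or_ss = [
        r
        for r in candidates
        if r.annotation in ("FeS-ligand", "intramolecular-disulfide")
    ]
    return SurveySummary(
        total=total,
        conserved=len(conserved),
        quantified=len(quantified),
        no_data=len(no_data),
        fes_no_data=len(fes),
        disulfide_no_data=len(ss),
        undetectable_no_data=len(undet),
        candidates=len(candidates),
        fes_or_disulfide_candidates=len(fes_or_ss),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_survey(
    sequences: Mapping[str, str],
    alignments: Mapping[str, Mapping[str, str]],
    reference_species: str,
    active_structure: Structure | None = None,
    deactive_structure: Structure | None = None,
    annotations: pd.DataFrame | None = None,
    exposure: Mapping[tuple[str, int], float] | None = None,
    params: SurveyParams = SurveyParams(),
) -> list[CysteineRecord]:
    """End-to-end survey over a set of subunits.

    ``sequences`` maps subunit -> reference precursor sequence;
    ``alignments`` maps subunit -> per-species gapped sequences.  The
    optional structures are matched by (chain == subunit, residue id ==
    precursor position).  ``annotations`` columns: subunit, position,
    annotation.  ``exposure`` maps (subunit, position) -> measured
    fraction.
    """
    ann: dict[tuple[str, int], str] = {}
    if annotations is not None:
        for _, row in annotations.iterrows():
            ann[(str(row["subunit"]), int(row["position"]))] = str(row["annotation"])
    sasa_a = (
        gamma_s_sasa(active_structure, params.probe_radius)
        if active_structure is not None
        else {}
    )
    sasa_d = (
        gamma_s_sasa(deactive_structure, params.probe_radius)
        if deactive_structure is not None
        else {}
    )
    records: list[CysteineRecord] = []
    for subunit, seq in sequences.items():
        recs = map_conserved_cysteines(
            alignments[subunit], reference_species, subunit=subunit
        )
        for rec in recs:
            key = (subunit, rec.position)
            rec.annotation = ann.get(key, "none")
            rec.detectability = classify_detectability(seq, rec.position, params)
            rec.sasa_active = sasa_a.get(key)
            rec.sasa_deactive = sasa_d.get(key)
            if active_structure is not None or deactive_structure is not None:
                rec.exposure_category = classify_exposure_states(
                    rec.sasa_active, rec.sasa_deactive, params.sasa_cutoff
                )
            if exposure is not None:
                rec.exposed_fraction = exposure.get(key)
            records.append(rec)
    return records


def records_to_frame(records: Sequence[CysteineRecord]) -> pd.DataFrame:
    """Flatten records for CSV export."""
    rows = []
    for r in records:
        rows.append(
            {
                "subunit": r.subunit,
                "position": r.position,
                "conserved": r.conserved,
                "annotation": r.annotation,
                "detectability": r.detectability,
                "sasa_active": r.sasa_active,
                "sasa_deactive": r.sasa_deactive,
                "state_active": r.exposure_category.get("active"),
                "state_deactive": r.exposure_category.get("deactive"),
                "candidate_pattern": r.exposure_category.get("candidate_pattern"),
                "exposed_fraction": r.exposed_fraction,
            }
        )
    return pd.DataFrame(rows)
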