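"""Peptide mass arithmetic with isotope-coded thiol labels.

Monoisotopic masses are computed from a single embedded atomic-mass table.
Isotope species are keyed ``"C"``, ``"13C"``, ``"H"``, ``"2H"`` etc.; the
bare element symbol denotes the most abundant (default) isotope.  All m/z
values use a proton mass of 1.00728 Da, i.e. ``(M + z * 1.00728) / z``.

Note on the TPP adduct: the triphenylphosphonium label carries an intrinsic
positive charge, but its printed composition (C25H27NOP) is treated here as
a neutral mass delta and protonated like any other species.  This convention
reproduces reference values to four decimals; the physically strict cation
convention does not.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ATOMIC_MASSES",
    "RESIDUE_FORMULAS",
    "PROTON_MASS",
    "WATER",
    "ElementalComposition",
    "LabelDefinition",
    "LABELS",
    "Peptide",
    "LabeledPeptideSpecies",
    "compose_mass",
    "residue_mass",
    "peptide_mass",
    "mz",
    "digest",
    "fragment_mz",
    "transition_list",
]

PROTON_MASS = 1.00728

#: Monoisotopic masses, Da.  Bare symbols are the default isotope.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.0078250,
    "2H": 2.0141018,
    "C": 12.0,
    "13C": 13.0033548,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.9720707,
    "P": 30.9737615,
}

#: Residue (i.e. dehydrated) elemental formulas of the 20 amino acids.
RESIDUE_FORMULAS: dict[str, str] = {
    "G": "C2 H3 N O",
    "A": "C3 H5 N O",
    "S": "C3 H5 N O2",
    "P": "C5 H7 N O",
    "V": "C5 H9 N O",
    "T": "C4 H7 N O2",
    "C": "C3 H5 N O S",
    "L": "C6 H11 N O",
    "I": "C6 H11 N O",
    "N": "C4 H6 N2 O2",
    "D": "C4 H5 N O3",
    "Q": "C5 H8 N2 O2",
    "K": "C6 H12 N2 O",
    "E": "C5 H7 N O3",
    "M": "C5 H9 N O S",
    "H": "C6 H7 N3 O",
    "F": "C9 H9 N O",
    "R": "C6 H12 N4 O",
    "Y": "C9 H9 N O2",
    "W": "C11 H10 N2 O",
}

AMINO_ACIDS = frozenset(RESIDUE_FORMULAS)

_TOKEN = re.compile(r"(\d*)([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """Signed multiset of isotope species, e.g. ``{"C": 2, "H": 3, ...}``.

    Supports element-wise addition/subtraction and scalar multiplication.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {k: int(v) for k, v in self.counts.items() if v != 0}
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, formula: str) -> "ElementalComposition":
        """Parse formulas like ``"C2 H3 N O"`` or ``"13C2 2H2 H N O"``.

        A leading integer marks a fixed mass number (isotope), a trailing
        integer the atom count.  Tokens may be whitespace-separated or run
        together (``"C2H3NO"``).
        """
        counts: dict[str, int] = {}
        pos = 0
        for token in formula.split():
            pos = 0
            while pos < len(token):
                m = _TOKEN.match(token, pos)
                if m is None or m.group(2) == "":
                    raise ValueError(f"cannot parse formula token {token!r}")
                isotope, element, count = m.groups()
                key = (isotope + element) if isotope else element
                counts[key] = counts.get(key, 0) + (int(count) if count else 1)
                pos = m.end()
        return cls(counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for k, v in other.counts.items():
            merged[k] = merged.get(k, 0) + v
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for k, v in other.counts.items():
            merged[k] = merged.get(k, 0) - v
        return ElementalComposition(merged)

    def __mul__(self, n: int) -> "ElementalComposition":
        return ElementalComposition({k: v * n for k, v in self.counts.items()})

    __rmul__ = __mul__

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da (0.0 for the empty composition)."""
        return compose_mass(self)


def compose_mass(composition: ElementalComposition) -> float:
    """Monoisotopic mass of ``composition`` in Da.

    Raises :class:`KeyError` naming the offending key for any isotope
    species absent from :data:`ATOMIC_MASSES`.
    """
    total = 0.0
    for key, count in composition.counts.items():
        if key not in ATOMIC_MASSES:
            raise KeyError(f"unknown element/isotope key: {key!r}")
        total += ATOMIC_MASSES[key] * count
    return total


WATER = ElementalComposition.parse("H2 O")

_RESIDUE_COMPOSITIONS = {
    aa: ElementalComposition.parse(f) for aa, f in RESIDUE_FORMULAS.items()
}
_RESIDUE_MASSES = {aa: c.mass for aa, c in _RESIDUE_COMPOSITIONS.items()}


def residue_mass(aa: str) -> float:
    """Monoisotopic residue (dehydrated) mass of a one-letter amino acid."""
    try:
        return _RESIDUE_MASSES[aa]
    except KeyError:
        raise ValueError(f"unknown amino acid: {aa!r}") from None


@dataclass(frozen=True)
class LabelDefinition:
    """A thiol-directed chemical label.

    ``delta`` is the neutral composition added to the cysteine thiol; it is
    ``None`` for the reversible MMTS blocker, which is displaced before MS
    analysis and never observed as a labeled species.
    """

    name: str
    delta: ElementalComposition | None
    channel: str  # "light" | "heavy" | "other"
    reversible: bool = False
    heavy_counterpart: str | None = None
    target_residue: str = "C"

    @property
    def mass(self) -> float:
        if self.delta is None:
            raise ValueError(
                f"label {self.name!r} is reversible and has no MS-observable delta"
            )
        return self.delta.mass


def _label(name, formula, channel, heavy=None, reversible=False):
    delta = None if formula is None else ElementalComposition.parse(formula)
    return LabelDefinition(name, delta, channel, reversible, heavy)


#: Built-in label registry.
LABELS: dict[str, LabelDefinition] = {
    lab.name: lab
    for lab in [
        _label("IAM-light", "C2 H3 N O", "light", heavy="IAM-heavy"),
        _label("IAM-heavy", "13C2 2H2 H N O", "heavy"),
        _label("NEM", "C6 H7 N O2", "light", heavy="d5-NEM"),
        _label("d5-NEM", "C6 2H5 H2 N O2", "heavy"),
        _label("TPP-IAM", "C25 H27 N O P", "light", heavy="d15-TPP-IAM"),
        _label("d15-TPP-IAM", "C25 H12 2H15 N O P", "heavy"),
        _label("MMTS", None, "other", reversible=True),
    ]
}


def _resolve_label(label: str | LabelDefinition) -> LabelDefinition:
    if isinstance(label, LabelDefinition):
        return label
    try:
        return LABELS[label]
    except KeyError:
        raise KeyError(
            f"unknown label {label!r}; registered: {sorted(LABELS)}"
        ) from None


@dataclass(frozen=True)
class Peptide:
    """A (tryptic) peptide located in its precursor protein.

    Coordinates are 1-based and inclusive in the complete precursor
    sequence, so ``end - start + 1 == len(sequence)``.
    """

    sequence: str
    protein_id: str = ""
    start: int = 1
    end: int = 0
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"invalid residues in sequence: {sorted(bad)}")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"coordinates {self.start}-{self.end} inconsistent with "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cysteine_sites(self) -> tuple[int, ...]:
        """1-based positions (within the peptide) of cysteine residues."""
        return tuple(i + 1 for i, aa in enumerate(self.sequence) if aa == "C")


def peptide_mass(
    sequence: str | Peptide,
    site_labels: Mapping[int, str | LabelDefinition] | None = None,
) -> float:
    """Neutral monoisotopic mass: residue sum + water + label deltas.

    ``site_labels`` maps 1-based positions *within the peptide* to labels;
    every labeled position must be a cysteine.
    """
    seq = sequence.sequence if isinstance(sequence, Peptide) else sequence
    if not seq:
        raise ValueError("empty sequence")
    mass = sum(residue_mass(aa) for aa in seq) + WATER.mass
    for pos, label in (site_labels or {}).items():
        if not 1 <= pos <= len(seq):
            raise ValueError(f"label position {pos} outside peptide (1-{len(seq)})")
        if seq[pos - 1] != "C":
            raise ValueError(
                f"label assigned to non-cysteine residue {seq[pos - 1]!r} at {pos}"
            )
        mass += _resolve_label(label).mass
    return mass


def mz(neutral_mass: float, z: int) -> float:
    """m/z of the z-fold protonated species, ``(M + z*1.00728)/z``."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * PROTON_MASS) / z


@dataclass(frozen=True)
class LabeledPeptideSpecies:
    """A peptide with per-site label assignment and a charge state."""

    peptide: Peptide
    site_labels: Mapping[int, LabelDefinition] = field(default_factory=dict)
    charge: int = 2

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        resolved = {p: _resolve_label(l) for p, l in self.site_labels.items()}
        object.__setattr__(self, "site_labels", resolved)
        self.neutral_mass  # validate label placement eagerly

    @property
    def neutral_mass(self) -> float:
        return peptide_mass(self.peptide, self.site_labels)

    @property
    def mz(self) -> float:
        return mz(self.neutral_mass, self.charge)

    def with_labels(
        self, labels: Mapping[int, str | LabelDefinition]
    ) -> "LabeledPeptideSpecies":
        return replace(self, site_labels=dict(labels))


def digest(
    protein_sequence: str,
    missed_cleavages_max: int = 0,
    protein_id: str = "",
) -> list[Peptide]:
    """In-silico tryptic digestion.

    Cleaves C-terminal to K or R, suppressed when the next residue is P.
    Emits every peptide with 0..``missed_cleavages_max`` missed cleavages,
    ordered by start coordinate then length.
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    if missed_cleavages_max < 0:
        raise ValueError("missed_cleavages_max must be >= 0")
    seq = protein_sequence
    # cut points: index i means a cut between seq[i-1] and seq[i]
    cuts = [0]
    for i in range(1, len(seq)):
        if seq[i - 1] in "KR" and seq[i] != "P":
            cuts.append(i)
    cuts.append(len(seq))
    peptides = []
    for a, start in enumerate(cuts[:-1]):
        for b in range(a + 1, min(a + 2 + missed_cleavages_max, len(cuts))):
            end = cuts[b]
            peptides.append(
                Peptide(
                    seq[start:end],
                    protein_id=protein_id,
                    start=start + 1,
                    end=end,
                    missed_cleavages=b - a - 1,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def fragment_mz(
    species: LabeledPeptideSpecies, series: str, index: int, z: int = 1
) -> float:
    """m/z of the ``y``/``b`` fragment ion of length ``index``.

    y_n: C-terminal n residues + water + z protons.
    b_n: N-terminal n residues + z protons.
    Site labels are included when the labeled residue falls inside the
    fragment.
    """
    if series not in ("y", "b"):
        raise ValueError(f"fragment series must be 'y' or 'b', got {series!r}")
    length = len(species.peptide)
    if not 1 <= index < length:
        raise ValueError(f"fragment index {index} out of range 1..{length - 1}")
    seq = species.peptide.sequence
    if series == "y":
        sub = seq[length - index :]
        positions = range(length - index + 1, length + 1)
        neutral = sum(residue_mass(aa) for aa in sub) + WATER.mass
    else:
        sub = seq[:index]
        positions = range(1, index + 1)
        neutral = sum(residue_mass(aa) for aa in sub)
    for pos, label in species.site_labels.items():
        if pos in positions:
            neutral += label.mass
    return mz(neutral, z)


def transition_list(
    peptide: str | Peptide,
    label_sets: Iterable[Mapping[int, str | LabelDefinition]] | None = None,
    precursor_z: int = 2,
    fragment_series: str = "y",
    fragment_index: int | None = None,
    fragment_z: int = 2,
    labels: Iterable[str] | None = None,
    species_names: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Build an MRM transition table (computed, not instrument-tuned).

    Either pass ``label_sets`` (one site->label mapping per channel row) or
    ``labels`` (label names applied to every cysteine of a single-cysteine
    peptide).  Columns: species, label, z, precursor_mz, product_mz.
    """
    pep = peptide if isinstance(peptide, Peptide) else Peptide(peptide)
    if label_sets is None:
        if labels is None:
            label_sets = []
        else:
            sites = pep.cysteine_sites
            label_sets = [{s: name for s in sites} for name in labels]
    label_sets = list(label_sets)
    if fragment_index is None:
        fragment_index = len(pep) - 2  # y_{L-2} mirrors the reference design
    rows = []
    names = list(species_names) if species_names is not None else None
    for i, assignment in enumerate(label_sets):
        sp = LabeledPeptideSpecies(pep, dict(assignment), precursor_z)
        label_names = "+".join(
            sorted({_resolve_label(l).name for l in assignment.values()})
        )
        rows.append(
            {
                "species": names[i] if names else f"{pep.sequence}/{label_names}",
                "label": label_names,
                "z": precursor_z,
                "precursor_mz": round(sp.mz, 4),
                "product_mz": round(
                    fragment_mz(sp, fragment_series, fragment_index, fragment_z), 4
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["species", "label", "z", "precursor_mz", "product_mz"]
    )


def brute_force_digest_count(sequence: str, missed: int) -> int:
    """Enumeration oracle: count peptides with exactly ``missed`` missed
    cleavages by enumerating all contiguous runs between cut sites.

    Independent of :func:`digest`; intended for testing on short sequences.
    """
    sites = [
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in "KR" and sequence[i] != "P"
    ]
    boundaries = [0, *sites, len(sequence)]
    count = 0
    for a, b in itertools.combinations(range(len(boundaries)), 2):
        if b - a - 1 == missed:
            count += 1
    return count
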