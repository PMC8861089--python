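"""Accurate-mass lipid annotation.

Chemical-formula arithmetic (monoisotopic masses), adduct m/z computation with
the electron mass accounted for, ppm scoring, and matching of feature m/z lists
against a lipid reference table.

The bundled reference contains the differential microglia lipid markers
(LysoPC, PC, SM, Cer/HexCer, DG, TG species) together with the phospholipid
calibrants used for internal lock-mass recalibration; a user-supplied CSV with
the same columns can extend or replace it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

# --------------------------------------------------------------------------
# Element masses (IUPAC monoisotopic, Da) and adduct deltas
# --------------------------------------------------------------------------

ELEMENT_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.9637064864,
}

ELECTRON_MASS = 0.00054857990907
PROTON_MASS = ELEMENT_MASS["H"] - ELECTRON_MASS  # 1.00727645...
WATER_MASS = 2 * ELEMENT_MASS["H"] + ELEMENT_MASS["O"]  # 18.0105646...

#: Mass delta added to the neutral monoisotopic mass, and ion charge.
#: Cation deltas subtract one electron mass; [M-H]- adds one.
ADDUCT_DELTAS: dict[str, tuple[float, int]] = {
    "M+H": (PROTON_MASS, +1),
    "M+Na": (ELEMENT_MASS["Na"] - ELECTRON_MASS, +1),
    "M+K": (ELEMENT_MASS["K"] - ELECTRON_MASS, +1),
    "M+H-H2O": (PROTON_MASS - WATER_MASS, +1),
    "M-H": (-PROTON_MASS, -1),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a molecular formula like ``C40H80NO8P`` into element counts."""
    if not text or not text.strip():
        raise ValidationError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValidationError(
                f"malformed formula {text!r} at position {pos}: {text[pos:]!r}"
            )
        element, digits = m.group(1), m.group(2)
        if element not in ELEMENT_MASS:
            raise ValidationError(
                f"unknown element {element!r} in formula {text!r} at position {m.start()}"
            )
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise ValidationError(
            f"malformed formula {text!r} at position {pos}: {text[pos:]!r}"
        )
    return counts


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Neutral monoisotopic mass in Da of a formula string or element-count map."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return float(sum(ELEMENT_MASS[el] * n for el, n in counts.items()))


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """Theoretical m/z of an adduct ion of a neutral of given monoisotopic mass.

    The electron mass is included in every delta (required to reproduce
    literature theoretical m/z at the 4th decimal).
    """
    if adduct not in ADDUCT_DELTAS:
        raise ValidationError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCT_DELTAS)}"
        )
    delta, charge = ADDUCT_DELTAS[adduct]
    return (neutral_mass + delta) / abs(charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValidationError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LipidSpecies:
    """A neutral reference lipid."""

    name: str
    lipid_class: str
    formula: str
    source: str = ""

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class AdductIon:
    """A charged adduct form of a reference lipid with its theoretical m/z."""

    species: LipidSpecies
    adduct: str
    charge: int = field(default=1)
    mz_theoretical: float = field(default=0.0)

    @classmethod
    def from_species(cls, species: LipidSpecies, adduct: str) -> "AdductIon":
        mz = adduct_mz(species.monoisotopic_mass, adduct)
        charge = ADDUCT_DELTAS[adduct][1]
        return cls(species=species, adduct=adduct, charge=charge, mz_theoretical=mz)

    @property
    def label(self) -> str:
        # "M+K" -> "[PC(16:0/16:0)+K]+"
        return f"[{self.species.name}{self.adduct[1:]}]{'+' if self.charge > 0 else '-'}"


@dataclass(frozen=True)
class Annotation:
    """A candidate assignment of a feature m/z, ranked by |ppm error|."""

    feature_mz: float
    candidate: AdductIon | None
    error_ppm: float | None
    rank: int = 0

    @property
    def assigned(self) -> bool:
        return self.candidate is not None


# --------------------------------------------------------------------------
# Reference table
# --------------------------------------------------------------------------


def load_reference_table(path=None) -> pd.DataFrame:
    """Load the lipid reference table (bundled one if ``path`` is None).

    Columns: name, lipid_class, formula, adduct plus, for marker rows, the
    literature values (TOF m/z, adjusted P, log2FC, printed theoretical m/z,
    observed high-resolution m/z, printed ppm, 1/K0, CCS).
    """
    if path is None:
        with resources.files("lipidfinger.data").joinpath("lipid_reference.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    required = {"name", "lipid_class", "formula", "adduct"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"reference table missing columns: {sorted(missing)}")
    return table


def reference_ions(table: pd.DataFrame | None = None) -> list[AdductIon]:
    """Materialize AdductIon records (with computed theoretical m/z) from a table."""
    if table is None:
        table = load_reference_table()
    ions = []
    for row in table.itertuples(index=False):
        species = LipidSpecies(
            name=row.name, lipid_class=row.lipid_class, formula=row.formula
        )
        ions.append(AdductIon.from_species(species, row.adduct))
    return ions


def match_features(
    features: Sequence[float],
    reference: Iterable[AdductIon] | None = None,
    tol_ppm: float = 1.0,
) -> list[Annotation]:
    """Match feature m/z values against reference adduct ions within ``tol_ppm``.

    Every candidate within tolerance is reported, ranked by |ppm error|
    (rank 0 = best). Features with no candidate yield a single unassigned
    Annotation. Matching is order-independent and deterministic.
    """
    ref = list(reference) if reference is not None else reference_ions()
    if not ref:
        raise ValidationError("reference table is empty")
    ref_mz = np.array([ion.mz_theoretical for ion in ref])
    annotations: list[Annotation] = []
    for fmz in features:
        err = (fmz - ref_mz) / ref_mz * 1e6
        idx = np.flatnonzero(np.abs(err) <= tol_ppm)
        if idx.size == 0:
            annotations.append(Annotation(feature_mz=float(fmz), candidate=None, error_ppm=None))
            continue
        order = idx[np.argsort(np.abs(err[idx]), kind="stable")]
        for rank, j in enumerate(order):
            annotations.append(
                Annotation(
                    feature_mz=float(fmz),
                    candidate=ref[j],
                    error_ppm=float(err[j]),
                    rank=rank,
                )
            )
    return annotations


def annotation_table(annotations: Sequence[Annotation]) -> pd.DataFrame:
    """Tabulate annotations with one row per (feature, candidate)."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "feature_mz": a.feature_mz,
                "assignment": a.candidate.label if a.candidate else "unassigned",
                "lipid_name": a.candidate.species.name if a.candidate else "",
                "lipid_class": a.candidate.species.lipid_class if a.candidate else "",
                "adduct": a.candidate.adduct if a.candidate else "",
                "mz_theoretical": round(a.candidate.mz_theoretical, 4) if a.candidate else np.nan,
                "error_ppm": round(a.error_ppm, 1) if a.error_ppm is not None else np.nan,
                "rank": a.rank,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_mz",
            "assignment",
            "lipid_name",
            "lipid_class",
            "adduct",
            "mz_theoretical",
            "error_ppm",
            "rank",
        ],
    )
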