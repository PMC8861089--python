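"""Rule-based MS/MS interpretation for choline- and sphingoid-containing lipids.

Predicts class- and adduct-specific diagnostic fragments (neutral losses of
trimethylamine and choline phosphate, the protonated phosphocholine headgroup
at m/z 184.0733, cyclophosphane-alkali ions, water losses, sphingoid-base
ions) and scores observed MS2 peak lists against them.

Confirmation logic: predictions carry a ``required_group`` label; a candidate
is confirmed when every required group has at least one matched prediction.
For protonated PC/LysoPC ions the headgroup ion and the choline phosphate
neutral loss are interchangeable evidence; for alkali adducts the
cyclophosphane-alkali ion takes the headgroup's place.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotate import (
    ELECTRON_MASS,
    ELEMENT_MASS,
    PROTON_MASS,
    WATER_MASS,
    AdductIon,
    monoisotopic_mass,
)
from .errors import ValidationError

# Diagnostic masses (Da / Th), all from formula arithmetic
NL_TRIMETHYLAMINE = monoisotopic_mass("C3H9N")  # 59.0735
NL_CHOLINE_PHOSPHATE = monoisotopic_mass("C5H14NO4P")  # 183.0660
HEADGROUP_ION = monoisotopic_mass("C5H14NO4P") + PROTON_MASS  # 184.0733
CYCLOPHOSPHANE = monoisotopic_mass("C2H5O4P")  # 123.9925
CYCLOPHOSPHANE_NA = CYCLOPHOSPHANE + ELEMENT_MASS["Na"] - ELECTRON_MASS  # 146.9818
CYCLOPHOSPHANE_K = CYCLOPHOSPHANE + ELEMENT_MASS["K"] - ELECTRON_MASS  # 162.9557

# Sphingoid d18:1 base ions: [sphingosine + H - H2O]+ and [... - 2 H2O]+
SPHINGOSINE = monoisotopic_mass("C18H37NO2")
BASE_D181_MINUS_H2O = SPHINGOSINE + PROTON_MASS - WATER_MASS  # 282.2791
BASE_D181_MINUS_2H2O = SPHINGOSINE + PROTON_MASS - 2 * WATER_MASS  # 264.2686

SUPPORTED_CLASSES = {"PC", "LysoPC", "SM", "Cer"}

_CHAIN = re.compile(r"(?:^|/)(?:d)?(?:O-)?(\d+):(\d+)")


@dataclass(frozen=True)
class FragmentPrediction:
    """A predicted fragment or neutral-loss product ion."""

    description: str
    mz_pred: float
    kind: str  # neutral-loss | diagnostic-ion | water-loss | base-ion | acyl-informative
    required: bool = False
    required_group: str = ""


@dataclass
class MsmsMatch:
    """Result of scoring an observed MS2 peak list against predictions."""

    matched: list[tuple[FragmentPrediction, float]] = field(default_factory=list)
    unmatched: list[FragmentPrediction] = field(default_factory=list)
    tol: float = 0.05
    score: float = 0.0
    confirmed: bool = False


def predict_fragments(candidate: AdductIon) -> list[FragmentPrediction]:
    """Predict diagnostic fragments for a candidate adduct ion.

    Classes with no specific positive-mode fragment rules here (DG, TG,
    HexCer: identified at the MS1 level) return an empty list.
    """
    cls = candidate.species.lipid_class
    if cls not in SUPPORTED_CLASSES:
        return []
    precursor = candidate.mz_theoretical
    adduct = candidate.adduct
    preds: list[FragmentPrediction] = []

    def nl(description: str, loss: float, **kw) -> None:
        preds.append(FragmentPrediction(description, precursor - loss, "neutral-loss", **kw))

    if cls in ("PC", "LysoPC"):
        nl("neutral loss of trimethylamine", NL_TRIMETHYLAMINE,
           required=True, required_group="nl59")
        nl("neutral loss of choline phosphate", NL_CHOLINE_PHOSPHATE,
           required=True, required_group="headgroup")
        if adduct in ("M+H", "M+H-H2O"):
            preds.append(FragmentPrediction(
                "phosphocholine headgroup ion", HEADGROUP_ION, "diagnostic-ion",
                required=True, required_group="headgroup"))
        elif adduct == "M+Na":
            preds.append(FragmentPrediction(
                "cyclophosphane + Na ion", CYCLOPHOSPHANE_NA, "diagnostic-ion",
                required=True, required_group="headgroup"))
        elif adduct == "M+K":
            preds.append(FragmentPrediction(
                "cyclophosphane + K ion", CYCLOPHOSPHANE_K, "diagnostic-ion",
                required=True, required_group="headgroup"))
        if cls == "LysoPC":
            preds.append(FragmentPrediction(
                "water loss", precursor - WATER_MASS, "water-loss"))
    elif cls == "SM":
        preds.append(FragmentPrediction(
            "phosphocholine headgroup ion", HEADGROUP_ION, "diagnostic-ion",
            required=True, required_group="headgroup"))
        preds.append(FragmentPrediction("water loss", precursor - WATER_MASS, "water-loss"))
        nl("neutral loss of trimethylamine", NL_TRIMETHYLAMINE)
        nl("neutral loss of choline phosphate", NL_CHOLINE_PHOSPHATE)
        if "d18:1" in candidate.species.name:
            preds.append(FragmentPrediction(
                "sphingoid base ion (d18:1, -2 H2O)", BASE_D181_MINUS_2H2O, "base-ion"))
    elif cls == "Cer":
        preds.append(FragmentPrediction(
            "water loss", precursor - WATER_MASS, "water-loss",
            required=True, required_group="waterloss"))
        if "d18:1" in candidate.species.name:
            preds.append(FragmentPrediction(
                "sphingoid base ion (d18:1, -H2O)", BASE_D181_MINUS_H2O, "base-ion"))
            preds.append(FragmentPrediction(
                "sphingoid base ion (d18:1, -2 H2O)", BASE_D181_MINUS_2H2O, "base-ion"))
    return [p for p in preds if 0 < p.mz_pred]


def acyl_fragments(candidate: AdductIon) -> list[FragmentPrediction]:
    """Optional acyl-chain-informative fragments for chain-resolved PC/LysoPC names.

    For each fatty acyl chain, losses of the free fatty acid and of its ketene
    from the precursor and from the choline-phosphate-loss ion. Sum-composition
    names (no chain split) yield an empty list. Never required for confirmation.
    """
    if candidate.species.lipid_class not in ("PC", "LysoPC"):
        return []
    name = candidate.species.name
    inner = name[name.find("(") + 1 : name.rfind(")")] if "(" in name else ""
    if "/" not in inner:
        return []
    chains = [(int(c), int(d)) for c, d in _CHAIN.findall(inner)]
    chains = [(c, d) for c, d in chains if c > 0]
    precursor = candidate.mz_theoretical
    preds: list[FragmentPrediction] = []
    seen: set[tuple[str, float]] = set()
    for carbons, dbonds in chains:
        n_h = 2 * carbons - 2 * dbonds  # free fatty acid CnH(2n-2d)O2
        fa = carbons * ELEMENT_MASS["C"] + n_h * ELEMENT_MASS["H"] + 2 * ELEMENT_MASS["O"]
        ketene = fa - WATER_MASS
        chain = f"C{carbons}:{dbonds}"
        for desc, loss in (
            (f"loss of fatty acid {chain}", fa),
            (f"loss of ketene {chain}", ketene),
            (f"loss of choline phosphate + fatty acid {chain}", NL_CHOLINE_PHOSPHATE + fa),
            (f"loss of choline phosphate + ketene {chain}", NL_CHOLINE_PHOSPHATE + ketene),
        ):
            mz = precursor - loss
            key = (desc, round(mz, 6))
            if mz > 0 and key not in seen:
                seen.add(key)
                preds.append(FragmentPrediction(desc, mz, "acyl-informative"))
    return preds


def match_msms(
    predictions: Sequence[FragmentPrediction],
    observed_mz: Sequence[float],
    tol: float = 0.05,
) -> MsmsMatch:
    """Match predictions against an observed MS2 peak list (m/z values).

    ``tol`` is an absolute m/z window (0.05 Th suits high-resolution spectra,
    0.3 Th TOF MS/MS). Score = fraction of required evidence groups matched;
    confirmed = all required groups matched. Monotone: adding observed peaks
    never lowers the score.
    """
    obs = np.sort(np.asarray(list(observed_mz), dtype=float))
    if obs.size == 0:
        raise ValidationError("observed MS2 peak list is empty")
    result = MsmsMatch(tol=tol)
    matched_groups: set[str] = set()
    all_groups = {p.required_group for p in predictions if p.required}
    for pred in predictions:
        i = np.searchsorted(obs, pred.mz_pred)
        best = None
        for j in (i - 1, i):
            if 0 <= j < obs.size and abs(obs[j] - pred.mz_pred) <= tol:
                if best is None or abs(obs[j] - pred.mz_pred) < abs(best - pred.mz_pred):
                    best = float(obs[j])
        if best is not None:
            result.matched.append((pred, best))
            if pred.required:
                matched_groups.add(pred.required_group)
        else:
            result.unmatched.append(pred)
    if all_groups:
        result.score = len(matched_groups) / len(all_groups)
        result.confirmed = matched_groups == all_groups
    else:
        any_matched = len(result.matched) > 0
        result.score = 1.0 if any_matched else 0.0
        result.confirmed = False  # nothing can be confirmed without required rules
    return result
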