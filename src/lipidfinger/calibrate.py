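"""Internal mass recalibration.

Quadratic lock-mass correction for TOF spectra (fit in the m/z domain:
reference = c0 + c1*obs + c2*obs^2 through >= 3 matched lock masses) and
single-point scale correction for ultra-high-resolution peak lists.

Default positive-mode lock masses are the phospholipid calibrants
LysoPC(16:0) [M+H]+ and PC(34:1) [M+H]+/[M+Na]+/[M+K]+, at full-precision
theoretical m/z from the annotation module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotate import AdductIon, LipidSpecies
from .errors import CalibrationError, ValidationError
from .spectra_io import Peak, PeakList, Spectrum

logger = logging.getLogger("lipidfinger")

#: TOF pre-calibration errors reach a few hundred ppm; the high-resolution
#: single-point correction instead uses the 5 ppm window of its instrument.
DEFAULT_TOF_TOL_PPM = 200.0
DEFAULT_HIRES_TOL_PPM = 5.0


@dataclass(frozen=True)
class LockMass:
    name: str
    mz_ref: float
    tol_ppm: float = DEFAULT_TOF_TOL_PPM

    def __post_init__(self) -> None:
        if self.mz_ref <= 0 or self.tol_ppm <= 0:
            raise ValidationError("lock mass m/z and tolerance must be positive")


def _calibrant(name: str, lipid_class: str, formula: str, adduct: str,
               tol_ppm: float = DEFAULT_TOF_TOL_PPM) -> LockMass:
    ion = AdductIon.from_species(LipidSpecies(name, lipid_class, formula), adduct)
    return LockMass(name=ion.label, mz_ref=ion.mz_theoretical, tol_ppm=tol_ppm)


def default_lock_masses(tol_ppm: float = DEFAULT_TOF_TOL_PPM) -> list[LockMass]:
    """LysoPC(16:0)+H and PC(34:1)+H/+Na/+K, positive mode."""
    return [
        _calibrant("LysoPC(16:0/0:0)", "LysoPC", "C24H50NO7P", "M+H", tol_ppm),
        _calibrant("PC(34:1)", "PC", "C42H82NO8P", "M+H", tol_ppm),
        _calibrant("PC(34:1)", "PC", "C42H82NO8P", "M+Na", tol_ppm),
        _calibrant("PC(34:1)", "PC", "C42H82NO8P", "M+K", tol_ppm),
    ]


@dataclass
class CalibrationModel:
    """m/z correction m' = c0 + c1*m + c2*m^2 with post-fit lock residuals."""

    kind: str  # "quadratic" | "single-point" | "identity"
    coefficients: tuple[float, float, float]
    residuals_ppm: dict[str, float] = field(default_factory=dict)

    def correct(self, mz) -> np.ndarray:
        c0, c1, c2 = self.coefficients
        mz = np.asarray(mz, dtype=float)
        return c0 + c1 * mz + c2 * mz**2

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(kind="identity", coefficients=(0.0, 1.0, 0.0))


def match_lock_masses(
    peaklist: PeakList, locks: list[LockMass]
) -> list[tuple[float, LockMass]]:
    """Pair each lock mass with the nearest peak inside its ppm window.

    Locks with no peak in the window are omitted; exact-distance ties go to
    the higher-intensity peak.
    """
    if len(peaklist) == 0:
        raise CalibrationError("cannot match lock masses against an empty peak list")
    matches = []
    for lock in locks:
        window = lock.mz_ref * lock.tol_ppm * 1e-6
        best: Peak | None = None
        for p in peaklist:
            d = abs(p.mz - lock.mz_ref)
            if d > window:
                continue
            if (
                best is None
                or d < abs(best.mz - lock.mz_ref)
                or (d == abs(best.mz - lock.mz_ref) and p.intensity > best.intensity)
            ):
                best = p
        if best is not None:
            matches.append((best.mz, lock))
        else:
            logger.info("lock mass %s (%.4f) not matched", lock.name, lock.mz_ref)
    return matches


def fit_quadratic(matches: list[tuple[float, LockMass]]) -> CalibrationModel:
    """Least-squares quadratic correction through >= 3 matched lock masses."""
    if len(matches) < 3:
        raise CalibrationError(
            f"quadratic calibration needs >= 3 lock-mass matches, got {len(matches)}"
        )
    obs = np.array([m for m, _ in matches])
    ref = np.array([lk.mz_ref for _, lk in matches])
    if np.unique(obs).size < 3:
        raise CalibrationError("rank-deficient design: duplicate observed m/z")
    design = np.column_stack([np.ones_like(obs), obs, obs**2])
    coeffs, *_ = np.linalg.lstsq(design, ref, rcond=None)
    model = CalibrationModel(kind="quadratic", coefficients=tuple(coeffs))
    corrected = model.correct(obs)
    model.residuals_ppm = {
        lk.name: float((c - lk.mz_ref) / lk.mz_ref * 1e6)
        for c, (_, lk) in zip(corrected, matches)
    }
    return model


def single_point_calibrate(
    peaklist: PeakList, lock: LockMass
) -> CalibrationModel:
    """Pure scale correction c1 = mz_ref / observed from one lock mass."""
    matches = match_lock_masses(peaklist, [lock])
    if not matches:
        raise CalibrationError(
            f"lock mass {lock.name} ({lock.mz_ref:.4f}) not found within "
            f"{lock.tol_ppm:g} ppm; calibration skipped"
        )
    observed = matches[0][0]
    model = CalibrationModel(
        kind="single-point", coefficients=(0.0, lock.mz_ref / observed, 0.0)
    )
    corrected = float(model.correct(observed))
    model.residuals_ppm = {lock.name: (corrected - lock.mz_ref) / lock.mz_ref * 1e6}
    return model


def apply_calibration(obj: Spectrum | PeakList, model: CalibrationModel):
    """Map every m/z through the correction, preserving order and type."""
    if isinstance(obj, Spectrum):
        corrected = model.correct(obj.mz)
        if np.any(np.diff(corrected) <= 0):
            raise CalibrationError("calibration model is non-monotone over this spectrum")
        if "calibrated" in obj.provenance:
            logger.warning("spectrum %s already calibrated; applying again", obj.sample_id)
        return obj.with_(mz=corrected, provenance=obj.provenance + ("calibrated",))
    if isinstance(obj, PeakList):
        corrected = model.correct(obj.mz)
        if corrected.size > 1 and np.any(np.diff(corrected) <= 0):
            raise CalibrationError("calibration model is non-monotone over this peak list")
        peaks = [
            Peak(mz=float(m), intensity=p.intensity, snr=p.snr)
            for m, p in zip(corrected, obj.peaks)
        ]
        return PeakList(peaks=peaks, source=obj.source)
    raise ValidationError(f"cannot calibrate object of type {type(obj).__name__}")
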