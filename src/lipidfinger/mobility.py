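"""Trapped-ion-mobility support.

Mason-Schamp conversion between reduced ion mobility (1/K0, V.s/cm^2) and
collisional cross section (CCS, A^2), a linear TIMS calibration against tuning
mix reference ions, and CCS agreement checks.

The conversion assumes a singly-to-lowly charged ion drifting in a neutral
buffer gas (N2 by default) at low field, where

    CCS = (3 z e)/(16 N0) * sqrt(2 pi / (mu kB T)) * (1/K0)

with reduced mass mu = m M_gas/(m + M_gas) and N0 the Loschmidt number
(gas number density at 273.15 K, 101325 Pa). The default effective drift-gas
temperature is 305 K, validated by a one-parameter fit against the bundled
lipid marker reference (``fit_default_temperature``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

# Physical constants (CODATA)
BOLTZMANN = 1.380649e-23  # J/K
ELEMENTARY_CHARGE = 1.602176634e-19  # C
LOSCHMIDT = 2.6867811e25  # m^-3
DALTON = 1.66053906660e-27  # kg

N2_MASS = 28.0134  # Da
DEFAULT_TEMPERATURE = 305.0  # K

#: ESI LC/MS tuning mix reference ions used for linear TIMS calibration:
#: (m/z, reference CCS in A^2), positive mode, N2.
TUNING_MIX: tuple[tuple[float, float], ...] = (
    (118.0862, 120.8),
    (322.0481, 152.8),
    (622.0289, 201.6),
    (922.0097, 241.8),
)


def ccs_from_k0(
    mz: float,
    charge: int = 1,
    inv_k0: float = 1.0,
    gas_mass: float = N2_MASS,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Convert reduced inverse mobility (V.s/cm^2) to CCS (A^2).

    ``mz`` is the observed mass-to-charge; the ion mass is ``mz * |charge|``.
    """
    mz = float(mz)
    if mz <= 0 or inv_k0 <= 0 or gas_mass <= 0 or temperature <= 0 or charge == 0:
        raise ValidationError("mz, charge, 1/K0, gas mass and temperature must be positive")
    z = abs(int(charge))
    ion_mass = mz * z
    mu = ion_mass * gas_mass / (ion_mass + gas_mass) * DALTON
    prefactor = (3.0 * z * ELEMENTARY_CHARGE) / (16.0 * LOSCHMIDT)
    thermal = np.sqrt(2.0 * np.pi / (mu * BOLTZMANN * temperature))
    inv_k0_si = inv_k0 * 1e4  # V.s/cm^2 -> V.s/m^2
    ccs_m2 = prefactor * thermal * inv_k0_si
    return float(ccs_m2 * 1e20)  # m^2 -> A^2


def k0_inverse_from_ccs(
    mz: float,
    charge: int = 1,
    ccs: float = 1.0,
    gas_mass: float = N2_MASS,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Invert Mason-Schamp: CCS (A^2) -> reduced inverse mobility (V.s/cm^2)."""
    unit = ccs_from_k0(mz, charge, 1.0, gas_mass, temperature)
    return float(ccs / unit)


@dataclass
class MobilityRecord:
    """An ion with measured reduced mobility and derived CCS."""

    mz: float
    charge: int = 1
    inv_k0: float = 0.0
    gas_mass: float = N2_MASS
    temperature: float = DEFAULT_TEMPERATURE
    ccs: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.inv_k0 <= 0:
            raise ValidationError("1/K0 must be positive")
        if not self.ccs:
            self.ccs = ccs_from_k0(
                self.mz, self.charge, self.inv_k0, self.gas_mass, self.temperature
            )


def fit_default_temperature(
    records: Sequence[tuple[float, float, float]],
    gas_mass: float = N2_MASS,
) -> tuple[float, np.ndarray]:
    """Fit the effective drift-gas temperature from (m/z, 1/K0, reference CCS) triples.

    CCS is proportional to T**-0.5 at fixed mobility, so the least-squares
    temperature has the closed form s* = sum(A c)/sum(A^2), T = s***-2 with
    A_i the T-independent part of each conversion. Returns the fitted T (K)
    and the per-record CCS residuals (A^2) at that T.
    """
    if len(records) < 3:
        raise ValidationError("need at least 3 records to fit the temperature")
    amp = np.array(
        [ccs_from_k0(mz, 1, ik0, gas_mass, temperature=1.0) for mz, ik0, _ in records]
    )
    ccs_ref = np.array([c for _, _, c in records], dtype=float)
    if np.any(ccs_ref <= 0) or np.allclose(amp, 0):
        raise ValidationError("degenerate records")
    s = float(np.dot(amp, ccs_ref) / np.dot(amp, amp))  # s = T**-0.5
    temperature = s**-2
    residuals = amp * s - ccs_ref
    return temperature, residuals


@dataclass
class TimsCalibration:
    """Linear map from the instrument mobility scale to 1/K0.

    ``references`` are (raw instrument mobility value, reference 1/K0) pairs;
    reference CCS values are converted to 1/K0 by inverting Mason-Schamp
    before fitting.
    """

    slope: float
    intercept: float
    residuals: np.ndarray

    @classmethod
    def fit(
        cls,
        raw_values: Sequence[float],
        references: Sequence[tuple[float, float]],
        charge: int = 1,
        gas_mass: float = N2_MASS,
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> "TimsCalibration":
        """Fit from raw mobility readings of reference ions given as (m/z, CCS)."""
        raw = np.asarray(raw_values, dtype=float)
        if raw.size < 2 or len(references) != raw.size:
            raise ValidationError("need >= 2 reference ions with one raw value each")
        if np.ptp(raw) == 0:
            raise ValidationError("identical raw mobility values: rank-deficient fit")
        target = np.array(
            [
                k0_inverse_from_ccs(mz, charge, ccs, gas_mass, temperature)
                for mz, ccs in references
            ]
        )
        slope, intercept = np.polyfit(raw, target, 1)
        residuals = (slope * raw + intercept) - target
        return cls(slope=float(slope), intercept=float(intercept), residuals=residuals)

    def apply(self, raw_values) -> np.ndarray:
        return self.slope * np.asarray(raw_values, dtype=float) + self.intercept


def ccs_deviation(ccs_obs: float, ccs_ref: float) -> float:
    """Percent deviation of an observed CCS from a reference value."""
    if ccs_ref <= 0:
        raise ValidationError("reference CCS must be positive")
    return 100.0 * (ccs_obs - ccs_ref) / ccs_ref
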