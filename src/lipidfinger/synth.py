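"""Synthetic whole-cell MALDI fingerprint spectra with known ground truth.

Emulates positive-mode profile TOF spectra in m/z 300-1800 at resolving power
~10,000: Gaussian peaks with C-13/H-2/N-15 binomial isotope envelopes, a
smooth exponential baseline, half-normal shot noise, per-spectrum total-ion-
current variability, a small quadratic mass miscalibration, and
group-dependent log2 fold-change effects on a subset of panel lipids.

The experiment layout mirrors the study design being emulated: a vehicle
group versus treated groups with 6 biological x 4 technical replicates,
biological replicates sharing a lognormal effect (sigma 0.3 in log2 units)
on which technical replicates add smaller jitter (sigma 0.1), chosen so the
default technical-replicate Pearson correlation lands in the observed ~0.9
regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import AdductIon, LipidSpecies, parse_formula, reference_ions
from .errors import ValidationError
from .spectra_io import Spectrum

# Heavy-isotope abundance and the shift applied per nominal mass unit
# (C-13 dominated; envelopes aggregated on the +k*1.003355 Da lattice).
ISOTOPE_ABUNDANCE = {"C": 0.0107, "H": 0.000115, "N": 0.003642}
C13_SHIFT = 1.0033548378


def isotope_envelope(formula: str, n_peaks: int = 3) -> list[tuple[float, float]]:
    """Approximate isotope envelope as (mass offset Da, relative abundance) pairs.

    Binomial C-13/H-2/N-15 convolution truncated at ``n_peaks``, offsets on
    the C-13 lattice, abundances normalized to max = 1. Adequate at TOF
    resolving power where fine structure is unresolved.
    """
    if n_peaks < 1:
        raise ValidationError("n_peaks must be >= 1")
    counts = parse_formula(formula)
    dist = np.zeros(n_peaks)
    dist[0] = 1.0
    for element, n in counts.items():
        p = ISOTOPE_ABUNDANCE.get(element, 0.0)
        if p == 0.0 or n == 0:
            continue
        # binomial pmf for number of heavy atoms of this element, truncated
        k = np.arange(n_peaks)
        pmf = np.zeros(n_peaks)
        from scipy.stats import binom

        pmf[: min(n_peaks, n + 1)] = binom.pmf(k[: min(n_peaks, n + 1)], n, p)
        dist = np.convolve(dist, pmf)[:n_peaks]
    dist /= dist.max()
    return [(k * C13_SHIFT, float(a)) for k, a in enumerate(dist)]


@dataclass
class SynthConfig:
    """Generator parameters; defaults encode the emulated study conditions."""

    mz_range: tuple[float, float] = (300.0, 1800.0)
    resolution: float = 10000.0
    grid_step: float = 0.01
    lipid_panel: list[tuple[AdductIon, float]] = field(default_factory=list)
    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    groups: tuple[str, ...] = ("vehicle", "treated")
    n_bio: int = 6
    n_tech: int = 4
    tic_cv: float = 0.15
    baseline_amp: float = 2.0
    baseline_decay: float = 300.0
    noise_sd: float = 0.05
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sigma_bio_log2: float = 0.3
    sigma_tech_log2: float = 0.1
    n_isotope_peaks: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0 or self.grid_step <= 0:
            raise ValidationError("resolution and grid step must be positive")
        if self.tic_cv < 0:
            raise ValidationError("tic_cv must be non-negative")
        if self.n_bio < 2:
            raise ValidationError("need n_bio >= 2 for any group used in testing")
        if not self.lipid_panel:
            self.lipid_panel = default_panel()
        if not self.group_effects:
            self.group_effects = default_group_effects(self.groups, self.lipid_panel)
        unknown = set(self.group_effects) - set(self.groups)
        if unknown:
            raise ValidationError(f"group_effects for undeclared groups: {sorted(unknown)}")

    def panel_keys(self) -> list[str]:
        return [ion.label for ion, _ in self.lipid_panel]


def background_ions(
    n: int = 60,
    mz_range: tuple[float, float] = (310.0, 1750.0),
    min_separation: float = 3.5,
    seed: int = 7,
) -> list[tuple[AdductIon, float]]:
    """Unannotated background lipid peaks emulating whole-cell complexity.

    Whole-cell fingerprints carry hundreds of features beyond the assigned
    markers; without them TIC normalization would couple the marker effects
    to the normalizer. Positions avoid a ``min_separation`` window around
    every bundled reference ion (and each other); abundances are lognormal.
    The internal seed is fixed so the background is part of the panel
    definition, not of the per-experiment randomness.
    """
    rng = np.random.default_rng(seed)
    taken = [ion.mz_theoretical for ion in reference_ions()]
    out: list[tuple[AdductIon, float]] = []
    while len(out) < n:
        mz = float(rng.uniform(*mz_range))
        if any(abs(mz - t) < min_separation for t in taken):
            continue
        taken.append(mz)
        # approximate lipid elemental composition at this mass for the envelope
        carbons = max(10, int(round(mz * 0.066)))
        hydrogens = max(20, int(round(carbons * 1.9)))
        formula = f"C{carbons}H{hydrogens}O6"
        species = LipidSpecies(
            name=f"background_{len(out)}", lipid_class="unknown", formula=formula
        )
        ion = AdductIon(species=species, adduct="M+H", charge=1, mz_theoretical=mz)
        abundance = float(rng.lognormal(mean=-1.0, sigma=0.8))
        out.append((ion, abundance))
    return out


def default_panel() -> list[tuple[AdductIon, float]]:
    """Bundled reference ions plus background peaks, deterministic abundances.

    Marker/calibrant base abundances cycle over a plausible dynamic range
    (x1 to x8) so the panel spans weak and strong peaks.
    """
    ions = reference_ions()
    levels = (1.0, 2.0, 4.0, 8.0, 3.0, 6.0)
    panel = [(ion, levels[i % len(levels)]) for i, ion in enumerate(ions)]
    return panel + background_ions()


def default_group_effects(
    groups: Sequence[str], panel: Sequence[tuple[AdductIon, float]],
    log2fc: float = 2.0,
) -> dict[str, dict[str, float]]:
    """Spike a strong effect on every other marker lipid per non-control group.

    The default |log2FC| = 2 sits at the top of the effect range whole-cell
    fingerprinting is meant to flag, large enough that the 6-vs-6 biological
    design detects the spikes reliably. The first group is the unspiked
    control; calibrant ions never receive an effect (they anchor the
    lock-mass recalibration) and background ions never do either.
    """
    calibrant_names = {"PC(34:1)"}
    effects: dict[str, dict[str, float]] = {}
    marker_keys = [
        ion.label
        for ion, _ in panel
        if ion.species.name not in calibrant_names
        and ion.species.lipid_class != "unknown"
    ]
    for group in groups[1:]:
        effects[group] = {key: log2fc for key in marker_keys[::2]}
    return effects


@dataclass
class GroundTruth:
    """Per-lipid theoretical m/z and effects plus per-spectrum factors."""

    lipids: pd.DataFrame  # key, mz_theoretical, base_abundance, log2fc_<group>...
    spectra: pd.DataFrame  # sample_id, group, bio_rep, tech_rep, tic_factor, drift a0,a1,a2

    def to_csv(self, lipids_path, spectra_path) -> None:
        self.lipids.to_csv(lipids_path, index=False)
        self.spectra.to_csv(spectra_path, index=False)


def _apply_drift(mz: np.ndarray | float, drift: tuple[float, float, float]):
    a0, a1, a2 = drift
    return mz * (1.0 + (a0 + a1 * mz + a2 * mz**2) * 1e-6)


def simulate_spectrum(
    truth_peaks: Sequence[tuple[float, float]],
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Render (m/z, abundance) stick peaks as a profile spectrum.

    Gaussian peaks of FWHM = m/z / resolution on a uniform grid, plus an
    exponential baseline and non-negative half-normal noise; peak positions
    are warped by the quadratic ppm drift m' = m (1 + (a0 + a1 m + a2 m^2) 1e-6).
    Apex intensity is proportional to abundance.
    """
    lo, hi = cfg.mz_range
    for mz0, _ in truth_peaks:
        if not lo <= mz0 <= hi:
            raise ValidationError(f"peak m/z {mz0} outside range {cfg.mz_range}")
    grid = np.arange(lo, hi + cfg.grid_step / 2, cfg.grid_step)
    signal = np.zeros_like(grid)
    fwhm_to_sigma = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    for mz0, abundance in truth_peaks:
        center = _apply_drift(mz0, cfg.drift)
        sigma = (center / cfg.resolution) * fwhm_to_sigma
        i0 = np.searchsorted(grid, center - 5 * sigma)
        i1 = np.searchsorted(grid, center + 5 * sigma)
        window = grid[i0:i1]
        signal[i0:i1] += abundance * np.exp(-0.5 * ((window - center) / sigma) ** 2)
    baseline = cfg.baseline_amp * np.exp(-(grid - lo) / cfg.baseline_decay)
    noise = 0.0
    if cfg.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        noise = np.abs(rng.normal(0.0, cfg.noise_sd, size=grid.size))
    return Spectrum(mz=grid, intensity=signal + baseline + noise)


def simulate_experiment(cfg: SynthConfig) -> tuple[list[Spectrum], GroundTruth]:
    """Simulate one spectrum per (group, biological, technical) replicate.

    Biological replicates share a per-lipid lognormal effect; technical
    replicates add smaller lognormal jitter; total intensity varies
    lognormally with CV = tic_cv. Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    panel = cfg.lipid_panel
    keys = cfg.panel_keys()
    n_lipids = len(panel)

    envelopes = [
        isotope_envelope(ion.species.formula, cfg.n_isotope_peaks) for ion, _ in panel
    ]
    tic_sigma = np.sqrt(np.log1p(cfg.tic_cv**2))

    spectra: list[Spectrum] = []
    rows = []
    for group in cfg.groups:
        effects = cfg.group_effects.get(group, {})
        lfc = np.array([effects.get(key, 0.0) for key in keys])
        for bio in range(1, cfg.n_bio + 1):
            bio_factor = 2.0 ** rng.normal(0.0, cfg.sigma_bio_log2, size=n_lipids)
            for tech in range(1, cfg.n_tech + 1):
                tech_factor = 2.0 ** rng.normal(0.0, cfg.sigma_tech_log2, size=n_lipids)
                tic_factor = float(np.exp(rng.normal(-0.5 * tic_sigma**2, tic_sigma)))
                abundances = (
                    np.array([base for _, base in panel])
                    * 2.0**lfc * bio_factor * tech_factor * tic_factor
                )
                peaks: list[tuple[float, float]] = []
                for (ion, _), env, ab in zip(panel, envelopes, abundances):
                    for offset, rel in env:
                        mz = ion.mz_theoretical + offset
                        if cfg.mz_range[0] <= mz <= cfg.mz_range[1]:
                            peaks.append((mz, ab * rel))
                sample_id = f"{group}_b{bio}_t{tech}"
                s = simulate_spectrum(peaks, cfg, rng)
                spectra.append(
                    s.with_(sample_id=sample_id, group=group, bio_rep=bio, tech_rep=tech)
                )
                rows.append(
                    dict(sample_id=sample_id, group=group, bio_rep=bio, tech_rep=tech,
                         tic_factor=tic_factor, drift_a0=cfg.drift[0],
                         drift_a1=cfg.drift[1], drift_a2=cfg.drift[2])
                )

    lipids = pd.DataFrame(
        {
            "key": keys,
            "name": [ion.species.name for ion, _ in panel],
            "adduct": [ion.adduct for ion, _ in panel],
            "mz_theoretical": [ion.mz_theoretical for ion, _ in panel],
            "base_abundance": [base for _, base in panel],
        }
    )
    for group in cfg.groups:
        effects = cfg.group_effects.get(group, {})
        lipids[f"log2fc_{group}"] = [effects.get(key, 0.0) for key in keys]
    truth = GroundTruth(lipids=lipids, spectra=pd.DataFrame(rows))
    return spectra, truth
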