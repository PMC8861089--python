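"""Spectral preprocessing and feature extraction.

The processing chain mirrors standard MALDI biotyping practice:
resample -> Savitzky-Golay smoothing (0.1 m/z width, 1 cycle, order 2) ->
TopHat (morphological opening) baseline subtraction with 10% minimal baseline
width -> TIC normalization -> averaging -> robust noise estimation ->
SNR > 3 peak picking on the total average spectrum -> per-sample feature
binning at a peak-width parameter of resolution 10,000 -> null/noise spectrum
exclusion -> replicate Pearson QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .errors import ValidationError
from .spectra_io import Peak, PeakList, Spectrum

logger = logging.getLogger("lipidfinger")

_META_COLUMNS = ["sample_id", "group", "bio_rep", "tech_rep"]


def _grid_step(s: Spectrum) -> float:
    diffs = np.diff(s.mz)
    step = float(diffs.mean())
    if not np.allclose(diffs, step, rtol=1e-6, atol=step * 1e-6):
        raise ValidationError("spectrum is not on a uniform grid; resample first")
    return step


def resample(s: Spectrum, step: float) -> Spectrum:
    """Linearly interpolate a spectrum onto a uniform grid of spacing ``step``."""
    if step <= 0:
        raise ValidationError("step must be positive")
    span = s.mz[-1] - s.mz[0]
    if step > span:
        raise ValidationError(f"step {step} exceeds spectrum span {span}")
    grid = np.arange(s.mz[0], s.mz[-1] + step / 2, step)
    values = np.interp(grid, s.mz, s.intensity)
    return s.with_(mz=grid, intensity=values)


def savgol_smooth(s: Spectrum, width_mz: float = 0.1, cycles: int = 1) -> Spectrum:
    """Savitzky-Golay smoothing (order 2) applied ``cycles`` times.

    The window is ``width_mz`` converted to grid points, rounded to the
    nearest odd integer >= 5. ``cycles=0`` is the identity.
    """
    if cycles == 0:
        return s.with_()
    step = _grid_step(s)
    window = int(round(width_mz / step))
    window = max(5, window + 1 if window % 2 == 0 else window)
    if window > len(s):
        raise ValidationError("smoothing window exceeds spectrum length")
    values = s.intensity
    for _ in range(cycles):
        values = signal.savgol_filter(values, window_length=window, polyorder=2)
    return s.with_(intensity=values)


def tophat_baseline(
    s: Spectrum, min_width_frac: float = 0.10
) -> tuple[Spectrum, Spectrum]:
    """TopHat baseline subtraction: morphological opening with a flat element.

    The structuring element spans ``min_width_frac`` of the m/z range.
    Returns (signal - baseline, clipped at 0; baseline).
    """
    step = _grid_step(s)
    span = s.mz[-1] - s.mz[0]
    size = int(round(min_width_frac * span / step))
    size += 1 - size % 2  # symmetric (odd) structuring element
    if size < 1 or size > len(s):
        raise ValidationError("structuring element must fit inside the spectrum")
    baseline = ndimage.grey_opening(s.intensity, size=size, mode="nearest")
    residual = np.clip(s.intensity - baseline, 0.0, None)
    return s.with_(intensity=residual), s.with_(intensity=baseline)


def tic_normalize(s: Spectrum) -> Spectrum:
    """Divide intensities by their sum (unit-TIC convention)."""
    total = s.tic
    if total <= 0:
        raise ValidationError(f"null spectrum {s.sample_id!r}: zero total ion current")
    return s.with_(intensity=s.intensity / total)


@dataclass
class NoiseModel:
    """Piecewise-constant robust noise level and background floor over m/z windows.

    ``level`` is the spread (1.4826 x MAD); ``floor`` is the per-window median,
    i.e. the residual background left under the noise after baseline
    subtraction. The SNR of an apex is measured above the floor in units of
    the level.
    """

    edges: np.ndarray  # window boundaries, len = n_windows + 1
    level: np.ndarray  # per-window noise spread, > 0 everywhere
    floor: np.ndarray | None = None  # per-window median background

    def __post_init__(self) -> None:
        if self.floor is None:
            self.floor = np.zeros_like(self.level)

    def _index(self, mz) -> np.ndarray:
        return np.clip(
            np.searchsorted(self.edges, mz, side="right") - 1, 0, self.level.size - 1
        )

    def at(self, mz) -> np.ndarray:
        return self.level[self._index(mz)]

    def floor_at(self, mz) -> np.ndarray:
        return self.floor[self._index(mz)]


def estimate_noise(s: Spectrum, window: float = 20.0) -> NoiseModel:
    """Per-window robust noise: 1.4826 x median absolute deviation.

    Windows of ``window`` Th; all-zero or degenerate windows fall back to a
    tiny positive floor so SNR stays defined. The per-window median is kept
    as the local background floor.
    """
    edges = np.arange(s.mz[0], s.mz[-1] + window, window)
    tiny = max(np.finfo(float).tiny, float(s.intensity[s.intensity > 0].min()) * 1e-6) \
        if np.any(s.intensity > 0) else np.finfo(float).tiny
    levels, floors = [], []
    idx = np.searchsorted(s.mz, edges)
    for i in range(len(edges) - 1):
        chunk = s.intensity[idx[i]: idx[i + 1]]
        if chunk.size == 0:
            levels.append(tiny)
            floors.append(0.0)
            continue
        med = float(np.median(chunk))
        mad = float(np.median(np.abs(chunk - med)))
        levels.append(max(1.4826 * mad, tiny))
        floors.append(med)
    return NoiseModel(edges=edges, level=np.array(levels), floor=np.array(floors))


def average_spectra(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of spectra sharing a grid and polarity."""
    if not spectra:
        raise ValidationError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if len(s) != len(first) or not np.allclose(s.mz, first.mz):
            raise ValidationError("spectra are not on identical m/z grids")
        if s.polarity != first.polarity:
            raise ValidationError("mixed polarities in average")
    mean = np.mean([s.intensity for s in spectra], axis=0)
    return first.with_(intensity=mean, sample_id="average")


def pick_peaks(
    avg: Spectrum,
    noise: NoiseModel,
    snr_min: float = 3.0,
    resolution: float = 10000.0,
) -> PeakList:
    """SNR-thresholded local-maximum peak picking on an average spectrum.

    SNR is the apex height above the local background floor in units of the
    local noise level. Apex m/z is refined by 3-point parabolic
    interpolation; peaks closer than m/z/(2 x resolution) are merged keeping
    the higher apex.
    """
    y = avg.intensity
    maxima = signal.argrelextrema(y, np.greater)[0]
    peaks: list[Peak] = []
    step = _grid_step(avg)
    for i in maxima:
        snr = (y[i] - noise.floor_at(avg.mz[i])) / noise.at(avg.mz[i])
        if snr <= snr_min:
            continue
        # parabolic apex refinement
        if 0 < i < y.size - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        mz = avg.mz[i] + delta * step
        peaks.append(Peak(mz=float(mz), intensity=float(y[i]), snr=float(snr)))
    # merge peaks closer than the instrument-resolution bin width
    merged: list[Peak] = []
    for p in sorted(peaks, key=lambda p: p.mz):
        if merged and (p.mz - merged[-1].mz) < p.mz / (2.0 * resolution):
            if p.intensity > merged[-1].intensity:
                merged[-1] = p
        else:
            merged.append(p)
    if not merged:
        logger.warning("no peaks above SNR %.1f", snr_min)
    return PeakList(peaks=merged, source="average-spectrum")


@dataclass
class FeatureMatrix:
    """Peak-binned, TIC-normalized intensities (features x samples)."""

    feature_mz: np.ndarray
    values: np.ndarray
    samples: pd.DataFrame  # columns sample_id, group, bio_rep, tech_rep

    def __post_init__(self) -> None:
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            self.feature_mz.size, len(self.samples)
        ):
            raise ValidationError("values must be a features x samples matrix")
        if np.any(np.diff(self.feature_mz) <= 0):
            raise ValidationError("feature m/z must be strictly increasing")
        if np.any(self.values < 0):
            raise ValidationError("feature intensities must be non-negative")

    @property
    def n_features(self) -> int:
        return self.feature_mz.size

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_values(self, group: str) -> np.ndarray:
        mask = (self.samples["group"] == group).to_numpy()
        return self.values[:, mask]

    def subset_samples(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            feature_mz=self.feature_mz,
            values=self.values[:, mask],
            samples=self.samples.loc[mask].reset_index(drop=True),
        )

    def collapse_technical(self) -> "FeatureMatrix":
        """Average technical replicates within each (group, bio_rep)."""
        key = self.samples[["group", "bio_rep"]].astype(str).agg("|".join, axis=1)
        order = key.drop_duplicates().tolist()
        cols, meta = [], []
        for k in order:
            mask = (key == k).to_numpy()
            cols.append(self.values[:, mask].mean(axis=1))
            row = self.samples.loc[mask.argmax()]
            meta.append(dict(sample_id=f"{row['group']}_b{row['bio_rep']}",
                             group=row["group"], bio_rep=row["bio_rep"], tech_rep=0))
        return FeatureMatrix(
            feature_mz=self.feature_mz,
            values=np.column_stack(cols),
            samples=pd.DataFrame(meta),
        )

    def to_tsv(self, path) -> None:
        table = pd.DataFrame(self.values, columns=self.samples["sample_id"])
        table.insert(0, "mz", np.round(self.feature_mz, 4))
        table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, samples: pd.DataFrame) -> "FeatureMatrix":
        table = pd.read_csv(path, sep="\t")
        return cls(
            feature_mz=table["mz"].to_numpy(),
            values=table.drop(columns="mz").to_numpy(),
            samples=samples,
        )


def bin_features(
    peaklist: PeakList,
    spectra: Sequence[Spectrum],
    resolution: float = 10000.0,
    width_multiplier: float = 2.0,
) -> FeatureMatrix:
    """Per-sample feature values: window maximum around each picked peak.

    The half-window is m/(2 x resolution) x width_multiplier. Windows falling
    outside a spectrum's range yield 0 (warned).
    """
    meta = pd.DataFrame(
        [{c: getattr(s, c) for c in _META_COLUMNS} for s in spectra]
    )
    mz = peaklist.mz
    if mz.size == 0:
        return FeatureMatrix(
            feature_mz=np.empty(0), values=np.empty((0, len(spectra))), samples=meta
        )
    half = mz / (2.0 * resolution) * width_multiplier
    values = np.zeros((mz.size, len(spectra)))
    for j, s in enumerate(spectra):
        lo_idx = np.searchsorted(s.mz, mz - half)
        hi_idx = np.searchsorted(s.mz, mz + half)
        for i, (a, b) in enumerate(zip(lo_idx, hi_idx)):
            if a >= b:
                logger.warning(
                    "feature %.4f outside spectrum %s; value set to 0", mz[i], s.sample_id
                )
                continue
            values[i, j] = s.intensity[a:b].max()
    return FeatureMatrix(feature_mz=mz, values=values, samples=meta)


def exclude_spectra(fm: FeatureMatrix, min_corr: float = 0.5) -> FeatureMatrix:
    """Drop null (zero-TIC) and noise (low-correlation) samples.

    A noise sample correlates with its group-average fingerprint below
    ``min_corr``. Raises if nothing survives.
    """
    if fm.n_samples < 1:
        raise ValidationError("feature matrix has no samples")
    keep = np.ones(fm.n_samples, dtype=bool)
    totals = fm.values.sum(axis=0)
    for j in np.flatnonzero(totals <= 0):
        keep[j] = False
        logger.info("excluding null spectrum %s", fm.samples["sample_id"].iloc[j])
    for group in fm.samples["group"].unique():
        mask = (fm.samples["group"] == group).to_numpy() & keep
        if mask.sum() < 2:
            continue
        mean_fp = fm.values[:, mask].mean(axis=1)
        for j in np.flatnonzero(mask):
            col = fm.values[:, j]
            if col.std() == 0 or mean_fp.std() == 0:
                continue
            r = float(np.corrcoef(col, mean_fp)[0, 1])
            if r < min_corr:
                keep[j] = False
                logger.info(
                    "excluding noise spectrum %s (r=%.2f to group mean)",
                    fm.samples["sample_id"].iloc[j], r,
                )
    if not keep.any():
        raise ValidationError("all spectra excluded by QC")
    return fm.subset_samples(keep)


def pearson_qc(fm: FeatureMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation between samples plus per-group mean +/- sd.

    Zero-variance columns yield missing (NaN) correlations.
    """
    if fm.n_samples < 2:
        raise ValidationError("need at least 2 samples for QC")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(fm.values.T)
    ids = fm.samples["sample_id"].tolist()
    corr_df = pd.DataFrame(corr, index=ids, columns=ids)
    summaries = []
    for group in fm.samples["group"].unique():
        idx = np.flatnonzero((fm.samples["group"] == group).to_numpy())
        if idx.size < 2:
            continue
        sub = corr[np.ix_(idx, idx)]
        pairs = sub[np.triu_indices(idx.size, k=1)]
        pairs = pairs[~np.isnan(pairs)]
        summaries.append(
            dict(group=group, n_pairs=pairs.size,
                 mean_r=float(pairs.mean()) if pairs.size else np.nan,
                 sd_r=float(pairs.std(ddof=1)) if pairs.size > 1 else np.nan)
        )
    return corr_df, pd.DataFrame(summaries)


def preprocess_spectrum(
    s: Spectrum,
    step: float = 0.01,
    smooth_width_mz: float = 0.1,
    smooth_cycles: int = 1,
    baseline_frac: float = 0.10,
) -> Spectrum:
    """The fixed single-spectrum chain: resample, smooth, baseline, TIC-normalize."""
    s = resample(s, step)
    s = savgol_smooth(s, width_mz=smooth_width_mz, cycles=smooth_cycles)
    s, _ = tophat_baseline(s, min_width_frac=baseline_frac)
    return tic_normalize(s)
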