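"""End-to-end fingerprinting pipeline and run reporting.

Fixed stage order: preprocess -> average -> noise -> peak picking ->
lock-mass recalibration -> feature binning -> QC exclusion -> differential
analysis per treated group -> overlap -> accurate-mass annotation ->
optional MS/MS confirmation -> optional mobility CCS conversion -> report.
Deterministic given the configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, calibrate, diffstats, mobility, msms, preprocess, synth
from .errors import ValidationError
from .spectra_io import (
    PeakList,
    Spectrum,
    load_experiment,
    read_metadata,
    write_peaklist,
    write_spectrum,
)

logger = logging.getLogger("lipidfinger")

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """All stage parameters in one place; defaults are the standard workflow values."""

    # inputs
    metadata_path: str = ""
    spectra_dir: str = ""
    reference_path: str = ""  # empty -> bundled lipid reference
    output_dir: str = "results"
    control_group: str = "vehicle"
    seed: int = 0
    # preprocessing
    grid_step: float = 0.01
    smooth_width_mz: float = 0.1
    smooth_cycles: int = 1
    baseline_frac: float = 0.10
    noise_window: float = 20.0
    snr_min: float = 3.0
    resolution: float = 10000.0
    bin_width_multiplier: float = 2.0
    exclude_min_corr: float = 0.5
    # calibration
    calibrate_locks: bool = True
    lock_tol_ppm: float = calibrate.DEFAULT_TOF_TOL_PPM
    # differential analysis
    alpha: float = 0.01
    fc_min: float = 0.3
    collapse_technical: bool = True
    # annotation
    annotate_tol_ppm: float = 50.0
    # msms
    msms_tol: float = 0.05
    # mobility
    ccs_temperature: float = mobility.DEFAULT_TEMPERATURE

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        for key, value in raw.items():
            if isinstance(value, dict):  # sectioned config: flatten
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class RunReport:
    """Per-stage summaries; every count equals the corresponding artifact's rows."""

    version: str = __version__
    config: dict = field(default_factory=dict)
    n_spectra_in: int = 0
    n_spectra_retained: int = 0
    n_peaks_picked: int = 0
    calibration: dict = field(default_factory=dict)
    qc_pearson: list = field(default_factory=list)
    n_significant: dict = field(default_factory=dict)
    venn_regions: dict = field(default_factory=dict)
    n_annotated: int = 0
    n_msms_confirmed: int = 0
    n_mobility_records: int = 0

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def run_synth(cfg: synth.SynthConfig, output_dir) -> tuple[Path, pd.DataFrame]:
    """Simulate an experiment and write spectra (TSV), metadata and truth tables."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    spectra, truth = synth.simulate_experiment(cfg)
    rows = []
    for s in spectra:
        rel = f"{s.sample_id}.tsv"
        write_spectrum(s, out / rel)
        rows.append(
            dict(sample_id=s.sample_id, group=s.group, bio_rep=s.bio_rep,
                 tech_rep=s.tech_rep, path=rel)
        )
    metadata = pd.DataFrame(rows)
    metadata.to_csv(out / "metadata.csv", index=False)
    truth.to_csv(out / "truth_lipids.csv", out / "truth_spectra.csv")
    return out, metadata


def run_fingerprint(
    config: RunConfig,
    spectra: list[Spectrum] | None = None,
    msms_observations: dict[str, list[float]] | None = None,
    mobility_records: pd.DataFrame | None = None,
) -> RunReport:
    """Execute the full fingerprinting analysis and write all artifacts.

    ``spectra`` may be passed directly (e.g. fresh from the simulator);
    otherwise they are loaded through the metadata table. ``msms_observations``
    maps an annotation label to an observed MS2 m/z list; ``mobility_records``
    is a table with columns feature_mz, charge, inv_k0 (and optionally
    ccs_ref).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config))

    if spectra is None:
        if not config.metadata_path:
            raise ValidationError("no spectra given and no metadata_path configured")
        metadata = read_metadata(config.metadata_path)
        spectra = load_experiment(metadata, base_dir=config.spectra_dir or Path(config.metadata_path).parent)
    report.n_spectra_in = len(spectra)

    # --- preprocessing (nulls dropped before TIC normalization) ---
    processed: list[Spectrum] = []
    for s in spectra:
        if s.tic <= 0:
            logger.info("dropping null spectrum %s before normalization", s.sample_id)
            continue
        processed.append(
            preprocess.preprocess_spectrum(
                s, step=config.grid_step, smooth_width_mz=config.smooth_width_mz,
                smooth_cycles=config.smooth_cycles, baseline_frac=config.baseline_frac,
            )
        )
    if not processed:
        raise ValidationError("no spectra survived preprocessing")

    avg = preprocess.average_spectra(processed)
    noise = preprocess.estimate_noise(avg, window=config.noise_window)
    peaklist = preprocess.pick_peaks(
        avg, noise, snr_min=config.snr_min, resolution=config.resolution
    )
    report.n_peaks_picked = len(peaklist)

    # --- lock-mass recalibration of the picked peak list ---
    model = calibrate.CalibrationModel.identity()
    if config.calibrate_locks and len(peaklist):
        locks = calibrate.default_lock_masses(tol_ppm=config.lock_tol_ppm)
        matches = calibrate.match_lock_masses(peaklist, locks)
        if len(matches) >= 3:
            model = calibrate.fit_quadratic(matches)
        else:
            logger.warning(
                "only %d lock masses matched; skipping recalibration", len(matches)
            )
    report.calibration = {
        "kind": model.kind,
        "coefficients": list(model.coefficients),
        "residuals_ppm": model.residuals_ppm,
    }

    # features are binned on the uncalibrated axis (spectra share the drift),
    # then reported at calibrated m/z
    fm = preprocess.bin_features(
        peaklist, processed, resolution=config.resolution,
        width_multiplier=config.bin_width_multiplier,
    )
    fm = preprocess.exclude_spectra(fm, min_corr=config.exclude_min_corr)
    report.n_spectra_retained = fm.n_samples
    calibrated_mz = np.sort(model.correct(fm.feature_mz))
    fm_out = preprocess.FeatureMatrix(
        feature_mz=calibrated_mz, values=fm.values, samples=fm.samples
    )
    fm_out.to_tsv(out / "features.tsv")
    if len(peaklist):
        write_peaklist(calibrate.apply_calibration(peaklist, model), out / "peaks.csv")

    corr, qc_summary = preprocess.pearson_qc(fm)
    qc_summary.to_csv(out / "qc.csv", index=False)
    corr.to_csv(out / "qc_pairwise.csv")
    report.qc_pearson = qc_summary.to_dict("records")

    # --- differential analysis: every non-control group vs control ---
    groups = [g for g in fm.samples["group"].unique() if g != config.control_group]
    if config.control_group not in set(fm.samples["group"]):
        raise ValidationError(f"control group {config.control_group!r} absent from data")
    volcano_frames = []
    significant_sets: dict[str, set] = {}
    for group in groups:
        res = diffstats.differential_analysis(
            fm, treated=group, control=config.control_group,
            collapse_technical=config.collapse_technical,
            alpha=config.alpha, fc_min=config.fc_min,
        )
        res.insert(0, "condition", group)
        res["feature_mz"] = np.round(model.correct(res["feature_mz"]), 4)
        volcano_frames.append(res)
        significant_sets[group] = set(np.flatnonzero(res["significant"].to_numpy()))
        report.n_significant[group] = int(res["significant"].sum())
    volcano = pd.concat(volcano_frames, ignore_index=True) if volcano_frames else pd.DataFrame()
    volcano.to_csv(out / "volcano.tsv", sep="\t", index=False)

    if len(significant_sets) >= 2:
        overlap = diffstats.venn_overlap(significant_sets)
        venn_rows = [
            {"conditions": "&".join(combo), "count": count}
            for combo, count in overlap.regions.items()
        ]
        venn_rows.append({"conditions": "shared_percent",
                          "count": overlap.shared_fraction_percent})
        pd.DataFrame(venn_rows).to_csv(out / "venn.csv", index=False)
        report.venn_regions = {"&".join(k): v for k, v in overlap.regions.items()}

    # --- annotation of significant features (union over conditions) ---
    sig_idx = sorted(set().union(*significant_sets.values())) if significant_sets else []
    sig_mz = model.correct(fm.feature_mz[sig_idx]) if sig_idx else np.empty(0)
    ref_table = annotate.load_reference_table(config.reference_path or None)
    ions = annotate.reference_ions(ref_table)
    annotations = annotate.match_features(sig_mz, ions, tol_ppm=config.annotate_tol_ppm)
    ann_table = annotate.annotation_table(annotations)
    ann_table.to_csv(out / "annotations.tsv", sep="\t", index=False)
    report.n_annotated = int((ann_table["assignment"] != "unassigned").sum())

    # --- optional MS/MS confirmation ---
    msms_rows = []
    if msms_observations:
        best = {a.candidate.label: a.candidate for a in annotations if a.assigned and a.rank == 0}
        for label, observed in msms_observations.items():
            candidate = best.get(label)
            if candidate is None:
                continue
            preds = msms.predict_fragments(candidate) + msms.acyl_fragments(candidate)
            if not preds:
                continue
            match = msms.match_msms(preds, observed, tol=config.msms_tol)
            for pred, obs_mz in match.matched:
                msms_rows.append(dict(candidate=label, prediction=pred.description,
                                      mz_pred=round(pred.mz_pred, 4), mz_obs=obs_mz,
                                      delta=round(obs_mz - pred.mz_pred, 4),
                                      matched=True, confirmed=match.confirmed))
            for pred in match.unmatched:
                msms_rows.append(dict(candidate=label, prediction=pred.description,
                                      mz_pred=round(pred.mz_pred, 4), mz_obs=np.nan,
                                      delta=np.nan, matched=False,
                                      confirmed=match.confirmed))
            if match.confirmed:
                report.n_msms_confirmed += 1
    pd.DataFrame(
        msms_rows,
        columns=["candidate", "prediction", "mz_pred", "mz_obs", "delta",
                 "matched", "confirmed"],
    ).to_csv(out / "msms_report.tsv", sep="\t", index=False)

    # --- optional ion mobility ---
    if mobility_records is not None and len(mobility_records):
        mob_rows = []
        for row in mobility_records.itertuples(index=False):
            ccs = mobility.ccs_from_k0(
                row.feature_mz, int(getattr(row, "charge", 1)), row.inv_k0,
                temperature=config.ccs_temperature,
            )
            entry = dict(feature_mz=row.feature_mz, inv_k0=row.inv_k0,
                         ccs=round(ccs, 1))
            ref = getattr(row, "ccs_ref", np.nan)
            if np.isfinite(ref):
                entry["deviation_percent"] = round(mobility.ccs_deviation(ccs, ref), 2)
            mob_rows.append(entry)
        pd.DataFrame(mob_rows).to_csv(out / "mobility.csv", index=False)
        report.n_mobility_records = len(mob_rows)

    report.to_json(out / "report.json")
    config.to_yaml(out / "config_used.yaml")
    logger.info("run complete: %d features, %s significant",
                fm.n_features, report.n_significant)
    return report


def run_annotate_table(
    feature_mz,
    reference_path=None,
    tol_ppm: float = 1.0,
) -> pd.DataFrame:
    """Standalone accurate-mass annotation of any feature m/z list."""
    table = annotate.load_reference_table(reference_path)
    ions = annotate.reference_ions(table)
    annotations = annotate.match_features(list(feature_mz), ions, tol_ppm=tol_ppm)
    return annotate.annotation_table(annotations)
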