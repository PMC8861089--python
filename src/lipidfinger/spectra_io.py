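"""Spectrum and peak-list data model plus readers/writers.

Profile spectra are (m/z, intensity) array pairs in Thomson with strictly
increasing m/z; peak lists are centroided. Supported formats: mzML (a
self-contained reader/writer for MS1 profile spectra with 32/64-bit,
optionally zlib-compressed binary arrays), two-column TSV/CSV spectra, CSV
peak lists and a CSV sample-metadata table.
"""

from __future__ import annotations

import base64
import logging
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("lipidfinger")


@dataclass
class Spectrum:
    """A profile mass spectrum with acquisition metadata.

    Invariants: equal-length arrays, strictly increasing m/z. Exact-duplicate
    m/z values are merged by summing intensities (logged); unsorted input is
    sorted with a warning.
    """

    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "positive"
    sample_id: str = ""
    group: str = ""
    bio_rep: int = 1
    tech_rep: int = 1
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValidationError("mz and intensity must be equal-length 1-D arrays")
        if self.mz.size == 0:
            raise ValidationError("empty spectrum")
        if self.polarity not in ("positive", "negative"):
            raise ValidationError(f"polarity must be positive|negative, got {self.polarity!r}")
        diffs = np.diff(self.mz)
        if np.any(diffs < 0):
            logger.warning("spectrum %s: non-monotone m/z axis, sorting", self.sample_id)
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            diffs = np.diff(self.mz)
        if np.any(diffs == 0):
            uniq, inverse = np.unique(self.mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, self.intensity)
            logger.info(
                "spectrum %s: merged %d duplicate m/z values (summed intensity)",
                self.sample_id, self.mz.size - uniq.size,
            )
            self.mz, self.intensity = uniq, summed

    def __len__(self) -> int:
        return self.mz.size

    @property
    def tic(self) -> float:
        """Total ion current (sum of intensities)."""
        return float(self.intensity.sum())

    def with_(self, **changes) -> "Spectrum":
        return replace(self, **changes)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    snr: float = 0.0

    def __post_init__(self) -> None:
        if self.snr < 0 or self.intensity < 0:
            raise ValidationError("peak intensity and SNR must be non-negative")


@dataclass
class PeakList:
    """An ordered (by m/z) collection of centroided peaks."""

    peaks: list[Peak]
    source: str = "single-spectrum"

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".mzml":
        return "mzml"
    return "tsv"


def read_spectrum(path, format: str | None = None, **metadata) -> Spectrum:
    """Read a profile spectrum from mzML or two-column text (TSV/CSV).

    For mzML the first MS1 spectrum is returned. ``metadata`` keyword
    arguments (sample_id, group, bio_rep, tech_rep, polarity) fill fields the
    file does not carry. Negative raw intensities (detector noise) are
    clipped to zero on load.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"spectrum file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "mzml":
        mz, intensity, polarity = _read_mzml(path)
        metadata.setdefault("polarity", polarity)
    elif fmt in ("tsv", "csv", "txt"):
        table = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
        if table.shape[1] < 2:
            raise ValidationError(f"{path}: expected two numeric columns")
        # tolerate a single header row
        table = table.apply(pd.to_numeric, errors="coerce").dropna()
        if table.empty:
            raise ValidationError(f"{path}: no numeric (m/z, intensity) rows")
        mz = table.iloc[:, 0].to_numpy(float)
        intensity = table.iloc[:, 1].to_numpy(float)
    else:
        raise ValidationError(f"unknown spectrum format {fmt!r}")
    metadata.setdefault("sample_id", path.stem)
    return Spectrum(mz=mz, intensity=np.clip(intensity, 0.0, None), **metadata)


def _decode_binary(ba_elem) -> np.ndarray | None:
    """Decode one mzML binaryDataArray (64/32-bit float, zlib or plain)."""
    accessions = {
        c.get("accession"): c.get("name", "")
        for c in ba_elem.iter(f"{{{_MZML_NS}}}cvParam")
    }
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    binary = ba_elem.find(f"{{{_MZML_NS}}}binary")
    if binary is None or not (binary.text or "").strip():
        return None
    raw = base64.b64decode(binary.text)
    if "MS:1000574" in accessions:  # zlib compression
        import zlib

        raw = zlib.decompress(raw)
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    kind = "mz" if "MS:1000514" in accessions else (
        "intensity" if "MS:1000515" in accessions else "other")
    return kind, values


def _read_mzml(path: Path) -> tuple[np.ndarray, np.ndarray, str]:
    """Minimal mzML reader: first MS1 spectrum's m/z and intensity arrays."""
    tree = ET.parse(path)
    for spec in tree.iter(f"{{{_MZML_NS}}}spectrum"):
        params = {
            c.get("accession"): c.get("value", "")
            for c in spec.findall(f"{{{_MZML_NS}}}cvParam")
        }
        ms_level = int(params.get("MS:1000511", "1") or 1)
        if ms_level != 1:
            continue
        polarity = "negative" if "MS:1000129" in params else "positive"
        mz = intensity = None
        for ba in spec.iter(f"{{{_MZML_NS}}}binaryDataArray"):
            decoded = _decode_binary(ba)
            if decoded is None:
                continue
            kind, values = decoded
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                intensity = values
        if mz is not None and intensity is not None and mz.size:
            return mz, intensity, polarity
    raise ValidationError(f"{path}: no MS1 spectrum found")


def write_spectrum(spectrum: Spectrum, path, format: str | None = None) -> None:
    """Write a spectrum as two-column TSV (6-decimal m/z) or minimal mzML."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "mzml":
        _write_mzml(spectrum, path)
    else:
        with open(path, "w") as fh:
            fh.write("mz\tintensity\n")
            for m, i in zip(spectrum.mz, spectrum.intensity):
                fh.write(f"{m:.6f}\t{i:.8g}\n")


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *values)
    return base64.b64encode(raw).decode("ascii")


def _write_mzml(spectrum: Spectrum, path: Path) -> None:
    """Minimal single-spectrum PSI mzML writer (64-bit, no compression)."""
    ET.register_namespace("", _MZML_NS)
    ns = f"{{{_MZML_NS}}}"
    root = ET.Element(f"{ns}mzML", version="1.1.0")
    cvlist = ET.SubElement(root, f"{ns}cvList", count="1")
    ET.SubElement(
        cvlist, f"{ns}cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run = ET.SubElement(root, f"{ns}run", id=spectrum.sample_id or "run")
    slist = ET.SubElement(run, f"{ns}spectrumList", count="1")
    spec = ET.SubElement(
        slist, f"{ns}spectrum", index="0", id="scan=1",
        defaultArrayLength=str(len(spectrum)),
    )

    def cv(parent, accession, name, value=""):
        ET.SubElement(parent, f"{ns}cvParam", cvRef="MS", accession=accession,
                      name=name, value=value)

    cv(spec, "MS:1000511", "ms level", "1")
    cv(spec, "MS:1000128", "profile spectrum")
    if spectrum.polarity == "negative":
        cv(spec, "MS:1000129", "negative scan")
    else:
        cv(spec, "MS:1000130", "positive scan")
    balist = ET.SubElement(spec, f"{ns}binaryDataArrayList", count="2")
    for values, accession, name in (
        (spectrum.mz, "MS:1000514", "m/z array"),
        (spectrum.intensity, "MS:1000515", "intensity array"),
    ):
        encoded = _encode_array(np.asarray(values, dtype=float))
        ba = ET.SubElement(balist, f"{ns}binaryDataArray", encodedLength=str(len(encoded)))
        cv(ba, "MS:1000523", "64-bit float")
        cv(ba, "MS:1000576", "no compression")
        cv(ba, accession, name)
        ET.SubElement(ba, f"{ns}binary").text = encoded
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def write_peaklist(peaklist: PeakList, path) -> None:
    """Write a peak list as CSV with header mz,intensity,snr (6-decimal m/z)."""
    if len(peaklist) == 0:
        raise ValidationError("refusing to write an empty peak list")
    with open(path, "w") as fh:
        fh.write("mz,intensity,snr\n")
        for p in peaklist:
            fh.write(f"{p.mz:.6f},{p.intensity:.8g},{p.snr:.6g}\n")


def read_peaklist(path, source: str = "single-spectrum") -> PeakList:
    table = pd.read_csv(path)
    if "mz" not in table.columns:
        # two-column headerless MS2 lists
        table = pd.read_csv(path, header=None, names=["mz", "intensity"])
        table["snr"] = 0.0
    peaks = [
        Peak(mz=float(r.mz), intensity=float(r.intensity), snr=float(getattr(r, "snr", 0.0)))
        for r in table.itertuples(index=False)
    ]
    return PeakList(peaks=peaks, source=source)


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata table (sample_id,group,bio_rep,tech_rep,path)."""
    table = pd.read_csv(path)
    required = {"sample_id", "group", "bio_rep", "tech_rep", "path"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"metadata table missing columns: {sorted(missing)}")
    return table


def load_experiment(metadata: pd.DataFrame, base_dir=None) -> list[Spectrum]:
    """Load all spectra referenced by a metadata table."""
    base = Path(base_dir) if base_dir else Path(".")
    spectra = []
    for row in metadata.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        spectra.append(
            read_spectrum(
                p, sample_id=str(row.sample_id), group=str(row.group),
                bio_rep=int(row.bio_rep), tech_rep=int(row.tech_rep),
            )
        )
    return spectra
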