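"""Reading and writing of REIMS spectra, manifests and result tables.

Two spectrum formats are supported:

* a self-describing CSV dialect — ``#key=value`` metadata comment lines
  (spectrum_id, sample_id, patient_id, modality, burn_index) followed by a
  ``mz,intensity`` header and numeric rows;
* a minimal mzML profile (MS1, negative mode), read with :mod:`pyteomics`
  and written by this module's own writer so cohorts round-trip without any
  vendor software.

The sample manifest is a CSV joining samples to patients, histology labels,
cancer subtype, modality and a coarse tissue-quality grade; the *patient* is
the unit of cross-validation downstream, so the join must be total.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Modality",
    "Histology",
    "CancerSubtype",
    "Quality",
    "RawSpectrum",
    "SampleRecord",
    "Manifest",
    "read_spectrum_table",
    "write_spectrum_table",
    "read_mzml",
    "write_mzml",
    "read_manifest",
    "write_manifest",
]


class Modality(str, Enum):
    DIATHERMY = "diathermy"
    CO2_LASER = "co2_laser"


class Histology(str, Enum):
    NORMAL = "normal"
    CANCER = "cancer"
    HYPERPLASIA = "hyperplasia"
    INSUFFICIENT = "insufficient"


class CancerSubtype(str, Enum):
    ENDOMETRIOID_LOW = "endometrioid_low"
    ENDOMETRIOID_HIGH = "endometrioid_high"
    SEROUS = "serous"
    CARCINOSARCOMA = "carcinosarcoma"
    CLEAR_CELL = "clear_cell"


class Quality(str, Enum):
    POOR = "poor"
    MODERATE = "moderate"
    GOOD = "good"


@dataclass
class RawSpectrum:
    """One acquisition event (a single tissue burn).

    ``mz`` is kept sorted (non-decreasing; duplicate m/z points are retained
    — downstream binning sums them) and intensities must be non-negative.
    Arrays may be empty for a degenerate burn.
    """

    mz: np.ndarray
    intensity: np.ndarray
    spectrum_id: str = ""
    sample_id: str = ""
    patient_id: str = ""
    modality: Modality = Modality.DIATHERMY
    burn_index: int = 1

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.intensity.size and float(self.intensity.min()) < 0:
            raise ValueError("intensities must be non-negative")
        if self.mz.size > 1 and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        self.modality = Modality(self.modality)
        if int(self.burn_index) < 1:
            raise ValueError("burn_index must be >= 1")
        self.burn_index = int(self.burn_index)

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    patient_id: str
    histology: Histology
    cancer_subtype: CancerSubtype | None = None
    quality: Quality = Quality.GOOD
    modality: Modality = Modality.DIATHERMY

    def __post_init__(self) -> None:
        object.__setattr__(self, "histology", Histology(self.histology))
        object.__setattr__(self, "quality", Quality(self.quality))
        object.__setattr__(self, "modality", Modality(self.modality))
        subtype = self.cancer_subtype
        if subtype is not None and subtype != "":
            object.__setattr__(self, "cancer_subtype", CancerSubtype(subtype))
        else:
            object.__setattr__(self, "cancer_subtype", None)
        if (self.histology is Histology.CANCER) != (self.cancer_subtype is not None):
            raise ValueError(
                f"sample {self.sample_id!r}: cancer_subtype must be set iff histology is cancer"
            )


@dataclass
class Manifest:
    records: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        if dupes:
            raise ValueError(f"duplicate sample_id(s) in manifest: {dupes}")
        self._by_id = {r.sample_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sample_id: str) -> SampleRecord:
        try:
            return self._by_id[sample_id]
        except KeyError:
            raise KeyError(f"sample_id {sample_id!r} not in manifest") from None

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def join(self, spectra: Iterable[RawSpectrum]) -> list[tuple[RawSpectrum, SampleRecord]]:
        """Pair each spectrum with its unique manifest record (total join)."""
        return [(s, self[s.sample_id]) for s in spectra]


# ---------------------------------------------------------------------------
# CSV spectrum dialect
# ---------------------------------------------------------------------------

_META_KEYS = ("spectrum_id", "sample_id", "patient_id", "modality", "burn_index")


def write_spectrum_table(s: RawSpectrum, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#spectrum_id={s.spectrum_id}\n")
        fh.write(f"#sample_id={s.sample_id}\n")
        fh.write(f"#patient_id={s.patient_id}\n")
        fh.write(f"#modality={s.modality.value}\n")
        fh.write(f"#burn_index={s.burn_index}\n")
        fh.write("mz,intensity\n")
        for mz, inten in zip(s.mz, s.intensity):
            fh.write(f"{float(mz)!r},{float(inten)!r}\n")


def read_spectrum_table(path) -> RawSpectrum:
    """Read the project CSV spectrum dialect.

    Metadata comes from ``#key=value`` comment lines; rows out of m/z order
    are sorted (stable). Negative intensities and non-numeric cells raise
    with the offending line number.
    """
    meta = {"burn_index": "1", "modality": "diathermy"}
    mzs: list[float] = []
    intens: list[float] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                cols = [c.strip().lower() for c in line.split(",")]
                if cols[:2] != ["mz", "intensity"]:
                    raise ValueError(
                        f"{path}: line {lineno}: expected header 'mz,intensity', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns, got {line!r}")
            try:
                mz, inten = float(parts[0]), float(parts[1])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric cell in {line!r}"
                ) from None
            if inten < 0:
                raise ValueError(
                    f"{path}: line {lineno}: negative intensity {inten} is invalid"
                )
            mzs.append(mz)
            intens.append(inten)
    if not header_seen:
        raise ValueError(f"{path}: missing 'mz,intensity' header row")
    return RawSpectrum(
        np.array(mzs), np.array(intens),
        spectrum_id=meta.get("spectrum_id", ""),
        sample_id=meta.get("sample_id", ""),
        patient_id=meta.get("patient_id", ""),
        modality=Modality(meta["modality"]),
        burn_index=int(meta["burn_index"]),
    )


# ---------------------------------------------------------------------------
# Minimal mzML (MS1 profile, negative mode)
# ---------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _encode_array(values: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{values.size}d", *values)).decode("ascii")


def write_mzml(spectra: Sequence[RawSpectrum], path) -> None:
    """Write a minimal MS1 negative-mode profile mzML file."""
    root = ET.Element("mzML", xmlns=_MZML_NS, version="1.1.0")
    run = ET.SubElement(root, "run", id="run1")
    slist = ET.SubElement(run, "spectrumList", count=str(len(spectra)))
    for i, s in enumerate(spectra):
        spec = ET.SubElement(
            slist, "spectrum",
            index=str(i), id=s.spectrum_id or f"scan={i + 1}",
            defaultArrayLength=str(len(s)),
        )
        ET.SubElement(spec, "cvParam", cvRef="MS", accession="MS:1000129",
                      name="negative scan", value="")
        ET.SubElement(spec, "cvParam", cvRef="MS", accession="MS:1000511",
                      name="ms level", value="1")
        bal = ET.SubElement(spec, "binaryDataArrayList", count="2")
        for arr, acc, name in (
            (s.mz, "MS:1000514", "m/z array"),
            (s.intensity, "MS:1000515", "intensity array"),
        ):
            encoded = _encode_array(np.asarray(arr, dtype=float))
            bda = ET.SubElement(bal, "binaryDataArray", encodedLength=str(len(encoded)))
            ET.SubElement(bda, "cvParam", cvRef="MS", accession="MS:1000523",
                          name="64-bit float", value="")
            ET.SubElement(bda, "cvParam", cvRef="MS", accession="MS:1000576",
                          name="no compression", value="")
            ET.SubElement(bda, "cvParam", cvRef="MS", accession=acc, name=name, value="")
            ET.SubElement(bda, "binary").text = encoded
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _decode_binary_array(bda: ET.Element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values)."""
    import zlib

    kind = None
    dtype = "<f8"
    compressed = False
    for cv in bda.iter(f"{{{_MZML_NS}}}cvParam"):
        acc = cv.get("accession", "")
        if acc == "MS:1000514":
            kind = "mz"
        elif acc == "MS:1000515":
            kind = "intensity"
        elif acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000574":
            compressed = True
    binary = bda.find(f"{{{_MZML_NS}}}binary")
    text = (binary.text or "") if binary is not None else ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path) -> list[RawSpectrum]:
    """Read MS1 spectra from a (minimal) mzML file.

    Supports 32/64-bit float binary arrays with no or zlib compression —
    the profile this module's own writer produces. Spectrum ids come from
    the native scan id; sample/patient metadata are *not* stored in mzML
    and must be joined from a sidecar manifest.
    """
    out: list[RawSpectrum] = []
    try:
        tree = ET.parse(str(path))
    except OSError:
        raise
    except Exception as exc:  # malformed/truncated XML
        raise OSError(f"malformed mzML file {path}: {exc}") from exc
    for spec in tree.getroot().iter(f"{{{_MZML_NS}}}spectrum"):
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.iter(f"{{{_MZML_NS}}}binaryDataArray"):
            kind, values = _decode_binary_array(bda)
            if kind:
                arrays[kind] = values
        out.append(
            RawSpectrum(
                arrays.get("mz", np.empty(0)),
                arrays.get("intensity", np.empty(0)),
                spectrum_id=str(spec.get("id", "")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Manifest CSV
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["sample_id", "patient_id", "histology", "cancer_subtype", "quality", "modality"]


def write_manifest(manifest: Manifest, path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_MANIFEST_COLUMNS)
        for r in manifest.records:
            w.writerow([
                r.sample_id, r.patient_id, r.histology.value,
                r.cancer_subtype.value if r.cancer_subtype else "",
                r.quality.value, r.modality.value,
            ])


def read_manifest(path) -> Manifest:
    """Read and validate the manifest CSV (enums matched case-insensitively)."""
    import csv

    records: list[SampleRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: manifest missing required columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    SampleRecord(
                        sample_id=row["sample_id"].strip(),
                        patient_id=row["patient_id"].strip(),
                        histology=row["histology"].strip().lower(),
                        cancer_subtype=row["cancer_subtype"].strip().lower() or None,
                        quality=row["quality"].strip().lower(),
                        modality=row["modality"].strip().lower(),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return Manifest(records)
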