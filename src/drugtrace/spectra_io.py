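"""Spectral and tabular I/O: the in-memory spectrum model, MGF read/write,
MS1 trace extraction from mzML, USI parsing, and feature-table loading.

MGF and mzML parsing are delegated to :mod:`pyteomics`; this module owns the
dialect conventions (PEPMASS first value = precursor m/z, RTINSECONDS
converted to minutes) and the validation contracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import base64
import struct
import zlib

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mgf as _mgf

__all__ = [
    "Spectrum",
    "FeatureTable",
    "MgfParseError",
    "read_mgf",
    "write_mgf",
    "read_mzml_ms1_traces",
    "parse_usi",
    "read_feature_table",
]


class MgfParseError(ValueError):
    """Malformed MGF block (missing precursor, bad peak line, ...)."""


@dataclass(frozen=True)
class Spectrum:
    """One MS scan: precursor, optional retention time (minutes) and peak list.

    Peaks are kept sorted ascending by m/z with non-negative intensities.
    """

    spectrum_id: str
    precursor_mz: float
    peaks: tuple[tuple[float, float], ...]
    rt: float | None = None
    ms_level: int = 2
    source_file: str = ""

    def __post_init__(self) -> None:
        peaks = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i < 0 for _, i in peaks):
            raise ValueError(f"{self.spectrum_id}: negative peak intensity")
        if self.ms_level == 2 and not self.precursor_mz > 0:
            raise ValueError(f"{self.spectrum_id}: MS2 spectrum needs precursor_mz > 0")
        object.__setattr__(self, "peaks", peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])

    @property
    def total_intensity(self) -> float:
        return float(sum(i for _, i in self.peaks))

    def with_peaks(self, peaks: Sequence[tuple[float, float]]) -> "Spectrum":
        return replace(self, peaks=tuple(peaks))


def read_mgf(path: str) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    One spectrum per BEGIN IONS block.  PEPMASS (first value) is the
    precursor m/z and is required; RTINSECONDS, when present, is converted to
    minutes.  When no TITLE is given a deterministic ``file::scan`` id is
    synthesized.  An empty file yields an empty list.
    """
    spectra: list[Spectrum] = []
    with _mgf.MGF(path, convert_arrays=1) as reader:
        for index, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise MgfParseError(f"{path}: block {index} is missing PEPMASS")
            precursor = float(pepmass[0])
            rt = params.get("rtinseconds")
            scan = params.get("scans", index)
            spectrum_id = str(params.get("title") or f"{path}::{scan}")
            peaks = tuple(
                zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())
            )
            spectra.append(
                Spectrum(
                    spectrum_id=spectrum_id,
                    precursor_mz=precursor,
                    peaks=peaks,
                    rt=float(rt) / 60.0 if rt is not None else None,
                    ms_level=2,
                    source_file=path,
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str) -> None:
    """Write spectra as MGF; round-trips with :func:`read_mgf` on the
    canonical fields (id, precursor, peaks, rt)."""
    with open(path, "w") as handle:
        for s in spectra:
            handle.write("BEGIN IONS\n")
            handle.write(f"TITLE={s.spectrum_id}\n")
            handle.write(f"PEPMASS={s.precursor_mz}\n")
            if s.rt is not None:
                handle.write(f"RTINSECONDS={s.rt * 60.0}\n")
            for mz, inten in s.peaks:
                handle.write(f"{mz} {inten}\n")
            handle.write("END IONS\n")


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary(array_element) -> np.ndarray:
    """Decode one mzML binaryDataArray (64/32-bit float, zlib or none)."""
    dtype = "d"
    compressed = False
    for cv in array_element.iter(f"{_MZML_NS}cvParam"):
        accession = cv.get("accession")
        if accession == "MS:1000521":  # 32-bit float
            dtype = "f"
        elif accession == "MS:1000574":  # zlib compression
            compressed = True
    binary = array_element.find(f"{_MZML_NS}binary")
    raw = base64.b64decode(binary.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    count = len(raw) // struct.calcsize(dtype)
    return np.array(struct.unpack(f"<{count}{dtype}", raw), dtype=float)


def _spectrum_arrays(spectrum_element) -> tuple[np.ndarray, np.ndarray]:
    mz = intensity = np.array([])
    for array in spectrum_element.iter(f"{_MZML_NS}binaryDataArray"):
        accessions = {
            cv.get("accession") for cv in array.iter(f"{_MZML_NS}cvParam")
        }
        if "MS:1000514" in accessions:
            mz = _decode_binary(array)
        elif "MS:1000515" in accessions:
            intensity = _decode_binary(array)
    return mz, intensity


def read_mzml_ms1_traces(
    path: str, targets: Sequence[tuple[float, float]]
) -> list[list[tuple[int, float, float]]]:
    """Extract per-target MS1 ion traces (XIC inputs) from an mzML run.

    For each ``(mz, tol)`` target, returns the summed intensity within
    ``mz ± tol`` for every MS1 scan, as ``(scan_index, rt_minutes, intensity)``
    tuples in acquisition order.  ``scan_index`` counts MS1 scans from 0.
    Uncompressed and zlib-compressed 32/64-bit float arrays are supported.
    """
    for mz, tol in targets:
        if tol <= 0:
            raise ValueError(f"tolerance must be positive (target m/z {mz})")
    traces: list[list[tuple[int, float, float]]] = [[] for _ in targets]
    n_ms1 = 0
    for _, element in etree.iterparse(path, tag=f"{_MZML_NS}spectrum"):
        ms_level = None
        rt = 0.0
        for cv in element.iter(f"{_MZML_NS}cvParam"):
            accession = cv.get("accession")
            if accession == "MS:1000511":
                ms_level = int(cv.get("value"))
            elif accession == "MS:1000016":
                rt = float(cv.get("value"))
                if cv.get("unitName") == "second":
                    rt /= 60.0
        if ms_level == 1:
            mz_array, int_array = _spectrum_arrays(element)
            for t, (target_mz, tol) in enumerate(targets):
                mask = np.abs(mz_array - target_mz) <= tol
                traces[t].append((n_ms1, rt, float(int_array[mask].sum())))
            n_ms1 += 1
        element.clear(keep_tail=True)
    if n_ms1 == 0:
        warnings.warn(f"{path}: no MS1 scans found; traces are empty")
    return traces


def parse_usi(usi: str) -> tuple[str, str, str]:
    """Split a Universal Spectrum Identifier into
    (collection_id, run_name, scan_ref).

    ``mzspec:MSV000080673:run1:scan:123`` ->
    ``("MSV000080673", "run1", "scan:123")``.
    """
    parts = usi.split(":")
    if parts[0] != "mzspec" or len(parts) < 5:
        raise ValueError(f"not a valid USI: {usi!r}")
    return parts[1], parts[2], ":".join(parts[3:5])


def format_usi(collection_id: str, run_name: str, scan_ref: str) -> str:
    """Inverse of :func:`parse_usi`."""
    return f"mzspec:{collection_id}:{run_name}:{scan_ref}"


_SAMPLE_COLUMNS = {"sample_id", "is_blank"}


@dataclass
class FeatureTable:
    """Chromatographic features x samples peak-area matrix with metadata.

    ``features``: one row per feature (feature_id, mz, rt, ms2_spectrum_id);
    ``areas``: DataFrame indexed by feature_id, one column per sample;
    ``samples``: metadata indexed by sample_id (is_blank, group, age, sex).
    """

    features: pd.DataFrame
    areas: pd.DataFrame
    samples: pd.DataFrame
    spectra: dict[str, Spectrum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.features["feature_id"].duplicated().any():
            dupes = self.features.loc[
                self.features["feature_id"].duplicated(), "feature_id"
            ].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if (self.areas.to_numpy() < 0).any():
            raise ValueError("negative peak areas")
        missing = set(self.areas.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples absent from metadata: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return [c for c in self.areas.columns if not self.samples.loc[c, "is_blank"]]

    @property
    def blank_ids(self) -> list[str]:
        return [c for c in self.areas.columns if self.samples.loc[c, "is_blank"]]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.features.copy(), self.areas.copy(), self.samples.copy(),
            dict(self.spectra),
        )


def read_feature_table(
    csv_path: str, metadata_path: str, mgf_path: str | None = None
) -> FeatureTable:
    """Load an MZmine-style wide feature quantification table plus sample
    metadata (and, optionally, the paired MGF of MS2 spectra)."""
    table = pd.read_csv(csv_path)
    meta = pd.read_csv(metadata_path)
    if not _SAMPLE_COLUMNS <= set(meta.columns):
        raise ValueError(f"sample metadata needs columns {sorted(_SAMPLE_COLUMNS)}")
    meta = meta.set_index("sample_id")
    meta["is_blank"] = meta["is_blank"].astype(bool)
    feature_cols = [
        c for c in ("feature_id", "mz", "rt", "ms2_spectrum_id") if c in table.columns
    ]
    if "feature_id" not in feature_cols:
        raise ValueError(f"{csv_path}: missing feature_id column")
    features = table[feature_cols].copy()
    features["feature_id"] = features["feature_id"].astype(str)
    sample_cols = [c for c in table.columns if c not in feature_cols]
    areas = table[sample_cols].copy()
    areas.index = features["feature_id"]
    spectra = {}
    if mgf_path is not None:
        spectra = {s.spectrum_id: s for s in read_mgf(mgf_path)}
    return FeatureTable(features=features, areas=areas, samples=meta, spectra=spectra)
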