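"""Centroided MALDI peak-list containers, readers/writers, and replicate merging.

Peak lists are assumed centroided and monoisotopic (on-instrument isotope
deconvolution); this module only normalizes (sorts, deduplicates), reads and
writes the plain-text exchange formats, and builds a consensus across
replicate target spots.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Peak",
    "PeakList",
    "read_peaklist",
    "write_peaklist",
    "merge_replicates",
    "centroid_local_maxima",
]

#: Two peaks closer than this (Da) are merged during normalization.
DEDUP_TOLERANCE = 0.01


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mz) and np.isfinite(self.intensity)):
            raise ValueError("peak values must be finite")
        if self.mz <= 0 or self.intensity < 0:
            raise ValueError("m/z must be positive and intensity non-negative")


@dataclass
class PeakList:
    """Centroided peaks of one sample, strictly ascending in m/z."""

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = _normalize(self.peaks)

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


def _normalize(peaks: list[Peak]) -> list[Peak]:
    """Sort ascending and merge peaks within DEDUP_TOLERANCE.

    Merged peaks get summed intensity at the intensity-weighted mean m/z.
    """
    out: list[Peak] = []
    for p in sorted(peaks, key=lambda p: p.mz):
        if out and p.mz - out[-1].mz < DEDUP_TOLERANCE:
            prev = out[-1]
            total = prev.intensity + p.intensity
            mz = (
                (prev.mz * prev.intensity + p.mz * p.intensity) / total
                if total > 0
                else (prev.mz + p.mz) / 2
            )
            out[-1] = Peak(mz, total)
        else:
            out.append(p)
    return out


def _parse_number(token: str, path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: non-numeric token {token!r}") from None


def read_peaklist(path, fmt: str | None = None, sample_id: str | None = None) -> PeakList:
    """Read a peak list from a two-column text file, CSV, or mzML.

    ``fmt`` is one of ``text2col``, ``csv``, ``mzml``; when omitted it is
    guessed from the file suffix. text2col allows ``#`` comments and blank
    lines; an empty spectrum yields an empty PeakList. mzML ingestion takes
    the centroid arrays of MS1 spectra.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".csv": "csv", ".mzml": "mzml"}.get(path.suffix.lower(), "text2col")
    sample_id = sample_id or path.stem
    if fmt == "mzml":
        return _read_mzml(path, sample_id)

    peaks: list[Peak] = []
    with open(path) as fh:
        if fmt == "text2col":
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
                mz = _parse_number(fields[0], path, lineno)
                inten = _parse_number(fields[1], path, lineno)
                peaks.append(Peak(mz, inten))
        elif fmt == "csv":
            reader = csv.reader(fh)
            for lineno, row in enumerate(reader, 1):
                if not row or not "".join(row).strip():
                    continue
                try:
                    mz, inten = float(row[0]), float(row[1])
                except (ValueError, IndexError):
                    if lineno == 1:  # header row
                        continue
                    raise ValueError(f"{path}:{lineno}: unparsable row {row!r}") from None
                peaks.append(Peak(mz, inten))
        else:
            raise ValueError(f"unknown peak-list format {fmt!r}")
    return PeakList(sample_id, peaks)


def _read_mzml(path, sample_id: str) -> PeakList:
    """Minimal mzML reader: centroid arrays of MS1 spectra.

    Supports the standard schema's 32/64-bit float binary arrays, with or
    without zlib compression. Deliberately small: chromatograms, non-MS1
    levels and vendor extensions are ignored.
    """
    import base64
    import struct
    import xml.etree.ElementTree as ET
    import zlib

    ns = "{http://psi.hupo.org/ms/mzml}"

    def decode(binary_array) -> list[float]:
        accessions = {
            cv.get("accession") for cv in binary_array.iter(f"{ns}cvParam")
        }
        text = binary_array.find(f"{ns}binary").text or ""
        raw = base64.b64decode(text)
        if "MS:1000574" in accessions:  # zlib compression
            raw = zlib.decompress(raw)
        width = "f" if "MS:1000521" in accessions else "d"  # 32- vs 64-bit
        count = len(raw) // struct.calcsize(width)
        return list(struct.unpack(f"<{count}{width}", raw))

    peaks: list[Peak] = []
    for _, spectrum in ET.iterparse(str(path)):
        if spectrum.tag != f"{ns}spectrum":
            continue
        params = {
            cv.get("accession"): cv.get("value")
            for cv in spectrum.iter(f"{ns}cvParam")
        }
        if params.get("MS:1000511", "1") != "1":  # ms level
            continue
        mz_array = intensity_array = None
        for binary_array in spectrum.iter(f"{ns}binaryDataArray"):
            accessions = {
                cv.get("accession") for cv in binary_array.iter(f"{ns}cvParam")
            }
            if "MS:1000514" in accessions:  # m/z array
                mz_array = decode(binary_array)
            elif "MS:1000515" in accessions:  # intensity array
                intensity_array = decode(binary_array)
        if mz_array is None or intensity_array is None:
            continue
        peaks.extend(
            Peak(float(m), float(i)) for m, i in zip(mz_array, intensity_array)
        )
        spectrum.clear()
    return PeakList(sample_id, peaks)


def write_peaklist(peaklist: PeakList, path, fmt: str | None = None) -> None:
    """Write to text2col (default) or CSV, m/z to 4 decimals."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "text2col"
    sep = "," if fmt == "csv" else "\t"
    with open(path, "w") as fh:
        for p in peaklist:
            fh.write(f"{p.mz:.4f}{sep}{p.intensity:.4f}\n")


def merge_replicates(
    peaklists: list[PeakList], tolerance: float = 0.15, min_count: int = 2
) -> PeakList:
    """Consensus peak list across replicate spots of the same sample.

    Peaks from all replicates are pooled and greedily clustered along m/z
    (a new cluster starts when the gap to the cluster's weighted mean exceeds
    ``tolerance``); clusters seen in at least ``min_count`` distinct
    replicates survive, at their intensity-weighted mean m/z and mean summed
    intensity. Defaults mirror triplicate spotting: 2-of-3 at 0.15 Da.
    """
    if len(peaklists) < 2:
        raise ValueError("need at least two replicates to merge")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if min_count > len(peaklists):
        raise ValueError(
            f"min_count {min_count} exceeds the {len(peaklists)} replicates"
        )
    pooled = sorted(
        (p.mz, p.intensity, idx)
        for idx, pl in enumerate(peaklists)
        for p in pl
    )
    clusters: list[list[tuple[float, float, int]]] = []
    for item in pooled:
        if clusters:
            members = clusters[-1]
            wsum = sum(i for _, i, _ in members)
            ref = (
                sum(m * i for m, i, _ in members) / wsum
                if wsum > 0
                else sum(m for m, _, _ in members) / len(members)
            )
            if item[0] - ref <= tolerance:
                members.append(item)
                continue
        clusters.append([item])

    peaks = []
    for members in clusters:
        reps = {r for _, _, r in members}
        if len(reps) < min_count:
            continue
        wsum = sum(i for _, i, _ in members)
        mz = (
            sum(m * i for m, i, _ in members) / wsum
            if wsum > 0
            else sum(m for m, _, _ in members) / len(members)
        )
        peaks.append(Peak(mz, wsum / len(peaklists)))
    sample_id = peaklists[0].sample_id
    return PeakList(f"{sample_id}_consensus", peaks)


def centroid_local_maxima(
    mz: np.ndarray, intensity: np.ndarray, sample_id: str = "centroided"
) -> PeakList:
    """Naive local-maximum centroider for synthetic profile-mode data.

    Real acquisitions are expected to arrive already centroided; this exists
    only so simulated profile traces can be pushed through the same pipeline.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.shape != intensity.shape or mz.ndim != 1:
        raise ValueError("mz and intensity must be matching 1-D arrays")
    peaks = [
        Peak(mz[i], intensity[i])
        for i in range(1, len(mz) - 1)
        if intensity[i] > 0
        and intensity[i] >= intensity[i - 1]
        and intensity[i] > intensity[i + 1]
    ]
    return PeakList(sample_id, peaks)
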