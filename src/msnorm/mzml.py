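"""Minimal read-only mzML support for centroided spectra.

Only the subset of mzML needed here is handled: per-spectrum m/z and
intensity binary arrays (32/64-bit float, optionally zlib-compressed,
little-endian), plus the total-ion-current value used to select the
probe-in-source time segments of a continuous acquisition.  Profile-mode
peak picking is out of scope.
"""

from __future__ import annotations

import base64
import struct
import zlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np

__all__ = ["MzmlSpectrum", "read_mzml", "select_by_tic"]

_NS = "{http://psi.hupo.org/ms/mzml}"

# PSI-MS controlled-vocabulary accessions
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_64BIT = "MS:1000523"
_CV_32BIT = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_NO_COMPRESSION = "MS:1000576"
_CV_TIC = "MS:1000285"
_CV_CENTROID = "MS:1000127"


@dataclass(frozen=True)
class MzmlSpectrum:
    """One centroided spectrum: parallel m/z / intensity arrays plus TIC."""

    index: int
    mz: np.ndarray
    intensity: np.ndarray
    tic: float

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


def _decode_binary(elem) -> np.ndarray:
    accessions = {cv.get("accession") for cv in elem.iter(f"{_NS}cvParam")}
    text = elem.findtext(f"{_NS}binary") or ""
    raw = base64.b64decode(text)
    if _CV_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _CV_32BIT in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def read_mzml(path) -> list[MzmlSpectrum]:
    """Parse centroided spectra from an mzML file."""
    tree = ET.parse(path)
    out: list[MzmlSpectrum] = []
    for i, spec in enumerate(tree.iter(f"{_NS}spectrum")):
        mz = intensity = None
        for arr in spec.iter(f"{_NS}binaryDataArray"):
            accessions = {cv.get("accession") for cv in arr.iter(f"{_NS}cvParam")}
            if _CV_MZ_ARRAY in accessions:
                mz = _decode_binary(arr)
            elif _CV_INTENSITY_ARRAY in accessions:
                intensity = _decode_binary(arr)
        if mz is None or intensity is None:
            continue
        tic = np.nan
        for cv in spec.iter(f"{_NS}cvParam"):
            if cv.get("accession") == _CV_TIC:
                tic = float(cv.get("value", "nan"))
        if not np.isfinite(tic):
            tic = float(intensity.sum())
        out.append(MzmlSpectrum(index=i, mz=mz, intensity=intensity, tic=tic))
    if not out:
        raise ValueError(f"no spectra with binary data found in {path}")
    return out


def select_by_tic(
    spectra: list[MzmlSpectrum], threshold_fraction: float = 0.1
) -> list[MzmlSpectrum]:
    """Keep spectra whose TIC exceeds a fraction of the maximum TIC.

    A simple probe-in-source selector: during an acquisition the total ion
    current jumps by orders of magnitude while the loaded probe is in the
    source, so thresholding on TIC isolates those segments.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    tic_max = max(s.tic for s in spectra)
    return [s for s in spectra if s.tic >= threshold_fraction * tic_max]
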