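"""In-memory acquisition model and mzML reading/writing.

A :class:`Run` holds an RT-ordered list of centroided :class:`Spectrum`
objects, each tagged as a full-MS survey scan or an AIF (all-ion
fragmentation) scan.  AIF scans are encoded in mzML as MS-level-2 spectra
whose precursor isolation window spans the whole acquisition range — no
precursor was selected — plus an HCD collision-energy term.  The reader and
the indexed-mzML writer (zlib-compressed base64 binary arrays, 64-bit m/z,
32-bit intensity) are self-contained and interoperate with standard
converters and viewers via the PSI-MS controlled-vocabulary accessions.
"""

from __future__ import annotations

import base64
import hashlib
import re
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Literal
from xml.sax.saxutils import quoteattr

import numpy as np
from lxml import etree

__all__ = ["Spectrum", "Run", "read_run", "write_run"]

ScanKind = Literal["full", "AIF"]


@dataclass(frozen=True)
class Spectrum:
    """One centroided scan: retention time (minutes), polarity, kind, peaks."""

    rt: float
    polarity: int  # +1 / -1
    scan_kind: ScanKind
    mz: np.ndarray
    intensity: np.ndarray
    collision_energy: float | None = None  # eV/NCE annotation for AIF scans

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.rt < 0:
            raise ValueError("retention time must be non-negative")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("peaks must be strictly increasing in m/z")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        if self.scan_kind == "AIF" and self.collision_energy is None:
            object.__setattr__(self, "collision_energy", 20.0)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class Run:
    """An RT-ordered single-polarity acquisition of full and AIF scans."""

    spectra: list[Spectrum]
    polarity: int = 0
    nce: float | None = None
    sid_energy: float | None = None
    instrument: str = "simulated q-orbitrap"

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("a Run needs at least one spectrum")
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("spectra must be RT-ordered")
        pols = {s.polarity for s in self.spectra}
        if len(pols) > 1:
            raise ValueError("mixed polarity within one run")
        if self.polarity == 0:
            self.polarity = self.spectra[0].polarity
        elif self.polarity not in pols:
            raise ValueError("run polarity does not match its spectra")

    def scans(self, kind: ScanKind | None = None) -> Iterator[Spectrum]:
        for s in self.spectra:
            if kind is None or s.scan_kind == kind:
                yield s

    def rt_range(self) -> tuple[float, float]:
        return self.spectra[0].rt, self.spectra[-1].rt

    def scale_intensities(self, k: float) -> "Run":
        """Return a copy with every centroid intensity multiplied by ``k``."""
        return Run(
            [replace(s, intensity=s.intensity * k) for s in self.spectra],
            polarity=self.polarity,
            nce=self.nce,
            sid_energy=self.sid_energy,
            instrument=self.instrument,
        )


# ---------------------------------------------------------------------------
# writing

_MZML_NS = "http://psi.hupo.org/ms/mzml"

_POL_CV = {
    +1: '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>',
    -1: '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>',
}


def _encode_array(values: np.ndarray, dtype: str) -> tuple[str, int]:
    raw = np.asarray(values, dtype=dtype).tobytes()
    comp = zlib.compress(raw)
    return base64.b64encode(comp).decode("ascii"), len(base64.b64encode(comp))


def _binary_block(values: np.ndarray, kind: str) -> str:
    if kind == "mz":
        dtype, bits_cv, arr_cv = (
            "<f8",
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>',
        )
    else:
        dtype, bits_cv, arr_cv = (
            "<f4",
            '<cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>',
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>',
        )
    b64, enc_len = _encode_array(values, dtype)
    return (
        f'<binaryDataArray encodedLength="{enc_len}">'
        f"{bits_cv}"
        '<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>'
        f"{arr_cv}"
        f"<binary>{b64}</binary>"
        "</binaryDataArray>"
    )


def _spectrum_xml(spec: Spectrum, index: int, mz_lo: float, mz_hi: float) -> tuple[str, str]:
    sid = f"scan={index + 1}"
    ms_level = 1 if spec.scan_kind == "full" else 2
    parts = [
        f'<spectrum index="{index}" id={quoteattr(sid)} defaultArrayLength="{spec.n_peaks}">',
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>',
        '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
        _POL_CV[spec.polarity],
        '<scanList count="1">'
        '<cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>'
        "<scan>"
        f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{spec.rt!r}" '
        'unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>'
        "</scan></scanList>",
    ]
    if spec.scan_kind == "AIF":
        center = 0.5 * (mz_lo + mz_hi)
        half = 0.5 * (mz_hi - mz_lo)
        ce = spec.collision_energy if spec.collision_energy is not None else 20.0
        parts.append(
            '<precursorList count="1"><precursor>'
            "<isolationWindow>"
            f'<cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" '
            f'value="{center!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            f'<cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" '
            f'value="{half!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            f'<cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" '
            f'value="{half!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            "</isolationWindow>"
            "<activation>"
            '<cvParam cvRef="MS" accession="MS:1000422" '
            'name="beam-type collision-induced dissociation" value=""/>'
            f'<cvParam cvRef="MS" accession="MS:1000045" name="collision energy" '
            f'value="{ce!r}" unitCvRef="UO" unitAccession="UO:0000266" unitName="electronvolt"/>'
            "</activation>"
            "</precursor></precursorList>"
        )
    parts.append('<binaryDataArrayList count="2">')
    parts.append(_binary_block(spec.mz, "mz"))
    parts.append(_binary_block(spec.intensity, "intensity"))
    parts.append("</binaryDataArrayList></spectrum>")
    return sid, "".join(parts)


def write_run(run: Run, path: str | Path) -> Path:
    """Serialize a run to indexed mzML.

    AIF scans become MS-level-2 spectra with a full-range isolation window
    (the no-precursor-selection convention) and an HCD collision-energy
    annotation; full scans are MS level 1.
    """
    path = Path(path)
    all_mz = np.concatenate([s.mz for s in run.spectra if s.n_peaks]) if any(
        s.n_peaks for s in run.spectra
    ) else np.array([400.0, 1200.0])
    mz_lo = float(min(50.0, all_mz.min() - 10)) if all_mz.size else 50.0
    mz_hi = float(all_mz.max() + 10) if all_mz.size else 2000.0

    header = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        f'<indexedmzML xmlns="{_MZML_NS}" '
        'xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance" '
        f'xsi:schemaLocation="{_MZML_NS} '
        'http://psidev.info/files/ms/mzML/xsd/mzML1.1.2_idx.xsd">\n'
        f'<mzML xmlns="{_MZML_NS}" version="1.1.0" id="aiflipid_run">\n'
        '<cvList count="2">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'version="4.1.0" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology" version="09:04:2014" '
        'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        "</cvList>"
        "<fileDescription><fileContent>"
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>'
        "</fileContent></fileDescription>"
        '<softwareList count="1"><software id="aiflipid" version="0.1.0">'
        '<cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" '
        'value="aiflipid"/></software></softwareList>'
        '<instrumentConfigurationList count="1">'
        f'<instrumentConfiguration id="IC1"><cvParam cvRef="MS" accession="MS:1000031" '
        f'name="instrument model" value={quoteattr(run.instrument)}/>'
        "</instrumentConfiguration></instrumentConfigurationList>"
        '<dataProcessingList count="1"><dataProcessing id="DP1">'
        '<processingMethod order="1" softwareRef="aiflipid">'
        '<cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>'
        "</processingMethod></dataProcessing></dataProcessingList>"
        '<run id="run1" defaultInstrumentConfigurationRef="IC1">\n'
        f'<spectrumList count="{len(run.spectra)}" defaultDataProcessingRef="DP1">\n'
    )

    buf = bytearray(header.encode("utf-8"))
    offsets: list[tuple[str, int]] = []
    for i, spec in enumerate(run.spectra):
        sid, xml = _spectrum_xml(spec, i, mz_lo, mz_hi)
        offsets.append((sid, len(buf)))
        buf.extend(xml.encode("utf-8"))
        buf.extend(b"\n")
    buf.extend(b"</spectrumList>\n</run>\n</mzML>\n")

    index_offset = len(buf)
    idx = ['<indexList count="1"><index name="spectrum">']
    for sid, off in offsets:
        idx.append(f'<offset idRef={quoteattr(sid)}>{off}</offset>')
    idx.append("</index></indexList>")
    idx.append(f"<indexListOffset>{index_offset}</indexListOffset>")
    buf.extend("".join(idx).encode("utf-8"))

    sha = hashlib.sha1(bytes(buf)).hexdigest()
    buf.extend(f"<fileChecksum>{sha}</fileChecksum></indexedmzML>\n".encode("utf-8"))
    path.write_bytes(bytes(buf))
    return path


# ---------------------------------------------------------------------------
# reading

def _centroid_profile(mz: np.ndarray, inten: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Very simple profile centroiding: local maxima with flank-weighted m/z."""
    if mz.size < 3:
        return mz, inten
    peaks_mz, peaks_i = [], []
    for j in range(1, mz.size - 1):
        if inten[j] > 0 and inten[j] >= inten[j - 1] and inten[j] > inten[j + 1]:
            lo, hi = j - 1, j + 1
            w = inten[lo : hi + 1]
            peaks_mz.append(float(np.average(mz[lo : hi + 1], weights=np.maximum(w, 1e-12))))
            peaks_i.append(float(w.sum()))
    return np.asarray(peaks_mz), np.asarray(peaks_i)


def _cv(el: etree._Element, accession: str) -> str | None:
    """Value of the first cvParam with the given accession under ``el``."""
    for p in el.iter("{*}cvParam"):
        if p.get("accession") == accession:
            return p.get("value", "")
    return None


def _cv_unit(el: etree._Element, accession: str) -> tuple[str | None, str | None]:
    for p in el.iter("{*}cvParam"):
        if p.get("accession") == accession:
            return p.get("value", ""), p.get("unitName")
    return None, None


def _decode_arrays(spec_el: etree._Element, index: int) -> tuple[np.ndarray, np.ndarray]:
    mz = inten = None
    for arr in spec_el.iter("{*}binaryDataArray"):
        acc = {p.get("accession") for p in arr.iter("{*}cvParam")}
        binary = arr.find("{*}binary")
        raw = base64.b64decode((binary.text or "").encode("ascii")) if binary is not None else b""
        if "MS:1000574" in acc:  # zlib
            raw = zlib.decompress(raw)
        dtype = "<f8" if "MS:1000523" in acc else "<f4"
        values = np.frombuffer(raw, dtype=dtype).astype(float)
        if "MS:1000514" in acc:
            mz = values
        elif "MS:1000515" in acc:
            inten = values
    if mz is None or inten is None:
        raise ValueError(f"scan {index}: missing m/z or intensity array")
    return mz, inten


def read_run(
    path: str | Path,
    centroid_profiles: bool = False,
    min_isolation_width: float = 100.0,
    aif_filter_pattern: str | None = None,
) -> Run:
    """Read an mzML file into a :class:`Run`.

    AIF scans are recognised as MS-level-2 spectra whose precursor isolation
    window is at least ``min_isolation_width`` m/z wide (i.e. no precursor
    was selected), or whose vendor filter string matches
    ``aif_filter_pattern`` when given.  Mixed polarity, profile spectra
    (unless ``centroid_profiles``) and unclassifiable scans are rejected.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    for _, spec_el in etree.iterparse(str(path), events=("end",), tag="{*}spectrum"):
        i = len(spectra)
        ms_level = int(_cv(spec_el, "MS:1000511") or 1)
        if _cv(spec_el, "MS:1000130") is not None:
            pol = +1
        elif _cv(spec_el, "MS:1000129") is not None:
            pol = -1
        else:
            raise ValueError(f"scan {i}: polarity not annotated")

        scan_el = spec_el.find("{*}scanList/{*}scan")
        rt_val, rt_unit = (_cv_unit(scan_el, "MS:1000016") if scan_el is not None
                           else (None, None))
        if rt_val is None:
            raise ValueError(f"scan {i}: no scan start time")
        rt_min = float(rt_val)
        if rt_unit and "second" in rt_unit.lower():
            rt_min /= 60.0

        mz, inten = _decode_arrays(spec_el, i)
        if _cv(spec_el, "MS:1000128") is not None:  # profile spectrum
            if not centroid_profiles:
                raise ValueError(f"scan {i} is profile mode; pass centroid_profiles=True")
            mz, inten = _centroid_profile(mz, inten)

        kind: ScanKind
        ce = None
        if ms_level == 1:
            kind = "full"
        else:
            kind_found = False
            if aif_filter_pattern is not None:
                fs = _cv(spec_el, "MS:1000512") or ""
                if fs and re.search(aif_filter_pattern, fs):
                    kind_found = True
            for prec in spec_el.iter("{*}precursor"):
                win = prec.find("{*}isolationWindow")
                if win is not None:
                    lo = float(_cv(win, "MS:1000828") or 0.0)
                    hi = float(_cv(win, "MS:1000829") or 0.0)
                    if lo + hi >= min_isolation_width:
                        kind_found = True
                act = prec.find("{*}activation")
                if act is not None:
                    ce_val = _cv(act, "MS:1000045")
                    if ce_val:
                        ce = float(ce_val)
            if not kind_found:
                raise ValueError(
                    f"scan {i}: MS level 2 but no AIF evidence "
                    "(narrow or missing isolation window)"
                )
            kind = "AIF"
        order = np.argsort(mz, kind="stable")
        spectra.append(
            Spectrum(rt_min, pol, kind, mz[order], inten[order], collision_energy=ce)
        )
        spec_el.clear()
    if not spectra:
        raise ValueError(f"{path} contains no spectra")
    return Run(spectra)
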