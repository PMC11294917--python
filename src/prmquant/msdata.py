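"""Data model and I/O for centroided LC-MS runs and targeted-acquisition tables.

The canonical retention-time unit is minutes throughout the package;
readers convert from seconds (or milliseconds) on the fly.  Spectra must be
centroided — profile data is rejected rather than peak-picked.

Supported on-disk formats:

* mzML (PSI standard) for runs — read by a self-contained parser covering
  centroided data (64/32-bit float arrays, zlib or uncompressed; RT units
  converted; precursor records honoured), written by a minimal serializer
  (uncompressed 64-bit arrays).
* CSV with headers ``target_id,precursor_mz,rt_center,rt_window,charge`` for
  inclusion lists (``rt_window`` is a *full* width; missing → 1.0 min).
* CSV ``target_id,fragment_mz,intensity`` or MSP blocks for reference MS2
  spectra; intensities are rescaled so each target's base peak is 1.0.
* Long-format CSV ``target_id,precursor_mz,product_mz,rt,intensity`` for MRM
  transition traces.
"""

from __future__ import annotations

import base64
import warnings
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "Run",
    "InclusionEntry",
    "ReferenceSpectrum",
    "TransitionTrace",
    "FormatError",
    "UnsupportedModeError",
    "read_run",
    "write_run",
    "read_inclusion_list",
    "write_inclusion_list",
    "read_reference_spectra",
    "read_transition_traces",
    "write_transition_traces",
    "read_calibration_design",
]


class FormatError(ValueError):
    """An input file violates the expected format or a type invariant."""


class UnsupportedModeError(FormatError):
    """Profile-mode spectra are not supported (no peak picking in scope)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """One centroided scan.

    ``mz``/``intensity`` are parallel arrays sorted ascending by m/z;
    ``rt`` is in minutes.  MS2 spectra carry the precursor m/z selected for
    fragmentation; MS1 spectra must not.
    """

    scan_id: str
    ms_level: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    isolation_width: float = 1.0
    collision_energy: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.ms_level not in (1, 2):
            raise ValueError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.rt < 0:
            raise ValueError(f"negative retention time: {self.rt}")
        if np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative centroid intensity")
        if self.ms_level == 1 and self.precursor_mz is not None:
            raise ValueError("MS1 spectrum must not carry a precursor m/z")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectrum requires a precursor m/z")

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass
class Run:
    """An ordered collection of spectra from one injection."""

    sample_id: str
    spectra: list[Spectrum]
    polarity: str = "positive"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.spectra = sorted(self.spectra, key=lambda s: s.rt)

    def ms1_spectra(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2_spectra(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]


@dataclass(frozen=True)
class InclusionEntry:
    """One targeted precursor: m/z plus a scheduled retention-time window.

    ``rt_window`` is the full window width; the acquisition window is
    ``rt_center ± rt_window / 2``.
    """

    target_id: str
    precursor_mz: float
    rt_center: float
    rt_window: float = 1.0
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.precursor_mz > 0:
            raise ValueError(f"{self.target_id}: precursor_mz must be > 0")
        if not self.rt_window > 0:
            raise ValueError(f"{self.target_id}: rt_window must be > 0")


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Library MS2 spectrum: fragment m/z with base-peak-relative intensities."""

    target_id: str
    fragments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError(f"{self.target_id}: reference spectrum has no fragments")
        rel = [i for _, i in self.fragments]
        if abs(max(rel) - 1.0) > 1e-9:
            raise ValueError(f"{self.target_id}: base peak must have relative intensity 1.0")
        mzs = sorted(m for m, _ in self.fragments)
        for a, b in zip(mzs, mzs[1:]):
            if b - a < 0.01:
                raise ValueError(
                    f"{self.target_id}: duplicate fragment m/z within 0.01 Th "
                    f"({a:.4f} vs {b:.4f})"
                )


@dataclass
class TransitionTrace:
    """One MRM channel: a precursor→product pair sampled over retention time."""

    target_id: str
    precursor_mz: float
    product_mz: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape or self.rt.ndim != 1:
            raise ValueError("rt and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.rt) < 0):
            order = np.argsort(self.rt, kind="stable")
            self.rt = self.rt[order]
            self.intensity = self.intensity[order]

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.rt.tolist(), self.intensity.tolist()))


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_RT_UNIT_TO_MIN = {
    "minute": 1.0,
    "second": 1.0 / 60.0,
    "millisecond": 1.0 / 60000.0,
    "UO:0000031": 1.0,
    "UO:0000010": 1.0 / 60.0,
    "UO:0000028": 1.0 / 60000.0,
}


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(el: ET.Element) -> dict[str, ET.Element]:
    """Direct cvParam children of an element, keyed by accession."""
    return {c.get("accession"): c for c in el if _local(c.tag) == "cvParam"}


def _children(el: ET.Element, name: str) -> list[ET.Element]:
    return [c for c in el if _local(c.tag) == name]


def _first(el: ET.Element, *path: str) -> ET.Element | None:
    cur = el
    for name in path:
        nxt = _children(cur, name)
        if not nxt:
            return None
        cur = nxt[0]
    return cur


def _decode_binary_array(bda: ET.Element) -> tuple[str | None, np.ndarray]:
    params = _cv_params(bda)
    dtype = "<f8"
    if "MS:1000521" in params:  # 32-bit float
        dtype = "<f4"
    elif "MS:1000522" in params:  # 64-bit integer
        dtype = "<i8"
    kind = None
    if "MS:1000514" in params:
        kind = "mz"
    elif "MS:1000515" in params:
        kind = "intensity"
    binary = _first(bda, "binary")
    raw = base64.b64decode(binary.text or "") if binary is not None else b""
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_run(path, format: str = "mzml") -> Run:
    """Read a centroided mzML file into a :class:`Run`.

    Retention times are converted to minutes regardless of the unit recorded
    in the file.  Profile-mode spectra raise :class:`UnsupportedModeError`
    (no peak picking in scope).  Both plain and indexed mzML are accepted.
    """
    if format != "mzml":
        raise FormatError(f"unsupported run format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    spectra: list[Spectrum] = []
    polarity = "positive"
    sample_id = path.stem
    try:
        context = ET.iterparse(str(path), events=("end",))
        for _, el in context:
            name = _local(el.tag)
            if name == "run":
                sample_id = el.get("id") or sample_id
                el.clear()
            elif name == "spectrum":
                spec, neg = _parse_spectrum(el)
                spectra.append(spec)
                if neg:
                    polarity = "negative"
                el.clear()
    except UnsupportedModeError:
        raise
    except ET.ParseError as exc:
        raise FormatError(f"cannot parse {path} as mzML: {exc}") from exc
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"invalid mzML content in {path}: {exc}") from exc
    if not spectra:
        raise FormatError(f"{path}: no spectra found (is this an mzML file?)")
    return Run(sample_id=sample_id, spectra=spectra, polarity=polarity)


def _parse_spectrum(el: ET.Element) -> tuple[Spectrum, bool]:
    params = _cv_params(el)
    scan_id = el.get("id", "")
    if "MS:1000128" in params:  # profile spectrum
        raise UnsupportedModeError(
            f"spectrum {scan_id!r} is profile-mode; only centroided data is supported"
        )
    if "MS:1000511" not in params:
        raise FormatError(f"spectrum {scan_id!r}: missing ms level")
    ms_level = int(params["MS:1000511"].get("value"))
    negative = "MS:1000129" in params
    scan = _first(el, "scanList", "scan")
    rt = 0.0
    if scan is not None:
        sparams = _cv_params(scan)
        if "MS:1000016" in sparams:
            p = sparams["MS:1000016"]
            unit = p.get("unitName") or p.get("unitAccession")
            rt = float(p.get("value")) * _RT_UNIT_TO_MIN.get(unit, 1.0)
    precursor_mz = None
    isolation_width = 1.0
    collision_energy = None
    prec = _first(el, "precursorList", "precursor")
    if prec is not None and ms_level == 2:
        ion = _first(prec, "selectedIonList", "selectedIon")
        if ion is None:
            raise FormatError(f"MS2 spectrum {scan_id!r}: no selected ion record")
        precursor_mz = float(_cv_params(ion)["MS:1000744"].get("value"))
        iso = _first(prec, "isolationWindow")
        if iso is not None:
            ip = _cv_params(iso)
            if "MS:1000828" in ip and "MS:1000829" in ip:
                isolation_width = float(ip["MS:1000828"].get("value")) + float(
                    ip["MS:1000829"].get("value")
                )
        act = _first(prec, "activation")
        if act is not None:
            ap = _cv_params(act)
            if "MS:1000045" in ap:
                collision_energy = float(ap["MS:1000045"].get("value"))
    mz = inten = None
    arr_list = _first(el, "binaryDataArrayList")
    if arr_list is not None:
        for bda in _children(arr_list, "binaryDataArray"):
            kind, arr = _decode_binary_array(bda)
            if kind == "mz":
                mz = arr
            elif kind == "intensity":
                inten = arr
    if mz is None or inten is None:
        raise FormatError(f"spectrum {scan_id!r}: missing m/z or intensity array")
    spec = Spectrum(
        scan_id=scan_id,
        ms_level=ms_level,
        rt=rt,
        mz=mz,
        intensity=inten,
        precursor_mz=precursor_mz,
        isolation_width=isolation_width,
        collision_energy=collision_energy,
    )
    return spec, negative


_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", **attrs) -> None:
    ET.SubElement(
        parent,
        "cvParam",
        cvRef=accession.split(":")[0],
        accession=accession,
        name=name,
        value=value,
        **attrs,
    )


def write_run(run: Run, path, rt_unit: str = "minute"):
    """Serialize a :class:`Run` as mzML 1.1.0.

    Peak arrays are stored as uncompressed little-endian 64-bit floats, so
    ``read_run(write_run(r))`` is an identity on (ms level, rt, peaks,
    precursor m/z) up to float round-trip.  ``rt_unit`` controls the unit the
    scan start times are recorded in (minutes by default).
    """
    if not run.spectra:
        raise ValueError("cannot write a run with no spectra")
    if rt_unit not in ("minute", "second"):
        raise ValueError(f"rt_unit must be minute|second, got {rt_unit!r}")
    unit_acc = "UO:0000031" if rt_unit == "minute" else "UO:0000010"
    scale = 1.0 if rt_unit == "minute" else 60.0

    root = ET.Element("mzML", xmlns=_MZML_NS, version="1.1.0")
    cv_list = ET.SubElement(root, "cvList", count="2")
    ET.SubElement(cv_list, "cv", id="MS", fullName="PSI-MS", URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    ET.SubElement(cv_list, "cv", id="UO", fullName="Unit Ontology", URI="http://ontologies.berkeleybop.org/uo.obo")
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    soft_list = ET.SubElement(root, "softwareList", count="1")
    soft = ET.SubElement(soft_list, "software", id="prmquant", version="0.1.0")
    _cv(soft, "MS:1000799", "custom unreleased software tool", value="prmquant")
    ic_list = ET.SubElement(root, "instrumentConfigurationList", count="1")
    ic = ET.SubElement(ic_list, "instrumentConfiguration", id="IC1")
    _cv(ic, "MS:1000031", "instrument model")
    dp_list = ET.SubElement(root, "dataProcessingList", count="1")
    dp = ET.SubElement(dp_list, "dataProcessing", id="DP1")
    pm = ET.SubElement(dp, "processingMethod", order="1", softwareRef="prmquant")
    _cv(pm, "MS:1000544", "Conversion to mzML")
    run_el = ET.SubElement(root, "run", id=run.sample_id, defaultInstrumentConfigurationRef="IC1")
    spec_list = ET.SubElement(
        run_el, "spectrumList", count=str(len(run.spectra)), defaultDataProcessingRef="DP1"
    )
    pol_acc, pol_name = (
        ("MS:1000130", "positive scan")
        if run.polarity == "positive"
        else ("MS:1000129", "negative scan")
    )
    for idx, spec in enumerate(run.spectra):
        sp = ET.SubElement(
            spec_list,
            "spectrum",
            index=str(idx),
            id=spec.scan_id,
            defaultArrayLength=str(spec.mz.size),
        )
        _cv(sp, "MS:1000511", "ms level", value=str(spec.ms_level))
        _cv(sp, "MS:1000579" if spec.ms_level == 1 else "MS:1000580",
            "MS1 spectrum" if spec.ms_level == 1 else "MSn spectrum")
        _cv(sp, "MS:1000127", "centroid spectrum")
        _cv(sp, pol_acc, pol_name)
        scan_list = ET.SubElement(sp, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = ET.SubElement(scan_list, "scan")
        _cv(
            scan,
            "MS:1000016",
            "scan start time",
            value=repr(spec.rt * scale),
            unitCvRef="UO",
            unitAccession=unit_acc,
            unitName=rt_unit,
        )
        if spec.ms_level == 2:
            prec_list = ET.SubElement(sp, "precursorList", count="1")
            prec = ET.SubElement(prec_list, "precursor")
            iso = ET.SubElement(prec, "isolationWindow")
            half = spec.isolation_width / 2.0
            _cv(iso, "MS:1000827", "isolation window target m/z", value=repr(spec.precursor_mz))
            _cv(iso, "MS:1000828", "isolation window lower offset", value=repr(half))
            _cv(iso, "MS:1000829", "isolation window upper offset", value=repr(half))
            sel_list = ET.SubElement(prec, "selectedIonList", count="1")
            sel = ET.SubElement(sel_list, "selectedIon")
            _cv(sel, "MS:1000744", "selected ion m/z", value=repr(spec.precursor_mz))
            act = ET.SubElement(prec, "activation")
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
            if spec.collision_energy is not None:
                _cv(act, "MS:1000045", "collision energy", value=repr(spec.collision_energy))
        arr_list = ET.SubElement(sp, "binaryDataArrayList", count="2")
        for arr, acc, name in (
            (spec.mz, "MS:1000514", "m/z array"),
            (spec.intensity, "MS:1000515", "intensity array"),
        ):
            payload = _b64(arr)
            bda = ET.SubElement(arr_list, "binaryDataArray", encodedLength=str(len(payload)))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, acc, name)
            ET.SubElement(bda, "binary").text = payload
    path = Path(path)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# delimited tables
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_inclusion_list(path) -> list[InclusionEntry]:
    """Read a CSV inclusion list (one targeted precursor per row).

    Required columns: ``target_id``, ``precursor_mz``, ``rt_center``;
    optional: ``rt_window`` (full width, default 1.0 min) and ``charge``.
    """
    df = pd.read_csv(path)
    _require_columns(df, ("target_id", "precursor_mz", "rt_center"), path)
    if df.empty:
        warnings.warn(f"{path}: empty inclusion list", stacklevel=2)
        return []
    dupes = df["target_id"][df["target_id"].duplicated()].unique()
    if len(dupes):
        raise FormatError(f"{path}: duplicate target_id(s): {sorted(map(str, dupes))}")
    entries = []
    for row in df.itertuples():
        idx = row.Index + 2  # header is line 1
        try:
            mz = float(row.precursor_mz)
            rt_center = float(row.rt_center)
            window = float(getattr(row, "rt_window", 1.0))
            if pd.isna(window):
                window = 1.0
            charge = getattr(row, "charge", None)
            charge = None if charge is None or pd.isna(charge) else int(charge)
            entries.append(
                InclusionEntry(str(row.target_id), mz, rt_center, window, charge)
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path} line {idx}: {exc}") from exc
    return entries


def write_inclusion_list(entries: list[InclusionEntry], path):
    pd.DataFrame(
        {
            "target_id": [e.target_id for e in entries],
            "precursor_mz": [e.precursor_mz for e in entries],
            "rt_center": [e.rt_center for e in entries],
            "rt_window": [e.rt_window for e in entries],
            "charge": [e.charge for e in entries],
        }
    ).to_csv(path, index=False)
    return path


def _normalize_fragments(target_id: str, frags: list[tuple[float, float]]) -> ReferenceSpectrum:
    if not frags:
        raise FormatError(f"{target_id}: no fragments")
    base = max(i for _, i in frags)
    if base <= 0:
        raise FormatError(f"{target_id}: all fragment intensities are zero")
    return ReferenceSpectrum(
        target_id=target_id,
        fragments=tuple((mz, inten / base) for mz, inten in frags),
    )


def _read_msp(path) -> dict[str, ReferenceSpectrum]:
    """Parse MSP spectral-library blocks (Name: / Num Peaks: / mz intensity)."""
    out: dict[str, ReferenceSpectrum] = {}
    name = None
    frags: list[tuple[float, float]] = []

    def flush():
        nonlocal name, frags
        if name is not None:
            out[name] = _normalize_fragments(name, frags)
        name, frags = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                flush()
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                if key.strip().lower() == "name":
                    flush()
                    name = value.strip()
                continue
            if name is None:
                raise FormatError(f"{path} line {lineno}: peak line before any Name:")
            parts = line.replace(";", " ").replace(",", " ").split()
            try:
                frags.append((float(parts[0]), float(parts[1])))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path} line {lineno}: bad peak line {line!r}") from exc
    flush()
    return out


def read_reference_spectra(path) -> dict[str, ReferenceSpectrum]:
    """Read reference MS2 spectra from CSV or MSP.

    Returns a map of target id → :class:`ReferenceSpectrum` with intensities
    rescaled so each target's base peak is 1.0.
    """
    path = Path(path)
    if path.suffix.lower() == ".msp":
        return _read_msp(path)
    df = pd.read_csv(path)
    _require_columns(df, ("target_id", "fragment_mz", "intensity"), path)
    out: dict[str, ReferenceSpectrum] = {}
    for target_id, grp in df.groupby("target_id", sort=False):
        frags = list(zip(grp["fragment_mz"].astype(float), grp["intensity"].astype(float)))
        out[str(target_id)] = _normalize_fragments(str(target_id), frags)
    if not out:
        raise FormatError(f"{path}: no reference spectra found")
    return out


def read_transition_traces(path) -> list[TransitionTrace]:
    """Read long-format MRM traces: one row per (channel, time point)."""
    df = pd.read_csv(path)
    _require_columns(df, ("target_id", "precursor_mz", "product_mz", "rt", "intensity"), path)
    traces = []
    for (tid, pre, prod), grp in df.groupby(
        ["target_id", "precursor_mz", "product_mz"], sort=False
    ):
        grp = grp.sort_values("rt")
        traces.append(
            TransitionTrace(
                target_id=str(tid),
                precursor_mz=float(pre),
                product_mz=float(prod),
                rt=grp["rt"].to_numpy(float),
                intensity=grp["intensity"].to_numpy(float),
            )
        )
    return traces


def write_transition_traces(traces: list[TransitionTrace], path):
    frames = [
        pd.DataFrame(
            {
                "target_id": t.target_id,
                "precursor_mz": t.precursor_mz,
                "product_mz": t.product_mz,
                "rt": t.rt,
                "intensity": t.intensity,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_calibration_design(path) -> pd.DataFrame:
    """Read a calibration design table: sample_id, target_id, concentration_ng_ml, replicate."""
    df = pd.read_csv(path)
    _require_columns(df, ("sample_id", "target_id", "concentration_ng_ml"), path)
    if "replicate" not in df.columns:
        df["replicate"] = 1
    if (df["concentration_ng_ml"].astype(float) < 0).any():
        raise FormatError(f"{path}: negative concentration in design")
    return df
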