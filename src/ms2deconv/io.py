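"""Readers and writers for the open formats the pipeline consumes.

mzML / mzXML are parsed with a compact internal XML reader (centroid scans,
binary arrays with optional zlib compression, precursor isolation metadata).
MGF goes through :mod:`pyteomics.mgf`; MSP through :mod:`matchms`.  Feature
tables are plain delimited text handled by pandas.

Retention-time units: seconds internally.  MGF ``RTINSECONDS`` is taken as
seconds; MSP ``RETENTIONTIME`` (the MS-DIAL dialect) as minutes and converted
on read.
"""

from __future__ import annotations

import base64
import logging
import struct
import xml.etree.ElementTree as ET
import zlib
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .spectrum import MS1Feature, RunData, Spectrum

logger = logging.getLogger(__name__)

#: fallback half-width (Th) when an MS2 scan carries no isolation metadata
DEFAULT_ISOLATION_HALF_WIDTH = 0.75

FEATURE_COLUMNS = ["mz_med", "rt_med", "mz_min", "mz_max", "rt_min", "rt_max", "intensity"]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as its declared format."""


# ---------------------------------------------------------------------------
# mzML / mzXML reading
# ---------------------------------------------------------------------------

def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(b64_text: str, precision: int, compressed: bool, big_endian=False) -> np.ndarray:
    raw = base64.b64decode(b64_text.strip())
    if compressed:
        raw = zlib.decompress(raw)
    dtype = (">" if big_endian else "<") + ("f8" if precision == 64 else "f4")
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_mzml_spectrum(elem, fallback_half_width: float) -> Spectrum | None:
    cv = {}
    for p in elem.iter():
        if _strip(p.tag) == "cvParam":
            cv.setdefault(p.get("name"), p.get("value"))
    ms_level = int(cv.get("ms level", 1))
    if "profile spectrum" in cv:
        raise FormatError(
            f"scan {elem.get('id')!r} is profile mode; centroided data required"
        )
    polarity = "negative" if "negative scan" in cv else "positive"
    rt = float("nan")
    for scan in elem.iter():
        if _strip(scan.tag) == "scan":
            for p in scan:
                if _strip(p.tag) == "cvParam" and p.get("name") == "scan start time":
                    rt = float(p.get("value"))
                    if p.get("unitName", "").startswith("minute"):
                        rt *= 60.0
            break
    precursor_mz = float("nan")
    iso_low = iso_high = float("nan")
    for node in elem.iter():
        tag = _strip(node.tag)
        if tag == "isolationWindow":
            vals = {p.get("name"): float(p.get("value")) for p in node if _strip(p.tag) == "cvParam"}
            target = vals.get("isolation window target m/z")
            if target is not None:
                iso_low = target - vals.get("isolation window lower offset", 0.0)
                iso_high = target + vals.get("isolation window upper offset", 0.0)
        elif tag == "selectedIon":
            for p in node:
                if _strip(p.tag) == "cvParam" and p.get("name") == "selected ion m/z":
                    precursor_mz = float(p.get("value"))
    arrays: dict[str, np.ndarray] = {}
    for bda in elem.iter():
        if _strip(bda.tag) != "binaryDataArray":
            continue
        precision, compressed, kind, text = 64, False, None, ""
        for p in bda:
            t = _strip(p.tag)
            if t == "cvParam":
                name = p.get("name")
                if name == "32-bit float":
                    precision = 32
                elif name == "64-bit float":
                    precision = 64
                elif name == "zlib compression":
                    compressed = True
                elif name in ("m/z array", "intensity array"):
                    kind = name
            elif t == "binary":
                text = p.text or ""
        if kind:
            arrays[kind] = _decode_binary(text, precision, compressed)
    mz = arrays.get("m/z array", np.array([]))
    inten = arrays.get("intensity array", np.array([]))
    if len(mz) == 0:
        return None
    if ms_level >= 2 and np.isnan(iso_low) and not np.isnan(precursor_mz):
        logger.warning(
            "scan %s: no isolation window metadata; falling back to precursor "
            "+/- %.2f Th", elem.get("id"), fallback_half_width,
        )
        iso_low = precursor_mz - fallback_half_width
        iso_high = precursor_mz + fallback_half_width
    return Spectrum(
        mz=mz, intensity=inten, precursor_mz=precursor_mz, precursor_rt=rt,
        ms_level=min(ms_level, 2), polarity=polarity,
        source_id=elem.get("id", ""), isolation_low=iso_low, isolation_high=iso_high,
    )


def _parse_mzxml_scan(elem, fallback_half_width: float) -> Spectrum | None:
    ms_level = int(elem.get("msLevel", 1))
    if elem.get("centroided", "1") == "0":
        raise FormatError(f"scan {elem.get('num')!r} is profile mode")
    rt_attr = elem.get("retentionTime", "PT0S")
    rt = float(rt_attr.replace("PT", "").replace("S", ""))
    polarity = "negative" if elem.get("polarity") == "-" else "positive"
    precursor_mz = float("nan")
    iso_low = iso_high = float("nan")
    mz = inten = None
    for child in elem:
        tag = _strip(child.tag)
        if tag == "precursorMz":
            precursor_mz = float(child.text)
            half = float(child.get("windowWideness", 2 * fallback_half_width)) / 2.0
            iso_low, iso_high = precursor_mz - half, precursor_mz + half
        elif tag == "peaks":
            compressed = child.get("compressionType", "none") == "zlib"
            precision = int(child.get("precision", "32"))
            pairs = _decode_binary(child.text or "", precision, compressed, big_endian=True)
            mz, inten = pairs[0::2], pairs[1::2]
    if mz is None or len(mz) == 0:
        return None
    return Spectrum(
        mz=mz, intensity=inten, precursor_mz=precursor_mz, precursor_rt=rt,
        ms_level=min(ms_level, 2), polarity=polarity,
        source_id=elem.get("num", ""), isolation_low=iso_low, isolation_high=iso_high,
    )


def read_ms_run(
    path: str | Path,
    level_filter: int | None = None,
    fallback_half_width: float = DEFAULT_ISOLATION_HALF_WIDTH,
) -> RunData:
    """Read a centroided mzML or mzXML run into a :class:`RunData`.

    MS2 scans carry precursor m/z and isolation-window bounds; scans missing
    isolation metadata get a precursor-centred fallback window and a warning.
    Profile-mode scans raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    ms1, ms2 = [], []
    try:
        if suffix == ".mzxml":
            for _, elem in ET.iterparse(str(path)):
                if _strip(elem.tag) == "scan":
                    s = _parse_mzxml_scan(elem, fallback_half_width)
                    if s is not None:
                        (ms1 if s.ms_level == 1 else ms2).append(s)
                    elem.clear()
        else:
            for _, elem in ET.iterparse(str(path)):
                if _strip(elem.tag).endswith("spectrum") and elem.get("index") is not None:
                    s = _parse_mzml_spectrum(elem, fallback_half_width)
                    if s is not None:
                        (ms1 if s.ms_level == 1 else ms2).append(s)
                    elem.clear()
    except ET.ParseError as exc:
        raise FormatError(f"cannot parse {path.name} as {suffix or 'mzML'}: {exc}") from exc
    if level_filter == 1:
        ms2 = []
    elif level_filter == 2:
        ms1 = []
    return RunData(ms1_scans=ms1, ms2_scans=ms2, source_path=str(path))


# ---------------------------------------------------------------------------
# mzML writing (for fixtures and round-trips)
# ---------------------------------------------------------------------------

def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def _spectrum_xml(idx: int, s: Spectrum) -> str:
    pol = ("MS:1000130", "positive scan") if s.polarity == "positive" else ("MS:1000129", "negative scan")
    prec = ""
    if s.ms_level == 2 and not np.isnan(s.precursor_mz):
        lo = s.isolation_low if not np.isnan(s.isolation_low) else s.precursor_mz - DEFAULT_ISOLATION_HALF_WIDTH
        hi = s.isolation_high if not np.isnan(s.isolation_high) else s.precursor_mz + DEFAULT_ISOLATION_HALF_WIDTH
        c = (lo + hi) / 2.0
        prec = (
            '<precursorList count="1"><precursor><isolationWindow>'
            f'<cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{c!r}" unitName="m/z"/>'
            f'<cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{c - lo!r}" unitName="m/z"/>'
            f'<cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{hi - c!r}" unitName="m/z"/>'
            '</isolationWindow><selectedIonList count="1"><selectedIon>'
            f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s.precursor_mz!r}" unitName="m/z"/>'
            "</selectedIon></selectedIonList><activation>"
            '<cvParam cvRef="MS" accession="MS:1000422" name="beam-type collision-induced dissociation"/>'
            "</activation></precursor></precursorList>"
        )
    mzb, inb = _b64(s.mz), _b64(s.intensity)
    sid = s.source_id or f"scan={idx + 1}"
    return (
        f'<spectrum index="{idx}" id="{sid}" defaultArrayLength="{len(s)}">'
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>'
        '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>'
        f'<cvParam cvRef="MS" accession="{pol[0]}" name="{pol[1]}"/>'
        '<scanList count="1"><scan>'
        f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.precursor_rt!r}" '
        'unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>'
        f"</scan></scanList>{prec}"
        '<binaryDataArrayList count="2">'
        f'<binaryDataArray encodedLength="{len(mzb)}">'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
        '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" unitName="m/z"/>'
        f"<binary>{mzb}</binary></binaryDataArray>"
        f'<binaryDataArray encodedLength="{len(inb)}">'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
        '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" unitName="number of detector counts"/>'
        f"<binary>{inb}</binary></binaryDataArray>"
        "</binaryDataArrayList></spectrum>"
    )


def write_mzml(run: RunData, path: str | Path) -> None:
    """Serialize a run to a minimal centroid-mode mzML file."""
    scans = sorted(run.ms1_scans + run.ms2_scans, key=lambda s: s.precursor_rt)
    body = "".join(_spectrum_xml(i, s) for i, s in enumerate(scans))
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        '<cvList count="2">'
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="UNIT-ONTOLOGY" URI="http://ontologies.berkeleybop.org/uo.obo"/>'
        "</cvList>"
        f'<run id="run"><spectrumList count="{len(scans)}">{body}</spectrumList></run></mzML>'
    )
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# MGF / MSP
# ---------------------------------------------------------------------------

def _count_mgf_blocks(path: Path) -> None:
    text = path.read_text()
    n_begin = text.count("BEGIN IONS")
    n_end = text.count("END IONS")
    if n_begin != n_end:
        raise FormatError(
            f"{path.name}: truncated MGF block #{min(n_begin, n_end) + 1} "
            f"({n_begin} BEGIN IONS vs {n_end} END IONS)"
        )


def read_spectra_file(path: str | Path, dialect: str | None = None) -> list[Spectrum]:
    """Read MGF or MSP spectra (one :class:`Spectrum` per block).

    Empty blocks ("Num Peaks: 0") are logged and excluded.  The dialect is
    inferred from the file suffix when not given.
    """
    path = Path(path)
    dialect = dialect or path.suffix.lstrip(".").lower()
    if dialect == "mgf":
        _count_mgf_blocks(path)
        out = []
        with _mgf.read(str(path)) as reader:
            for k, entry in enumerate(reader):
                params = entry["params"]
                if len(entry["m/z array"]) == 0:
                    logger.warning("%s: block %d has no peaks; excluded", path.name, k)
                    continue
                rt = params.get("rtinseconds")
                if rt is None and "retention_time" in params:
                    rt = float(params["retention_time"]) * 60.0
                pep = params.get("pepmass", (float("nan"),))
                out.append(Spectrum(
                    mz=entry["m/z array"], intensity=entry["intensity array"],
                    precursor_mz=float(pep[0]) if pep[0] is not None else float("nan"),
                    precursor_rt=float(rt) if rt is not None else float("nan"),
                    source_id=str(params.get("title", k)),
                    metadata={k2: v for k2, v in params.items() if k2 not in ("pepmass",)},
                ))
        return out
    if dialect == "msp":
        from matchms.importing import load_from_msp

        n_blocks = sum(
            1 for line in path.read_text().splitlines()
            if line.strip().lower().startswith(("name:", "compound_name:"))
        )
        out = []
        for k, ms in enumerate(load_from_msp(str(path), metadata_harmonization=True)):
            if ms is None or len(ms.peaks.mz) == 0:
                logger.warning("%s: block %d is empty; excluded", path.name, k)
                continue
            meta = dict(ms.metadata)
            rt = meta.get("retention_time")
            # MS-DIAL writes RETENTIONTIME in minutes
            rt_s = float(rt) * 60.0 if rt is not None else float("nan")
            out.append(Spectrum(
                mz=ms.peaks.mz, intensity=ms.peaks.intensities,
                precursor_mz=float(meta.get("precursor_mz", float("nan"))),
                precursor_rt=rt_s,
                source_id=str(meta.get("compound_name", k)),
                metadata=meta,
            ))
        if n_blocks and len(out) < n_blocks:
            logger.warning(
                "%s: %d of %d MSP blocks were empty or unparseable and were excluded",
                path.name, n_blocks - len(out), n_blocks,
            )
        return out
    raise FormatError(f"unknown spectra dialect {dialect!r}")


def write_spectra_file(spectra: Iterable[Spectrum], path: str | Path, dialect: str | None = None) -> None:
    """Write spectra as MGF or MSP."""
    path = Path(path)
    dialect = dialect or path.suffix.lstrip(".").lower()
    if dialect == "mgf":
        entries = []
        for s in spectra:
            params = {"title": s.source_id}
            if not np.isnan(s.precursor_mz):
                params["pepmass"] = s.precursor_mz
            if not np.isnan(s.precursor_rt):
                params["rtinseconds"] = s.precursor_rt
            entries.append({
                "m/z array": s.mz, "intensity array": s.intensity, "params": params,
            })
        _mgf.write(entries, str(path), file_mode="w")
        return
    if dialect == "msp":
        lines = []
        for s in spectra:
            lines.append(f"NAME: {s.source_id or 'unknown'}")
            if not np.isnan(s.precursor_mz):
                lines.append(f"PRECURSORMZ: {s.precursor_mz:.6f}")
            if not np.isnan(s.precursor_rt):
                lines.append(f"RETENTIONTIME: {s.precursor_rt / 60.0:.6f}")
            lines.append(f"Num Peaks: {len(s)}")
            for m, i in zip(s.mz, s.intensity):
                lines.append(f"{m:.6f}\t{i:.6f}")
            lines.append("")
        path.write_text("\n".join(lines))
        return
    raise FormatError(f"unknown spectra dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path) -> list[MS1Feature]:
    """Read a delimited MS1 feature table (csv or tsv)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"mz_med", "rt_med"} - set(df.columns)
    if missing:
        raise FormatError(f"feature table lacks required columns: {sorted(missing)}")
    feats = []
    for idx, row in df.iterrows():
        feats.append(MS1Feature(
            mz_med=row["mz_med"], rt_med=row["rt_med"],
            mz_min=row.get("mz_min", float("nan")), mz_max=row.get("mz_max", float("nan")),
            rt_min=row.get("rt_min", float("nan")), rt_max=row.get("rt_max", float("nan")),
            intensity=row.get("intensity", 0.0),
            feature_id=str(row["feature_id"]) if "feature_id" in df.columns else f"F{idx}",
        ))
    return feats


def write_feature_table(features: list[MS1Feature], path: str | Path) -> None:
    rows = [
        {
            "feature_id": f.feature_id, "mz_med": f.mz_med, "rt_med": f.rt_med,
            "mz_min": f.mz_min, "mz_max": f.mz_max, "rt_min": f.rt_min,
            "rt_max": f.rt_max, "intensity": f.intensity,
        }
        for f in features
    ]
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
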