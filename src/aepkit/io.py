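"""Read and write AEP waveform records in XML and CSV.

The XML dialect is owned by this package (vendor export schemas are not
public) and is documented in ``docs/formats.md``.  In short::

    <aep_records>
      <record id="r1" patient="p1" ear="left" subtype="ABR" fs_hz="30000">
        <stimulus type="click" rate_hz="22" intensity_db_nhl="80"
                  highpass_hz="33" lowpass_hz="1500"/>
        <samples unit="uV">0.01 -0.02 ...</samples>
      </record>
    </aep_records>

Voltage values are written as shortest-round-trip decimal text (``repr``),
so reading back a written file reproduces the float64 series bit-exactly.
The CSV layout is long format with columns ``record_id, patient_id, ear,
subtype, fs_hz, sample_index, value_uv``; stimulus metadata is not part of
the CSV schema and subtype defaults are applied on read (with a logged
notice).  Reading performs no resampling, filtering, or scaling.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree

from .errors import RecordParseError, ValidationError
from .records import AEPRecord, StimulusConfig

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["record_id", "patient_id", "ear", "subtype", "fs_hz",
               "sample_index", "value_uv"]


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("xml", "csv"):
            raise ValueError(f"format must be 'xml' or 'csv', got {format!r}")
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("xml", "csv"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_records(path, format: str | None = None) -> list[AEPRecord]:
    """Read a collection of :class:`AEPRecord` from ``path``.

    Records are returned in file order.  Malformed files raise
    :class:`RecordParseError` naming the offending line/element; a record
    violating an invariant raises :class:`ValidationError` naming the record
    and field.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    return _read_xml(path) if fmt == "xml" else _read_csv(path)


def write_records(records: Iterable[AEPRecord], path, format: str | None = None) -> None:
    """Write records to ``path``; inverse of :func:`read_records`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    records = list(records)
    if fmt == "xml":
        _write_xml(records, path)
    else:
        _write_csv(records, path)


# ---------------------------------------------------------------- XML

_STIM_ATTRS = [("type", "stimulus_type", str), ("rate_hz", "rate_hz", float),
               ("intensity_db_nhl", "intensity_db_nhl", float),
               ("highpass_hz", "highpass_hz", float),
               ("lowpass_hz", "lowpass_hz", float)]


def _read_xml(path: Path) -> list[AEPRecord]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise RecordParseError(f"{path.name}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "aep_records":
        raise RecordParseError(
            f"{path.name}: line {root.sourceline}: expected root element "
            f"<aep_records>, found <{root.tag}>")
    out: list[AEPRecord] = []
    for el in root.iterchildren(tag=etree.Element):
        if el.tag != "record":
            raise RecordParseError(
                f"{path.name}: line {el.sourceline}: unexpected element <{el.tag}>")
        rid = el.get("id")
        if rid is None:
            raise RecordParseError(
                f"{path.name}: line {el.sourceline}: <record> missing 'id'")
        try:
            attrs = {a: el.get(a) for a in ("patient", "ear", "subtype", "fs_hz")}
            missing = [a for a, v in attrs.items() if v is None]
            if missing:
                raise RecordParseError(
                    f"{path.name}: line {el.sourceline}: record {rid!r} missing "
                    f"attribute(s) {missing}")
            stim_el = el.find("stimulus")
            stimulus = None
            if stim_el is not None:
                kwargs = {}
                for attr, fieldname, conv in _STIM_ATTRS:
                    raw = stim_el.get(attr)
                    if raw is None:
                        raise RecordParseError(
                            f"{path.name}: line {stim_el.sourceline}: <stimulus> "
                            f"missing attribute {attr!r}")
                    kwargs[fieldname] = conv(raw)
                stimulus = StimulusConfig(**kwargs)
            else:
                logger.info("record %s: no <stimulus> element; applying %s defaults",
                            rid, attrs["subtype"])
            samp_el = el.find("samples")
            if samp_el is None or samp_el.text is None:
                raise RecordParseError(
                    f"{path.name}: line {el.sourceline}: record {rid!r} has no "
                    f"<samples> element")
            samples = np.array(samp_el.text.split(), dtype=np.float64)
            out.append(AEPRecord(
                record_id=rid, patient_id=attrs["patient"], ear=attrs["ear"],
                subtype=attrs["subtype"], fs_hz=float(attrs["fs_hz"]),
                samples=samples, stimulus=stimulus))
        except ValueError as exc:
            raise RecordParseError(
                f"{path.name}: line {el.sourceline}: record {rid!r}: {exc}") from exc
    return out


def _write_xml(records: Sequence[AEPRecord], path: Path) -> None:
    root = etree.Element("aep_records")
    for rec in records:
        el = etree.SubElement(root, "record", id=rec.record_id,
                              patient=rec.patient_id, ear=rec.ear,
                              subtype=rec.subtype, fs_hz=repr(float(rec.fs_hz)))
        stim = rec.stimulus
        etree.SubElement(el, "stimulus", type=stim.stimulus_type,
                         rate_hz=repr(float(stim.rate_hz)),
                         intensity_db_nhl=repr(float(stim.intensity_db_nhl)),
                         highpass_hz=repr(float(stim.highpass_hz)),
                         lowpass_hz=repr(float(stim.lowpass_hz)))
        samp = etree.SubElement(el, "samples", unit="uV")
        samp.text = " ".join(repr(v) for v in rec.samples.tolist())
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------- CSV

def _read_csv(path: Path) -> list[AEPRecord]:
    try:
        df = pd.read_csv(path, dtype={"record_id": str, "patient_id": str},
                         float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise RecordParseError(f"{path.name}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise RecordParseError(f"{path.name}: missing column(s) {missing}")
    out: list[AEPRecord] = []
    if df.empty:
        return out
    for rid, grp in df.groupby("record_id", sort=False):
        grp = grp.sort_values("sample_index")
        idx = grp["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise RecordParseError(
                f"{path.name}: record {rid!r}: sample_index must run 0..n-1 "
                f"without gaps")
        meta = grp.iloc[0]
        logger.info("record %s: CSV carries no stimulus metadata; applying %s "
                    "defaults", rid, meta["subtype"])
        out.append(AEPRecord(
            record_id=str(rid), patient_id=str(meta["patient_id"]),
            ear=str(meta["ear"]), subtype=str(meta["subtype"]),
            fs_hz=float(meta["fs_hz"]),
            samples=grp["value_uv"].to_numpy(dtype=np.float64)))
    return out


def _write_csv(records: Sequence[AEPRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for rec in records:
            prefix = (f"{rec.record_id},{rec.patient_id},{rec.ear},"
                      f"{rec.subtype},{repr(float(rec.fs_hz))}")
            for i, v in enumerate(rec.samples.tolist()):
                fh.write(f"{prefix},{i},{repr(v)}\n")
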