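"""Minimal DICOM codec: explicit VR little endian, part-10 files.

Supports exactly the subset of the standard this package reads and writes —
single-frame CT/PT image objects with rescale and radiopharmaceutical
metadata, and RTSTRUCT contour objects. Sequences are written with defined
lengths; the reader also tolerates undefined-length sequences and items.
"""

from __future__ import annotations

import struct
from pathlib import Path

from .core import InputError, MetadataError

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
PET_STORAGE = "1.2.840.10008.5.1.4.1.1.128"
RTSTRUCT_STORAGE = "1.2.840.10008.5.1.4.1.1.481.3"

# UID root reserved for locally generated identifiers.
_UID_ROOT = "2.25"

_LONG_VRS = {"OB", "OW", "OF", "SQ", "UT", "UN"}
_STRING_VRS = {"AE", "AS", "CS", "DA", "DS", "DT", "IS", "LO", "LT",
               "PN", "SH", "ST", "TM", "UI", "UT"}

# keyword -> (group, element, VR)
DICT: dict[str, tuple[int, int, str]] = {
    "FileMetaInformationGroupLength": (0x0002, 0x0000, "UL"),
    "MediaStorageSOPClassUID": (0x0002, 0x0002, "UI"),
    "MediaStorageSOPInstanceUID": (0x0002, 0x0003, "UI"),
    "TransferSyntaxUID": (0x0002, 0x0010, "UI"),
    "SOPClassUID": (0x0008, 0x0016, "UI"),
    "SOPInstanceUID": (0x0008, 0x0018, "UI"),
    "AcquisitionDate": (0x0008, 0x0022, "DA"),
    "AcquisitionTime": (0x0008, 0x0032, "TM"),
    "Modality": (0x0008, 0x0060, "CS"),
    "PatientName": (0x0010, 0x0010, "PN"),
    "PatientWeight": (0x0010, 0x1030, "DS"),
    "SliceThickness": (0x0018, 0x0050, "DS"),
    "RadiopharmaceuticalStartTime": (0x0018, 0x1072, "TM"),
    "RadionuclideTotalDose": (0x0018, 0x1074, "DS"),
    "RadionuclideHalfLife": (0x0018, 0x1075, "DS"),
    "StudyInstanceUID": (0x0020, 0x000D, "UI"),
    "SeriesInstanceUID": (0x0020, 0x000E, "UI"),
    "SeriesNumber": (0x0020, 0x0011, "IS"),
    "InstanceNumber": (0x0020, 0x0013, "IS"),
    "ImagePositionPatient": (0x0020, 0x0032, "DS"),
    "ImageOrientationPatient": (0x0020, 0x0037, "DS"),
    "FrameOfReferenceUID": (0x0020, 0x0052, "UI"),
    "SamplesPerPixel": (0x0028, 0x0002, "US"),
    "PhotometricInterpretation": (0x0028, 0x0004, "CS"),
    "Rows": (0x0028, 0x0010, "US"),
    "Columns": (0x0028, 0x0011, "US"),
    "PixelSpacing": (0x0028, 0x0030, "DS"),
    "BitsAllocated": (0x0028, 0x0100, "US"),
    "BitsStored": (0x0028, 0x0101, "US"),
    "HighBit": (0x0028, 0x0102, "US"),
    "PixelRepresentation": (0x0028, 0x0103, "US"),
    "RescaleIntercept": (0x0028, 0x1052, "DS"),
    "RescaleSlope": (0x0028, 0x1053, "DS"),
    "RadiopharmaceuticalInformationSequence": (0x0054, 0x0016, "SQ"),
    "Units": (0x0054, 0x1001, "CS"),
    "DecayCorrection": (0x0054, 0x1102, "CS"),
    "StructureSetLabel": (0x3006, 0x0002, "SH"),
    "StructureSetROISequence": (0x3006, 0x0020, "SQ"),
    "ROINumber": (0x3006, 0x0022, "IS"),
    "ReferencedFrameOfReferenceUID": (0x3006, 0x0024, "UI"),
    "ROIName": (0x3006, 0x0026, "LO"),
    "ROIContourSequence": (0x3006, 0x0039, "SQ"),
    "ContourSequence": (0x3006, 0x0040, "SQ"),
    "ContourGeometricType": (0x3006, 0x0042, "CS"),
    "NumberOfContourPoints": (0x3006, 0x0046, "IS"),
    "ContourData": (0x3006, 0x0050, "DS"),
    "ReferencedROINumber": (0x3006, 0x0084, "IS"),
    "PixelData": (0x7FE0, 0x0010, "OW"),
}

_TAG_TO_KEYWORD = {(g, e): kw for kw, (g, e, _vr) in DICT.items()}

_uid_counter = 0


def new_uid() -> str:
    """A fresh (process-unique) UID under the local root."""
    global _uid_counter
    _uid_counter += 1
    import os
    import time
    return f"{_UID_ROOT}.{os.getpid()}.{int(time.time() * 1000)}.{_uid_counter}"


def format_ds(value: float) -> str:
    """Format a number as a DICOM decimal string (<= 16 characters)."""
    if float(value) == int(value) and abs(value) < 1e15:
        return str(int(value))
    s = f"{value:.10g}"
    if len(s) > 16:
        s = f"{value:.8g}"
    if len(s) > 16:
        s = f"{value:.6e}"
    return s


class Dataset(dict):
    """A DICOM dataset keyed by tag ``(group, element)``, values ``(vr, value)``.

    Keyword access goes through the local dictionary: ``ds["Rows"]`` or
    ``ds.get("Rows", default)``.
    """

    def kw(self, keyword: str) -> tuple[int, int]:
        try:
            g, e, _ = DICT[keyword]
        except KeyError:
            raise KeyError(f"unknown DICOM keyword {keyword!r}") from None
        return (g, e)

    def __contains__(self, key) -> bool:  # type: ignore[override]
        if isinstance(key, str):
            key = self.kw(key)
        return dict.__contains__(self, key)

    def __getitem__(self, key):
        if isinstance(key, str):
            tag = self.kw(key)
            if not dict.__contains__(self, tag):
                raise MetadataError(f"missing DICOM tag {key} "
                                    f"({tag[0]:04X},{tag[1]:04X})")
            return dict.__getitem__(self, tag)[1]
        return dict.__getitem__(self, key)

    def get(self, key, default=None):  # type: ignore[override]
        try:
            if isinstance(key, str):
                return self[key]
        except MetadataError:
            return default
        return dict.get(self, key, default)

    def set(self, keyword: str, value) -> None:
        g, e, vr = DICT[keyword]
        dict.__setitem__(self, (g, e), (vr, value))


# ---------------------------------------------------------------- encoding

def _pad(raw: bytes, vr: str) -> bytes:
    if len(raw) % 2:
        raw += b"\x00" if vr == "UI" else b" "
    return raw


def _encode_value(vr: str, value) -> bytes:
    if vr == "SQ":
        out = b""
        for item in value:
            body = _encode_dataset(item)
            out += struct.pack("<HHI", 0xFFFE, 0xE000, len(body)) + body
        return out
    if vr in ("OB", "OW"):
        return value if len(value) % 2 == 0 else value + b"\x00"
    if vr == "US":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}H", *[int(v) for v in vals])
    if vr == "UL":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}I", *[int(v) for v in vals])
    if vr in ("SS", "SL"):
        fmt = "h" if vr == "SS" else "i"
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}{fmt}", *[int(v) for v in vals])
    if vr in ("FL", "FD"):
        fmt = "f" if vr == "FL" else "d"
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}{fmt}", *[float(v) for v in vals])
    if vr == "DS":
        if isinstance(value, (list, tuple)):
            s = "\\".join(v if isinstance(v, str) else format_ds(v) for v in value)
        elif isinstance(value, str):
            s = value
        else:
            s = format_ds(value)
        return _pad(s.encode("ascii"), vr)
    if vr == "IS":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return _pad("\\".join(str(int(v)) for v in vals).encode("ascii"), vr)
    if vr in _STRING_VRS:
        if isinstance(value, (list, tuple)):
            value = "\\".join(str(v) for v in value)
        return _pad(str(value).encode("ascii"), vr)
    raise InputError(f"cannot encode VR {vr}")


def _decode_value(vr: str, raw: bytes):
    if vr in ("OB", "OW", "UN"):
        return raw
    if vr == "US":
        vals = list(struct.unpack(f"<{len(raw) // 2}H", raw))
    elif vr == "UL":
        vals = list(struct.unpack(f"<{len(raw) // 4}I", raw))
    elif vr == "SS":
        vals = list(struct.unpack(f"<{len(raw) // 2}h", raw))
    elif vr == "SL":
        vals = list(struct.unpack(f"<{len(raw) // 4}i", raw))
    elif vr == "FL":
        vals = list(struct.unpack(f"<{len(raw) // 4}f", raw))
    elif vr == "FD":
        vals = list(struct.unpack(f"<{len(raw) // 8}d", raw))
    elif vr == "DS":
        s = raw.decode("ascii").strip("\x00 ")
        vals = [float(p) for p in s.split("\\")] if s else []
    elif vr == "IS":
        s = raw.decode("ascii").strip("\x00 ")
        vals = [int(p) for p in s.split("\\")] if s else []
    elif vr in _STRING_VRS:
        s = raw.decode("ascii", errors="replace").strip("\x00 ")
        parts = s.split("\\")
        return parts[0] if len(parts) == 1 else parts
    else:
        return raw
    if not vals:
        return None
    return vals[0] if len(vals) == 1 else vals


def _encode_element(group: int, elem: int, vr: str, value) -> bytes:
    raw = _encode_value(vr, value)
    head = struct.pack("<HH", group, elem) + vr.encode("ascii")
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(raw)) + raw
    if len(raw) > 0xFFFF:
        raise InputError(f"value too long for short VR {vr}")
    return head + struct.pack("<H", len(raw)) + raw


def _encode_dataset(ds: Dataset) -> bytes:
    out = b""
    for (group, elem) in sorted(ds.keys()):
        vr, value = dict.__getitem__(ds, (group, elem))
        out += _encode_element(group, elem, vr, value)
    return out


# ---------------------------------------------------------------- decoding

def _parse_dataset(buf: bytes, pos: int, end: int) -> tuple[Dataset, int]:
    ds = Dataset()
    while pos < end:
        group, elem = struct.unpack_from("<HH", buf, pos)
        pos += 4
        if (group, elem) == (0xFFFE, 0xE00D):  # item delimiter
            pos += 4
            break
        vr = buf[pos:pos + 2].decode("ascii")
        if vr in _LONG_VRS:
            length = struct.unpack_from("<I", buf, pos + 4)[0]
            pos += 8
        else:
            length = struct.unpack_from("<H", buf, pos + 2)[0]
            pos += 4
        if vr == "SQ":
            items, pos = _parse_sequence(buf, pos, length)
            ds[(group, elem)] = ("SQ", items)
        else:
            if length == 0xFFFFFFFF:
                raise InputError("undefined length outside a sequence")
            raw = buf[pos:pos + length]
            pos += length
            ds[(group, elem)] = (vr, _decode_value(vr, raw))
    return ds, pos


def _parse_sequence(buf: bytes, pos: int, length: int) -> tuple[list, int]:
    items: list[Dataset] = []
    seq_end = len(buf) if length == 0xFFFFFFFF else pos + length
    while pos < seq_end:
        group, elem = struct.unpack_from("<HH", buf, pos)
        item_len = struct.unpack_from("<I", buf, pos + 4)[0]
        pos += 8
        if (group, elem) == (0xFFFE, 0xE0DD):  # sequence delimiter
            break
        if (group, elem) != (0xFFFE, 0xE000):
            raise InputError(f"malformed sequence item tag "
                             f"({group:04X},{elem:04X})")
        if item_len == 0xFFFFFFFF:
            item, pos = _parse_dataset(buf, pos, len(buf))
        else:
            item, pos = _parse_dataset(buf, pos, pos + item_len)
        items.append(item)
    return items, pos


# ---------------------------------------------------------------- file I/O

def dcmwrite(path: str | Path, ds: Dataset) -> None:
    """Write a dataset as a part-10 file (explicit VR little endian)."""
    meta = Dataset()
    meta.set("MediaStorageSOPClassUID", ds.get("SOPClassUID", ""))
    meta.set("MediaStorageSOPInstanceUID", ds.get("SOPInstanceUID", ""))
    meta.set("TransferSyntaxUID", EXPLICIT_VR_LE)
    meta_body = _encode_dataset(meta)
    meta.set("FileMetaInformationGroupLength", len(meta_body))
    body = (b"\x00" * 128 + b"DICM"
            + _encode_dataset(meta) + _encode_dataset(ds))
    Path(path).write_bytes(body)


def dcmread(path: str | Path) -> Dataset:
    """Read a part-10 explicit-VR-little-endian file."""
    buf = Path(path).read_bytes()
    if buf[128:132] != b"DICM":
        raise InputError(f"{path}: not a DICOM part-10 file")
    ds, _ = _parse_dataset(buf, 132, len(buf))
    ts = ds.get("TransferSyntaxUID", EXPLICIT_VR_LE)
    if ts != EXPLICIT_VR_LE:
        raise InputError(f"{path}: unsupported transfer syntax {ts}")
    return ds


def is_dicom(path: str | Path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False
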