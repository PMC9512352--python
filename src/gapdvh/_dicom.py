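"""Minimal DICOM part-10 codec: explicit VR little endian, uncompressed.

Only the narrow dialect produced by this package's phantom writer (and by
mainstream TPS exports of RT Dose / RT Structure Set objects in explicit VR
little endian) is supported.  Datasets are plain dicts keyed by ``(group,
element)`` tag tuples; sequence values are lists of nested dicts.  Values are
decoded per VR: DS/IS/US/UL/FL/FD to numbers (a list when multivalued),
string VRs to stripped ``str``, OB/OW to raw ``bytes``.
"""

from __future__ import annotations

import struct
from typing import Any

from .errors import FormatError

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
RT_DOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
RT_STRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
_IMPLEMENTATION_UID = "1.2.826.0.1.3680043.10.1291.1"

# VRs using the 2-byte-reserved + 4-byte-length layout
_LONG_VRS = {"OB", "OW", "OF", "SQ", "UT", "UN"}
_STRING_VRS = {"AE", "AS", "CS", "DA", "DS", "DT", "IS", "LO", "LT", "PN",
               "SH", "ST", "TM", "UI", "UT"}

_ITEM = (0xFFFE, 0xE000)
_ITEM_DELIM = (0xFFFE, 0xE00D)
_SEQ_DELIM = (0xFFFE, 0xE0DD)

Tag = tuple[int, int]
Dataset = dict[Tag, tuple[str, Any]]


# ---------------------------------------------------------------------------
# encoding

def _encode_value(vr: str, value: Any) -> bytes:
    if vr == "SQ":
        out = b""
        for item in value:
            body = encode_dataset(item)
            out += struct.pack("<HHI", *_ITEM, len(body)) + body
        return out
    if vr in ("OB", "OW"):
        return bytes(value)
    if vr == "US":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}H", *vals)
    if vr == "UL":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}I", *vals)
    if vr == "FD":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}d", *vals)
    if vr == "DS":
        vals = value if isinstance(value, (list, tuple)) else [value]
        text = "\\".join(f"{float(v):.10g}" for v in vals)
    elif vr == "IS":
        vals = value if isinstance(value, (list, tuple)) else [value]
        text = "\\".join(str(int(v)) for v in vals)
    elif vr in _STRING_VRS:
        vals = value if isinstance(value, (list, tuple)) else [value]
        text = "\\".join(str(v) for v in vals)
    else:
        raise FormatError(f"unsupported VR for encoding: {vr}")
    data = text.encode("ascii")
    if len(data) % 2:
        data += b"\x00" if vr == "UI" else b" "
    return data


def _encode_element(tag: Tag, vr: str, value: Any) -> bytes:
    data = _encode_value(vr, value)
    group, elem = tag
    if vr in _LONG_VRS:
        head = struct.pack("<HH2sHI", group, elem, vr.encode(), 0, len(data))
    else:
        if len(data) > 0xFFFF:
            raise FormatError(f"value too long for short-form VR {vr}")
        head = struct.pack("<HH2sH", group, elem, vr.encode(), len(data))
    return head + data


def encode_dataset(ds: Dataset) -> bytes:
    return b"".join(
        _encode_element(tag, vr, value)
        for tag, (vr, value) in sorted(ds.items())
    )


def write_file(path: str, sop_class_uid: str, sop_instance_uid: str,
               dataset: Dataset) -> None:
    """Write a part-10 file (128-byte preamble, DICM, file meta, dataset)."""
    meta: Dataset = {
        (0x0002, 0x0001): ("OB", b"\x00\x01"),
        (0x0002, 0x0002): ("UI", sop_class_uid),
        (0x0002, 0x0003): ("UI", sop_instance_uid),
        (0x0002, 0x0010): ("UI", EXPLICIT_VR_LE),
        (0x0002, 0x0012): ("UI", _IMPLEMENTATION_UID),
    }
    meta_bytes = encode_dataset(meta)
    group_len = _encode_element((0x0002, 0x0000), "UL", len(meta_bytes))
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128)
        fh.write(b"DICM")
        fh.write(group_len)
        fh.write(meta_bytes)
        fh.write(encode_dataset(dataset))


# ---------------------------------------------------------------------------
# decoding

def _decode_value(vr: str, data: bytes) -> Any:
    if vr in ("OB", "OW", "UN"):
        return data
    if vr == "US":
        vals = list(struct.unpack(f"<{len(data) // 2}H", data))
    elif vr == "UL":
        vals = list(struct.unpack(f"<{len(data) // 4}I", data))
    elif vr == "FD":
        vals = list(struct.unpack(f"<{len(data) // 8}d", data))
    elif vr == "DS":
        text = data.decode("ascii").strip("\x00 ")
        vals = [float(v) for v in text.split("\\")] if text else []
    elif vr == "IS":
        text = data.decode("ascii").strip("\x00 ")
        vals = [int(v) for v in text.split("\\")] if text else []
    elif vr in _STRING_VRS:
        text = data.decode("ascii").strip("\x00 ")
        parts = text.split("\\")
        return parts[0].strip() if len(parts) == 1 else [p.strip() for p in parts]
    else:
        raise FormatError(f"unsupported VR for decoding: {vr}")
    if len(vals) == 1:
        return vals[0]
    return vals


class _Reader:
    def __init__(self, buf: bytes, pos: int = 0):
        self.buf = buf
        self.pos = pos

    def read(self, n: int) -> bytes:
        if self.pos + n > len(self.buf):
            raise FormatError("truncated DICOM stream")
        out = self.buf[self.pos:self.pos + n]
        self.pos += n
        return out

    def peek_tag(self) -> Tag:
        return struct.unpack_from("<HH", self.buf, self.pos)

    @property
    def exhausted(self) -> bool:
        return self.pos >= len(self.buf)


def _parse_sequence(r: _Reader, length: int) -> list[Dataset]:
    items: list[Dataset] = []
    end = None if length == 0xFFFFFFFF else r.pos + length
    while (end is None and not r.exhausted) or (end is not None and r.pos < end):
        tag = struct.unpack("<HH", r.read(4))
        item_len, = struct.unpack("<I", r.read(4))
        if tag == _SEQ_DELIM:
            break
        if tag != _ITEM:
            raise FormatError(f"expected sequence item, got tag {tag}")
        if item_len == 0xFFFFFFFF:
            items.append(_parse_dataset(r, stop_at_item_delim=True))
        else:
            items.append(_parse_dataset(_Reader(r.read(item_len))))
    return items


def _parse_dataset(r: _Reader, stop_at_item_delim: bool = False) -> Dataset:
    ds: Dataset = {}
    while not r.exhausted:
        if stop_at_item_delim and r.peek_tag() == _ITEM_DELIM:
            r.read(8)
            break
        group, elem = struct.unpack("<HH", r.read(4))
        vr = r.read(2).decode("ascii")
        if vr in _LONG_VRS:
            r.read(2)
            length, = struct.unpack("<I", r.read(4))
        else:
            length, = struct.unpack("<H", r.read(2))
        if vr == "SQ":
            ds[(group, elem)] = ("SQ", _parse_sequence(r, length))
        else:
            if length == 0xFFFFFFFF:
                raise FormatError("undefined length outside a sequence")
            ds[(group, elem)] = (vr, _decode_value(vr, r.read(length)))
    return ds


def read_file(path: str) -> Dataset:
    """Read a part-10 explicit-VR-little-endian file into a tag-keyed dict."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise FormatError(f"{path}: not a part-10 DICOM file")
    r = _Reader(buf, 132)
    # file meta group (always explicit VR LE)
    group, elem = struct.unpack("<HH", r.read(4))
    if (group, elem) != (0x0002, 0x0000):
        raise FormatError("missing file meta group length")
    r.read(2 + 2)  # VR UL + 2-byte length
    meta_len, = struct.unpack("<I", r.read(4))
    meta = _parse_dataset(_Reader(r.read(meta_len)))
    ts = meta.get((0x0002, 0x0010), (None, None))[1]
    if ts != EXPLICIT_VR_LE:
        raise FormatError(
            f"unsupported transfer syntax {ts!r} (only explicit VR LE)"
        )
    return _parse_dataset(r)


def value(ds: Dataset, tag: Tag, default: Any = None) -> Any:
    entry = ds.get(tag)
    return default if entry is None else entry[1]
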