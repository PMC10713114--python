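"""FCS 3.0/3.1 reading and writing, channel subsetting/renaming, checkpoints.

The reader honors ``$DATATYPE`` (F/D/I), ``$BYTEORD``, ``$PnB`` and
``$PnR`` and cross-checks the declared event count (``$TOT``) against the
number of rows actually decodable from the DATA segment.  The writer
emits a single unambiguous dialect: FCS 3.1, ``$DATATYPE=F`` (float32),
little-endian, one data segment, list mode.

Checkpoints persist a whole :class:`~cytopipe.model.Dataset` — events,
tags, keywords, provenance — to a single self-describing, versioned
container (a zip of .npy arrays plus a JSON manifest) and restore it
bit-exactly.
"""

from __future__ import annotations

import io
import json
import re
import struct
import zipfile
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ChannelLookupError,
    DimensionError,
    IntegrityError,
    UnsupportedFormatError,
)
from .model import ChannelInfo, Dataset, Sample

__all__ = [
    "read_fcs",
    "write_fcs",
    "subset_rename",
    "save_checkpoint",
    "load_checkpoint",
    "read_sample_sheet",
]

_SUPPORTED_VERSIONS = ("FCS3.0", "FCS3.1")
CHECKPOINT_VERSION = 1

# time/scatter channels are recognized by conventional $PnN prefixes
_ROLE_PATTERNS = (
    (re.compile(r"^time$", re.IGNORECASE), "time"),
    (re.compile(r"^(FSC|SSC)", re.IGNORECASE), "scatter"),
)


def _infer_role(short_name: str) -> str:
    for pat, role in _ROLE_PATTERNS:
        if pat.match(short_name):
            return role
    return "fluorescence"


# ---------------------------------------------------------------------------
# reading


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise IntegrityError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    # the final delimiter is optional in the wild; strip it if present
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise IntegrityError("TEXT segment has an odd number of delimited fields")
    text = {}
    for i in range(0, len(parts), 2):
        key = parts[i].decode("utf-8", errors="replace").strip()
        val = parts[i + 1].decode("utf-8", errors="replace").strip()
        if key:
            text[key] = val
    return text


def _byte_order(text: Mapping[str, str]) -> str:
    byteord = text.get("$BYTEORD", "1,2,3,4").replace(" ", "")
    if byteord in ("1,2,3,4", "1,2"):
        return "<"
    if byteord in ("4,3,2,1", "2,1"):
        return ">"
    raise UnsupportedFormatError(f"unsupported $BYTEORD {byteord!r}")


def _int_mask(pnr: int) -> int:
    # integer data are masked to the next power of two covering $PnR
    bits = max(1, int(np.ceil(np.log2(max(pnr, 2)))))
    return (1 << bits) - 1


def read_fcs(path: str | Path) -> Sample:
    """Read one FCS 3.0/3.1 file into a :class:`Sample`.

    Raises
    ------
    UnsupportedFormatError
        If the file does not declare FCS version 3.0 or 3.1.
    IntegrityError
        If the declared ``$TOT`` disagrees with the number of decodable
        rows, or the TEXT segment is malformed.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 58:
        raise IntegrityError(f"{path}: file too short to hold an FCS header")
    version = raw[0:6].decode("ascii", errors="replace")
    if version not in _SUPPORTED_VERSIONS:
        raise UnsupportedFormatError(
            f"{path}: declares {version!r}; only FCS 3.0/3.1 are supported"
        )

    def _offset(lo: int, hi: int) -> int:
        field = raw[lo:hi].decode("ascii", errors="replace").strip()
        return int(field) if field else 0

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)

    text = _parse_text_segment(raw[text_start : text_end + 1])

    # large files put 0 in the header and real offsets in TEXT
    if data_start == 0 or data_end == 0:
        data_start = int(text.get("$BEGINDATA", "0"))
        data_end = int(text.get("$ENDDATA", "0"))
    if data_end <= data_start:
        raise IntegrityError(f"{path}: no DATA segment located")

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F").upper()
    order = _byte_order(text)
    data = raw[data_start : data_end + 1]

    bits = [int(text[f"$P{i}B"]) for i in range(1, n_par + 1)]
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise UnsupportedFormatError("$DATATYPE=F requires $PnB=32 for all parameters")
        bytes_per_event = 4 * n_par
        n_rows = len(data) // bytes_per_event
        if n_rows != n_tot:
            raise IntegrityError(
                f"{path}: $TOT declares {n_tot} events but DATA segment decodes "
                f"{n_rows} rows"
            )
        events = np.frombuffer(
            data[: n_rows * bytes_per_event], dtype=f"{order}f4"
        ).reshape(n_rows, n_par)
    elif datatype == "D":
        if any(b != 64 for b in bits):
            raise UnsupportedFormatError("$DATATYPE=D requires $PnB=64 for all parameters")
        bytes_per_event = 8 * n_par
        n_rows = len(data) // bytes_per_event
        if n_rows != n_tot:
            raise IntegrityError(
                f"{path}: $TOT declares {n_tot} events but DATA segment decodes "
                f"{n_rows} rows"
            )
        events = np.frombuffer(
            data[: n_rows * bytes_per_event], dtype=f"{order}f8"
        ).reshape(n_rows, n_par)
    elif datatype == "I":
        if any(b % 8 != 0 or b > 64 for b in bits):
            raise UnsupportedFormatError(
                "$DATATYPE=I supports only byte-aligned $PnB up to 64"
            )
        bytes_per_event = sum(b // 8 for b in bits)
        n_rows = len(data) // bytes_per_event
        if n_rows != n_tot:
            raise IntegrityError(
                f"{path}: $TOT declares {n_tot} events but DATA segment decodes "
                f"{n_rows} rows"
            )
        events = np.empty((n_rows, n_par), dtype=np.float64)
        offset = 0
        buf = data[: n_rows * bytes_per_event]
        for j, b in enumerate(bits):
            width = b // 8
            dtype = {1: "u1", 2: "u2", 4: "u4", 8: "u8"}.get(width)
            if dtype is None:
                raise UnsupportedFormatError(f"unsupported integer width {b} bits")
            col = np.ndarray(
                (n_rows,),
                dtype=f"{order}{dtype}",
                buffer=buf,
                offset=offset,
                strides=(bytes_per_event,),
            )
            pnr = int(float(text.get(f"$P{j + 1}R", str(1 << b))))
            events[:, j] = col & _int_mask(pnr)
            offset += width
    else:
        raise UnsupportedFormatError(f"unsupported $DATATYPE {datatype!r}")

    channels = []
    for i in range(1, n_par + 1):
        short = text.get(f"$P{i}N", f"P{i}")
        label = text.get(f"$P{i}S", short) or short
        channels.append(ChannelInfo(short, label, _infer_role(short), i))

    sample = Sample(
        sample_id=path.stem,
        events=np.ascontiguousarray(events, dtype=np.float64),
        channels=channels,
        keywords=text,
    )
    sample.log("read_fcs", path=str(path), version=version, datatype=datatype)
    return sample


# ---------------------------------------------------------------------------
# writing


def write_fcs(
    sample: Sample,
    path: str | Path,
    extra_channels: Mapping[str, np.ndarray] | None = None,
) -> Path:
    """Write a sample as FCS 3.1, float32, little-endian, single data segment.

    ``extra_channels`` appends derived columns (e.g. UMAP coordinates or
    cluster labels) after the panel channels, so the exported file can be
    opened for further manual analysis in conventional software.
    """
    path = Path(path)
    extra = {}
    for name, vec in (extra_channels or {}).items():
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != (sample.n_events,):
            raise DimensionError(
                f"extra channel {name!r} has length {vec.shape}, "
                f"expected ({sample.n_events},)"
            )
        extra[name] = vec

    matrix = sample.events
    if extra:
        matrix = np.column_stack([matrix] + list(extra.values()))
    matrix32 = np.ascontiguousarray(matrix, dtype="<f4")
    n_tot, n_par = matrix32.shape
    data_bytes = matrix32.tobytes()

    names = [(c.short_name, c.label) for c in sample.channels]
    names += [(name, name) for name in extra]

    def build_text(begin_data: int, end_data: int) -> bytes:
        kv: list[tuple[str, str]] = [
            ("$BEGINANALYSIS", "0"),
            ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"),
            ("$ENDSTEXT", "0"),
            ("$BEGINDATA", str(begin_data)),
            ("$ENDDATA", str(end_data)),
            ("$DATATYPE", "F"),
            ("$MODE", "L"),
            ("$BYTEORD", "1,2,3,4"),
            ("$NEXTDATA", "0"),
            ("$TOT", str(n_tot)),
            ("$PAR", str(n_par)),
        ]
        for i, (short, label) in enumerate(names, start=1):
            col_max = float(np.max(matrix32[:, i - 1])) if n_tot else 0.0
            pnr = sample.keywords.get(f"$P{i}R") if i <= sample.n_channels else None
            kv.append((f"$P{i}N", short))
            kv.append((f"$P{i}S", label))
            kv.append((f"$P{i}B", "32"))
            kv.append((f"$P{i}E", "0,0"))
            kv.append((f"$P{i}R", pnr or str(int(np.ceil(max(col_max, 1.0))))))
        if "$SPILLOVER" in sample.keywords:
            kv.append(("$SPILLOVER", sample.keywords["$SPILLOVER"]))
        elif "SPILL" in sample.keywords:
            kv.append(("SPILL", sample.keywords["SPILL"]))
        delim = "/"
        parts = [delim]
        for k, v in kv:
            parts.append(f"{k}{delim}{v if v != '' else ' '}{delim}")
        return "".join(parts).encode("utf-8")

    # two-pass: TEXT length depends on the data offsets it embeds
    header_len = 58
    text = build_text(0, 0)
    for _ in range(4):
        text_start = header_len
        text_end = text_start + len(text) - 1
        begin_data = text_end + 1
        end_data = begin_data + len(data_bytes) - 1
        new_text = build_text(begin_data, end_data)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    else:  # pragma: no cover - offset widths stabilize within two passes
        raise RuntimeError("TEXT segment offsets failed to stabilize")

    text_start = header_len
    text_end = text_start + len(text) - 1
    begin_data = text_end + 1
    end_data = begin_data + len(data_bytes) - 1

    def fmt(n: int) -> bytes:
        s = str(n)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + fmt(text_start) + fmt(text_end)
    if end_data <= 99_999_999:
        header += fmt(begin_data) + fmt(end_data)
    else:
        header += fmt(0) + fmt(0)
    header += fmt(0) + fmt(0)  # no analysis segment
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data_bytes)
    return path


# ---------------------------------------------------------------------------
# panel subsetting / renaming


def subset_rename(
    dataset: Dataset,
    keep: Sequence[str],
    rename: Mapping[str, str] | None = None,
) -> Dataset:
    """Restrict the panel to ``keep`` (by $PnN short name, in that order)
    and relabel channels per ``rename``.

    Time and scatter parameters are conventionally dropped here, keeping
    only the fluorescence/metal channels used downstream.  Event values
    are untouched; only columns are selected and reordered.
    """
    rename = dict(rename or {})
    panel_short = [c.short_name for c in dataset.panel]
    for name in keep:
        if name not in panel_short:
            raise ChannelLookupError(
                f"channel {name!r} not in panel; available: {panel_short}"
            )
    unknown = set(rename) - set(keep)
    if unknown:
        raise ChannelLookupError(f"rename keys {sorted(unknown)} not in keep list")

    new_samples = []
    for s in dataset.samples:
        idx = [panel_short.index(name) for name in keep]
        channels = []
        for pos, name in enumerate(keep, start=1):
            old = s.channels[panel_short.index(name)]
            channels.append(
                ChannelInfo(old.short_name, rename.get(name, old.label), old.role, pos)
            )
        ns = Sample(
            sample_id=s.sample_id,
            events=s.events[:, idx].copy(),
            channels=channels,
            group=s.group,
            tags={k: v.copy() for k, v in s.tags.items()},
            keywords=dict(s.keywords),
            provenance=[dict(p) for p in s.provenance],
        )
        ns.log("subset_rename", keep=list(keep), rename=rename)
        new_samples.append(ns)
    return Dataset(new_samples, dict(dataset.groups))


# ---------------------------------------------------------------------------
# checkpoints


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def save_checkpoint(dataset: Dataset, path: str | Path) -> Path:
    """Persist a dataset to a single versioned container file.

    The container is a zip holding one .npy per array (events and tags)
    plus a JSON manifest with channels, keywords, groups and provenance.
    ``load_checkpoint(save_checkpoint(d))`` is bit-exact.
    """
    path = Path(path)
    manifest: dict = {
        "format": "cytopipe-checkpoint",
        "version": CHECKPOINT_VERSION,
        "groups": dataset.groups,
        "samples": [],
    }
    arrays: dict[str, np.ndarray] = {}
    for i, s in enumerate(dataset.samples):
        arrays[f"events_{i}"] = s.events
        tag_keys = {}
        for j, (name, vec) in enumerate(s.tags.items()):
            arrays[f"tag_{i}_{j}"] = np.asarray(vec)
            tag_keys[name] = f"tag_{i}_{j}"
        manifest["samples"].append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "channels": [
                    {"short_name": c.short_name, "label": c.label, "role": c.role, "index": c.index}
                    for c in s.channels
                ],
                "keywords": s.keywords,
                "provenance": s.provenance,
                "tags": tag_keys,
            }
        )
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, default=_json_default))
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, arr, allow_pickle=False)
            zf.writestr(name + ".npy", buf.getvalue())
    return path


def load_checkpoint(path: str | Path) -> Dataset:
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            if manifest.get("format") != "cytopipe-checkpoint":
                raise IntegrityError(f"{path}: not a cytopipe checkpoint")
            if manifest.get("version") != CHECKPOINT_VERSION:
                raise IntegrityError(
                    f"{path}: checkpoint version {manifest.get('version')} "
                    f"not supported (expected {CHECKPOINT_VERSION})"
                )
            samples = []
            for entry in manifest["samples"]:
                events = np.load(io.BytesIO(zf.read("events_" + str(len(samples)) + ".npy")))
                tags = {
                    name: np.load(io.BytesIO(zf.read(key + ".npy")))
                    for name, key in entry["tags"].items()
                }
                samples.append(
                    Sample(
                        sample_id=entry["sample_id"],
                        events=events,
                        channels=[ChannelInfo(**c) for c in entry["channels"]],
                        group=entry["group"],
                        tags=tags,
                        keywords=entry["keywords"],
                        provenance=entry["provenance"],
                    )
                )
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, EOFError, ValueError) as exc:
        if isinstance(exc, IntegrityError):
            raise
        raise IntegrityError(f"{path}: corrupted or truncated checkpoint ({exc})") from exc
    return Dataset(samples, manifest["groups"])


# ---------------------------------------------------------------------------
# sample sheets


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a delimited sample sheet with columns sample_id, group, path."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "group", "path"}
    missing = required - set(df.columns)
    if missing:
        raise IntegrityError(f"sample sheet missing columns: {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def read_dataset(sheet: str | Path | pd.DataFrame) -> Dataset:
    """Load every FCS file listed in a sample sheet into a Dataset."""
    df = sheet if isinstance(sheet, pd.DataFrame) else read_sample_sheet(sheet)
    samples, groups = [], {}
    for row in df.itertuples(index=False):
        s = read_fcs(row.path)
        s.sample_id = str(row.sample_id)
        s.group = str(row.group)
        groups[s.sample_id] = s.group
        samples.append(s)
    return Dataset(samples, groups)
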