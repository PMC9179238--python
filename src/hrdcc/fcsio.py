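"""Minimal FCS 3.1 reading and writing.

Implements the subset of the FCS 3.1 standard this package needs: list-mode
(``$MODE L``) single-dataset files with 32-bit little-endian float data
(``$DATATYPE F``).  Hidden truth labels are never written into the FCS
file itself; they go to a ``*_truth.csv`` sidecar keyed by event index.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventMatrix

_DELIM = "/"
_HEADER_LEN = 58  # "FCS3.1" + 4 spaces + 6 x 8-char offsets


class FCSError(ValueError):
    """Raised for unreadable, truncated, or malformed FCS files."""


def _text_segment(pairs: dict[str, str]) -> bytes:
    parts = [""]
    for key, value in pairs.items():
        parts.append(key)
        parts.append(str(value))
    return (_DELIM.join(parts) + _DELIM).encode("ascii")


def write_fcs(em: EventMatrix, path: str | Path) -> Path:
    """Write an :class:`EventMatrix` as an FCS 3.1 file.

    Truth labels, if present, are written to ``<stem>_truth.csv`` next to
    the FCS file with columns (event_index, label).
    """
    path = Path(path)
    if em.n_events == 0:
        raise FCSError("refusing to write an empty EventMatrix")
    values = em.data.to_numpy(dtype=np.float32)
    if not np.all(np.isfinite(values)):
        raise FCSError("event matrix contains non-finite values")
    n_events, n_par = values.shape
    data_bytes = values.astype("<f4").tobytes()

    pairs: dict[str, str] = {
        "$FIL": path.name,
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(em.channels, start=1):
        pairs[f"$P{i}N"] = name
        pairs[f"$P{i}B"] = "32"
        pairs[f"$P{i}E"] = "0,0"
        pairs[f"$P{i}R"] = str(int(max(1.0, np.ceil(float(values[:, i - 1].max())))))

    # two-pass layout: offsets depend on the text length
    begin_text = _HEADER_LEN
    for _ in range(3):
        text = _text_segment({**pairs})
        begin_data = begin_text + len(text)
        end_data = begin_data + len(data_bytes) - 1
        pairs["$BEGINDATA"] = str(begin_data)
        pairs["$ENDDATA"] = str(end_data)
        text = _text_segment(pairs)
        new_begin_data = begin_text + len(text)
        if new_begin_data == begin_data:
            break
        begin_data = new_begin_data

    end_text = begin_text + len(text) - 1
    header = (b"FCS3.1    "
              + f"{begin_text:>8d}".encode()
              + f"{end_text:>8d}".encode()
              + f"{begin_data:>8d}".encode()
              + f"{end_data:>8d}".encode()
              + f"{0:>8d}".encode() + f"{0:>8d}".encode())
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data_bytes)

    if em.truth_labels is not None:
        sidecar = path.with_name(path.stem + "_truth.csv")
        pd.DataFrame({"event_index": np.arange(em.n_events),
                      "label": em.truth_labels}).to_csv(sidecar, index=False)
    return path


def read_fcs(path: str | Path, load_truth: bool = True) -> EventMatrix:
    """Read an FCS 3.0/3.1 float list-mode file written by this package
    (or any compliant file using ``$DATATYPE F``)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_LEN:
        raise FCSError(f"{path}: truncated header (file length {len(raw)} < {_HEADER_LEN})")
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise FCSError(f"{path}: unsupported FCS version {version!r} at offset 0")
    try:
        begin_text = int(raw[10:18]); end_text = int(raw[18:26])
        begin_data = int(raw[26:34]); end_data = int(raw[34:42])
    except ValueError as exc:
        raise FCSError(f"{path}: unparseable segment offsets at offset 10") from exc
    if end_text >= len(raw):
        raise FCSError(f"{path}: TEXT segment exceeds file size at offset {end_text}")

    text = raw[begin_text:end_text + 1].decode("ascii", errors="replace")
    delim = text[0]
    tokens = text[1:].split(delim)
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    kv = {tokens[i]: tokens[i + 1] for i in range(0, len(tokens) - 1, 2)}

    if kv.get("$DATATYPE") != "F":
        raise FCSError(f"{path}: only $DATATYPE F is supported, got {kv.get('$DATATYPE')!r}")
    n_par = int(kv["$PAR"]); n_tot = int(kv["$TOT"])
    begin_data = int(kv.get("$BEGINDATA", begin_data))
    end_data = int(kv.get("$ENDDATA", end_data))
    expected = n_par * n_tot * 4
    blob = raw[begin_data:end_data + 1]
    if len(blob) < expected:
        raise FCSError(
            f"{path}: DATA segment truncated at offset {begin_data + len(blob)} "
            f"(expected {expected} bytes, found {len(blob)})")
    byteord = kv.get("$BYTEORD", "1,2,3,4")
    dtype = "<f4" if byteord.startswith("1") else ">f4"
    values = np.frombuffer(blob[:expected], dtype=dtype).reshape(n_tot, n_par)
    names = [kv.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    data = pd.DataFrame(np.asarray(values, dtype=np.float64), columns=names)

    labels = None
    sidecar = path.with_name(path.stem + "_truth.csv")
    if load_truth and sidecar.exists():
        truth = pd.read_csv(sidecar)
        labels = truth.sort_values("event_index")["label"].to_numpy()
    return EventMatrix(path.stem, data, labels, {"path": str(path), "keywords": kv})
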