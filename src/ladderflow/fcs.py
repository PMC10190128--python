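"""Minimal FCS 3.1 writer and reader.

Writes per-event parameter tables as list-mode, little-endian float32 FCS
files and reads them back.  Only the subset of the standard that a
downstream cytometry tool needs to ingest the export is implemented:
HEADER, a single TEXT segment with the required keywords, and a DATA
segment; no ANALYSIS segment, no supplemental TEXT.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_fcs", "read_fcs"]

_DELIM = "/"


def _text_segment(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for k, v in keywords.items():
        parts.append(f"{k}{_DELIM}{v}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(path: Path | str, data: np.ndarray,
              parameter_names: list[str],
              extra_keywords: dict[str, str] | None = None) -> Path:
    """Write an (events, parameters) float array as an FCS 3.1 file."""
    data = np.atleast_2d(np.asarray(data, dtype="<f4"))
    n_events, n_par = data.shape
    if n_events < 1:
        raise ValueError("cannot export an FCS file with zero events")
    if len(parameter_names) != n_par:
        raise ValueError("one parameter name per column required")

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par), "$TOT": str(n_events),
    }
    for i, name in enumerate(parameter_names, start=1):
        rng = max(float(np.max(data[:, i - 1])), 1.0)
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(np.ceil(rng)) + 1)
    keywords.update(extra_keywords or {})

    header_len = 58  # "FCS3.1" + 4 spaces + 6 x 8-char offsets
    # iterate because BEGINDATA/ENDDATA lengths feed back into TEXT length
    begin_data, end_data = 0, 0
    for _ in range(4):
        keywords["$BEGINDATA"] = str(begin_data)
        keywords["$ENDDATA"] = str(end_data)
        text = _text_segment(keywords)
        text_begin = header_len
        text_end = text_begin + len(text) - 1
        new_begin = text_end + 1
        new_end = new_begin + data.nbytes - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end

    header = (
        "FCS3.1    "
        + f"{text_begin:>8d}" + f"{text_end:>8d}"
        + f"{begin_data:>8d}" + f"{end_data:>8d}"
        + f"{0:>8d}" + f"{0:>8d}"
    ).encode("ascii")
    assert len(header) == header_len

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())
    return path


def read_fcs(path: Path | str) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Read an FCS file written by :func:`write_fcs`.

    Returns (data, parameter_names, keywords).
    """
    raw = Path(path).read_bytes()
    if not raw[:6] == b"FCS3.1":
        raise ValueError("not an FCS 3.1 file")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_begin:text_end + 1].decode("ascii")
    delim = text[0]
    fields = text[1:].split(delim)
    keywords = {fields[i]: fields[i + 1]
                for i in range(0, len(fields) - 1, 2)}

    n_par = int(keywords["$PAR"])
    n_events = int(keywords["$TOT"])
    begin_data = int(keywords["$BEGINDATA"])
    if keywords.get("$DATATYPE") != "F":
        raise ValueError("only $DATATYPE F supported")
    dtype = "<f4" if keywords.get("$BYTEORD", "1,2,3,4") == "1,2,3,4" else ">f4"
    data = np.frombuffer(raw, dtype=dtype, count=n_events * n_par,
                         offset=begin_data).reshape(n_events, n_par)
    names = [keywords[f"$P{i}N"] for i in range(1, n_par + 1)]
    return data.astype(float), names, keywords
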