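"""Text-file exchange between the optimizer and the instrument side.

The two sides communicate through two ASCII files in a shared directory:

* the parameter file, written by the optimizer — one ``name=value`` line per
  tuning parameter plus a ``seq=N`` request sequence number;
* the intensity-result file, written by the instrument side — one line per
  peak of the form ``mass=..., intensity=..., fwhm=..., mass_error=...``
  plus the echoed ``seq=N``.

A reader polls its file until the sequence number advances past the last one
it saw, or a timeout elapses.
"""

from __future__ import annotations

import os
import time
from typing import Mapping, Sequence

__all__ = [
    "ProtocolError",
    "ProtocolTimeout",
    "write_params",
    "read_params",
    "write_intensities",
    "read_intensities",
    "wait_for_sequence",
]


class ProtocolError(ValueError):
    """Malformed exchange file."""


class ProtocolTimeout(TimeoutError):
    """The peer did not produce a newer sequence number in time."""


def write_params(path: str, params: Mapping[str, float], seq: int) -> None:
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        for name, value in params.items():
            fh.write(f"{name}={value!r}\n")
        fh.write(f"seq={int(seq)}\n")
    os.replace(tmp, path)  # atomic publish so readers never see partial files


def read_params(path: str) -> tuple[dict[str, float], int]:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ProtocolError(f"{path}: empty parameter file")
    params: dict[str, float] = {}
    seq: int | None = None
    for ln in lines:
        if "=" not in ln:
            raise ProtocolError(f"{path}: malformed line {ln!r}")
        name, _, value = ln.partition("=")
        name = name.strip()
        try:
            if name == "seq":
                seq = int(value)
            else:
                params[name] = float(value)
        except ValueError:
            raise ProtocolError(f"{path}: malformed line {ln!r}") from None
    if seq is None:
        raise ProtocolError(f"{path}: missing seq line")
    return params, seq


def write_intensities(path: str, peaks: Sequence[Mapping[str, float]], seq: int) -> None:
    """``peaks`` rows need keys mass, intensity, fwhm, mass_error."""
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        for row in peaks:
            fh.write(
                "mass={mass!r}, intensity={intensity!r}, "
                "fwhm={fwhm!r}, mass_error={mass_error!r}\n".format(**row)
            )
        fh.write(f"seq={int(seq)}\n")
    os.replace(tmp, path)


def read_intensities(path: str) -> tuple[list[dict[str, float]], int]:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ProtocolError(f"{path}: empty intensity file")
    peaks: list[dict[str, float]] = []
    seq: int | None = None
    for ln in lines:
        if ln.startswith("seq="):
            try:
                seq = int(ln[4:])
            except ValueError:
                raise ProtocolError(f"{path}: malformed line {ln!r}") from None
            continue
        row: dict[str, float] = {}
        for item in ln.split(","):
            if "=" not in item:
                raise ProtocolError(f"{path}: malformed line {ln!r}")
            key, _, value = item.partition("=")
            try:
                row[key.strip()] = float(value)
            except ValueError:
                raise ProtocolError(f"{path}: malformed line {ln!r}") from None
        missing = {"mass", "intensity", "fwhm", "mass_error"} - row.keys()
        if missing:
            raise ProtocolError(f"{path}: line {ln!r} missing fields {sorted(missing)}")
        peaks.append(row)
    if seq is None:
        raise ProtocolError(f"{path}: missing seq line")
    return peaks, seq


def wait_for_sequence(path, reader, last_seq: int, timeout: float = 5.0,
                      poll: float = 0.05):
    """Poll ``reader(path)`` until its sequence number exceeds ``last_seq``.

    Returns the parsed payload and the new sequence number; raises
    ProtocolTimeout if the peer never advances.
    """
    deadline = time.monotonic() + timeout
    while True:
        if os.path.exists(path):
            try:
                payload, seq = reader(path)
            except ProtocolError:
                payload, seq = None, last_seq  # partially written; retry
            if seq > last_seq:
                return payload, seq
        if time.monotonic() >= deadline:
            raise ProtocolTimeout(
                f"{path}: no sequence newer than {last_seq} within {timeout} s"
            )
        time.sleep(poll)
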