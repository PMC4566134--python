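"""SHELX HKLF4 fixed-width reflection files.

Each record is ``%4d%4d%4d%8.2f%8.2f`` (h, k, l, intensity, sigma); the file
is terminated by an all-zero record.  This is the only reflection exchange
format the package speaks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_shelx_hkl", "read_shelx_hkl", "format_hkl_record"]


class ShelxFormatError(ValueError):
    pass


def format_hkl_record(h: int, k: int, l: int, intensity: float, sigma: float) -> str:
    for name, idx in (("h", h), ("k", k), ("l", l)):
        if not (-999 <= idx <= 999):
            raise ShelxFormatError(f"index {name}={idx} overflows the 4-column field")
    line = f"{h:4d}{k:4d}{l:4d}{intensity:8.2f}{sigma:8.2f}"
    if len(line) != 28:
        raise ShelxFormatError(
            f"record ({h},{k},{l}, I={intensity}, sigma={sigma}) overflows its field widths"
        )
    return line


def write_shelx_hkl(path, hkl, intensity, sigma) -> None:
    hkl = np.asarray(hkl, dtype=int)
    intensity = np.asarray(intensity, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    with open(path, "w") as fh:
        for (h, k, l), ival, sval in zip(hkl, intensity, sigma):
            fh.write(format_hkl_record(int(h), int(k), int(l), ival, sval) + "\n")
        fh.write(format_hkl_record(0, 0, 0, 0.0, 0.0) + "\n")


def read_shelx_hkl(path):
    """Read an HKLF4 file; returns (hkl (n,3) int, I (n,), sigma (n,))."""
    hkl, ivals, svals = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                h = int(line[0:4])
                k = int(line[4:8])
                l = int(line[8:12])
                ival = float(line[12:20])
                sval = float(line[20:28])
            except ValueError as exc:
                raise ShelxFormatError(f"{path}:{lineno}: malformed record") from exc
            if h == 0 and k == 0 and l == 0:
                break
            hkl.append((h, k, l))
            ivals.append(ival)
            svals.append(sval)
    return (
        np.array(hkl, dtype=int).reshape(-1, 3),
        np.array(ivals),
        np.array(svals),
    )
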