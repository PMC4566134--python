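"""Line-oriented text format for serial-snapshot pattern streams.

A stream file is a sequence of blocks::

    BEGIN_PATTERN <id>
    h k l I sigma
    ...
    END_PATTERN

This is a deliberately simplified analog of a serial-crystallography stream
file: one block per indexed snapshot, one partial-intensity record per line.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["write_stream", "read_stream"]


class StreamFormatError(ValueError):
    pass


def write_stream(path, stream) -> None:
    """Write a PatternStream (see sirasfx.simulate) to a text file."""
    df = stream.records
    with open(path, "w") as fh:
        for pid, group in df.groupby("pattern_id", sort=True):
            fh.write(f"BEGIN_PATTERN {pid}\n")
            for h, k, l, i, s in zip(group.h, group.k, group.l, group.I, group.sigma):
                fh.write(f"{h} {k} {l} {i:.4f} {s:.4f}\n")
            fh.write("END_PATTERN\n")


def read_stream(path):
    from ..simulate import PatternStream

    rows = []
    current = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "BEGIN_PATTERN":
                if current is not None:
                    raise StreamFormatError(f"line {lineno}: nested BEGIN_PATTERN")
                current = int(parts[1])
            elif parts[0] == "END_PATTERN":
                if current is None:
                    raise StreamFormatError(f"line {lineno}: END_PATTERN without BEGIN")
                current = None
            else:
                if current is None:
                    raise StreamFormatError(f"line {lineno}: record outside a pattern block")
                if len(parts) != 5:
                    raise StreamFormatError(f"line {lineno}: expected 'h k l I sigma'")
                rows.append(
                    (current, int(parts[0]), int(parts[1]), int(parts[2]),
                     float(parts[3]), float(parts[4]))
                )
    if current is not None:
        raise StreamFormatError("unterminated pattern block at end of file")
    df = pd.DataFrame(rows, columns=["pattern_id", "h", "k", "l", "I", "sigma"])
    return PatternStream(records=df)
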