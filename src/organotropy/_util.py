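"""Small shared helpers."""

from __future__ import annotations

import hashlib
import math
from pathlib import Path


def round_half_away(x: float) -> int:
    """Round to the closest integer, halves away from zero.

    Avoids banker's rounding: round_half_away(8.5) == 9, round_half_away(-8.5) == -9.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_id_list(ids, path: str | Path) -> None:
    """One identifier per line."""
    Path(path).write_text("\n".join(str(i) for i in ids) + "\n")


def read_id_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
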