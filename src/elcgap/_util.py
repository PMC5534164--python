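"""Small shared helpers: rounding convention and seed derivation."""

from __future__ import annotations

import math
import zlib

EARTH_RADIUS_KM = 6371.0088


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going away from zero (half-up).

    All integer percentages and count rules in this package use this convention
    (e.g. 20.6 -> 21, 1.6 -> 2, 2.5 -> 3), not banker's rounding.
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def pct(part: float, whole: float) -> int:
    """Integer percentage of `part` in `whole`, rounded half-up."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total is undefined")
    return round_half_up(100.0 * part / whole)


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from one master seed.

    Uses a CRC32 of the stage label mixed into the master seed so every stage
    of the pipeline can be rerun independently with a reproducible stream.
    """
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode("utf-8"))) % (2**31)
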