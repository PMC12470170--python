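"""Small shared helpers: seed derivation and DNA utilities."""

from __future__ import annotations

import zlib

import numpy as np

BASES = "ACGT"


def derive_seed(*parts) -> int:
    """Derive a stable 31-bit seed from arbitrary string/int parts.

    CRC32 is stable across platforms and Python versions, unlike ``hash``.
    """
    payload = ":".join(str(p) for p in parts).encode()
    return zlib.crc32(payload) & 0x7FFFFFFF


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))
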