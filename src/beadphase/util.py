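"""Small shared helpers: seeded RNG streams and sequence encoding."""

from __future__ import annotations

import zlib

import numpy as np

ALPHABET = "ACGT"

# ASCII byte -> base index lookup (255 marks a non-ACGT byte)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible random stream for a named pipeline stage.

    The stream is keyed by (seed, crc32(stage)) so adding or reordering
    stages never perturbs the draws of the others.
    """
    return np.random.default_rng([int(seed), zlib.crc32(stage.encode())])


def encode_seq(seq: str) -> np.ndarray:
    """Nucleotide string -> uint8 array of base indices (A=0..T=3)."""
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        raise ValueError(f"sequence contains non-ACGT characters: {seq!r}")
    return arr


def encode_seq_lenient(seq: str) -> np.ndarray:
    """Like :func:`encode_seq` but maps non-ACGT bytes to 255 instead of
    raising, so they mismatch every reference base."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_seq(arr: np.ndarray) -> str:
    """Inverse of :func:`encode_seq`."""
    return _DECODE[arr].tobytes().decode()


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniformly random ACGT string."""
    return decode_seq(rng.integers(0, 4, size=length, dtype=np.uint8))
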