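"""Base encoding and the tagged-read container shared across modules.

Sequences are held internally as ``uint8`` code arrays (A=0, C=1, G=2, T=3,
N=4); strings are only materialised at I/O boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

BASE_ALPHABET = "ACGTN"
A, C, G, T, N = range(5)

_DECODE = np.frombuffer(BASE_ALPHABET.encode(), dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASE_ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode_seq(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string into a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGTN character in sequence: {bad!r}")
    return codes


def decode_seq(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into a string."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass
class TaggedRead:
    """One raw sequencing read carrying its duplex barcode pair.

    ``orientation`` records the order in which the two molecular tags were
    observed: reads from the two strands of one double-stranded molecule see
    the same pair in opposite order (``ab`` vs ``ba``).
    """

    name: str
    contig: str
    start: int
    end: int
    seq: np.ndarray  # uint8 codes
    tag_a: Optional[str]
    tag_b: Optional[str]
    orientation: str  # "ab" or "ba"
    softclip: bool = False
    fragment_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.seq = np.asarray(self.seq, dtype=np.uint8)

    @property
    def length(self) -> int:
        return int(self.seq.size)

    @property
    def sequence(self) -> str:
        return decode_seq(self.seq)

    def has_tags(self) -> bool:
        return bool(self.tag_a) and bool(self.tag_b)

    def copy(self) -> "TaggedRead":
        return replace(self, seq=self.seq.copy())
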