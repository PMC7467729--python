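"""Small DNA sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: byte-level complement lookup used by the vectorised paths
_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCAtgca"):
    _COMP_TABLE[_a] = _b

BASES = "ACGT"


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return all(c in "ACGT" for c in seq)


def check_dna(seq: str) -> None:
    """Raise ValueError naming the first non-ACGT position, if any."""
    for i, c in enumerate(seq):
        if c not in "ACGT":
            raise ValueError(f"non-ACGT character {c!r} at position {i}")


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA of length n drawn from rng."""
    idx = rng.integers(0, 4, size=n)
    return "".join(BASES[i] for i in idx)


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    return _COMP_TABLE[arr][::-1]
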