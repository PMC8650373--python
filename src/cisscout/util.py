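"""Small sequence and array helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: uint8 codes 0..3 -> A,C,G,T
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings.

    Raises ValueError on unequal lengths; N counts as a mismatch.
    """
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def find_motif_positions(seq: str, motif: str) -> np.ndarray:
    """All 0-based start positions of ``motif`` in ``seq``, overlaps included.

    Vectorised sliding comparison on the byte representation; suitable for
    chromosome-scale strings.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    m = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    k = len(m)
    if len(arr) < k:
        return np.empty(0, dtype=np.int64)
    mask = arr[: len(arr) - k + 1] == m[0]
    for j in range(1, k):
        mask &= arr[j : len(arr) - k + 1 + j] == m[j]
    return np.nonzero(mask)[0].astype(np.int64)


def random_dna(rng: np.random.Generator, length: int) -> str:
    """I.i.d. uniform A/C/G/T string of the given length."""
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return BASES[codes].tobytes().decode("ascii")


def validate_dna(seq: str, name: str = "sequence") -> None:
    if not seq or set(seq) - set("ACGT"):
        raise ValueError(f"{name} must be non-empty uppercase A/C/G/T")
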