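"""Small shared helpers: alphabets, reverse complement, hashing."""

from __future__ import annotations

import hashlib

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ConfigurationError(ValueError):
    """Raised when a user-supplied configuration violates a contract."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """DNA-alphabet string to RNA alphabet (T -> U) for report output."""
    return seq.replace("T", "U").replace("t", "u")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def hamming(a: str, b: str, cutoff: int | None = None) -> int:
    """Mismatch count between equal-length strings; any N counts as a mismatch.

    With a cutoff, returns cutoff+1 as soon as it is exceeded (early exit).
    """
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    d = 0
    for x, y in zip(a, b):
        if x != y or x == "N" or y == "N":
            d += 1
            if cutoff is not None and d > cutoff:
                return d
    return d
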