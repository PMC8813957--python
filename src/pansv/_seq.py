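"""Low-level DNA string helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    """Random DNA of length n with expected GC fraction ``gc``."""
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]  # A C G T
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    n = len(seq) - seq.count("N")
    if n == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / n


def match_len_forward(a: str, b: str, i: int, j: int, limit: int | None = None) -> int:
    """Length of the exact common prefix of a[i:] and b[j:]; N never matches.

    Chunked slice comparison so long anchors do not pay a per-character
    Python loop.
    """
    n = 0
    chunk = 1024
    max_n = min(len(a) - i, len(b) - j)
    if limit is not None:
        max_n = min(max_n, limit)
    while n < max_n:
        step = min(chunk, max_n - n)
        x = a[i + n : i + n + step]
        y = b[j + n : j + n + step]
        if x == y and "N" not in x:
            n += step
            continue
        for t in range(step):
            ca = x[t]
            if ca != y[t] or ca == "N":
                return n + t
        n += step
    return n


def match_len_backward(a: str, b: str, i: int, j: int, limit: int | None = None) -> int:
    """Length of the exact common suffix of a[:i] and b[:j]; N never matches."""
    n = 0
    chunk = 1024
    max_n = min(i, j)
    if limit is not None:
        max_n = min(max_n, limit)
    while n < max_n:
        step = min(chunk, max_n - n)
        x = a[i - n - step : i - n]
        y = b[j - n - step : j - n]
        if x == y and "N" not in x:
            n += step
            continue
        for t in range(1, step + 1):
            ca = a[i - n - t]
            if ca != b[j - n - t] or ca == "N":
                return n + t - 1
        n += step
    return n
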