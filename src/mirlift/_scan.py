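"""Substitution-only (Hamming) sequence scanning primitives.

All higher-level homology operations — full-length stem-loop discovery on a
genome, fuzzy placement of a mature miRNA inside a precursor, read-to-mature
assignment — reduce to the same primitive: count mismatches between a short
query and every same-length window of a longer subject.  Keeping that
primitive in one place makes the whole pipeline's mismatch accounting exact
and auditable.

Encoding: A/C/G/T -> 0..3.  Ambiguity codes in a *subject* encode to 4 and in
a *query* to 5, so an ambiguous base can never match anything (an N in the
genome always counts as a mismatch).
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUacgtuNn", "TGCAAtgcaaNn")

# uint8 lookup tables indexed by character ordinal
_SUBJECT_LUT = np.full(256, 4, dtype=np.uint8)
_QUERY_LUT = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    for _c in (_b, _b.lower()):
        _SUBJECT_LUT[ord(_c)] = _i
        _QUERY_LUT[ord(_c)] = _i
# U behaves as T so RNA-alphabet inputs scan transparently
for _lut in (_SUBJECT_LUT, _QUERY_LUT):
    _lut[ord("U")] = 3
    _lut[ord("u")] = 3


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result is DNA-alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str, query: bool = False) -> np.ndarray:
    """Encode a sequence to uint8 codes; see module docstring for alphabet."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return (_QUERY_LUT if query else _SUBJECT_LUT)[raw]


def ambiguous_fraction(seq: str) -> float:
    """Fraction of characters outside the unambiguous ACGT/U alphabet."""
    if not seq:
        return 0.0
    return float(np.mean(encode(seq, query=True) == 5))


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings (ambiguity ≠ anything)."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return int(np.count_nonzero(encode(a, query=True) != encode(b)))


def mismatch_profile(query: np.ndarray, subject: np.ndarray) -> np.ndarray:
    """Mismatch count of ``query`` against every window of ``subject``.

    Returns an int32 array of length ``len(subject) - len(query) + 1`` whose
    i-th entry is the Hamming distance between the query and
    ``subject[i : i + len(query)]``.  Empty if the subject is shorter than
    the query.
    """
    m, n = len(query), len(subject)
    if n < m or m == 0:
        return np.zeros(0, dtype=np.int32)
    span = n - m + 1
    mm = np.zeros(span, dtype=np.int32)
    for j in range(m):
        mm += subject[j : j + span] != query[j]
    return mm


def scan(query_seq: str, subject_arr: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """All (start, mismatches) placements of the query on one subject strand."""
    prof = mismatch_profile(encode(query_seq, query=True), subject_arr)
    starts = np.nonzero(prof <= max_mm)[0]
    return [(int(s), int(prof[s])) for s in starts]


def best_windows(needle: str, haystack: str) -> tuple[int, list[int]]:
    """Minimum-Hamming same-length placements of ``needle`` in ``haystack``.

    Returns ``(best_mm, offsets)`` with offsets ascending; ``(len(needle),
    [])`` if the haystack is shorter than the needle.
    """
    prof = mismatch_profile(encode(needle, query=True), encode(haystack))
    if prof.size == 0:
        return len(needle), []
    best = int(prof.min())
    return best, [int(i) for i in np.nonzero(prof == best)[0]]
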